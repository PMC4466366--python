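"""Scan/compare report generation, CSV/JSON writers and test fixtures.

CSV is the primary interchange format (RFC 4180 via pandas, shortest
round-trip float formatting, so numeric columns re-read losslessly);
run summaries are JSON; event dumps can optionally go to HDF5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chains import (ChainPhysics, ELECTRON_IONISATION, ELECTRON_EXCITATION,
                     PROTON_IONISATION)
from .errors import ConfigError, DomainError
from .quadrature import total_cross_section
from .dielectric import ConstantELF, DrudeELF
from .electron import RuddElectronParams, PowerLawPhotoXS
from .proton import RuddProtonParams


# ---------------------------------------------------------------------------
# Cross-section scans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanRequest:
    particle: str            # "electron" | "proton"
    process: str             # "ionisation" | "excitation"
    chain: str
    e_min_ev: float
    e_max_ev: float
    points: int
    log: bool = True

    def __post_init__(self) -> None:
        if not self.e_min_ev < self.e_max_ev:
            raise ConfigError("require e_min < e_max")
        if self.points < 2:
            raise ConfigError("require at least 2 grid points")
        if self.particle not in ("electron", "proton"):
            raise ConfigError(f"unknown particle {self.particle!r}")
        if self.process not in ("ionisation", "excitation"):
            raise ConfigError(f"unknown process {self.process!r}")
        if self.particle == "proton" and self.process == "excitation":
            raise ConfigError("no proton excitation model is implemented")

    def grid(self) -> np.ndarray:
        if self.log:
            return np.geomspace(self.e_min_ev, self.e_max_ev, self.points)
        return np.linspace(self.e_min_ev, self.e_max_ev, self.points)


def _channel_iter(physics: ChainPhysics, request: ScanRequest):
    medium = physics.medium
    if request.particle == "electron" and request.process == "ionisation":
        for orb in medium.orbitals:
            yield orb.label, \
                (lambda t, w, o=orb: physics.electron_ionisation_dcs(t, w, o)), \
                (lambda t, o=orb: physics.electron_ionisation_support(t, o))
    elif request.particle == "electron" and request.process == "excitation":
        for lvl in medium.excitation_levels:
            yield lvl.label, \
                (lambda t, w, l=lvl: physics.electron_excitation_dcs(t, w, l)), \
                (lambda t, l=lvl: physics.excitation_support(t, l))
    else:
        for orb in medium.orbitals:
            yield orb.label, \
                (lambda t, w, o=orb: physics.proton_ionisation_dcs(t, w, o)), \
                (lambda t, o=orb: physics.proton_support(t, o))


def channel_total(physics: ChainPhysics, request: ScanRequest, label: str,
                  e_ev: float, tol: float = 1e-6) -> tuple[str, float]:
    """(model id, total cross-section m²) of one channel at one energy."""
    for lbl, dcs_fn, sup_fn in _channel_iter(physics, request):
        if lbl == label:
            holder = {}

            def dcs(w):
                m, v = dcs_fn(e_ev, w)
                holder["m"] = m
                return v

            sig = total_cross_section(dcs, e_ev, sup_fn(e_ev), tol)
            model = holder.get("m") or _model_of(physics, request, e_ev)
            return model, sig
    raise KeyError(label)


def _model_of(physics: ChainPhysics, request: ScanRequest, e_ev: float) -> str:
    process = {("electron", "ionisation"): ELECTRON_IONISATION,
               ("electron", "excitation"): ELECTRON_EXCITATION,
               ("proton", "ionisation"): PROTON_IONISATION}[
                   (request.particle, request.process)]
    return physics.chain.model_for(process, e_ev)


def cmd_scan(request: ScanRequest, physics: ChainPhysics,
             tol: float = 1e-6) -> pd.DataFrame:
    """Total cross-section scan: one row per energy, one sigma column per
    channel plus their sum, the active model id and the chain name."""
    grid = request.grid()
    labels = [lbl for lbl, _, _ in _channel_iter(physics, request)]
    rows = []
    for e in grid:
        row = {"energy_eV": float(e)}
        total = 0.0
        model = _model_of(physics, request, e)
        for lbl in labels:
            m, sig = channel_total(physics, request, lbl, float(e), tol)
            row[f"sigma_{lbl}_m2"] = sig
            total += sig
            if m:
                model = m
        row["sigma_total_m2"] = total
        row["model_id"] = model
        row["chain"] = physics.chain.name
        rows.append(row)
    return pd.DataFrame(rows)


def cmd_compare(chain_a: ChainPhysics, chain_b: ChainPhysics,
                request: ScanRequest, tol: float = 1e-6) -> pd.DataFrame:
    """Per-energy totals under two chains with their ratio (NaN where either
    total is zero)."""
    a = cmd_scan(request, chain_a, tol)
    b = cmd_scan(request, chain_b, tol)
    out = pd.DataFrame({
        "energy_eV": a["energy_eV"],
        "sigma_a_m2": a["sigma_total_m2"],
        "sigma_b_m2": b["sigma_total_m2"],
        "model_a": a["model_id"],
        "model_b": b["model_id"],
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["sigma_a_m2"] / out["sigma_b_m2"]
    ratio[(out["sigma_a_m2"] == 0) | (out["sigma_b_m2"] == 0)] = np.nan
    out["ratio"] = ratio
    return out


def write_curve_csv(df: pd.DataFrame, path) -> None:
    # 17 significant digits: float64 round-trips exactly through the CSV
    df.to_csv(path, index=False, lineterminator="\n",
              float_format=lambda v: format(v, ".17g"))


def read_curve_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Transport reports
# ---------------------------------------------------------------------------

def events_frame(histories) -> pd.DataFrame:
    rows = []
    for hi, h in enumerate(histories):
        for ev in h.events:
            rows.append({
                "history": hi, "generation": ev.generation,
                "channel": ev.channel, "model": ev.model, "label": ev.label,
                "w_ev": ev.w_ev,
                "x_m": ev.position[0], "y_m": ev.position[1],
                "z_m": ev.position[2],
            })
    return pd.DataFrame(rows, columns=[
        "history", "generation", "channel", "model", "label", "w_ev",
        "x_m", "y_m", "z_m"])


def write_events(histories, path, fmt: str = "csv") -> None:
    df = events_frame(histories)
    if fmt == "csv":
        df.to_csv(path, index=False, lineterminator="\n")
    elif fmt == "hdf5":
        import h5py
        with h5py.File(path, "w") as f:
            for col in df.columns:
                data = df[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                f.create_dataset(col, data=data)
    else:
        raise ConfigError(f"unknown event format {fmt!r}")


def run_summary(histories, seed: int, chain: str, config_hash: str) -> dict:
    counts = np.array([h.n_ionisations for h in histories], dtype=float)
    se = float(counts.std(ddof=1) / math.sqrt(len(counts))) \
        if len(counts) > 1 else 0.0
    return {
        "n_histories": len(histories),
        "mean_ionisations": float(counts.mean()),
        "standard_error": se,
        "mean_excitations": float(np.mean([h.n_excitations for h in histories])),
        "seed": seed,
        "chain": chain,
        "config_hash": config_hash,
    }


def write_summary_json(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyDCS:
    """An analytic differential cross-section with closed-form total and CDF
    (the independent oracle for sampler and quadrature tests)."""

    name: str
    support: tuple[float, float]
    fn: Callable
    total: float
    cdf: Callable
    quantile: Callable


def _power_law_toy(norm: float, w_lo: float, w_hi: float) -> ToyDCS:
    """dcs = norm / W² on [w_lo, w_hi]; total = norm (1/lo - 1/hi)."""
    total = norm * (1.0 / w_lo - 1.0 / w_hi)

    def fn(w):
        w = np.asarray(w, dtype=float)
        out = np.where((w >= w_lo) & (w <= w_hi), norm / np.maximum(w, 1e-300) ** 2, 0.0)
        return out if out.ndim else float(out)

    def cdf(w):
        w = np.clip(np.asarray(w, dtype=float), w_lo, w_hi)
        out = (1.0 / w_lo - 1.0 / w) / (1.0 / w_lo - 1.0 / w_hi)
        return out if out.ndim else float(out)

    def quantile(u):
        u = np.asarray(u, dtype=float)
        inv = 1.0 / w_lo - u * (1.0 / w_lo - 1.0 / w_hi)
        out = 1.0 / inv
        return out if out.ndim else float(out)

    return ToyDCS("power_law", (w_lo, w_hi), fn, total, cdf, quantile)


def _uniform_toy(height: float, w_lo: float, w_hi: float) -> ToyDCS:
    total = height * (w_hi - w_lo)

    def fn(w):
        w = np.asarray(w, dtype=float)
        out = np.where((w >= w_lo) & (w <= w_hi), height, 0.0)
        return out if out.ndim else float(out)

    def cdf(w):
        w = np.clip(np.asarray(w, dtype=float), w_lo, w_hi)
        out = (w - w_lo) / (w_hi - w_lo)
        return out if out.ndim else float(out)

    def quantile(u):
        u = np.asarray(u, dtype=float)
        out = w_lo + u * (w_hi - w_lo)
        return out if out.ndim else float(out)

    return ToyDCS("uniform", (w_lo, w_hi), fn, total, cdf, quantile)


def generate_fixtures(kind: str, seed: int = 0):
    """Deterministic synthetic fixtures for oracle tests.

    kinds: 'toy_dcs' -> dict of ToyDCS (power_law, uniform);
    'random_rudd_params' -> (RuddElectronParams, RuddProtonParams);
    'toy_elf' -> (ConstantELF, DrudeELF); 'toy_pe' -> PowerLawPhotoXS.
    """
    rng = np.random.default_rng(seed)
    if kind == "toy_dcs":
        return {
            "power_law": _power_law_toy(float(rng.uniform(0.5, 2.0)), 1.0, 100.0),
            "uniform": _uniform_toy(float(rng.uniform(0.5, 2.0)), 0.0, 10.0),
        }
    if kind == "random_rudd_params":
        el = RuddElectronParams(a1=float(rng.uniform(0.5, 2.0)),
                                a2=float(rng.uniform(0.5, 2.0)),
                                b1=float(rng.uniform(0.0, 5.0)),
                                b2=float(rng.uniform(0.0, 30.0)))
        pr = RuddProtonParams(a1=float(rng.uniform(0.5, 2.0)),
                              b1=float(rng.uniform(10.0, 100.0)),
                              c1=float(rng.uniform(0.1, 1.0)),
                              d1=float(rng.uniform(-0.5, 0.0)),
                              e1=float(rng.uniform(0.1, 1.0)),
                              a2=float(rng.uniform(0.5, 2.0)),
                              b2=float(rng.uniform(5.0, 30.0)),
                              c2=float(rng.uniform(0.1, 1.0)),
                              d2=float(rng.uniform(0.0, 0.2)),
                              alpha=float(rng.uniform(0.3, 1.0)))
        return el, pr
    if kind == "toy_elf":
        return (ConstantELF(float(rng.uniform(0.5, 2.0))),
                DrudeELF(terms=((float(rng.uniform(15, 25)),
                                 float(rng.uniform(5, 15)),
                                 float(rng.uniform(100, 600))),)))
    if kind == "toy_pe":
        return PowerLawPhotoXS(
            sigma0_m2={lbl: float(rng.uniform(1e-23, 1e-21))
                       for lbl in ("1b1", "3a1", "1b2", "2a1", "1a1")},
            exponent=float(rng.uniform(2.5, 3.5)))
    raise ConfigError(f"unknown fixture kind {kind!r}")
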