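"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument lies outside the physical domain of a model."""


class ConfigError(ValueError):
    """A configuration file or model-chain request is invalid."""


class ProviderContractError(ValueError):
    """A pluggable provider (photo-XS, ELF) violated its contract."""


class NumericalError(RuntimeError):
    """A numerical routine failed to converge; carries the best estimate."""

    def __init__(self, message: str, estimate: float | None = None):
        super().__init__(message)
        self.estimate = estimate
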