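"""Exception types used across the package."""


class EopEmdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EopEmdError):
    """Invalid configuration value, unknown medium/species/temperature."""


class GeometryError(EopEmdError):
    """Inconsistent device geometry or grid labeling."""


class SolverError(EopEmdError):
    """Linear solve failed, did not converge, or produced unphysical output."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class AnalysisError(EopEmdError):
    """A readout could not be computed from the supplied curve."""
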