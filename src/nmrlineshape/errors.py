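"""Exception hierarchy."""


class NmrLineshapeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NmrLineshapeError, ValueError):
    """An argument is outside its physical or logical domain."""


class ConfigurationError(NmrLineshapeError):
    """Inconsistent or incomplete configuration (spins, ROIs, grids, links)."""


class SolverError(NmrLineshapeError, RuntimeError):
    """Numerical solver failed to converge; carries diagnostics in args."""


class UnsupportedExperimentError(NmrLineshapeError):
    """Pulse sequence not implemented (e.g. TROSY, sensitivity-enhanced HSQC)."""


class UnsupportedLayoutError(NmrLineshapeError, OSError):
    """Spectrum file exists but is not a 2D real plane."""


class EstimationError(NmrLineshapeError):
    """Noise estimation failed; set the noise level manually."""


class DesignError(NmrLineshapeError):
    """Titration design is unrealizable with the given stock."""
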