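"""Exception hierarchy for the simulator."""


class OctFfrError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(OctFfrError, ValueError):
    """A physical or numerical parameter is outside its valid domain."""


class FormatError(OctFfrError, ValueError):
    """An input file or table does not match the expected dialect."""


class MergeError(OctFfrError, ValueError):
    """Pullback merging failed (landmark misalignment, gaps)."""


class CorrectionError(OctFfrError, ValueError):
    """Effective-lumen-radius correction produced a non-positive radius."""


class BuildError(OctFfrError, ValueError):
    """Network assembly failed (inconsistent geometry extents)."""


class ConvergenceError(OctFfrError, RuntimeError):
    """An iterative scheme did not converge within its iteration budget."""


class CalibrationError(OctFfrError, RuntimeError):
    """Cohort calibration failed (no bracket, missing observations)."""


class ConfigError(OctFfrError, ValueError):
    """Unknown configuration key or invalid configuration value."""
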