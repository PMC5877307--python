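"""Exception and warning types used across the package."""


class SedmineError(Exception):
    """Base class for all package-specific errors."""


class SimulationError(SedmineError):
    """Invalid simulator request (unknown label, too-short duration, ...)."""


class WindowingError(SedmineError):
    """Stream cannot be windowed (non-uniform sampling, bad parameters)."""


class DecompositionError(SedmineError):
    """Gravity/dynamic decomposition is unstable or ill-posed."""


class FeatureError(SedmineError):
    """Feature extraction precondition violated (empty series, short segment)."""


class ClassificationError(SedmineError):
    """k-NN store or query is invalid (empty store, length mismatch)."""


class SplitError(SedmineError):
    """Dataset split precondition violated (bad ratios, tiny class)."""


class TimelineError(SedmineError):
    """Engine input streams or epoch records are inconsistent."""


class ConfigError(SedmineError):
    """Configuration file or parameter set is invalid."""


class AnnotationError(SedmineError):
    """Training annotation refers to a span outside the recording."""


class LowGravityWarning(UserWarning):
    """Estimated gravity magnitude is implausibly small (< 1 m/s²)."""


class MissingAudioWarning(UserWarning):
    """Audio sampling was due but no audio was available for the epoch."""
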