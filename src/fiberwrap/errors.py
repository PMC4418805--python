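"""Exception types shared across the pipeline.

Every stage raises a subclass of :class:`FiberwrapError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class FiberwrapError(Exception):
    """Base class for all pipeline errors."""


class CalibrationError(FiberwrapError):
    """No physical voxel size could be determined for a stack."""


class EmptySceneError(FiberwrapError):
    """A synthetic scene contains no objects or a zero-sized grid."""


class NotAFiberError(FiberwrapError):
    """A labeled component is too blob-like to carry a fiber axis."""


class EmptyForegroundError(FiberwrapError):
    """Segmentation produced no foreground after size filtering."""


class InsufficientDataError(FiberwrapError):
    """Too few observations for the requested statistic."""


class NoTransitionError(FiberwrapError):
    """An intensity profile contains no detectable stained/unstained edge."""


class ConfigError(FiberwrapError):
    """A run configuration is inconsistent (e.g. unmapped channel role)."""
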