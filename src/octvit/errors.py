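"""Exception hierarchy for OCT vitreous analysis."""


class OctVitError(Exception):
    """Base class for all package errors."""


class InputError(OctVitError):
    """Unreadable or malformed input file."""


class EmptyStackError(InputError):
    """A stack source contained zero frames."""


class FormatError(InputError):
    """Frames within one stack have inconsistent shapes or types."""


class SegmentationError(OctVitError):
    """Layer segmentation failed (e.g. no retinal band in most columns)."""


class DegenerateFrameError(OctVitError):
    """A frame is degenerate for the requested measurement (e.g. zero RPE signal)."""


class InsufficientDataError(OctVitError):
    """Too few observations for the requested statistic."""


class PhantomError(OctVitError):
    """Phantom configuration cannot be realised (e.g. blobs do not fit)."""
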