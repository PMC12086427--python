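"""Exception types shared across the package."""


class NeurostatesError(Exception):
    """Base class for package-specific errors."""


class RecordingFormatError(NeurostatesError, ValueError):
    """A recording file or sidecar violates the expected on-disk schema."""


class DegenerateDataError(NeurostatesError, ValueError):
    """Input data admit no meaningful value for the requested statistic.

    Raised e.g. for zero-variance spatial patterns, all-constant recordings,
    or segmentations with no usable within-state pairs.
    """
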