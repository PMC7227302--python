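"""Exception hierarchy for the pipeline's hard gates.

Every gate in the data-handling rules (sampling-rate floor, session
duration, segment quality, beat plausibility) raises a distinct error so
callers can log *why* data was rejected rather than silently dropping it.
"""


class CoascreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CoascreenError, ValueError):
    """A model or configuration parameter violates its invariant."""


class MetadataError(CoascreenError):
    """Required record metadata (sidecar) is missing or inconsistent."""


class FormatError(CoascreenError):
    """A waveform file is malformed (e.g. non-uniform time axis)."""


class FidelityError(CoascreenError):
    """Sampling rate below the 125 Hz fidelity floor."""


class UnsupportedRateError(CoascreenError):
    """Sampling rate is neither 125 nor 250 Hz."""


class TooShortError(CoascreenError):
    """Signal too short for the requested operation."""


class SegmentUnusableError(CoascreenError):
    """A 60-s window yielded too few plausible beats to analyse."""


class AnnotationConflictError(CoascreenError):
    """Overlapping site annotations for the same probe."""


class EmptyGroupError(CoascreenError):
    """A statistical contrast or classifier was given an empty class."""
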