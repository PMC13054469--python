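"""Exception hierarchy for the tracking pipeline.

Every stage raises a subclass of :class:`NeedleTrackError`, so callers can
catch pipeline failures without masking programming errors.
"""


class NeedleTrackError(Exception):
    """Base class for all needletrack errors."""


class GeometryError(NeedleTrackError):
    """Invalid array-geometry request (too few elements, bad scale, ...)."""


class InfeasibleGeometryError(GeometryError):
    """Grid snapping could not resolve element collisions within one grid diagonal."""


class InvalidSubsetError(GeometryError):
    """Requested sparsification subset size outside [3, N]."""


class InvalidPlanError(GeometryError):
    """Sparsification plan sizes not strictly descending or out of range."""


class ExcitationError(NeedleTrackError):
    """Excitation specification violates its invariants."""


class SceneError(NeedleTrackError):
    """Acoustic scene violates its invariants (e.g. receiver behind the probe)."""


class TruncationError(SceneError):
    """Requested trace too short to contain all arrivals plus the excitation."""


class FilterDesignError(NeedleTrackError):
    """Band-pass corner frequencies are not realisable at the sampling rate."""


class SignalError(NeedleTrackError):
    """Empty or malformed signal passed to a signal-processing operation."""


class DegenerateSignalError(SignalError):
    """Signal has no usable peak (e.g. a flat envelope)."""


class FrameError(NeedleTrackError):
    """Malformed RF frame (ragged traces, missing element ids, ...)."""


class InsufficientObservationsError(NeedleTrackError):
    """Fewer than three accepted time-of-arrival observations; frame untrackable."""


class DegenerateGeometryError(NeedleTrackError):
    """Transmitter geometry is rank deficient (collinear); position unobservable."""


class ModelError(NeedleTrackError):
    """Invalid acquisition model (zero transmissions per frame)."""


class UndefinedSNRError(NeedleTrackError):
    """Baseline has zero variability; SNR is undefined."""
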