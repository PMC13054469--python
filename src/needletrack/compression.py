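"""Band-pass filtering, matched-filter pulse compression and envelope detection.

Pulse compression cross-correlates the received trace r(t) with the transmit
template c(t) (equivalently, convolves with the time-reversed template),
concentrating the 5 µs coded chirp into a short peak and raising the
amplitude SNR by ≈ √(T·B).  The lag axis is calibrated so that a trace
containing the template delayed by τ yields its envelope peak at lag τ — i.e.
lags are times of the excitation *start*, matching the simulator's
time-of-arrival convention.

Filtering is zero-phase (forward–backward Butterworth): a causal filter
would shift every peak by its group delay and bias the ToA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import FilterDesignError, SignalError

DEFAULT_FILTER_ORDER = 4


@dataclass(frozen=True)
class CompressedTrace:
    """Pulse-compressed signal(s) with a calibrated lag axis.

    ``samples`` may be 1D (one trace) or 2D (N_elements, n_lags); ``lag_axis``
    is shared, uniform with spacing 1/sample_rate, and a lag equals the
    arrival time of the excitation start.
    """

    samples: np.ndarray
    envelope: np.ndarray
    lag_axis: np.ndarray  # µs
    sample_rate: float  # MHz

    def peak_lag(self, refine: bool = True) -> float:
        """Lag of the envelope maximum (1D traces only), optionally sub-sample.

        Sub-sample refinement fits a parabola through the three envelope
        samples around the maximum.
        """
        if self.envelope.ndim != 1:
            raise SignalError("peak_lag is defined for a single trace")
        return peak_time(self.envelope, self.lag_axis, refine=refine)


def peak_time(env: np.ndarray, lag_axis: np.ndarray, refine: bool = True) -> float:
    """Time of the envelope maximum, with optional parabolic sub-sample refinement.

    Ties are broken by the earliest lag (np.argmax convention).
    """
    i = int(np.argmax(env))
    t = float(lag_axis[i])
    if refine and 0 < i < len(env) - 1:
        y0, y1, y2 = float(env[i - 1]), float(env[i]), float(env[i + 1])
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper local maximum
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            t += delta * float(lag_axis[1] - lag_axis[0])
    return t


def bandpass(
    trace: np.ndarray,
    sample_rate: float,
    f_lo: float,
    f_hi: float,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Forward–backward application gives exactly zero group delay, so envelope
    peaks are not shifted by the filtering.
    """
    if not 0 < f_lo < f_hi < sample_rate / 2.0:
        raise FilterDesignError(
            f"need 0 < f_lo < f_hi < {sample_rate / 2} MHz, got ({f_lo}, {f_hi})"
        )
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise SignalError("empty trace")
    sos = scipy.signal.butter(
        order, [f_lo, f_hi], btype="bandpass", fs=sample_rate, output="sos"
    )
    return scipy.signal.sosfiltfilt(sos, trace, axis=-1)


def envelope(samples: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert envelope), last axis."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise SignalError("empty signal")
    return np.abs(scipy.signal.hilbert(samples, axis=-1))


def pulse_compress(
    trace: np.ndarray, template: np.ndarray, sample_rate: float
) -> CompressedTrace:
    """Cross-correlate trace(s) with the template on a calibrated lag axis.

    Works on a single trace or a 2D stack (N_elements, M).  The full
    correlation is returned: lags run from −(len(template)−1)/fs to
    (M−1)/fs, and a noiseless trace containing the template delayed by τ
    peaks at lag τ within half a sample.
    """
    trace = np.asarray(trace, dtype=float)
    template = np.asarray(template, dtype=float)
    if trace.size == 0 or template.size == 0:
        raise SignalError("empty trace or template")
    m = template.shape[-1]
    if trace.shape[-1] < m:
        raise SignalError("template longer than trace")

    rev = template[::-1]
    if trace.ndim == 1:
        samples = scipy.signal.fftconvolve(trace, rev, mode="full")
    elif trace.ndim == 2:
        samples = scipy.signal.fftconvolve(trace, rev[None, :], mode="full", axes=-1)
    else:
        raise SignalError("trace must be 1D or 2D")

    lags = (np.arange(samples.shape[-1]) - (m - 1)) / sample_rate
    return CompressedTrace(
        samples=samples,
        envelope=envelope(samples),
        lag_axis=lags,
        sample_rate=sample_rate,
    )
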