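"""Reliability-gated time-of-arrival (ToA) estimation per element.

Intraoperative traces are corrupted by ambient noise and by multipath echoes
from tissue boundaries.  Each compressed envelope therefore passes two gates
before its peak time is accepted as a ToA:

1. *Noise gate* — the baseline noise level σ is the standard deviation of the
   compressed envelope over the first ``baseline_window`` µs (default 5 µs),
   where no arrival is expected.  A trace whose half-maximum amplitude
   A_50 = 0.5·max falls below ``sigma_multiplier``·σ (default 4, i.e. peak
   < 8σ) is rejected as ``noisy``.  A ``literal_width`` mode that compares
   the half-max width in samples against 4σ is retained for sensitivity
   analysis only.
2. *Consistency gate* — the amplitude-weighted centre of mass (CoM) of *all*
   envelope samples above A_50 is compared with the peak time; a
   displacement beyond ``com_delay_limit`` µs (default 2 µs) indicates
   secondary lobes (multipath) and the trace is rejected as ``inconsistent``.

The noise gate runs first; only traces passing both gates contribute ranges
to multilateration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compression import bandpass, peak_time, pulse_compress
from .errors import DegenerateSignalError, FrameError
from .excitation import RFFrame

log = logging.getLogger(__name__)

REASON_NONE = "none"
REASON_NOISY = "noisy"
REASON_INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class GateConfig:
    """Thresholds for the ToA reliability gates (all positive).

    width_mode selects the interpretation of the noise gate; the default
    ``amplitude_gate`` rejects when A_50 < sigma_multiplier·σ.
    """

    sigma_multiplier: float = 4.0
    com_delay_limit: float = 2.0  # µs
    baseline_window: float = 5.0  # µs
    width_mode: str = "amplitude_gate"  # or "literal_width"

    def __post_init__(self) -> None:
        if min(self.sigma_multiplier, self.com_delay_limit, self.baseline_window) <= 0:
            raise ValueError("all gate thresholds must be positive")
        if self.width_mode not in ("amplitude_gate", "literal_width"):
            raise ValueError(f"unknown width_mode {self.width_mode!r}")


@dataclass(frozen=True)
class ToADecision:
    """Per-element ToA estimate with gating diagnostics."""

    element_id: int
    peak_toa: float  # µs
    half_max_width: float  # µs
    com_time: float  # µs
    baseline_sigma: float
    peak_amplitude: float
    accepted: bool
    rejection_reason: str = REASON_NONE

    def __post_init__(self) -> None:
        if self.accepted and self.rejection_reason != REASON_NONE:
            raise ValueError("accepted decisions must have rejection_reason 'none'")


def half_max_width(env: np.ndarray, lag_axis: np.ndarray) -> float:
    """Width (µs) of the contiguous region around the global peak where env ≥ A_50.

    Crossings are located by linear interpolation.  A flat envelope has no
    peak and raises :class:`DegenerateSignalError`.
    """
    env = np.asarray(env, dtype=float)
    if env.size == 0:
        raise DegenerateSignalError("empty envelope")
    i = int(np.argmax(env))
    peak = env[i]
    if peak <= env.min() or not np.isfinite(peak):
        raise DegenerateSignalError("flat envelope has no half-max width")
    a50 = 0.5 * peak
    dt = float(lag_axis[1] - lag_axis[0])

    # walk left
    j = i
    while j > 0 and env[j - 1] >= a50:
        j -= 1
    if j == 0:
        left = float(lag_axis[0])
    else:
        frac = (env[j] - a50) / (env[j] - env[j - 1])
        left = float(lag_axis[j]) - frac * dt

    # walk right
    k = i
    n = len(env)
    while k < n - 1 and env[k + 1] >= a50:
        k += 1
    if k == n - 1:
        right = float(lag_axis[n - 1])
    else:
        frac = (env[k] - a50) / (env[k] - env[k + 1])
        right = float(lag_axis[k]) + frac * dt

    return right - left


def center_of_mass_above_half_max(env: np.ndarray, lag_axis: np.ndarray) -> float:
    """Amplitude-weighted mean lag over ALL samples with env ≥ A_50.

    Secondary lobes above threshold pull the CoM away from the peak; that
    displacement is exactly what the multipath gate measures.
    """
    env = np.asarray(env, dtype=float)
    if env.size == 0:
        raise DegenerateSignalError("empty envelope")
    peak = env.max()
    if peak <= env.min() or not np.isfinite(peak):
        raise DegenerateSignalError("flat envelope has no centre of mass")
    mask = env >= 0.5 * peak
    w = env[mask]
    return float(np.sum(np.asarray(lag_axis)[mask] * w) / np.sum(w))


def detect_reliable_toas(
    frame: RFFrame,
    template: np.ndarray,
    gates: GateConfig = GateConfig(),
    band: tuple = (1.0, 5.0),
    refine: bool = True,
) -> list:
    """Run the full per-element chain: bandpass → compress → envelope → gates.

    Returns one :class:`ToADecision` per element in frame order.  An
    all-rejected frame is not an error here; downstream range conversion
    decides whether enough observations survive.

    Parameters
    ----------
    band : (f_lo, f_hi) MHz
        Pass band of the zero-phase pre-filter (1–5 MHz for the chirp system).
    refine : bool
        Parabolic sub-sample refinement of the accepted peak time.
    """
    if frame.traces.shape[1] < len(template):
        raise FrameError("frame traces shorter than the template")
    fs = frame.sample_rate
    filtered = bandpass(frame.traces, fs, band[0], band[1])
    ct = pulse_compress(filtered, template, fs)
    lag = ct.lag_axis
    causal = lag >= 0.0
    # baseline = every compressed sample before the window's end, including the
    # acausal correlation lags: same noise statistics, more samples for σ
    base = lag < gates.baseline_window
    if not np.any(base):
        raise FrameError("traces too short to contain the baseline window")

    decisions = []
    for row, eid in zip(ct.envelope, frame.element_ids):
        env_c = row[causal]
        lag_c = lag[causal]
        sigma = float(np.std(row[base]))
        i_peak = int(np.argmax(env_c))
        peak_amp = float(env_c[i_peak])
        grid_peak = float(lag_c[i_peak])
        a50 = 0.5 * peak_amp

        if grid_peak < gates.baseline_window:
            warnings.warn(
                "envelope peak lies inside the baseline noise window; "
                "baseline σ is contaminated by signal",
                stacklevel=2,
            )

        try:
            hw = half_max_width(env_c, lag_c)
            com = center_of_mass_above_half_max(env_c, lag_c)
        except DegenerateSignalError:
            decisions.append(
                ToADecision(int(eid), grid_peak, 0.0, grid_peak, sigma, peak_amp,
                            accepted=False, rejection_reason=REASON_NOISY)
            )
            continue

        # noise gate first, as in the detection algorithm
        if gates.width_mode == "amplitude_gate":
            noisy = a50 < gates.sigma_multiplier * sigma
        else:  # literal_width: half-max width in samples vs σ in amplitude units
            noisy = hw * fs < gates.sigma_multiplier * sigma
        if noisy:
            decisions.append(
                ToADecision(int(eid), grid_peak, hw, com, sigma, peak_amp,
                            accepted=False, rejection_reason=REASON_NOISY)
            )
            continue

        if abs(com - grid_peak) > gates.com_delay_limit:
            decisions.append(
                ToADecision(int(eid), grid_peak, hw, com, sigma, peak_amp,
                            accepted=False, rejection_reason=REASON_INCONSISTENT)
            )
            continue

        toa = peak_time(env_c, lag_c, refine=refine)
        decisions.append(
            ToADecision(int(eid), toa, hw, com, sigma, peak_amp,
                        accepted=True, rejection_reason=REASON_NONE)
        )

    n_acc = sum(d.accepted for d in decisions)
    log.debug("gated frame: %d/%d elements accepted", n_acc, len(decisions))
    return decisions


def decisions_to_frame(decisions) -> pd.DataFrame:
    """Tabulate decisions with the standard export columns."""
    return pd.DataFrame(
        {
            "element_id": [d.element_id for d in decisions],
            "peak_toa_us": [d.peak_toa for d in decisions],
            "half_max_width_us": [d.half_max_width for d in decisions],
            "com_time_us": [d.com_time for d in decisions],
            "sigma": [d.baseline_sigma for d in decisions],
            "peak_amplitude": [d.peak_amplitude for d in decisions],
            "accepted": [d.accepted for d in decisions],
            "reason": [d.rejection_reason for d in decisions],
        }
    )


def decisions_to_csv(decisions, path) -> None:
    decisions_to_frame(decisions).to_csv(path, index=False)
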