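"""Transmit waveforms and the synthetic acoustic-propagation simulator.

The tracking receiver is a point hydrophone embedded at the needle tip; during
the tracking phase each array element fires in turn and the hydrophone records
one trace per element.  The simulator replaces that hardware: it produces the
excitation waveform delayed by the one-way propagation time τ_i = ‖p − s_i‖/c
to each element, scaled by 1/‖p − s_i‖ spherical spreading, with optional
discrete multipath echoes, frequency-proportional attenuation, per-element
time-of-arrival jitter and additive white Gaussian noise.

Conventions: time in µs, frequency in MHz, distance in mm, sound speed in
mm/µs (water ≈ 1.48).  The transmit trigger defines t = 0 and the excitation
is emitted starting at t = 0, so the time of arrival is the delay of the
excitation's *start*.  Delays are applied in the frequency domain (phase
ramp), so the ground-truth τ_i is not quantised to the sample grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .errors import ExcitationError, FrameError, SceneError, TruncationError
from .geometry import ElementLayout

DEFAULT_SOUND_SPEED = 1.48  # mm/µs, water at ~20 °C
DEFAULT_SAMPLE_RATE = 26.0  # MHz

_FWHM_SIGMAS = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class ExcitationSpec:
    """Parametric transmit waveform: linear chirp or Gaussian tone burst.

    For a chirp the instantaneous frequency sweeps linearly from ``f_start``
    at t = 0 to ``f_stop`` at t = ``duration``.  For a tone burst,
    ``n_cycles`` periods of ``f_center`` fit between the Gaussian envelope's
    half-amplitude points.
    """

    kind: str  # "chirp" | "toneburst"
    sample_rate: float = DEFAULT_SAMPLE_RATE  # MHz
    f_start: float | None = None  # MHz
    f_stop: float | None = None  # MHz
    duration: float | None = None  # µs (chirp)
    f_center: float | None = None  # MHz (toneburst)
    n_cycles: int | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ExcitationError("sample_rate must be positive")
        nyquist = self.sample_rate / 2.0
        if self.kind == "chirp":
            if None in (self.f_start, self.f_stop, self.duration):
                raise ExcitationError("chirp needs f_start, f_stop and duration")
            if not 0 < self.f_start <= self.f_stop < nyquist:
                raise ExcitationError(
                    f"need 0 < f_start ≤ f_stop < {nyquist} MHz, got "
                    f"({self.f_start}, {self.f_stop})"
                )
            if self.duration <= 0:
                raise ExcitationError("duration must be positive")
        elif self.kind == "toneburst":
            if None in (self.f_center, self.n_cycles):
                raise ExcitationError("toneburst needs f_center and n_cycles")
            if not 0 < self.f_center < nyquist:
                raise ExcitationError(f"need 0 < f_center < {nyquist} MHz")
            if self.n_cycles < 1:
                raise ExcitationError("n_cycles must be ≥ 1")
        else:
            raise ExcitationError(f"unknown excitation kind {self.kind!r}")

    @classmethod
    def chirp(
        cls,
        f_start: float = 1.0,
        f_stop: float = 5.0,
        duration: float = 5.0,
        sample_rate: float = DEFAULT_SAMPLE_RATE,
    ) -> "ExcitationSpec":
        """The system's tracking excitation: 5 µs linear sweep, 1→5 MHz."""
        return cls(
            kind="chirp",
            f_start=f_start,
            f_stop=f_stop,
            duration=duration,
            sample_rate=sample_rate,
        )

    @classmethod
    def toneburst(
        cls,
        f_center: float = 3.0,
        n_cycles: int = 4,
        sample_rate: float = DEFAULT_SAMPLE_RATE,
    ) -> "ExcitationSpec":
        """The conventional excitation: four-cycle Gaussian burst at 3 MHz."""
        return cls(
            kind="toneburst",
            f_center=f_center,
            n_cycles=n_cycles,
            sample_rate=sample_rate,
        )

    @property
    def record_duration(self) -> float:
        """Length of the generated waveform in µs."""
        if self.kind == "chirp":
            return float(self.duration)
        fwhm = self.n_cycles / self.f_center
        return 6.0 * fwhm / _FWHM_SIGMAS  # ±3σ of the Gaussian envelope

    @property
    def band(self) -> tuple:
        """Nominal (f_lo, f_hi) band in MHz for the matched band-pass filter."""
        if self.kind == "chirp":
            return (float(self.f_start), float(self.f_stop))
        bw = self.f_center / self.n_cycles  # ~envelope bandwidth
        return (max(self.f_center - 2 * bw, 0.05), self.f_center + 2 * bw)


def make_chirp(spec: ExcitationSpec) -> np.ndarray:
    """Linear-FM sinusoid, unit peak amplitude, round(duration·fs) samples."""
    if spec.kind != "chirp":
        raise ExcitationError("make_chirp requires a chirp spec")
    n = round(spec.duration * spec.sample_rate)
    t = np.arange(n) / spec.sample_rate
    return scipy.signal.chirp(t, f0=spec.f_start, t1=spec.duration, f1=spec.f_stop)


def make_toneburst(spec: ExcitationSpec) -> np.ndarray:
    """Gaussian-windowed sinusoid: n_cycles of f_center between half-amplitude points."""
    if spec.kind != "toneburst":
        raise ExcitationError("make_toneburst requires a toneburst spec")
    fwhm = spec.n_cycles / spec.f_center  # µs between half-amplitude points
    sigma = fwhm / _FWHM_SIGMAS
    half = 3.0 * sigma
    n = round(2 * half * spec.sample_rate)
    t = np.arange(n) / spec.sample_rate - half
    w = np.exp(-0.5 * (t / sigma) ** 2)
    s = w * np.cos(2.0 * np.pi * spec.f_center * t)
    return s / np.max(np.abs(s))


def waveform(spec: ExcitationSpec) -> np.ndarray:
    """Dispatch to :func:`make_chirp` or :func:`make_toneburst`."""
    return make_chirp(spec) if spec.kind == "chirp" else make_toneburst(spec)


@dataclass(frozen=True)
class AcousticScene:
    """Point receiver in a homogeneous medium.

    ``multipath`` entries are (extra_delay µs, relative_amplitude) echoes added
    after the direct arrival on every element.  ``toa_jitter_sigma`` adds
    zero-mean Gaussian per-element delay jitter (µs), modelling residual
    per-channel timing uncertainty.  ``attenuation_db_mhz_cm`` enables a
    frequency-proportional amplitude filter (soft tissue ≈ 0.5 dB/(MHz·cm));
    default off, matching water-tank conditions.
    """

    receiver_position: tuple  # (x, y, z) mm, z > 0
    sound_speed: float = DEFAULT_SOUND_SPEED  # mm/µs
    noise_sigma: float = 0.0  # linear amplitude units
    multipath: tuple = ()  # ((extra_delay_us, relative_amplitude), ...)
    attenuation_db_mhz_cm: float | None = None
    toa_jitter_sigma: float = 0.0  # µs
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.receiver_position, dtype=float)
        if p.shape != (3,):
            raise SceneError("receiver_position must be a 3-vector")
        if p[2] <= 0:
            raise SceneError(f"receiver must lie in front of the probe (z > 0), got z={p[2]}")
        if self.sound_speed <= 0:
            raise SceneError("sound_speed must be positive")
        if self.noise_sigma < 0:
            raise SceneError("noise_sigma must be ≥ 0")
        if self.toa_jitter_sigma < 0:
            raise SceneError("toa_jitter_sigma must be ≥ 0")
        for delay, amp in self.multipath:
            if delay <= 0 or amp <= 0:
                raise SceneError("multipath entries need extra_delay > 0 and amplitude > 0")
        object.__setattr__(self, "receiver_position", tuple(p))

    @property
    def receiver(self) -> np.ndarray:
        return np.asarray(self.receiver_position, dtype=float)


@dataclass(frozen=True)
class RFFrame:
    """One tracking acquisition: per-element received traces.

    ``t0`` is the transmit trigger time, defined as 0; sample m of every
    trace is the pressure at time t0 + m/sample_rate.
    """

    traces: np.ndarray  # (N_elements, M)
    sample_rate: float  # MHz
    element_ids: np.ndarray
    t0: float = 0.0  # µs

    def __post_init__(self) -> None:
        tr = np.asarray(self.traces, dtype=float)
        ids = np.asarray(self.element_ids, dtype=int)
        if tr.ndim != 2:
            raise FrameError("traces must be a 2D (N_elements, M) array")
        if ids.shape != (tr.shape[0],):
            raise FrameError("element_ids must align with traces")
        if self.sample_rate <= 0:
            raise FrameError("sample_rate must be positive")
        object.__setattr__(self, "traces", tr)
        object.__setattr__(self, "element_ids", ids)

    @property
    def n_elements(self) -> int:
        return self.traces.shape[0]

    @property
    def time_axis(self) -> np.ndarray:
        return self.t0 + np.arange(self.traces.shape[1]) / self.sample_rate

    def select(self, element_ids) -> "RFFrame":
        """Sub-frame containing only the requested element ids."""
        wanted = set(int(i) for i in np.asarray(element_ids).ravel())
        mask = np.array([int(i) in wanted for i in self.element_ids])
        if mask.sum() != len(wanted):
            raise FrameError("frame does not contain all requested element_ids")
        return RFFrame(self.traces[mask], self.sample_rate, self.element_ids[mask], self.t0)

    # ------------------------------------------------------------------ I/O
    def save_h5(self, path, compressed: bool = False) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("traces", data=self.traces)
            fh.create_dataset("element_ids", data=self.element_ids)
            fh.attrs["sample_rate_mhz"] = self.sample_rate
            fh.attrs["t0_us"] = self.t0
            fh.attrs["compressed"] = compressed

    @classmethod
    def load_h5(cls, path) -> "RFFrame":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                traces=fh["traces"][...],
                element_ids=fh["element_ids"][...],
                sample_rate=float(fh.attrs["sample_rate_mhz"]),
                t0=float(fh.attrs["t0_us"]),
            )

    def save_csv(self, path) -> None:
        df = pd.DataFrame(self.traces.T, columns=[f"el_{i}" for i in self.element_ids])
        df.insert(0, "t_us", self.time_axis)
        df.to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "RFFrame":
        df = pd.read_csv(path)
        t = df.pop("t_us").to_numpy(float)
        ids = np.array([int(c.split("_", 1)[1]) for c in df.columns])
        fs = 1.0 / float(np.mean(np.diff(t)))
        return cls(df.to_numpy(float).T, fs, ids, t0=float(t[0]))


def propagation_delays(layout: ElementLayout, scene: AcousticScene) -> np.ndarray:
    """Noise-free one-way delays τ_i = ‖p − s_i‖ / c (µs) per element."""
    d = np.linalg.norm(scene.receiver - layout.positions, axis=1)
    return d / scene.sound_speed


def synthesize_frame(
    layout: ElementLayout,
    scene: AcousticScene,
    spec: ExcitationSpec,
    trace_duration: float,
    rng: np.random.Generator | None = None,
) -> RFFrame:
    """Simulate one tracking frame for a point receiver.

    Each trace is the excitation delayed by τ_i with sub-sample accuracy
    (frequency-domain phase ramp, zero-padded to ≥ 2× the trace length to
    avoid circular wrap-around), scaled by 1/distance, plus scaled multipath
    copies and i.i.d. Gaussian noise.  With the same ``scene.rng_seed`` the
    output is bit-identical across runs.

    Parameters
    ----------
    trace_duration : float
        Record length in µs; must exceed the latest arrival plus the
        excitation duration, else :class:`TruncationError`.
    rng : numpy Generator, optional
        Overrides ``scene.rng_seed`` (used by the sweep to stream seeds).
    """
    fs = spec.sample_rate
    exc = waveform(spec)
    dists = np.linalg.norm(scene.receiver - layout.positions, axis=1)
    tau = dists / scene.sound_speed

    if rng is None:
        rng = np.random.default_rng(scene.rng_seed)
    if scene.toa_jitter_sigma > 0:
        tau = tau + rng.normal(0.0, scene.toa_jitter_sigma, size=tau.shape)

    extra = max((d for d, _ in scene.multipath), default=0.0)
    latest = tau.max() + extra + spec.record_duration
    n_trace = round(trace_duration * fs)
    if trace_duration <= latest:
        raise TruncationError(
            f"trace_duration {trace_duration} µs truncates arrivals; need > {latest:.2f} µs"
        )

    nfft = 1 << math.ceil(math.log2(2 * (n_trace + len(exc))))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)  # MHz
    spectrum = np.fft.rfft(exc, nfft)

    paths = [(0.0, 1.0)] + list(scene.multipath)
    transfer = np.zeros((layout.n_elements, len(freqs)), dtype=complex)
    for extra_delay, rel_amp in paths:
        total_tau = tau + extra_delay
        amp = rel_amp / dists
        if scene.attenuation_db_mhz_cm is not None:
            path_cm = (scene.sound_speed * total_tau) / 10.0
            att = 10.0 ** (
                -scene.attenuation_db_mhz_cm
                * np.outer(path_cm, freqs)
                / 20.0
            )
        else:
            att = 1.0
        phase = np.exp(-2j * np.pi * np.outer(total_tau, freqs))
        transfer += amp[:, None] * phase * att

    traces = np.fft.irfft(spectrum[None, :] * transfer, nfft)[:, :n_trace]
    if scene.noise_sigma > 0:
        traces = traces + rng.normal(0.0, scene.noise_sigma, size=traces.shape)

    return RFFrame(traces=traces, sample_rate=fs, element_ids=layout.element_ids)
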