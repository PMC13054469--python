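"""One-way delay-and-sum (DAS) tracking baseline.

The comparison method reconstructs a volumetric tracking image by coherently
summing each element's compressed trace sampled at the one-way delay
τ_i(v) = ‖v − s_i‖/c for every voxel v, then takes the envelope of the sum
and localises the needle tip as the intensity-weighted centre of mass above a
−6 dB threshold.  Only transmit-to-receiver delays are involved: the
hydrophone is a point receiver, so there is no receive aperture.

Coherent summation uses the analytic (complex) compressed signal so that the
envelope of the sum is exact; an envelope-then-sum (incoherent) variant is
available for sensitivity checks.  No apodization is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .compression import CompressedTrace, bandpass, pulse_compress
from .errors import SignalError
from .excitation import RFFrame
from .geometry import ElementLayout

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_DB = -6.0


@dataclass(frozen=True)
class VolumeSpec:
    """Axis-aligned reconstruction grid: [x0, x1]×[y0, y1]×[z0, z1], isotropic voxels."""

    x_mm: tuple = (-12.0, 12.0)
    y_mm: tuple = (-12.0, 12.0)
    z_mm: tuple = (5.0, 50.0)
    voxel_mm: float = 0.2

    def axes(self):
        ax = [
            np.arange(lo, hi + 0.5 * self.voxel_mm, self.voxel_mm)
            for lo, hi in (self.x_mm, self.y_mm, self.z_mm)
        ]
        return ax

    def voxel_centers(self) -> np.ndarray:
        xs, ys, zs = self.axes()
        grid = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([g.ravel() for g in grid], axis=1)


@dataclass(frozen=True)
class TrackingVolume:
    """Reconstructed tracking intensity volume."""

    origin: np.ndarray  # (3,) mm, centre of voxel [0,0,0]
    voxel_size: float  # mm
    intensity: np.ndarray  # (nx, ny, nz), ≥ 0

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(inten)) or np.any(inten < 0):
            raise ValueError("intensity must be finite and non-negative")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "intensity", inten)

    @property
    def dims(self) -> tuple:
        return self.intensity.shape

    def voxel_center(self, index) -> np.ndarray:
        return self.origin + self.voxel_size * np.asarray(index, dtype=float)

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("intensity", data=self.intensity)
            fh.attrs["origin_mm"] = self.origin
            fh.attrs["voxel_mm"] = self.voxel_size


def _interp_complex(analytic: np.ndarray, query_idx: np.ndarray) -> np.ndarray:
    """Linear interpolation of a complex trace at fractional sample indices.

    Out-of-support queries contribute zero.
    """
    n = analytic.shape[-1]
    i0 = np.floor(query_idx).astype(np.int64)
    frac = query_idx - i0
    valid = (i0 >= 0) & (i0 < n - 1)
    i0c = np.clip(i0, 0, n - 2)
    out = analytic[i0c] * (1.0 - frac) + analytic[i0c + 1] * frac
    out[~valid] = 0.0
    return out


def das_beamform(
    frame: RFFrame,
    layout: ElementLayout,
    grid: VolumeSpec,
    sound_speed: float,
    template: np.ndarray,
    band: tuple = (1.0, 5.0),
    coherent: bool = True,
) -> TrackingVolume:
    """Reconstruct the tracking volume from per-element compressed traces.

    For each voxel v the intensity is |Σ_i a_i(τ_i(v))| with a_i the analytic
    compressed trace of element i, linearly interpolated at the one-way delay
    τ_i(v) (coherent sum, envelope after summation).  With ``coherent=False``
    the envelopes are summed instead.
    """
    if frame.n_elements != layout.n_elements or np.any(
        frame.element_ids != layout.element_ids
    ):
        frame = frame.select(layout.element_ids)

    fs = frame.sample_rate
    filtered = bandpass(frame.traces, fs, band[0], band[1])
    ct = pulse_compress(filtered, template, fs)
    fields = scipy.signal.hilbert(ct.samples, axis=-1) if coherent else ct.envelope

    voxels = grid.voxel_centers()
    lag0 = float(ct.lag_axis[0])
    acc = np.zeros(len(voxels), dtype=complex if coherent else float)
    out_of_support = False
    for pos, row in zip(layout.positions, fields):
        tau = np.linalg.norm(voxels - pos, axis=1) / sound_speed
        q = (tau - lag0) * fs
        if q.min() < 0 or q.max() > row.shape[-1] - 1:
            out_of_support = True
        acc += _interp_complex(row, q)
    if out_of_support:
        warnings.warn(
            "some voxel delays fall outside the trace support; those voxels "
            "received zero contribution",
            stacklevel=2,
        )

    xs, ys, zs = grid.axes()
    intensity = np.abs(acc).reshape(len(xs), len(ys), len(zs))
    return TrackingVolume(
        origin=np.array([xs[0], ys[0], zs[0]]),
        voxel_size=grid.voxel_mm,
        intensity=intensity,
    )


def com_localize(
    volume: TrackingVolume, threshold_db: float = DEFAULT_THRESHOLD_DB
) -> np.ndarray:
    """Intensity-weighted centroid over voxels within ``threshold_db`` of the peak."""
    inten = volume.intensity
    peak = inten.max()
    if peak <= 0:
        raise SignalError("volume has no signal (max intensity is zero)")
    thr = peak * 10.0 ** (threshold_db / 20.0)
    idx = np.argwhere(inten >= thr)
    w = inten[tuple(idx.T)]
    centers = volume.origin + volume.voxel_size * idx
    return np.asarray((centers * w[:, None]).sum(axis=0) / w.sum())


def lobe_extent(volume: TrackingVolume, level_db: float = -6.0) -> float:
    """Largest axis-aligned extent (mm) of the supra-level region around the peak.

    A coarse width metric used to compare main-lobe broadening between
    aperture sizes.
    """
    inten = volume.intensity
    thr = inten.max() * 10.0 ** (level_db / 20.0)
    idx = np.argwhere(inten >= thr)
    spans = (idx.max(axis=0) - idx.min(axis=0) + 1) * volume.voxel_size
    return float(spans.max())
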