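"""Range-based 3D localization by Gauss–Newton nonlinear least squares.

Each accepted ToA t_i converts to a range d_i = c·t_i from transmitter s_i,
defining a sphere around that element.  The receiver position p minimises

    Σ_i ( ‖p − s_i‖ − d_i )²,

solved by damped Gauss–Newton with Jacobian rows (p − s_i)ᵀ/‖p − s_i‖.  Three
non-collinear transmitters determine the position (up to the front/back
mirror, resolved by the z > 0 half-space constraint); additional elements
overdetermine the fit and average down timing noise.

Initialisation uses the closed-form linearised solution: differencing squared
sphere equations against a reference element cancels ‖p‖² and yields a linear
system.  With all transmitters in the z = 0 plane that system only constrains
(x, y); z is then recovered from the sphere radii and projected to z > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientObservationsError
from .geometry import ElementLayout

MIN_OBSERVATIONS = 3
DEFAULT_TOL = 1e-6  # mm, step-norm stopping tolerance
DEFAULT_MAX_ITER = 50
MAX_HALVINGS = 8


@dataclass(frozen=True)
class RangeSet:
    """Ranges d_i = c·t_i paired with their transmitter positions."""

    element_ids: np.ndarray
    ranges: np.ndarray  # mm
    transmitter_positions: np.ndarray  # (n, 3) mm
    sound_speed: float  # mm/µs

    def __post_init__(self) -> None:
        ids = np.asarray(self.element_ids, dtype=int)
        d = np.asarray(self.ranges, dtype=float)
        s = np.asarray(self.transmitter_positions, dtype=float)
        if len(d) < MIN_OBSERVATIONS:
            raise InsufficientObservationsError(
                f"need ≥ {MIN_OBSERVATIONS} ranges, got {len(d)}"
            )
        if np.any(d < 0):
            raise ValueError("ranges must be non-negative")
        if s.shape != (len(d), 3):
            raise ValueError("transmitter_positions must be (n, 3)")
        object.__setattr__(self, "element_ids", ids)
        object.__setattr__(self, "ranges", d)
        object.__setattr__(self, "transmitter_positions", s)

    def __len__(self) -> int:
        return len(self.ranges)


@dataclass(frozen=True)
class PositionEstimate:
    """Solved 3D receiver position with solver diagnostics."""

    position: np.ndarray  # (3,) mm
    residual_rms: float  # mm
    n_used: int
    iterations: int
    converged: bool


def ranges_from_toas(
    decisions, layout: ElementLayout, sound_speed: float
) -> RangeSet:
    """Convert accepted ToA decisions to ranges; rejected elements are excluded."""
    accepted = [d for d in decisions if d.accepted]
    if len(accepted) < MIN_OBSERVATIONS:
        raise InsufficientObservationsError(
            f"only {len(accepted)} accepted ToAs; ≥ {MIN_OBSERVATIONS} needed "
            "for 3D multilateration"
        )
    id_to_row = {int(e): i for i, e in enumerate(layout.element_ids)}
    rows = [id_to_row[d.element_id] for d in accepted]
    return RangeSet(
        element_ids=np.array([d.element_id for d in accepted]),
        ranges=np.array([sound_speed * d.peak_toa for d in accepted]),
        transmitter_positions=layout.positions[rows],
        sound_speed=sound_speed,
    )


def residual_report(ranges: RangeSet, position) -> np.ndarray:
    """Per-element residuals r_i = ‖p − s_i‖ − d_i (mm)."""
    p = np.asarray(position, dtype=float)
    return np.linalg.norm(p - ranges.transmitter_positions, axis=1) - ranges.ranges


def _linear_init(s: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Closed-form linearised initial guess, projected into z > 0.

    Differencing squared range equations against element 0 gives
    2(s_0 − s_i)ᵀ p = d_i² − d_0² − ‖s_i‖² + ‖s_0‖².  For the planar (z = 0)
    arrays used here the z column vanishes, so (x, y) come from the linear
    system and z from averaging sqrt(d_i² − ρ_i²) over the spheres.
    """
    A3 = 2.0 * (s[0] - s[1:])
    b = d[1:] ** 2 - d[0] ** 2 - np.sum(s[1:] ** 2, axis=1) + np.sum(s[0] ** 2)

    lateral_rank = np.linalg.matrix_rank(A3[:, :2], tol=1e-9)
    if lateral_rank < 2:
        raise DegenerateGeometryError(
            "transmitters are collinear; position is unobservable"
        )

    if np.linalg.matrix_rank(A3, tol=1e-9) == 3:
        p = np.linalg.lstsq(A3, b, rcond=None)[0]
        if p[2] <= 0:
            p[2] = abs(p[2]) if p[2] != 0 else 1e-3
        return p

    xy = np.linalg.lstsq(A3[:, :2], b, rcond=None)[0]
    rho2 = np.sum((s[:, :2] - xy) ** 2, axis=1)
    z2 = np.maximum(d**2 - rho2, 0.0)
    z = float(np.sqrt(np.mean(z2)))
    return np.array([xy[0], xy[1], max(z, 1e-3)])


def solve_position(
    ranges: RangeSet,
    init=None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    weights=None,
) -> PositionEstimate:
    """Damped Gauss–Newton minimisation of the squared range residuals.

    Steps that would increase the cost are halved (up to 8 times); an
    accepted iterate therefore never increases the sum of squared residuals.
    Returns diagnostics even when max_iter is exhausted (converged=False).

    Parameters
    ----------
    init : 3-vector, optional
        Starting point; default is the closed-form linearised solution with
        the z > 0 half-space constraint applied (the needle is always in
        front of the probe face).
    weights : array, optional
        Per-element weights; default uniform (the method uses none).
    """
    s = ranges.transmitter_positions
    d = ranges.ranges
    w = np.ones(len(d)) if weights is None else np.sqrt(np.asarray(weights, float))

    if init is None:
        p = _linear_init(s, d)
    else:
        p = np.array(init, dtype=float)
        if p[2] <= 0:
            p[2] = abs(p[2]) if p[2] != 0 else 1e-3

    def cost(q):
        r = np.linalg.norm(q - s, axis=1) - d
        return r, float(np.sum((w * r) ** 2))

    r, ssr = cost(p)
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        diff = p - s
        dist = np.linalg.norm(diff, axis=1)
        safe = dist > 1e-12
        J = np.zeros_like(diff)
        J[safe] = diff[safe] / dist[safe, None]
        step, *_ = np.linalg.lstsq(w[:, None] * J, -(w * r), rcond=None)

        alpha = 1.0
        improved = False
        for _ in range(MAX_HALVINGS + 1):
            r_new, ssr_new = cost(p + alpha * step)
            if ssr_new <= ssr:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
        p = p + alpha * step
        r, ssr = r_new, ssr_new
        if np.linalg.norm(alpha * step) < tol:
            converged = True
            break

    return PositionEstimate(
        position=p,
        residual_rms=float(np.sqrt(np.mean(r**2))),
        n_used=len(d),
        iterations=iterations,
        converged=converged,
    )
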