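"""Range conversion and Gauss–Newton position solving."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import needletrack as nt
from needletrack.errors import DegenerateGeometryError, InsufficientObservationsError
from needletrack.multilateration import RangeSet, residual_report
from needletrack.toa import ToADecision

from conftest import grid_search_oracle


def _decision(eid, toa, accepted=True):
    return ToADecision(
        element_id=eid, peak_toa=toa, half_max_width=0.2, com_time=toa,
        baseline_sigma=0.01, peak_amplitude=1.0, accepted=accepted,
        rejection_reason="none" if accepted else "noisy",
    )


def exact_rangeset(layout, p):
    d = np.linalg.norm(np.asarray(p) - layout.positions, axis=1)
    return RangeSet(layout.element_ids, d, layout.positions, 1.48)


class TestRangesFromToas:
    def test_range_is_speed_times_toa(self, layout13):
        decisions = [
            _decision(int(e), 13.5135) for e in layout13.element_ids
        ]
        rs = nt.ranges_from_toas(decisions, layout13, 1.48)
        assert rs.ranges[0] == pytest.approx(20.0, abs=1e-3)
        assert len(rs) == 13

    def test_rejected_elements_excluded(self, layout13):
        decisions = [
            _decision(int(e), 15.0, accepted=(i >= 10))
            for i, e in enumerate(layout13.element_ids)
        ]
        rs = nt.ranges_from_toas(decisions, layout13, 1.48)
        assert len(rs) == 3

    def test_fewer_than_three_accepted_raises(self, layout13):
        decisions = [
            _decision(int(e), 15.0, accepted=(i >= 11))
            for i, e in enumerate(layout13.element_ids)
        ]
        with pytest.raises(InsufficientObservationsError):
            nt.ranges_from_toas(decisions, layout13, 1.48)


class TestSolvePosition:
    def test_exact_recovery_from_noiseless_ranges(self, layout13):
        truth = np.array([2.0, 4.0, 30.0])
        est = nt.solve_position(exact_rangeset(layout13, truth))
        assert np.linalg.norm(est.position - truth) < 1e-6
        assert est.converged and est.n_used == 13
        assert est.residual_rms < 1e-9

    def test_zero_range_anchor_recovers_transmitter(self, layout13):
        truth = layout13.positions[0].copy()  # receiver at a transmitter (z = 0)
        d = np.linalg.norm(truth - layout13.positions, axis=1)
        rs = RangeSet(layout13.element_ids, d, layout13.positions, 1.48)
        est = nt.solve_position(rs)
        assert np.linalg.norm(est.position - truth) < 1e-4

    def test_three_element_mirror_resolved_to_front_halfspace(self, layout):
        lay3 = nt.sparsify(layout, 3)
        truth = np.array([1.0, -2.0, 25.0])
        est = nt.solve_position(exact_rangeset(lay3, truth))
        assert est.position[2] > 0
        assert np.linalg.norm(est.position - truth) < 1e-6

    def test_collinear_transmitters_degenerate(self):
        s = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        d = np.linalg.norm(np.array([1.0, 2.0, 10.0]) - s, axis=1)
        rs = RangeSet(np.arange(5), d, s, 1.48)
        with pytest.raises(DegenerateGeometryError):
            nt.solve_position(rs)

    def test_objective_never_increases(self, layout13):
        rng = np.random.default_rng(4)
        truth = np.array([3.0, 1.0, 35.0])
        d = np.linalg.norm(truth - layout13.positions, axis=1)
        d += 1.48 * rng.normal(0, 0.1, 13)
        rs = RangeSet(layout13.element_ids, d, layout13.positions, 1.48)
        # start far away: the damped solver must still descend
        start = np.array([-5.0, 5.0, 10.0])
        est = nt.solve_position(rs, init=start)
        ssr_start = float(np.sum(residual_report(rs, start) ** 2))
        ssr_end = float(np.sum(residual_report(rs, est.position) ** 2))
        assert ssr_end <= ssr_start

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, seed, layout13):
        rng = np.random.default_rng(seed)
        truth = np.array([rng.uniform(-4, 4), rng.uniform(-4, 4), rng.uniform(10, 40)])
        d = np.linalg.norm(truth - layout13.positions, axis=1)
        d += 1.48 * rng.normal(0, 0.05, 13)
        perm = rng.permutation(13)
        est1 = nt.solve_position(
            RangeSet(layout13.element_ids, d, layout13.positions, 1.48)
        )
        est2 = nt.solve_position(
            RangeSet(
                layout13.element_ids[perm], d[perm], layout13.positions[perm], 1.48
            )
        )
        assert np.allclose(est1.position, est2.position, atol=1e-8)

    def test_overdetermination_reduces_error(self, layout):
        """More elements average down identical ToA jitter (paired seeds)."""
        lay13 = nt.sparsify(layout, 13)
        lay4 = nt.sparsify(layout, 4)
        errs = {13: [], 4: []}
        for seed in range(60):
            rng = np.random.default_rng(seed)
            truth = np.array(
                [rng.uniform(-4, 4), rng.uniform(-4, 4), rng.uniform(10, 40)]
            )
            jitter = 1.48 * rng.normal(0, 0.05, 13)
            for lay, key in ((lay13, 13), (lay4, 4)):
                idx = [
                    int(np.where(lay13.element_ids == e)[0][0])
                    for e in lay.element_ids
                ]
                d = np.linalg.norm(truth - lay.positions, axis=1) + jitter[idx]
                est = nt.solve_position(
                    RangeSet(lay.element_ids, d, lay.positions, 1.48)
                )
                errs[key].append(np.linalg.norm(est.position - truth))
        assert np.mean(errs[13]) <= np.mean(errs[4])

    def test_matches_grid_search_oracle(self, layout13):
        """GN finds the same minimum the brute-force grid search finds."""
        rng = np.random.default_rng(11)
        for _ in range(3):
            truth = np.array(
                [rng.uniform(-3, 3), rng.uniform(-3, 3), rng.uniform(12, 35)]
            )
            d = np.linalg.norm(truth - layout13.positions, axis=1)
            d += 1.48 * rng.normal(0, 0.05, 13)
            rs = RangeSet(layout13.element_ids, d, layout13.positions, 1.48)
            est = nt.solve_position(rs)
            oracle_p, oracle_ssr = grid_search_oracle(
                layout13.positions, d, truth, half=2.0, step=0.05
            )
            ssr_gn = float(np.sum(residual_report(rs, est.position) ** 2))
            assert ssr_gn <= oracle_ssr + 1e-9
            assert np.linalg.norm(est.position - oracle_p) < 0.3


class TestResidualReport:
    def test_exact_ranges_zero_residuals(self, layout13):
        truth = np.array([0.0, 0.0, 20.0])
        rs = exact_rangeset(layout13, truth)
        assert np.allclose(residual_report(rs, truth), 0.0, atol=1e-12)

    def test_inflated_range_shows_as_negative_residual(self, layout13):
        truth = np.array([0.0, 0.0, 20.0])
        d = np.linalg.norm(truth - layout13.positions, axis=1)
        d[3] += 1.0
        rs = RangeSet(layout13.element_ids, d, layout13.positions, 1.48)
        r = residual_report(rs, truth)
        assert r[3] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(np.delete(r, 3), 0.0, atol=1e-12)

    def test_estimate_rms_matches_recomputation(self, layout13):
        rng = np.random.default_rng(2)
        truth = np.array([1.0, 1.0, 28.0])
        d = np.linalg.norm(truth - layout13.positions, axis=1) + rng.normal(0, 0.1, 13)
        rs = RangeSet(layout13.element_ids, d, layout13.positions, 1.48)
        est = nt.solve_position(rs)
        r = residual_report(rs, est.position)
        assert est.residual_rms == pytest.approx(np.sqrt(np.mean(r**2)), rel=1e-9)
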