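"""Counting-strategy dynamics: field, critical line, eigenvalue types,
boundary critical curves."""

import numpy as np
import pytest

import memodyn as md
from memodyn.counting import counting_field, counting_jacobian, r_counting
from memodyn.memone import SaturationStatus

from conftest import interior_points


class TestCountingField:
    def test_vanishes_on_critical_line(self, game):
        q = md.critical_line(0.5, game)
        assert np.allclose(q, [0.65 / 1.1, 0.5, 0.45 / 1.1], atol=1e-12)
        assert np.max(np.abs(counting_field(q, game))) < 1e-12

    def test_rescale_identity(self, game):
        Q = interior_points(50, 3, seed=31, lo=0.1, hi=0.9)
        for q in Q:
            f = counting_field(q, game)
            g = md.numeric_gradient_counting(q, game) * r_counting(*q) ** 2
            assert np.max(np.abs(f - g)) < 1e-7 * max(1.0, np.max(np.abs(f)))

    def test_sign_agreement_with_gradient(self, game):
        Q = interior_points(1000, 3, seed=37, lo=0.1, hi=0.9)
        F = counting_field(Q, game)
        for i in range(0, 1000, 9):
            g = md.numeric_gradient_counting(Q[i], game)
            keep = np.abs(F[i]) > 1e-8
            assert np.all(np.sign(F[i][keep]) == np.sign(g[keep]))

    def test_factor_two_versus_memone_middle_component(self, game, rng):
        # within the counting subspace the raw 3-cube gradient doubles the
        # memory-one CD component: the embedding is not distance-preserving
        for _ in range(10):
            q = rng.uniform(0.1, 0.9, 3)
            g3 = md.numeric_gradient_counting(q, game)
            g4 = md.numeric_gradient([q[0], q[1], q[1], q[2]], game)
            assert g3[1] == pytest.approx(2 * g4[1], abs=1e-5)
            assert g3[0] == pytest.approx(g4[0], abs=1e-5)
            assert g3[2] == pytest.approx(g4[3], abs=1e-5)

    def test_forbidden_combinations_absent_on_grid(self, game):
        # rising q1 with falling q2 or q0 does not occur on the census grid
        # (in rare thin regions elsewhere in the cube it can)
        tally = md.sign_census(md.GridSpec(9, 3), game).tally
        for pat in tally:
            if "0" not in pat:
                assert not (pat[1] == "+" and (pat[0] == "-" or pat[2] == "-")), pat

    def test_sigma_duality(self, game):
        # time reversal: the field at the rotated point is the
        # component-reversed field (the rotation's derivative flips sign)
        Q = interior_points(500, 3, seed=43, lo=0.0, hi=1.0)
        F = counting_field(Q, game)
        Fs = counting_field(md.sigma_counting(Q), game)
        assert np.max(np.abs(Fs - F[:, ::-1])) < 1e-9


class TestCriticalLine:
    def test_endpoints(self, game):
        a, b_ = md.critical_line_endpoints(game)
        assert np.allclose(a, [2 / 11, 1 / 11, 0.0], atol=1e-12)
        assert np.allclose(b_, [1.0, 10 / 11, 9 / 11], atol=1e-12)

    @pytest.mark.parametrize("c", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_length_formula(self, c):
        game = md.GamePayoffs.donation(1.0, c)
        a, b_ = md.critical_line_endpoints(game)
        assert np.linalg.norm(b_ - a) == pytest.approx(
            md.critical_line_length(game), abs=1e-12
        )
        assert md.critical_line_length(game) == pytest.approx(
            np.sqrt(3) * (1 - c) / (1 + c), abs=1e-12
        )

    def test_limits(self):
        # nearly-free cooperation: the line spans the cube diagonal
        assert md.critical_line_length(
            md.GamePayoffs.donation(1.0, 1e-9)
        ) == pytest.approx(np.sqrt(3), abs=1e-6)
        assert md.critical_line_length(
            md.GamePayoffs.donation(1.0, 1 - 1e-9)
        ) == pytest.approx(0.0, abs=1e-6)

    def test_out_of_range(self, game):
        with pytest.raises(md.OutOfRangeError):
            md.critical_line(0.05, game)
        with pytest.raises(md.OutOfRangeError):
            md.critical_line(0.95, game)

    def test_line_points_are_equalizers(self, game):
        from memodyn.engine import payoff_batch

        for t in (0.2, 0.5, 0.8):
            q = md.critical_line(t, game)
            p = np.array([q[0], q[1], q[1], q[2]])
            opp = interior_points(100, 4, seed=47)
            vals = payoff_batch(opp, np.broadcast_to(p, opp.shape), game)
            assert np.ptp(vals) < 1e-8


class TestJacobianAndClassification:
    def test_jacobian_matches_finite_differences(self, game, rng):
        h = 1e-6
        for _ in range(20):
            q = rng.uniform(0.1, 0.9, 3)
            J = counting_jacobian(q, game)
            for j in range(3):
                hi, lo = q.copy(), q.copy()
                hi[j] += h
                lo[j] -= h
                col = (counting_field(hi, game) - counting_field(lo, game)) / (2 * h)
                assert np.max(np.abs(J[:, j] - col)) < 1e-6

    def test_neutral_eigenvalue_along_line(self, game):
        # the line direction (1,1,1)/sqrt(3) is a continuum of equilibria,
        # hence an exact zero eigenvalue
        for t in (0.2, 0.5, 0.8):
            q = md.critical_line(t, game)
            J = counting_jacobian(q, game)
            assert np.max(np.abs(J @ np.ones(3))) < 1e-12

    def test_all_five_types_occur(self):
        seen = set()
        for c in (0.2, 0.4, 0.6, 0.8):
            game = md.GamePayoffs.donation(1.0, c)
            lo = c / (1 + c)
            hi = 1 / (1 + c)
            for t in np.linspace(lo, hi, 202)[1:-1]:
                seen.add(md.classify_critical(float(t), game).label)
        assert {"source", "spiral source", "spiral sink", "sink", "saddle"} <= seen

    def test_sink_source_duality(self, game):
        partner = {
            "sink": "source",
            "source": "sink",
            "spiral sink": "spiral source",
            "spiral source": "spiral sink",
            "saddle": "saddle",
            "non-hyperbolic": "non-hyperbolic",
        }
        lo, hi = 1 / 11, 10 / 11
        for t in np.linspace(lo + 0.01, hi - 0.01, 50):
            a = md.classify_critical(float(t), game).label
            b_ = md.classify_critical(float(lo + hi - t), game).label
            assert b_ == partner[a]

    def test_eigenvalues_continuous_in_t(self, game):
        ts = np.arange(0.3, 0.4, 1e-3)
        prev = None
        for t in ts:
            ev = np.sort_complex(np.asarray(md.classify_critical(float(t), game).eigenvalues))
            if prev is not None:
                assert np.max(np.abs(ev - prev)) < 5e-2
            prev = ev


class TestBoundaryCriticalCurves:
    def test_grim_is_boundary_critical(self, game):
        pts = md.boundary_critical_counting("q2=1", game, resolution=60)
        d = np.min(np.linalg.norm(pts - np.array([1.0, 0.0, 0.0]), axis=1))
        assert d < 1e-6
        assert np.max(np.abs(counting_field(np.array([1.0, 0.0, 0.0]), game))) < 1e-12

    def test_sigma_maps_faces_onto_each_other(self, game):
        a = md.boundary_critical_counting("q2=1", game, resolution=60, include_edge=False)
        b_ = md.boundary_critical_counting("q0=0", game, resolution=60, include_edge=False)
        if len(a) and len(b_):
            img = md.sigma_counting(a)
            for pt in img[:: max(1, len(img) // 25)]:
                assert np.min(np.linalg.norm(b_ - pt, axis=1)) < 0.05

    def test_shared_edge_is_critical(self, game):
        for s in np.linspace(0, 1, 11):
            q = np.array([1.0, s, 0.0])
            assert np.max(np.abs(counting_field(q, game))) < 1e-12


class TestCountingBoundarySaturation:
    def test_q1_zero_face_saturated(self, game, rng):
        for _ in range(200):
            x, z = rng.uniform(0.01, 0.99, 2)
            assert md.counting_boundary_saturation(
                np.array([x, 0.0, z]), game
            ).is_saturated

    def test_q1_one_face_unsaturated(self, game, rng):
        for _ in range(200):
            x, z = rng.uniform(0.01, 0.99, 2)
            assert (
                md.counting_boundary_saturation(np.array([x, 1.0, z]), game)
                is SaturationStatus.UNSATURATED
            )

    def test_matches_normal_component_sign(self, game, rng):
        for _ in range(250):
            q = rng.uniform(0.01, 0.99, 3)
            face = rng.integers(0, 3)
            side = rng.integers(0, 2)
            q[face] = float(side)
            status = md.counting_boundary_saturation(q, game)
            comp = counting_field(q, game)[face]
            outward = comp if side == 1 else -comp
            assert status.is_saturated == bool(outward >= 0)

    def test_interior_rejected(self, game):
        with pytest.raises(md.NotOnBoundaryError):
            md.counting_boundary_saturation(np.array([0.5, 0.5, 0.5]), game)
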