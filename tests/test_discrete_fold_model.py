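"""Two-layer bead-spring fold model: energies, constraints, minimization."""

import numpy as np
import pytest

from blipsim import discrete_fold_model as dfm
from blipsim.surface_math import polygon_area


def small_params(**kw):
    defaults = dict(N=48, M=6, ER=2.0, c2=1e3, c4=1e3, c5=1e3, c6=1e3)
    defaults.update(kw)
    return dfm.ModelParams(**defaults)


class TestInitialization:
    def test_perimeter_ratio_is_er(self):
        p = dfm.ModelParams(N=200, M=20, ER=4.0)
        st = dfm.init_two_layer(p)
        seg = np.roll(st.outer, -1, axis=0) - st.outer
        L = np.hypot(seg[:, 0], seg[:, 1]).sum()
        assert L / p.target_inner_perimeter == pytest.approx(4.0, rel=1e-3)

    def test_er1_m0_is_plain_circle(self):
        p = dfm.ModelParams(N=100, M=0, ER=1.0)
        st = dfm.init_two_layer(p)
        assert st.inner.shape == (0, 2)
        r = np.linalg.norm(st.outer, axis=1)
        assert np.allclose(r, r[0])

    @pytest.mark.parametrize("N,M", [(200, 20), (100, 7), (50, 13)])
    def test_contact_spacing_uniform(self, N, M):
        st = dfm.init_two_layer(dfm.ModelParams(N=N, M=M, ER=2.0))
        gaps = np.diff(np.concatenate([st.contacts, [st.contacts[0] + N]]))
        assert set(gaps) <= {N // M, N // M + 1}


class TestEnergyTerms:
    def test_outer_regular_polygon(self):
        p = small_params()
        st = dfm.init_two_layer(p)
        # direct recomputation: bending from the turning-angle curvature plus
        # the quadratic spring term about the rest length L/N
        from blipsim.surface_math import turning_angle_curvature

        kappa = turning_angle_curvature(st.outer)
        e = np.roll(st.outer, -1, axis=0) - st.outer
        lengths = np.hypot(e[:, 0], e[:, 1])
        a = p.outer_perimeter / p.N
        expected = p.c1 * np.sum(kappa**2) + p.c2 * np.sum((lengths - a) ** 2)
        assert dfm.outer_energy(st, p) == pytest.approx(expected, rel=1e-9)

    def test_stretch_quadratic_increment(self):
        # with bending off, moving one bead changes exactly the two adjacent
        # spring terms: dH = c2 * sum over both edges of (l' - a)^2 - (l - a)^2
        p = small_params(c1=0.0)
        st = dfm.init_two_layer(p)
        a = p.outer_perimeter / p.N
        st2 = st.copy()
        st2.outer[3] += [0.01, -0.02]
        def edge_len(s, i):
            return float(np.linalg.norm(s.outer[(i + 1) % p.N] - s.outer[i]))
        expected = p.c2 * sum(
            (edge_len(st2, i) - a) ** 2 - (edge_len(st, i) - a) ** 2
            for i in (2, 3))
        assert (dfm.outer_energy(st2, p) - dfm.outer_energy(st, p)
                == pytest.approx(expected, rel=1e-9))

    def test_doubling_c1_doubles_bending(self):
        p = small_params(c2=0.0)
        st = dfm.init_two_layer(p)
        p2 = small_params(c1=2.0, c2=0.0)
        assert dfm.outer_energy(st, p2) == pytest.approx(2 * dfm.outer_energy(st, p))

    def test_inner_regular_polygon_area_term_zero(self):
        # a regular M-gon of exactly the target area leaves only the springs
        p = small_params()
        M = p.M
        r = np.sqrt(2 * p.A_target / (M * np.sin(2 * np.pi / M)))
        ang = 2 * np.pi * np.arange(M) / M
        inner = r * np.column_stack([np.cos(ang), np.sin(ang)])
        base = dfm.init_two_layer(p)
        st = dfm.TwoLayerState(base.outer, inner, base.contacts)
        e = np.roll(inner, -1, axis=0) - inner
        expected = p.c3 * np.sum(e[:, 0]**2 + e[:, 1]**2)
        assert dfm.inner_energy(st, p) == pytest.approx(expected, rel=1e-10)

    def test_degenerate_inner_area(self):
        p = small_params(M=3)
        st = dfm.init_two_layer(p)
        st.inner[:] = [[0, 0], [1e-3, 0], [2e-3, 0]]  # collinear, A = 0
        e = dfm.inner_energy(st, p)
        springs = p.c3 * sum(np.sum((st.inner[(j + 1) % 3] - st.inner[j])**2)
                             for j in range(3))
        assert e == pytest.approx(p.c4 * p.A_target**2 + springs, rel=1e-10)

    def test_contact_energy_values(self):
        p = small_params()
        st = dfm.init_two_layer(p)
        assert dfm.contact_energy(st, p) == pytest.approx(0.0, abs=1e-8)
        st.inner[0] += [0.3, 0.4]
        assert dfm.contact_energy(st, p) == pytest.approx(p.c5 * 0.25, rel=1e-9)

    def test_cross_penalty_single_bead(self):
        p = small_params(M=4)
        square = np.array([[0.0, 0], [2, 0], [2, 2], [0, 2]])
        outer = np.array([[1.0, 0.5]] + [[5 + k, 5.0] for k in range(p.N - 1)])
        st = dfm.TwoLayerState(outer, square, np.arange(4))
        # bead (1, 0.5) is inside, 0.5 above the bottom edge
        assert dfm.cross_penalty(st, p) == pytest.approx(p.c6 * 0.25, rel=1e-9)

    def test_cross_penalty_outside_zero(self):
        p = small_params(M=4)
        square = np.array([[0.0, 0], [2, 0], [2, 2], [0, 2]])
        outer = np.array([[5.0 + k, 5.0] for k in range(p.N)])
        st = dfm.TwoLayerState(outer, square, np.arange(4))
        assert dfm.cross_penalty(st, p) == 0.0


class TestPredicates:
    def test_winding_number_convex(self):
        square = np.array([[0.0, 0], [2, 0], [2, 2], [0, 2]])
        assert dfm.winding_number([1.0, 1.0], square) == 1
        assert dfm.winding_number([10.0, 10.0], square) == 0

    def test_winding_number_pentagram_core(self):
        # self-overlapping star: the core is wound twice
        ang = np.pi / 2 + 2 * np.pi * np.arange(5) * 2 / 5
        star = np.column_stack([np.cos(ang), np.sin(ang)])
        assert dfm.winding_number([0.0, 0.0], star) == 2

    @pytest.mark.parametrize(
        "a1,a2,b1,b2,expected",
        [
            ((0, 0), (1, 1), (0, 1), (1, 0), True),        # X crossing
            ((0, 0), (1, 0), (0, 1), (1, 1), False),       # parallel
            ((0, 0), (2, 0), (1, 0), (3, 0), True),        # collinear overlap
            ((0, 0), (1, 0), (1, 0), (2, 1), False),       # shared endpoint
            ((0, 0), (1, 0), (2, 0), (3, 0), False),       # collinear disjoint
        ],
    )
    def test_segments_cross(self, a1, a2, b1, b2, expected):
        assert dfm.segments_cross(a1, a2, b1, b2) is expected

    def test_any_self_crossing(self):
        bow = np.array([[0.0, 0], [1, 1], [1, 0], [0, 1]])
        assert dfm.any_self_crossing(bow)
        square = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        assert not dfm.any_self_crossing(square)


class TestMinimize:
    def test_energy_monotone_and_descent(self):
        p = small_params()
        st = dfm.init_two_layer(p)
        res = dfm.minimize(st, p, max_iter=5000)
        assert np.all(np.diff(res.energy_trace) <= 1e-12)
        assert res.energy < dfm.total_energy(st, p)
        assert not dfm.any_self_crossing(res.state.outer)

    def test_er1_m0_stays_circle(self):
        p = dfm.ModelParams(N=60, M=0, ER=1.0, c2=1e3)
        st = dfm.init_two_layer(p)
        res = dfm.minimize(st, p, max_iter=3000)
        r = np.linalg.norm(res.state.outer, axis=1)
        assert np.ptp(r) / r.mean() < 1e-3
        assert dfm.fold_metrics(res.state, p)["n_lobes"] == 0

    def test_tiny_instance_local_minimality(self):
        """No single-bead grid perturbation of the relaxed state lowers H."""
        p = dfm.ModelParams(N=12, M=3, ER=1.5, c2=1e3, c4=1e3, c5=1e3, c6=1e3)
        res = dfm.minimize(dfm.init_two_layer(p), p, max_iter=60_000, tol=1e-12)
        H0 = res.energy
        delta = 1e-4 * p.outer_perimeter / p.N
        best = H0
        for layer in ("outer", "inner"):
            arr = getattr(res.state, layer)
            for i in range(arr.shape[0]):
                for dx in (-delta, 0.0, delta):
                    for dy in (-delta, 0.0, delta):
                        trial = res.state.copy()
                        getattr(trial, layer)[i] += [dx, dy]
                        best = min(best, dfm.total_energy(trial, p))
        assert best >= H0 - 1e-6 * abs(H0)


class TestSteadyState:
    def test_fold_count_matches_contacts(self, steady_states):
        for (M, ER), (res, p) in steady_states.items():
            assert dfm.fold_metrics(res.state, p)["n_lobes"] == M

    def test_inner_spring_lengths_reach_contracted_circle(self, steady_states):
        # at steady state each cortex spring approaches (perimeter of the
        # circle of area A_target) / M
        res, p = steady_states[(40, 4.0)]
        e = np.roll(res.state.inner, -1, axis=0) - res.state.inner
        lengths = np.hypot(e[:, 0], e[:, 1])
        assert np.allclose(lengths, 2 * np.sqrt(np.pi * p.A_target) / p.M,
                           rtol=0.02)

    def test_symmetric_folds_have_equal_areas(self, steady_states):
        res, p = steady_states[(20, 4.0)]
        areas = [f["area"] for f in dfm.fold_metrics(res.state, p)["folds"]]
        assert np.ptp(areas) / np.mean(areas) < 1e-6

    def test_invariant_grid_fold_counts(self):
        # spot-check corners of the (M, ER) grid beyond the acceptance set
        for M, ER in [(10, 2.0), (25, 6.0)]:
            p = dfm.ModelParams(N=400, M=M, ER=ER)
            res = dfm.steady_state(p)
            assert dfm.fold_metrics(res.state, p)["n_lobes"] == M
            assert not res.residuals["self_crossing"]


class TestRescale:
    def test_identity_and_quarter(self, steady_states):
        res, p = steady_states[(20, 4.0)]
        A = abs(polygon_area(res.state.outer))
        same = dfm.rescale_to_target_area(res.state, A)
        assert np.allclose(same.outer, res.state.outer)
        quarter = dfm.rescale_to_target_area(res.state, A / 4.0)
        assert np.allclose(quarter.outer, res.state.outer / 2.0)

    def test_hits_target_exactly(self, steady_states):
        res, _ = steady_states[(40, 4.0)]
        scaled = dfm.rescale_to_target_area(res.state, 7.5)
        assert abs(polygon_area(scaled.outer)) == pytest.approx(7.5, rel=1e-10)
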