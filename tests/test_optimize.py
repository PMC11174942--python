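"""Nelder-Mead step, PSO update, the hybrid optimizer, and the
calibration driver."""

import numpy as np
import pytest

from rppgbp import (
    BPParams,
    CohortSpec,
    NMPSOConfig,
    Simplex,
    build_param_table,
    estimate_bp,
    fit_bp_params,
    generate_cohort,
    nm_step,
    nmpso_optimize,
    pso_optimize,
)
from rppgbp.bp import default_intervals
from rppgbp.errors import DegenerateInputError, InvalidArgumentError, UnderdeterminedError
from rppgbp.optimize import SwarmState, pso_update


def sphere_at(c):
    return lambda x: float(np.sum((np.asarray(x) - c) ** 2))


class TestNMStep:
    def test_one_dimensional_hand_derivation(self):
        # f = x^2, simplex {-1, 2}: reflection of 2 through centroid -1
        # gives -4 (f=16, worse than everything), inside contraction
        # gives -1 + 0.5*(2 - (-1)) = 0.5 (f=0.25, accepted).
        f = lambda x: float(x[0] ** 2)
        s = Simplex.from_points(np.array([[-1.0], [2.0]]), f)
        out = nm_step(s, f)
        np.testing.assert_allclose(np.sort(out.points.ravel()), [-1.0, 0.5])
        assert out.values[0] == pytest.approx(0.25)
        assert out.values[0] <= 1.0

    def test_expansion_when_reflection_beats_best(self):
        # f = x^2, simplex {2, 3}: reflect 3 through 2 -> 1 (f=1 < f_low=4),
        # expand -> 2 + 2*(1-2) = 0 (f=0), expansion wins.
        f = lambda x: float(x[0] ** 2)
        s = Simplex.from_points(np.array([[2.0], [3.0]]), f)
        out = nm_step(s, f)
        assert out.values[0] == pytest.approx(0.0)
        assert 0.0 in out.points

    def test_best_point_untouched_when_it_is_the_minimizer(self):
        f = sphere_at(np.zeros(2))
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        out = nm_step(Simplex.from_points(pts, f), f)
        assert any(np.array_equal(p, [0.0, 0.0]) for p in out.points)
        assert out.values[0] == 0.0

    def test_constant_objective_completes(self):
        f = lambda x: 7.5
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        out = nm_step(Simplex.from_points(pts, f), f)
        np.testing.assert_allclose(out.values, 7.5)

    def test_never_worsens_best_value(self, rng):
        f = lambda x: float(np.sum(x**2) + np.sin(3 * x).sum())
        for _ in range(20):
            pts = rng.uniform(-3, 3, size=(3, 2))
            s = Simplex.from_points(pts, f)
            out = nm_step(s, f)
            assert out.values[0] <= s.values[0] + 1e-12

    def test_degenerate_simplex_rejected(self):
        f = sphere_at(np.zeros(2))
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])  # collinear
        with pytest.raises(DegenerateInputError):
            nm_step(Simplex.from_points(pts, f), f)


class _PinnedRng:
    """Stub RNG returning fixed values for rand1 then rand2."""

    def __init__(self, r1, r2):
        self.vals = [r1, r2]

    def uniform(self, size=None):
        return np.full(size, self.vals.pop(0))


class TestPSOUpdate:
    def _state(self, f, x, v, config, rng):
        n, dim = x.shape
        values = np.array([f(p) for p in x])
        g = int(np.argmin(values))
        return SwarmState(x=x.copy(), v=v.copy(), values=values,
                          pbest_x=x.copy(), pbest_val=values.copy(),
                          gbest_x=x[g].copy(), gbest_val=float(values[g]))

    def test_zero_coefficients_freeze_positions(self, rng):
        f = sphere_at(np.zeros(2))
        cfg = NMPSOConfig(w=0.0, c1=0.0, c2=0.0)
        x = rng.uniform(0, 120, size=(4, 2))
        st = self._state(f, x, np.ones((4, 2)), cfg, rng)
        pso_update(st, cfg, np.random.default_rng(0), f)
        np.testing.assert_array_equal(st.x, x)
        np.testing.assert_array_equal(st.v, np.zeros((4, 2)))

    def test_velocity_is_inertia_only_at_both_bests(self):
        f = sphere_at(np.zeros(1))
        cfg = NMPSOConfig(w=0.5)
        x = np.array([[10.0]])
        st = self._state(f, x, np.array([[4.0]]), cfg, None)
        # particle sits at its pbest and the gbest: attraction vanishes
        pso_update(st, cfg, np.random.default_rng(0), f)
        assert st.v[0, 0] == pytest.approx(0.5 * 4.0)
        assert st.x[0, 0] == pytest.approx(10.0 + 2.0)

    def test_hand_evaluation_with_pinned_randoms(self):
        # one particle, one dimension: v' = w v + r1 c1 (pbest - x)
        #                                   + r2 c2 (gbest - x); x' = x + v'
        f = sphere_at(np.zeros(1))
        cfg = NMPSOConfig(w=0.5, c1=1.5, c2=1.5)
        st = SwarmState(x=np.array([[10.0]]), v=np.array([[2.0]]),
                        values=np.array([100.0]),
                        pbest_x=np.array([[6.0]]), pbest_val=np.array([36.0]),
                        gbest_x=np.array([4.0]), gbest_val=16.0)
        pso_update(st, cfg, _PinnedRng(0.5, 0.25), f)
        v_expected = 0.5 * 2.0 + 0.5 * 1.5 * (6.0 - 10.0) + 0.25 * 1.5 * (4.0 - 10.0)
        assert st.v[0, 0] == pytest.approx(v_expected)  # -4.25
        assert st.x[0, 0] == pytest.approx(10.0 + v_expected)

    def test_mask_leaves_unmasked_particles_bit_identical(self, rng):
        f = sphere_at(np.zeros(2))
        cfg = NMPSOConfig()
        x = rng.uniform(0, 120, size=(7, 2))
        st = self._state(f, x, rng.uniform(-1, 1, size=(7, 2)), cfg, rng)
        keep = x[:3].copy()
        pso_update(st, cfg, np.random.default_rng(1), f, mask=np.arange(3, 7))
        np.testing.assert_array_equal(st.x[:3], keep)

    def test_positions_clamped_to_box(self, rng):
        f = sphere_at(np.zeros(2))
        cfg = NMPSOConfig(x_min=0.0, x_max=120.0, v_max=500.0)
        x = np.full((3, 2), 119.0)
        st = self._state(f, x, np.full((3, 2), 400.0), cfg, rng)
        pso_update(st, cfg, np.random.default_rng(0), f)
        assert np.all(st.x <= 120.0) and np.all(st.x >= 0.0)


class TestNMPSO:
    def test_sphere_convergence_small(self):
        for seed in range(5):
            c = np.array([30.0, 80.0, 55.0])
            res = nmpso_optimize(sphere_at(c), 3, NMPSOConfig(seed=seed))
            assert res.fun < 1e-3
            np.testing.assert_allclose(res.x, c, atol=0.1)

    def test_history_monotone_non_increasing(self):
        res = nmpso_optimize(sphere_at(np.array([60.0, 60.0])), 2, NMPSOConfig(seed=1))
        assert np.all(np.diff(res.history) <= 0)

    def test_deterministic_under_seed(self):
        f = sphere_at(np.array([25.0, 95.0]))
        a = nmpso_optimize(f, 2, NMPSOConfig(seed=11))
        b = nmpso_optimize(f, 2, NMPSOConfig(seed=11))
        np.testing.assert_array_equal(a.history, b.history)
        np.testing.assert_array_equal(a.x, b.x)

    def test_constant_objective_flat_history(self):
        res = nmpso_optimize(lambda x: 3.25, 2, NMPSOConfig(seed=0, n_iter=10))
        assert res.fun == 3.25
        np.testing.assert_allclose(res.history, 3.25)

    def test_beats_plain_pso_on_rosenbrock(self):
        def rosen(x):
            a, b = x[0] - 50.0, x[1] - 50.0
            return float((1 - a) ** 2 + 100 * (b - a**2) ** 2)

        wins = 0
        for seed in range(20):
            cfg = NMPSOConfig(seed=seed, n_iter=200)
            hybrid = nmpso_optimize(rosen, 2, cfg).fun
            plain = pso_optimize(rosen, 2, cfg).fun
            wins += hybrid < plain
        assert wins > 10

    def test_invalid_budget(self):
        with pytest.raises(InvalidArgumentError):
            NMPSOConfig(n_iter=0)


class TestFitBPParams:
    def test_noiseless_recovery_within_half_mmhg(self):
        recs = generate_cohort(CohortSpec(n_subjects=50, bmi_range=(21, 23), seed=5))
        for kind in ("sbp", "dbp"):
            params, fitness = fit_bp_params(recs, kind)
            pred = np.array([estimate_bp(params, r.feature(kind), r.bmi) for r in recs])
            ref = np.array([r.reference(kind) for r in recs])
            rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
            assert rmse < 0.5
            assert fitness == pytest.approx(rmse, abs=1e-9)

    def test_fitness_at_true_parameters_is_zero(self):
        spec = CohortSpec(n_subjects=20, seed=2)
        recs = generate_cohort(spec)
        p = spec.true_params_sbp
        pred = np.array([estimate_bp(p, r.e_peak, r.bmi) for r in recs])
        ref = np.array([r.sbp_ref for r in recs])
        assert np.sqrt(np.mean((pred - ref) ** 2)) == pytest.approx(0.0, abs=1e-9)

    def test_identical_records_underdetermined(self):
        from rppgbp import SubjectRecord

        r = SubjectRecord(1.7, 65.0, 120.0, 80.0, 0.5, 0.4)
        with pytest.raises(UnderdeterminedError):
            fit_bp_params([r] * 10, "sbp")

    def test_too_few_records(self):
        recs = generate_cohort(CohortSpec(n_subjects=2, seed=0))
        with pytest.raises(UnderdeterminedError):
            fit_bp_params(recs, "sbp")


class TestBuildParamTable:
    def _cohort(self, intervals, n=8, noise=0.0, seed=0):
        out = []
        for k, (lo, hi) in enumerate(intervals):
            out += generate_cohort(CohortSpec(
                n_subjects=n, bmi_range=(lo, hi), bp_noise_sd=noise, seed=seed + k))
        return out

    def test_no_expansion_equals_single_fit(self):
        intervals = [(21.0, 23.0)]
        cohort = self._cohort(intervals, n=12, seed=4)
        cfg = NMPSOConfig(seed=7, n_iter=300)
        table = build_param_table(cohort, intervals, expansion_target=1, config=cfg)
        single, _ = fit_bp_params(cohort, "sbp", cfg)
        assert table.intervals[0].sbp == single

    def test_zero_jitter_groups_average_to_single_fit(self):
        intervals = [(21.0, 23.0)]
        cohort = self._cohort(intervals, n=10, seed=6)
        cfg = NMPSOConfig(seed=3, n_iter=300)
        table = build_param_table(cohort, intervals, expansion_target=4,
                                  config=cfg, jitter_frac=0.0)
        single, _ = fit_bp_params(cohort, "sbp", cfg)
        np.testing.assert_allclose(table.intervals[0].sbp.as_array(),
                                   single.as_array(), atol=1e-9)

    def test_noiseless_two_interval_recovery(self):
        intervals = [(19.0, 21.0), (21.0, 23.0)]
        cohort = self._cohort(intervals, n=10, seed=8)
        table = build_param_table(cohort, intervals, expansion_target=5, seed=2)
        for iv in table.intervals:
            recs = [r for r in cohort if iv.contains(r.bmi)]
            for kind in ("sbp", "dbp"):
                p = iv.sbp if kind == "sbp" else iv.dbp
                pred = np.array([estimate_bp(p, r.feature(kind), r.bmi) for r in recs])
                ref = np.array([r.reference(kind) for r in recs])
                assert np.sqrt(np.mean((pred - ref) ** 2)) < 1.0

    def test_empty_interval_rejected(self):
        intervals = [(19.0, 21.0), (25.0, 27.0)]
        cohort = self._cohort([(19.0, 21.0)], n=5, seed=1)
        with pytest.raises(InvalidArgumentError, match=r"25\.0"):
            build_param_table(cohort, intervals)
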