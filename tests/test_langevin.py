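import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from microstab.langevin import (
    LangevinParams,
    classify_phase,
    find_critical_fitness,
    has_interior_mode,
    infer_fitness,
    phi0,
    simulate,
    steady_state_pdf,
)


class TestPhi0:
    def test_single_taxon_collapses_to_F(self):
        for alpha in (-0.5, 0.0, 0.5, 0.75):
            assert phi0([2.3], alpha) == pytest.approx(2.3)

    def test_two_equal_units_at_half(self):
        assert phi0([1.0, 1.0], 0.5) == pytest.approx(np.sqrt(2))

    @given(st.floats(0.1, 5.0), st.integers(1, 30), st.floats(-1.0, 0.9))
    def test_equal_fitness_factoring(self, f, k, alpha):
        assert phi0([f] * k, alpha) == pytest.approx(f * k ** (1 - alpha), rel=1e-9)

    def test_alpha_ge_one_rejected(self):
        with pytest.raises(ValueError):
            phi0([1.0], 1.0)


class TestSimulate:
    def test_single_taxon_pinned_at_one(self):
        p = LangevinParams(0.75, 0.75, [2.0], 0.3)
        traj = simulate(p, [1.0], dt=1e-3, n_steps=500, seed=0)
        np.testing.assert_allclose(traj.x, 1.0, atol=1e-12)

    def test_symmetric_fixed_point_without_noise(self):
        k = 5
        p = LangevinParams(0.75, 0.75, [1.0] * k, 0.0)
        traj = simulate(p, [1 / k] * k, dt=1e-3, n_steps=200, seed=0)
        np.testing.assert_allclose(traj.x, 1 / k, atol=1e-12)

    def test_composition_conserved(self):
        rng = np.random.default_rng(4)
        F = rng.uniform(0.5, 3.0, 10)
        p = LangevinParams(0.75, 0.75, F, 0.2)
        x0 = F ** 4 / (F**4).sum()
        traj = simulate(p, x0, n_steps=2000, seed=1, record_every=50)
        np.testing.assert_allclose(traj.x.sum(axis=1), 1.0, atol=1e-9)

    def test_seeded_reproducibility(self):
        p = LangevinParams(0.75, 0.75, [1.0, 2.0], 0.2)
        a = simulate(p, [0.2, 0.8], n_steps=500, seed=9)
        b = simulate(p, [0.2, 0.8], n_steps=500, seed=9)
        np.testing.assert_array_equal(a.x, b.x)

    def test_oversized_dt_rejected(self):
        p = LangevinParams(0.75, 0.75, [1.0, 2.0], 2.0)
        with pytest.raises(ValueError, match="dt"):
            simulate(p, [0.5, 0.5], dt=5.0, n_steps=100, seed=0)

    def test_invalid_x0_rejected(self):
        p = LangevinParams(0.75, 0.75, [1.0, 2.0], 0.2)
        with pytest.raises(ValueError):
            simulate(p, [0.7, 0.7], n_steps=10, seed=0)


class TestSteadyState:
    def test_equal_branch_mode_closed_form(self):
        ss = steady_state_pdf(0.5, 0.75, F=0.5, V=0.5, phi0_val=0.5)
        assert ss.branch == "equal"
        assert ss.mode_is_interior
        assert ss.x_M == pytest.approx(0.390625, abs=1e-9)

    def test_density_normalized(self):
        for args in [(0.5, 0.75, 0.5, 0.5, 0.5), (0.75, 0.75, 1.0, 0.2, 2.1)]:
            ss = steady_state_pdf(*args)
            assert np.trapezoid(ss.density, ss.grid) == pytest.approx(1.0, abs=1e-6)
            assert np.all(ss.density >= 0)

    def test_low_noise_mode_approaches_deterministic_fixed_point(self):
        F, alpha = 1.0, 0.75
        p0 = phi0([F] * 10, alpha)
        x_star = (F / p0) ** (1 / (1 - alpha))
        ss = steady_state_pdf(alpha, 0.75, F, V=0.01, phi0_val=p0)
        assert ss.mode_is_interior
        assert ss.x_M == pytest.approx(x_star, rel=1e-2)

    def test_branch_continuity(self):
        # generic branch tending to 2*beta = 1 + alpha matches the equal branch
        alpha, beta = 0.5, 0.75
        eq = steady_state_pdf(alpha, beta, 0.5, 0.5, 0.5)
        gen = steady_state_pdf(alpha + 1e-7, beta, 0.5, 0.5, 0.5)
        assert gen.branch == "generic"
        np.testing.assert_allclose(gen.density, eq.density, rtol=1e-3)
        assert gen.x_M == pytest.approx(eq.x_M, rel=1e-4)

    def test_mode_exists_only_above_phase_line(self):
        # alpha = beta = 0.75 with dominant-taxon phi0: transition at F = 3V^2
        V = 0.2
        assert has_interior_mode(0.75, 0.75, F=1.05 * 3 * V**2, V=V,
                                 phi0_val=1.05 * 3 * V**2)
        assert not has_interior_mode(0.75, 0.75, F=0.95 * 3 * V**2, V=V,
                                     phi0_val=0.95 * 3 * V**2)

    def test_beta_one_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            steady_state_pdf(0.5, 1.0, 1.0, 0.2, 1.0)


class TestClassifyPhase:
    def test_self_consistent_closed_form(self):
        d = classify_phase(0.75, 0.75, F=0.12, V=0.2)
        assert d.F_crit == pytest.approx(0.12, abs=1e-12)  # 3 V^2
        assert d.method == "closed_form:beta_eq_alpha"

    def test_equal_branch_closed_form(self):
        d = classify_phase(0.5, 0.75, F=1.0, V=1.0, phi0_val=1.0)
        assert d.F_crit == pytest.approx(0.75)
        assert d.method == "closed_form:equal_branch"

    def test_deep_ordered_phase(self):
        d = classify_phase(0.75, 0.75, F=2.0, V=0.1)
        assert d.phase == "ordered" and d.margin > 0

    def test_disordered_below_line(self):
        d = classify_phase(0.75, 0.75, F=0.05, V=0.2)
        assert d.phase == "disordered" and d.margin < 0

    @pytest.mark.parametrize(
        "alpha,beta,V,phi0_val",
        [(0.75, 0.75, 0.3, None), (0.5, 0.75, 0.6, 1.0), (0.6, 0.6, 0.4, 2.0)],
    )
    def test_bisection_matches_closed_forms(self, alpha, beta, V, phi0_val):
        numeric = find_critical_fitness(alpha, beta, V, phi0_val)
        if phi0_val is None:
            closed = 4 * beta * V**2
        elif abs(beta - alpha) < 1e-9:
            closed = np.sqrt(4 * beta * phi0_val * V**2)
        else:
            closed = beta * V**2
        assert abs(numeric - closed) / closed < 0.005


class TestInferFitness:
    def test_saturated_series_flagged_at_bound(self):
        # a taxon pinned at the top of the domain favors ever-larger fitness;
        # the MLE runs to the edge of the search bracket and must be flagged
        est = infer_fitness([0.99] * 30, V=0.2)
        assert est.at_bound and est.F == pytest.approx(100.0, rel=0.01)

    def test_constant_series_has_interior_mle(self):
        est = infer_fitness([0.3] * 30, V=0.2)
        assert not est.at_bound and est.F > 0

    def test_identical_series_identical_estimates(self):
        rng = np.random.default_rng(2)
        series = np.clip(0.1 + 0.02 * rng.standard_normal(40), 1e-4, 1)
        a = infer_fitness(series, V=0.2, phi0_val=2.0)
        b = infer_fitness(series.copy(), V=0.2, phi0_val=2.0)
        assert a.F == b.F

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="5"):
            infer_fitness([0.1, 0.2, 0.3], V=0.2)
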