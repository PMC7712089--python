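"""The embedded discrepancy operator and the enriched ODE system."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glvenrich import (
    DiscrepancyParams,
    EnrichedModel,
    GLVModel,
    Trajectory,
    UnsolvableDiscrepancyError,
    enriched_equilibrium,
    enriched_rhs,
    equilibrium,
    glv_rhs,
    resolve_derivative,
    sign_change_diagnostic,
    simulate,
    simulate_enriched,
    simulate_enriched_batch,
    subsample_partial_model,
)


def _random_admissible(rng, s):
    return DiscrepancyParams(delta0=-rng.uniform(0, 2, s),
                             delta1=-rng.uniform(0, 0.9, s))


class TestResolveDerivative:
    def test_piecewise_logistic_regimes(self, logistic_enriched):
        # x' = x - x^2 - 0.5|x'| collapses to 2x(1-x) while descending
        # and (2/3)x(1-x) while ascending
        em = logistic_enriched
        for x in np.linspace(0.05, 1.95, 39):
            got = enriched_rhs(em, np.array([x]))[0]
            expect = 2 * x * (1 - x) if x > 1 else (2 / 3) * x * (1 - x)
            assert abs(got - expect) < 1e-12

    def test_zero_growth_gives_zero_derivative(self):
        v = resolve_derivative(np.array([0.0, 1.0, -1.0]), np.full(3, -0.5))
        np.testing.assert_array_equal(v, [0.0, 1.0 / 1.5, -2.0])

    def test_unsolvable_delta1_rejected(self):
        with pytest.raises(UnsolvableDiscrepancyError, match="unsolvable"):
            resolve_derivative(np.array([1.0]), np.array([-1.0]))

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(g=st.floats(-1e3, 1e3), d1=st.floats(-0.999, 0.0))
    def test_implicit_equation_satisfied(self, g, d1):
        v = resolve_derivative(np.array([g]), np.array([d1]))[0]
        assert abs(v - g - d1 * abs(v)) < 1e-12 * max(1.0, abs(g))


class TestDiscrepancyParams:
    def test_positive_entries_rejected(self):
        with pytest.raises(ValueError):
            DiscrepancyParams(delta0=np.array([0.1]), delta1=np.array([-0.1]))

    def test_delta1_at_minus_one_rejected(self):
        with pytest.raises(UnsolvableDiscrepancyError):
            DiscrepancyParams(delta0=np.array([-0.1]), delta1=np.array([-1.0]))

    def test_vector_roundtrip(self):
        p = DiscrepancyParams(delta0=np.array([-1.0, -2.0]),
                              delta1=np.array([-0.1, -0.2]))
        q = DiscrepancyParams.from_vector(p.to_vector())
        np.testing.assert_array_equal(q.delta0, p.delta0)
        np.testing.assert_array_equal(q.delta1, p.delta1)

    def test_json_roundtrip(self, tmp_path):
        p = DiscrepancyParams(delta0=np.array([-0.8]), delta1=np.array([-0.02]))
        p.to_json(tmp_path / "d.json")
        q = DiscrepancyParams.from_json(tmp_path / "d.json")
        np.testing.assert_array_equal(q.to_vector(), p.to_vector())


class TestEnrichedRHS:
    def test_zero_discrepancy_matches_partial_model(self, random_models):
        rng = np.random.default_rng(3)
        m = random_models[0]
        em = EnrichedModel(partial=m, disc=DiscrepancyParams(
            delta0=np.zeros(m.S), delta1=np.zeros(m.S)))
        for _ in range(50):
            x = rng.lognormal(0, 1, m.S)
            np.testing.assert_allclose(enriched_rhs(em, x), glv_rhs(m, x),
                                       rtol=1e-12)


class TestEnrichedEquilibrium:
    def test_showcase_scalar_solve(self, poc_partial):
        em = EnrichedModel(partial=poc_partial,
                           disc=DiscrepancyParams(delta0=np.array([-0.837]),
                                                  delta1=np.array([-0.0224])))
        x_eq = enriched_equilibrium(em)
        np.testing.assert_allclose(x_eq, [(5 - 0.837) / 3.0])
        assert abs(x_eq[0] - 1.4) < 0.02  # close to the detailed equilibrium

    def test_zero_delta0_recovers_partial_equilibrium(self, poc_partial):
        em = EnrichedModel(partial=poc_partial,
                           disc=DiscrepancyParams(delta0=np.array([0.0]),
                                                  delta1=np.array([-0.5])))
        np.testing.assert_allclose(enriched_equilibrium(em),
                                   equilibrium(poc_partial))

    def test_delta0_shifts_equilibrium_downward_when_uncoupled(self,
                                                               random_models):
        # componentwise monotonicity in delta0 requires A^{-1} <= 0
        # entrywise, which holds for diagonal (uncoupled) A but *not* for the
        # generator's fully coupled matrices: the inverse of an all-negative
        # symmetric matrix has positive off-diagonal entries, so a negative
        # delta0 on one species can raise another's equilibrium
        rng = np.random.default_rng(4)
        for m in random_models[:50]:
            diag = GLVModel(A=np.diag(np.diag(m.A)), r=m.r)
            em = EnrichedModel(partial=diag, disc=_random_admissible(rng, m.S))
            assert (enriched_equilibrium(em) <= equilibrium(diag) + 1e-12).all()

    def test_delta0_can_raise_a_coupled_equilibrium_component(self):
        # counterexample documenting the coupled case: depress species 2 and
        # its competitor's equilibrium rises
        m = GLVModel(A=np.array([[-3.0, -1.0], [-1.0, -2.0]]), r=np.array([5.0, 3.0]))
        em = EnrichedModel(partial=m, disc=DiscrepancyParams(
            delta0=np.array([0.0, -1.0]), delta1=np.zeros(2)))
        x_en, x_pa = enriched_equilibrium(em), equilibrium(m)
        assert x_en[1] < x_pa[1]
        assert x_en[0] > x_pa[0]


class TestSimulateEnriched:
    def test_zero_discrepancy_matches_partial_trajectory(self, poc_partial):
        em = EnrichedModel(partial=poc_partial,
                           disc=DiscrepancyParams(delta0=np.array([0.0]),
                                                  delta1=np.array([0.0])))
        grid = np.linspace(0, 5, 51)
        a = simulate_enriched(em, np.array([0.3]), grid)
        b = simulate(poc_partial, np.array([0.3]), grid)
        np.testing.assert_allclose(a.states, b.states, atol=1e-7)

    def test_posterior_mean_operator_tracks_detailed_model(self, poc_detailed,
                                                           poc_partial):
        # with the reported posterior means, the enriched terminal state is
        # within 2% of the detailed model's
        em = EnrichedModel(partial=poc_partial,
                           disc=DiscrepancyParams(delta0=np.array([-0.837]),
                                                  delta1=np.array([-0.0224])))
        grid = np.linspace(0, 20, 81)
        xe = simulate_enriched(em, np.array([0.5]), grid).final_state[0]
        xd = simulate(poc_detailed, np.array([0.5, 0.5]), grid).final_state[0]
        assert abs(xe - xd) / xd < 0.02

    @pytest.mark.parametrize("x0", [0.1, 1.9])
    def test_logistic_regimes_are_monotone(self, logistic_enriched, x0):
        grid = np.linspace(0, 12, 121)
        traj = simulate_enriched(logistic_enriched, np.array([x0]), grid)
        d = np.diff(traj.states[:, 0])
        assert (d >= -1e-9).all() if x0 < 1 else (d <= 1e-9).all()
        assert np.isnan(sign_change_diagnostic(traj)).all()

    def test_fixed_sign_regime_matches_scaled_smooth_system(self, poc_partial):
        # while the derivative sign is constant, the enriched trajectory
        # solves the smooth GLV system with growth and interactions scaled
        # by lambda = 1/(1 - delta1) (ascending branch)
        disc = DiscrepancyParams(delta0=np.array([-0.8]), delta1=np.array([-0.4]))
        em = EnrichedModel(partial=poc_partial, disc=disc)
        lam = 1.0 / (1.0 - disc.delta1[0])
        scaled = GLVModel(A=lam * poc_partial.A,
                          r=lam * (poc_partial.r + disc.delta0))
        grid = np.linspace(0, 4, 41)
        a = simulate_enriched(em, np.array([0.2]), grid)  # ascending throughout
        b = simulate(scaled, np.array([0.2]), grid)
        np.testing.assert_allclose(a.states, b.states, atol=1e-6)

    def test_batch_matches_single_trajectories(self, poc_partial):
        rng = np.random.default_rng(5)
        em = EnrichedModel(partial=poc_partial, disc=_random_admissible(rng, 1))
        X0 = rng.lognormal(0, 1, (4, 1))
        grid = np.linspace(0, 3, 16)
        batch = simulate_enriched_batch(em, X0, grid)
        for k in range(4):
            single = simulate_enriched(em, X0[k], grid)
            np.testing.assert_allclose(batch[k], single.states, atol=1e-6)


class TestSignChangeDiagnostic:
    def test_overshoot_trajectory_flags_turning_point(self):
        t = np.linspace(0, 2, 81)
        states = (1.0 - (t - 1.0) ** 2)[:, None] + 1.0  # peak at t = 1
        t_star = sign_change_diagnostic(Trajectory(times=t, states=states))
        assert abs(t_star[0] - 1.0) < 0.05

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            sign_change_diagnostic(
                Trajectory(times=np.array([0.0, 1.0]), states=np.ones((2, 1)))
            )

    def test_random_enriched_runs_settle_before_horizon(self, random_models):
        # supports the fixed-sign-after-t* conjecture: the latest sign change
        # happens well before the end of the run
        rng = np.random.default_rng(6)
        for m in random_models[:10]:
            s = max(1, m.S // 2)
            p = subsample_partial_model(m, s)
            em = EnrichedModel(partial=p, disc=_random_admissible(rng, s))
            traj = simulate_enriched(em, rng.lognormal(0, 1, s),
                                     np.linspace(0, 10, 201))
            t_star = sign_change_diagnostic(traj)
            finite = t_star[np.isfinite(t_star)]
            assert (finite < 8.0).all()
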