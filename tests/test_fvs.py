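import numpy as np
import pytest

from pbesim.discretization import (
    AggregationKernel,
    build_geometric_grid,
    build_pair_index_set,
    build_uniform_grid,
)
from pbesim.fvs import (
    InvalidStateError,
    ParticleState,
    SolverConfig,
    euler_step,
    fvs_number_rhs,
    fvs_tracer_rhs,
    integrate,
    make_coupled_rhs,
    total_tracer_mass,
)
from pbesim.oracles import discrete_smoluchowski_reference


class TestTracerRhs:
    def test_monodisperse_hand_value(self, grid4, pairs4, constant_kernel, monodisperse4):
        rate = fvs_tracer_rhs(monodisperse4, grid4, pairs4, constant_kernel)
        np.testing.assert_allclose(rate, [-1.0, 1.0, 0.0, 0.0], atol=1e-15)

    def test_zero_state(self, grid4, pairs4, constant_kernel):
        state = ParticleState(N=np.zeros(4), m=np.zeros(4))
        np.testing.assert_array_equal(fvs_tracer_rhs(state, grid4, pairs4, constant_kernel), 0.0)

    def test_zero_number_zeroes_rate(self, grid4, pairs4, constant_kernel):
        state = ParticleState(N=np.zeros(4), m=np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(fvs_tracer_rhs(state, grid4, pairs4, constant_kernel), 0.0)

    def test_dimension_mismatch(self, grid4, pairs4, constant_kernel):
        state = ParticleState(N=np.zeros(3), m=np.zeros(3))
        with pytest.raises(InvalidStateError):
            fvs_tracer_rhs(state, grid4, pairs4, constant_kernel)

    def test_batch_total_conserved_in_domain(self, grid4, pairs4):
        # state confined to the two smallest cells: every birth pair in-domain
        rng = np.random.default_rng(7)
        kernel = AggregationKernel("additive", 1.0)
        state = ParticleState(N=np.array([*rng.random(2), 0, 0]), m=np.array([*rng.random(2), 0, 0]))
        rate = fvs_tracer_rhs(state, grid4, pairs4, kernel)
        assert abs(rate.sum()) < 1e-14


class TestNumberRhs:
    def test_monodisperse_hand_value(self, grid4, pairs4, constant_kernel, monodisperse4):
        rate = fvs_number_rhs(monodisperse4, grid4, pairs4, constant_kernel)
        np.testing.assert_allclose(rate, [-1.0, 0.5, 0.0, 0.0], atol=1e-15)

    def test_total_number_rate(self, grid4, pairs4):
        # with all pairs in-domain, d(mu0)/dt = -1/2 sum_jk beta N_j N_k
        kernel = AggregationKernel("constant", 1.3)
        N = np.array([0.4, 0.3, 0.0, 0.0])
        state = ParticleState(N=N, m=np.zeros(4))
        rate = fvs_number_rhs(state, grid4, pairs4, kernel)
        expected = -0.5 * 1.3 * N.sum() ** 2
        assert abs(rate.sum() - expected) < 1e-14

    def test_zero_state(self, grid4, pairs4, constant_kernel):
        state = ParticleState(N=np.zeros(4), m=np.zeros(4))
        np.testing.assert_array_equal(fvs_number_rhs(state, grid4, pairs4, constant_kernel), 0.0)


class TestEulerStep:
    def test_arithmetic(self):
        state = ParticleState(N=np.array([1.0, 0.0]), m=np.array([1.0, 0.0]))
        new = euler_step(state, np.zeros(2), np.array([-1.0, 1.0]), 0.1)
        np.testing.assert_allclose(new.m, [0.9, 0.1])
        np.testing.assert_allclose(new.N, [1.0, 0.0])
        assert new.t == pytest.approx(0.1)

    def test_zero_dt_identity(self):
        state = ParticleState(N=np.array([1.0, 2.0]), m=np.array([3.0, 4.0]), t=1.5)
        new = euler_step(state, np.ones(2), np.ones(2), 0.0)
        np.testing.assert_array_equal(new.N, state.N)
        np.testing.assert_array_equal(new.m, state.m)

    def test_sum_preserved_for_zero_sum_rate(self):
        state = ParticleState(N=np.zeros(3), m=np.array([1.0, 2.0, 3.0]))
        rate = np.array([0.5, -0.2, -0.3])
        new = euler_step(state, np.zeros(3), rate, 0.7)
        assert new.m.sum() == pytest.approx(state.m.sum())

    def test_negative_dt_rejected(self):
        state = ParticleState(N=np.zeros(2), m=np.zeros(2))
        with pytest.raises(ValueError):
            euler_step(state, np.zeros(2), np.zeros(2), -0.1)


class TestIntegrate:
    def test_zero_rhs_constant_trajectory(self, grid4):
        state = ParticleState(N=np.array([1.0, 2.0, 0.0, 0.0]), m=np.array([1.0, 0.0, 0.0, 0.0]))
        rhs = lambda t, N, m: (np.zeros(4), np.zeros(4))
        res = integrate(state, rhs, SolverConfig(), 1.0, grid4)
        np.testing.assert_allclose(res.N[-1], state.N, atol=1e-12)
        np.testing.assert_allclose(res.m[-1], state.m, atol=1e-12)

    def test_single_euler_step_matches_euler_step(self, grid4, pairs4, constant_kernel, monodisperse4):
        rhs = make_coupled_rhs(grid4, pairs4, constant_kernel)
        cfg = SolverConfig(method="explicit_euler", dt=0.25)
        res = integrate(monodisperse4, rhs, cfg, 0.25, grid4)
        dN, dm = rhs(0.0, monodisperse4.N, monodisperse4.m)
        manual = euler_step(monodisperse4, dN, dm, 0.25)
        np.testing.assert_allclose(res.N[-1], manual.N)
        np.testing.assert_allclose(res.m[-1], manual.m)

    def test_euler_approaches_adaptive(self, grid4, pairs4, constant_kernel, monodisperse4):
        rhs = make_coupled_rhs(grid4, pairs4, constant_kernel)
        ref = integrate(monodisperse4, rhs, SolverConfig(rtol=1e-10, atol=1e-12), 0.5, grid4)
        errs = []
        for dt in (0.05, 0.025):
            res = integrate(monodisperse4, rhs, SolverConfig(method="explicit_euler", dt=dt), 0.5, grid4)
            errs.append(np.abs(res.N[-1] - ref.N[-1]).max())
        assert errs[1] < errs[0]  # first-order decay
        assert errs[1] < 0.05

    def test_invalid_method(self):
        with pytest.raises(ValueError):
            SolverConfig(method="rk4")
        with pytest.raises(ValueError):
            SolverConfig(method="explicit_euler")  # dt missing


class TestConservationAndMoments:
    def test_batch_tracer_mass_conserved(self):
        grid = build_geometric_grid(1, 23, 1.0)
        pairs = build_pair_index_set(grid)
        kernel = AggregationKernel("additive", 1.0)
        rhs = make_coupled_rhs(grid, pairs, kernel)
        N = np.zeros(23)
        m = np.zeros(23)
        N[0] = m[0] = 1.0
        res = integrate(ParticleState(N=N, m=m), rhs, SolverConfig(), 1.6, grid)
        totals = res.m.sum(axis=1)
        assert np.all(np.abs(totals / totals[0] - 1.0) < 1e-6)

    def test_total_tracer_mass(self):
        assert total_tracer_mass(ParticleState(N=np.zeros(3), m=np.array([1.0, 0, 0]))) == 1.0
        assert total_tracer_mass(ParticleState(N=np.zeros(3), m=np.zeros(3))) == 0.0

    def test_constant_kernel_mu0_closed_form(self):
        # mu0(t) = mu0(0) / (1 + beta0*mu0(0)*t/2) for constant kernel
        grid = build_geometric_grid(1, 20, 1.0)
        pairs = build_pair_index_set(grid)
        kernel = AggregationKernel("constant", 1.0)
        rhs = make_coupled_rhs(grid, pairs, kernel)
        N = np.zeros(20)
        m = np.zeros(20)
        N[0] = m[0] = 1.0
        res = integrate(ParticleState(N=N, m=m), rhs, SolverConfig(rtol=1e-10, atol=1e-13), 4.0, grid)
        mu0 = res.N.sum(axis=1)
        exact = 1.0 / (1.0 + res.times / 2.0)
        np.testing.assert_allclose(mu0, exact, rtol=1e-4)


class TestLinearGridExactness:
    @pytest.mark.parametrize("family", ["constant", "additive", "multiplicative"])
    def test_matches_discrete_smoluchowski(self, family):
        I = 8
        grid = build_uniform_grid(I)
        pairs = build_pair_index_set(grid)
        kernel = AggregationKernel(family, 1.0)
        rhs = make_coupled_rhs(grid, pairs, kernel)
        N0 = np.zeros(I)
        m0 = np.zeros(I)
        N0[0] = m0[0] = 1.0
        t_end = 0.4
        res = integrate(ParticleState(N=N0, m=m0), rhs,
                        SolverConfig(rtol=1e-10, atol=1e-13), t_end, grid)
        ref = discrete_smoluchowski_reference(I, kernel, N0, m0, t_end)
        np.testing.assert_allclose(res.N[-1], ref.N, rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(res.m[-1], ref.m, rtol=1e-6, atol=1e-12)
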