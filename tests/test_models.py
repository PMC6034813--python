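import numpy as np
import pytest

from migscale import (
    COUNTRYSIDE,
    FlowMatrix,
    GravityParams,
    ScalingParams,
    SimulationConfig,
    SynthSpec,
    destination_probs_gravity_scaling,
    destination_probs_scaling,
    expected_flow_matrix,
    fit_gravity,
    gen_city_system,
    gen_flows,
    gravity_flux,
    international_inflow,
    intervening_population,
    radiation_flux,
    simulate_two_step,
    step1_leave_probs,
)
from migscale.beta_curve import BetaCurve
from migscale.synthetic import expected_flows

from conftest import make_fit, make_planar_system


def make_params(
    leave_beta=0.9,
    leave_log_alpha=np.log(0.05),
    cs_beta=0.8,
    cs_log_alpha=-1000.0,
    dest_beta=1.0,
    p_cs=0.0322,
):
    return ScalingParams(
        leave_city_fit=make_fit(leave_beta, leave_log_alpha),
        to_countryside_fit=make_fit(cs_beta, cs_log_alpha),
        beta_curve=BetaCurve.constant(dest_beta, (1.0, 1e9)),
        p_countryside_leave=p_cs,
    )


class TestStepOne:
    def test_probabilities_partition_unity(self, toy_system):
        params = make_params(cs_log_alpha=np.log(0.01))
        p_stay, p_city, p_cs = step1_leave_probs(toy_system, params)
        assert np.allclose(p_stay + p_city + p_cs, 1.0)
        assert np.all((p_city >= 0) & (p_city <= 1))

    def test_scale_free_when_linear(self, toy_system):
        params = make_params(leave_beta=1.0, leave_log_alpha=np.log(0.04))
        _, p_city, _ = step1_leave_probs(toy_system, params)
        assert np.allclose(p_city, 0.04)

    def test_error_when_probabilities_exceed_one(self, toy_system):
        params = make_params(leave_beta=1.5, leave_log_alpha=0.0, cs_log_alpha=np.log(0.9))
        with pytest.raises(ValueError, match="extrapolated"):
            step1_leave_probs(toy_system, params)


class TestDestinationKernels:
    def test_equal_sizes_split_evenly(self):
        system = make_planar_system([500, 2000, 2000], [(0, 0), (5, 0), (9, 0)])
        probs = destination_probs_scaling(0, system, make_params(dest_beta=0.7))
        assert probs[0] == 0.0
        assert probs[1] == pytest.approx(0.5) and probs[2] == pytest.approx(0.5)

    def test_linear_kernel_proportional_to_size(self):
        system = make_planar_system([500, 1_000_000, 3_000_000], [(0, 0), (5, 0), (9, 0)])
        probs = destination_probs_scaling(0, system, make_params(dest_beta=1.0))
        assert probs[1] == pytest.approx(0.25) and probs[2] == pytest.approx(0.75)

    def test_countryside_kernel_favours_small_cities_per_capita(self):
        system = make_planar_system([200_000, 20_000_000], [(0, 0), (5, 0)])
        params = make_params()
        probs = destination_probs_scaling(COUNTRYSIDE, system, params)
        per_capita = probs / system.populations
        assert per_capita[0] / per_capita[1] == pytest.approx(0.01 ** (0.5971 - 1), rel=1e-9)

    def test_gravity_scaling_equidistant_recovers_scaling(self):
        system = make_planar_system([500, 1000, 2000], [(0, 0), (0, 7), (0, -7)])
        params = make_params(dest_beta=0.8)
        pi = destination_probs_scaling(0, system, params)
        pi_gs = destination_probs_gravity_scaling(0, system, params)
        assert np.allclose(pi, pi_gs)

    def test_gravity_scaling_inverse_distance(self):
        system = make_planar_system([500, 1000, 1000], [(0, 0), (10, 0), (20, 0)])
        probs = destination_probs_gravity_scaling(0, system, make_params(dest_beta=0.9))
        assert probs[1] == pytest.approx(2 / 3) and probs[2] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("kernel_seed", range(3))
    def test_probability_vectors_sum_to_one(self, kernel_seed):
        spec = SynthSpec(n_cities=15, rng_seed=kernel_seed)
        system = gen_city_system(spec)
        params = make_params(dest_beta=0.9)
        for i in range(system.n):
            assert destination_probs_scaling(i, system, params).sum() == pytest.approx(
                1.0, abs=1e-12
            )
            assert destination_probs_gravity_scaling(
                i, system, params
            ).sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_region_rejected(self, toy_system):
        with pytest.raises(KeyError, match="Atlantis"):
            destination_probs_scaling("Atlantis", toy_system, make_params())


class TestSimulator:
    def test_mean_flows_match_analytic_expectation(self, toy_system):
        params = make_params(leave_beta=0.9, leave_log_alpha=np.log(0.3), dest_beta=1.0)
        config = SimulationConfig(sample_fraction=1.0, n_reps=400, rng_seed=99, keep_reps=True)
        result = simulate_two_step(toy_system, params, config)
        expected = expected_flow_matrix(toy_system, params, "scaling")
        mean = result.per_rep_flows.mean(axis=0)
        se = result.per_rep_flows.std(axis=0, ddof=1) / np.sqrt(config.n_reps)
        off = ~np.eye(3, dtype=bool)
        assert np.all(np.abs(mean - expected)[off] <= 3 * se[off] + 1e-9)

    def test_zero_leave_rate_gives_zero_flows(self, toy_system):
        params = make_params(leave_log_alpha=-1000.0)
        config = SimulationConfig(sample_fraction=1.0, n_reps=5, rng_seed=1)
        result = simulate_two_step(toy_system, params, config)
        assert result.flows.total == 0

    def test_seed_determinism(self, toy_system):
        params = make_params()
        config = SimulationConfig(sample_fraction=0.5, n_reps=10, rng_seed=77)
        r1 = simulate_two_step(toy_system, params, config)
        r2 = simulate_two_step(toy_system, params, config)
        assert r1.flows == r2.flows
        assert np.array_equal(r1.to_countryside, r2.to_countryside)

    def test_leavers_never_exceed_population(self):
        system = make_planar_system(
            [1000, 5000, 20000], [(0, 0), (8, 0), (16, 0)], countryside=10000
        )
        params = make_params(leave_beta=1.0, leave_log_alpha=np.log(0.4),
                             cs_beta=1.0, cs_log_alpha=np.log(0.3))
        config = SimulationConfig(sample_fraction=1.0, n_reps=50, rng_seed=3, keep_reps=True)
        result = simulate_two_step(system, params, config)
        leavers = result.per_rep_flows.sum(axis=2)
        assert np.all(leavers <= system.populations[None, :])

    def test_countryside_channel_active(self):
        system = make_planar_system([1000, 5000], [(0, 0), (8, 0)], countryside=100000)
        params = make_params()
        config = SimulationConfig(sample_fraction=1.0, n_reps=30, rng_seed=5)
        result = simulate_two_step(system, params, config)
        total_in = result.from_countryside.sum()
        expected = 100000 * 0.0322
        assert abs(total_in - expected) < 5 * np.sqrt(expected)


class TestInternationalInflow:
    def test_linear_region_allocates_proportionally(self, rng):
        system = make_planar_system([100_000, 900_000], [(0, 0), (5, 0)])
        params = make_params()
        params.international_dest_fits["Europe"] = make_fit(1.0, -10.0)
        alloc = international_inflow(system, params, {"Europe": 100_000}, rng)
        share = alloc["Europe"].iloc[1] / 100_000
        assert share == pytest.approx(0.9, abs=0.01)

    def test_unknown_region(self, toy_system):
        with pytest.raises(KeyError):
            international_inflow(toy_system, make_params(), {"Mars": 10}, 0)


class TestGravity:
    def test_hand_arithmetic_and_symmetry(self):
        system = make_planar_system([10, 20], [(0, 0), (7, 0)])
        F = gravity_flux(system, GravityParams(a=1.0, b=0.0))
        assert F[0, 1] == pytest.approx(200.0)
        assert F[0, 1] == F[1, 0]

    def test_formula_evaluation(self):
        system = make_planar_system([1_000_000, 1_000_000], [(0, 0), (100, 0)])
        F = gravity_flux(system, GravityParams(a=2.59e-6, b=0.753))
        assert F[0, 1] == pytest.approx(2.59e6 / 100**0.753, rel=1e-12)

    def test_symmetric_matrix_on_random_system(self):
        spec = SynthSpec(n_cities=12, rng_seed=5)
        system = gen_city_system(spec)
        F = gravity_flux(system, GravityParams(a=1e-6, b=1.0))
        assert np.allclose(F, F.T)

    def test_exact_recovery_zero_residual(self):
        spec = SynthSpec(n_cities=40, kernel="gravity", rng_seed=8,
                         gravity_a=3.1e-6, gravity_b=1.2)
        system = gen_city_system(spec)
        M = expected_flows(system, spec)
        observed = FlowMatrix(np.rint(M), system.ids)
        fit = fit_gravity(system, observed)
        assert fit.b == pytest.approx(1.2, abs=5e-3)
        assert fit.a == pytest.approx(3.1e-6, rel=0.02)

    def test_scale_equivariance(self):
        spec = SynthSpec(n_cities=30, kernel="gravity", rng_seed=9)
        system = gen_city_system(spec)
        flow = gen_flows(system, spec)
        doubled = FlowMatrix(flow.counts * 2, flow.ids)
        f1 = fit_gravity(system, flow)
        f2 = fit_gravity(system, doubled)
        assert f2.a == pytest.approx(2 * f1.a, rel=1e-4)
        assert f2.b == pytest.approx(f1.b, abs=1e-4)

    def test_all_zero_flows_rejected(self):
        spec = SynthSpec(n_cities=10, rng_seed=4)
        system = gen_city_system(spec)
        zero = FlowMatrix(np.zeros((10, 10), dtype=int), system.ids)
        with pytest.raises(Exception, match="all-zero"):
            fit_gravity(system, zero)

    def test_gravity_scaling_is_generically_asymmetric(self):
        spec = SynthSpec(n_cities=10, rng_seed=13)
        system = gen_city_system(spec)
        params = make_params(dest_beta=0.9)
        F = expected_flow_matrix(system, params, "gravity-scaling")
        assert not np.allclose(F, F.T)

    def test_equal_distances_collapse_to_scaling(self):
        # equilateral triangle: every pair equidistant
        system = make_planar_system(
            [1000, 2000, 4000], [(0, 0), (10, 0), (5, 10 * np.sqrt(3) / 2)]
        )
        params = make_params(dest_beta=0.8)
        F_s = expected_flow_matrix(system, params, "scaling")
        F_gs = expected_flow_matrix(system, params, "gravity-scaling")
        assert np.allclose(F_s, F_gs)


class TestRadiation:
    def test_intervening_nearest_and_farthest(self):
        system = make_planar_system(
            [100, 200, 300, 400], [(0, 0), (1, 0), (2, 0), (3, 0)]
        )
        assert intervening_population(system, 0, 1) == 0
        assert intervening_population(system, 0, 3) == 200 + 300

    def test_intervening_matches_bruteforce(self):
        spec = SynthSpec(n_cities=20, rng_seed=17)
        system = gen_city_system(spec)
        d = system.distance_matrix()
        P = system.populations
        for i in range(20):
            for j in range(20):
                if i == j:
                    continue
                brute = sum(
                    int(P[k]) for k in range(20) if k not in (i, j) and d[i, k] < d[i, j]
                )
                assert intervening_population(system, i, j) == brute

    def test_two_city_closed_form(self):
        system = make_planar_system([100, 300], [(0, 0), (5, 0)])
        F = radiation_flux(system, [50, 60])
        assert F[0, 1] == pytest.approx(50.0)
        assert F[1, 0] == pytest.approx(60.0)

    def test_three_city_line_hand_values(self):
        system = make_planar_system([100, 100, 100], [(0, 0), (1, 0), (2, 0)])
        F = radiation_flux(system, [40, 40, 40])
        # middle city splits evenly
        assert F[1, 0] == pytest.approx(20.0) and F[1, 2] == pytest.approx(20.0)
        # end city: weights 1/2 (adjacent) and 1/6 (far, s=100) -> 3/4, 1/4
        assert F[0, 1] == pytest.approx(30.0)
        assert F[0, 2] == pytest.approx(10.0)

    def test_rows_match_supplied_outflows(self):
        spec = SynthSpec(n_cities=25, rng_seed=19)
        system = gen_city_system(spec)
        out = np.arange(1, 26) * 10.0
        F = radiation_flux(system, out)
        assert np.allclose(F.sum(axis=1), out)
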