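"""Gillespie engine, ensemble statistics and the master-equation oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbsquench.dynamics import (
    DecayEnsemble,
    Trajectory,
    gillespie_run,
    master_equation_channel_fractions,
    master_equation_mean_lifetime,
    master_equation_solve,
    master_equation_survival,
    mean_lifetime,
    quench_fraction,
    run_ensemble,
    survival_curve,
)
from pbsquench.errors import ConfigurationError, NonTerminatingStateError
from pbsquench.kinetics import RateMatrix
from pbsquench.network import PigmentClass
from pbsquench.synthetic import CanParameterSpec, make_can_sampler


def single_pigment(rate=1.0):
    return RateMatrix(np.zeros((1, 1)), np.array([rate]), ["p0"])


def make_ensemble(decay_times, classes=None):
    trajectories = [
        Trajectory([(0.0, 0)], t, 0, seed) for seed, t in enumerate(decay_times)
    ]
    classes = classes or [PigmentClass.APCA_PCB] * len(decay_times)
    return DecayEnsemble(trajectories, classes)


class TestGillespie:
    def test_single_pigment_exponential_mean(self):
        times = np.array(
            [gillespie_run(single_pigment(1.0), 0, s).decay_time
             for s in range(10_000)]
        )
        # Exponential(1): mean 1 ps, SE = 1/√N; allow 3 SE
        assert abs(times.mean() - 1.0) < 3.0 / np.sqrt(10_000)

    def test_disconnected_pigment_never_visited(self):
        rates = RateMatrix(np.zeros((2, 2)), np.array([0.5, 0.5]), ["a", "b"])
        for s in range(50):
            traj = gillespie_run(rates, 0, s)
            assert all(idx == 0 for _, idx in traj.hops)
            assert traj.terminal_index == 0

    def test_identical_seed_bit_identical(self):
        rng = np.random.default_rng(5)
        transfer = rng.uniform(0, 1, (4, 4))
        np.fill_diagonal(transfer, 0)
        rates = RateMatrix(transfer, rng.uniform(0.1, 0.5, 4),
                           [f"p{i}" for i in range(4)])
        a = gillespie_run(rates, 2, 99)
        b = gillespie_run(rates, 2, 99)
        assert a.hops == b.hops
        assert a.decay_time == b.decay_time

    def test_reachable_absorbing_state_rejected(self):
        transfer = np.array([[0.0, 1.0], [0.0, 0.0]])
        rates = RateMatrix(transfer, np.array([0.1, 0.0]), ["a", "b"])
        with pytest.raises(NonTerminatingStateError, match="b"):
            gillespie_run(rates, 0, 1)
        # unreachable absorbing state is fine
        rates2 = RateMatrix(np.zeros((2, 2)), np.array([0.1, 0.0]), ["a", "b"])
        gillespie_run(rates2, 0, 1)

    def test_survival_matches_master_equation_on_random_network(self):
        """Core oracle-equivalence property on a 6-pigment network."""
        rng = np.random.default_rng(41)
        n = 6
        transfer = rng.uniform(0, 0.4, (n, n))
        np.fill_diagonal(transfer, 0)
        rates = RateMatrix(transfer, rng.uniform(0.05, 0.3, n),
                           [f"p{i}" for i in range(n)])
        n_runs = 3000
        decays = np.array(
            [gillespie_run(rates, 0, 1000 + s).decay_time for s in range(n_runs)]
        )
        times = np.linspace(0.5, 15.0, 10)
        p0 = np.eye(n)[0]
        s_exact = master_equation_survival(rates, p0, times)
        s_mc = (decays[None, :] > times[:, None]).mean(axis=1)
        sigma = np.sqrt(s_exact * (1 - s_exact) / n_runs)
        assert np.all(np.abs(s_mc - s_exact) < 3.5 * sigma)


class TestTrajectoryInvariants:
    def test_times_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            Trajectory([(0.0, 0), (0.0, 1)], 1.0, 1, 0)

    def test_decay_after_last_hop(self):
        with pytest.raises(ValueError):
            Trajectory([(0.0, 0), (2.0, 1)], 1.0, 1, 0)

    def test_terminal_matches_last_hop(self):
        with pytest.raises(ValueError):
            Trajectory([(0.0, 0)], 1.0, 3, 0)


class TestSurvivalAndLifetime:
    def test_step_function_for_identical_decays(self):
        ens = make_ensemble([5.0] * 20)
        grid = np.array([0.0, 4.99, 5.0, 10.0])
        assert survival_curve(ens, grid).tolist() == [1.0, 1.0, 0.0, 0.0]

    def test_exponential_band(self):
        rng = np.random.default_rng(8)
        k = 0.01
        ens = make_ensemble(rng.exponential(1 / k, 10_000))
        grid = np.array([10.0, 50.0, 100.0, 300.0])
        s = survival_curve(ens, grid)
        expected = np.exp(-k * grid)
        sigma = np.sqrt(expected * (1 - expected) / 10_000)
        assert np.all(np.abs(s - expected) < 4 * sigma)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_survival_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        ens = make_ensemble(rng.exponential(10.0, 50))
        s = survival_curve(ens, np.linspace(0, 100, 40))
        assert np.all(np.diff(s) <= 0)
        assert s[0] <= 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            survival_curve(make_ensemble([1.0]), [])

    def test_mean_of_small_set(self):
        est = mean_lifetime(make_ensemble([1.0, 2.0, 3.0]))
        assert est.mean == pytest.approx(2.0)
        assert est.se == pytest.approx(1.0 / np.sqrt(3))

    def test_exponential_mean_100ps(self):
        rng = np.random.default_rng(12)
        ens = make_ensemble(rng.exponential(100.0, 10_000))
        est = mean_lifetime(ens)
        assert abs(est.mean - 100.0) < 3 * 100.0 / np.sqrt(10_000)
        assert est.exp_fit == est.mean


class TestQuenchFraction:
    def test_no_can_terminal(self):
        assert quench_fraction(make_ensemble([1.0, 2.0])) == 0.0

    def test_overwhelming_sink(self):
        # CAN coupled with overwhelming rate: every run ends on the sink
        transfer = np.array([[0.0, 1e4], [1e-6, 0.0]])
        rates = RateMatrix(transfer, np.array([1e-4, 1e3]), ["pcb", "can"])
        terminals = [gillespie_run(rates, 0, s).terminal_index for s in range(200)]
        classes = [PigmentClass.CAN if t == 1 else PigmentClass.APCA_PCB
                   for t in terminals]
        ens = DecayEnsemble(
            [Trajectory([(0.0, 0)], 1.0, 0, 0)] * len(classes), classes
        )
        assert quench_fraction(ens) > 0.99

    def test_matches_flux_splitting_oracle(self):
        """Terminal-channel frequencies vs the time-integrated flux
        decomposition of the master equation on a 4-pigment toy."""
        rng = np.random.default_rng(19)
        transfer = rng.uniform(0.05, 0.5, (4, 4))
        np.fill_diagonal(transfer, 0)
        decay = np.array([0.02, 0.05, 0.3, 0.08])
        rates = RateMatrix(transfer, decay, list("abcd"))
        p0 = np.eye(4)[0]
        expected = master_equation_channel_fractions(rates, p0)
        assert expected.sum() == pytest.approx(1.0, abs=1e-10)
        n_runs = 4000
        terminals = np.array(
            [gillespie_run(rates, 0, 7000 + s).terminal_index
             for s in range(n_runs)]
        )
        observed = np.bincount(terminals, minlength=4) / n_runs
        sigma = np.sqrt(expected * (1 - expected) / n_runs)
        assert np.all(np.abs(observed - expected) < 4 * sigma)


class TestMasterEquation:
    def test_single_pigment_scalar_decay(self):
        rates = single_pigment(0.2)
        times = np.array([0.0, 1.0, 5.0, 10.0])
        p = master_equation_solve(rates, [1.0], times)
        assert np.allclose(p[:, 0], np.exp(-0.2 * times), atol=1e-10)

    def test_closed_symmetric_exchange_equilibrates(self):
        transfer = np.array([[0.0, 0.3], [0.3, 0.0]])
        rates = RateMatrix(transfer, np.zeros(2), ["a", "b"])
        p = master_equation_solve(rates, [1.0, 0.0], [100.0])
        assert np.allclose(p[0], [0.5, 0.5], atol=1e-10)

    def test_probability_conservation(self):
        rng = np.random.default_rng(29)
        n = 5
        transfer = rng.uniform(0, 0.5, (n, n))
        np.fill_diagonal(transfer, 0)
        decay = rng.uniform(0.01, 0.1, n)
        rates = RateMatrix(transfer, decay, [f"p{i}" for i in range(n)])
        times = np.linspace(0.0, 50.0, 501)
        p = master_equation_solve(rates, np.eye(n)[2], times)
        assert np.all(p >= -1e-10)
        # population + cumulative decayed mass = 1 (fine trapezoidal grid)
        flux = (p * decay).sum(axis=1)
        decayed = np.concatenate(
            [[0.0], np.cumsum(0.5 * (flux[1:] + flux[:-1]) * np.diff(times))]
        )
        assert np.allclose(p.sum(axis=1) + decayed, 1.0, atol=1e-4)
        # analytic mean lifetime equals the integrated survival
        mean_lt = master_equation_mean_lifetime(rates, np.eye(n)[2])
        grid = np.linspace(0, 1500.0, 1501)
        integral = np.trapezoid(
            master_equation_survival(rates, np.eye(n)[2], grid), grid
        )
        assert mean_lt == pytest.approx(integral, rel=1e-3)

    def test_dimension_validation(self):
        with pytest.raises(ValueError):
            master_equation_solve(single_pigment(), [0.5, 0.5], [1.0])


class TestRunEnsemble:
    def test_no_rod_pigments_rejected(self, toy_network, lineshapes):
        core_only = toy_network
        import copy

        net = copy.deepcopy(core_only)
        for p in net.pigments:
            if p.pigment_class is PigmentClass.ROD_PCB:
                p.pigment_class = PigmentClass.APCB_PCB
        with pytest.raises(ConfigurationError, match="ROD_PCB"):
            run_ensemble(net, None, lineshapes, 2, 1)

    def test_reproducible_from_master_seed(self, toy_network, lineshapes):
        spec = CanParameterSpec()
        sampler = make_can_sampler(spec, toy_network.metadata["can_attachment"])
        a = run_ensemble(toy_network, sampler, lineshapes, 10, 123)
        b = run_ensemble(toy_network, sampler, lineshapes, 10, 123)
        assert np.array_equal(a.decay_times, b.decay_times)
        assert a.sampled_parameters == b.sampled_parameters
        c = run_ensemble(toy_network, sampler, lineshapes, 10, 124)
        assert not np.array_equal(a.decay_times, c.decay_times)

    def test_unquenched_matches_master_equation(
        self, unquenched_network, lineshapes
    ):
        """With no carotenoids the ensemble mean lifetime must match the
        master-equation mean over uniformly sampled rod starts."""
        from pbsquench.kinetics import build_rate_matrix

        net = unquenched_network
        ens = run_ensemble(net, None, lineshapes, 400, 77)
        est = mean_lifetime(ens)
        rates = build_rate_matrix(net, lineshapes)
        rod = net.indices_of_class(PigmentClass.ROD_PCB)
        p0 = np.zeros(rates.n)
        p0[rod] = 1.0 / rod.size
        expected = master_equation_mean_lifetime(rates, p0)
        assert abs(est.mean - expected) < 4 * est.se

    def test_quenching_monotone_in_coupling(self, lineshapes):
        """Increasing the CAN coupling never lengthens the master-equation
        lifetime on a small chain + sink network (coupling grid check)."""
        from pbsquench.kinetics import pair_rates

        lifetimes = []
        for v in (0.0, 10.0, 30.0, 60.0, 120.0):
            transfer = np.zeros((3, 3))
            # chain: rod-like -> ApcA-like, fixed
            k_f, k_b = pair_rates(16130.0, 15150.0, 15.0,
                                  lineshapes["pcb"], lineshapes["pcb"], 300.0)
            transfer[0, 1], transfer[1, 0] = k_f, k_b
            if v > 0:
                k_f, k_b = pair_rates(15150.0, 14731.0, v,
                                      lineshapes["pcb"], lineshapes["can"], 300.0)
                transfer[1, 2], transfer[2, 1] = k_f, k_b
            rates = RateMatrix(
                transfer, np.array([1 / 1600, 1 / 1600, 0.25]),
                ["rod", "apca", "can"],
            )
            lifetimes.append(
                master_equation_mean_lifetime(rates, np.eye(3)[0])
            )
        assert all(b <= a + 1e-9 for a, b in zip(lifetimes, lifetimes[1:]))
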