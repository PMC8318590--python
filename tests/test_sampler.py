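import math

import numpy as np
import pytest

from ptmetad import (GridAxis, Hill, HillsLedger, MetaDParams,
                     ParallelTempering, Replica, ReplicaLadder, WTEParams,
                     bias_energy, hill_height, langevin_step, make_potential,
                     pt_exchange, run_wt_metad, steered_run, wte_prestage,
                     DEFAULT_LADDER)
from ptmetad.constants import KB
from ptmetad.sampler import LangevinState

from oracles import direct_gaussian_sum, pt_acceptance_quadrature


class TestPotentials:
    @pytest.mark.parametrize("name,params", [
        ("harmonic", {"k": 120.0}),
        ("double_well_1d", {"barrier": 10.0, "tilt": 3.0}),
        ("double_well_2d", {"barrier": 10.0, "tilt": 2.0, "ky": 40.0}),
        ("mueller_brown", {}),
    ])
    def test_gradient_matches_finite_difference(self, name, params):
        pot = make_potential(name, **params)
        rng = np.random.default_rng(0)
        lo, hi = pot.domain
        x = rng.uniform(np.atleast_1d(lo), np.atleast_1d(hi),
                        size=(20, pot.dim))
        g = pot.gradient(x)
        eps = 1e-6
        for k in range(pot.dim):
            dx = np.zeros(pot.dim)
            dx[k] = eps
            fd = (pot.energy(x + dx) - pot.energy(x - dx)) / (2 * eps)
            np.testing.assert_allclose(g[:, k], fd, rtol=1e-5, atol=1e-7)

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown potential"):
            make_potential("quartic_swamp")


class TestHillHeight:
    def test_zero_bias_gives_w0(self):
        p = MetaDParams(w0=4.0, bias_factor=15.0)
        assert hill_height(0.0, p, 300.0) == 4.0

    def test_halves_at_log2_scale(self):
        p = MetaDParams(w0=4.0, bias_factor=15.0)
        v = (p.bias_factor - 1) * KB * 300.0 * math.log(2)
        assert hill_height(v, p, 300.0) == pytest.approx(2.0)

    def test_large_bias_factor_limit(self):
        p = MetaDParams(w0=4.0, bias_factor=1e9)
        assert hill_height(50.0, p, 300.0) == pytest.approx(4.0, rel=1e-6)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            hill_height(0.0, MetaDParams(), -5.0)


class TestBiasEnergy:
    def test_empty_ledger(self):
        assert bias_energy([0.0], HillsLedger()) == 0.0

    def test_single_hill_center_and_one_sigma(self):
        ledger = HillsLedger()
        ledger.append(Hill(1.0, [0.3], [0.1], 2.0))
        assert bias_energy([0.3], ledger) == pytest.approx(2.0)
        assert bias_energy([0.4], ledger) == pytest.approx(2.0 * math.exp(-0.5))

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(9)
        ledger = HillsLedger()
        for t in range(1, 51):
            ledger.append(Hill(float(t), rng.uniform(-1, 1, 2),
                               rng.uniform(0.05, 0.3, 2),
                               rng.uniform(0.1, 2.0)))
        for _ in range(20):
            p = rng.uniform(-1.5, 1.5, 2)
            want = direct_gaussian_sum(p, ledger.centers, ledger.sigmas,
                                       ledger.heights)
            assert bias_energy(p, ledger) == pytest.approx(want, rel=1e-12)

    def test_dimension_mismatch(self):
        ledger = HillsLedger()
        ledger.append(Hill(1.0, [0.0, 0.0], [0.1, 0.1], 1.0))
        with pytest.raises(ValueError, match="dimensionality"):
            bias_energy([0.0], ledger)


class TestLedgerInvariants:
    def test_times_strictly_increasing(self):
        ledger = HillsLedger()
        ledger.append(Hill(1.0, [0.0], [0.1], 1.0))
        with pytest.raises(ValueError, match="strictly increasing"):
            ledger.append(Hill(1.0, [0.0], [0.1], 1.0))

    def test_height_capped_at_w0(self):
        ledger = HillsLedger(params=MetaDParams(w0=1.0))
        with pytest.raises(ValueError, match="W0"):
            ledger.append(Hill(1.0, [0.0], [0.1], 2.0))


class TestLangevinStep:
    def test_zero_gradient_no_noise_keeps_position(self):
        pot = make_potential("harmonic", k=50.0)
        state = LangevinState([0.0], [0.0])
        out = langevin_step(state, pot, 300.0, 2.0, 0.01, rng=None)
        assert out.x == pytest.approx([0.0])
        assert out.v == pytest.approx([0.0])

    def test_deterministic_update_matches_hand_computation(self):
        k, dt, fr = 50.0, 0.01, 2.0
        pot = make_potential("harmonic", k=k)
        x0, v0 = 0.2, 0.1
        out = langevin_step(LangevinState([x0], [v0]), pot, 300.0, fr, dt,
                            rng=None)
        # BAOAB without noise: half kick, half drift, damp, half drift, kick
        v = v0 + 0.5 * dt * (-k * x0)
        x = x0 + 0.5 * dt * v
        v = math.exp(-fr * dt) * v
        x = x + 0.5 * dt * v
        v = v + 0.5 * dt * (-k * x)
        assert out.x[0] == pytest.approx(x, rel=1e-12)
        assert out.v[0] == pytest.approx(v, rel=1e-12)

    def test_seeded_reproducibility(self):
        pot = make_potential("double_well_1d")
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            state = LangevinState([-0.5], [0.0])
            for _ in range(100):
                state = langevin_step(state, pot, 300.0, 2.0, 0.01, rng)
            runs.append(state.x.copy())
        np.testing.assert_array_equal(runs[0], runs[1])


class TestWtMetad:
    def test_hill_count_and_schedule_bound(self):
        pot = make_potential("double_well_1d")
        metad = MetaDParams(w0=4.0, bias_factor=15.0, stride=1.0,
                            widths=[0.05])
        traj, ledger = run_wt_metad(pot, metad, n_steps=10_000, dt=0.01,
                                    seed=3)
        assert len(ledger) == 100  # one hill per ps over 100 ps
        assert np.all(ledger.heights <= 4.0 + 1e-12)
        assert np.all(ledger.heights > 0)
        # heights decay on average as the bias fills
        assert ledger.heights[-20:].mean() < ledger.heights[:20].mean()

    def test_bit_reproducible_ledgers(self):
        pot = make_potential("double_well_1d")
        metad = MetaDParams(stride=1.0, widths=[0.05])
        _, l1 = run_wt_metad(pot, metad, n_steps=5_000, dt=0.01, seed=11)
        _, l2 = run_wt_metad(pot, metad, n_steps=5_000, dt=0.01, seed=11)
        np.testing.assert_array_equal(l1.centers, l2.centers)
        np.testing.assert_array_equal(l1.heights, l2.heights)

    def test_late_hills_shrink_on_bounded_domain(self):
        # well-tempered convergence: late heights fall below 0.1 W0
        pot = make_potential("double_well_1d", barrier=6.0)
        metad = MetaDParams(w0=4.0, bias_factor=15.0, stride=1.0,
                            widths=[0.05])
        _, ledger = run_wt_metad(pot, metad, n_steps=250_000, dt=0.01, seed=5)
        # typical late heights converge below 0.1 W0 (rare excursions to
        # the domain edge can still deposit larger hills)
        assert np.median(ledger.heights[-100:]) < 0.4


class TestPtExchange:
    @staticmethod
    def replica(temp, x, pot, ledger=None):
        bias = None
        if ledger is not None:
            class _L:
                def __init__(self, led):
                    self.led = led

                def value(self, x):
                    return bias_energy(np.atleast_1d(x), self.led)
            bias = _L(ledger)
        return Replica(temp, np.atleast_1d(x), np.zeros(1), pot, cv_bias=bias)

    def test_equal_temperature_equal_bias_always_accepts(self):
        pot = make_potential("harmonic", k=50.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            ri = self.replica(300.0, rng.normal(), pot)
            rj = self.replica(300.0, rng.normal(), pot)
            assert pt_exchange(ri, rj, rng)

    def test_accepts_when_delta_nonnegative(self):
        pot = make_potential("harmonic", k=50.0)
        rng = np.random.default_rng(1)
        # hotter replica holds the lower-energy configuration: delta >= 0
        ri = self.replica(300.0, 1.0, pot)
        rj = self.replica(400.0, 0.0, pot)
        assert pt_exchange(ri, rj, rng)

    def test_swap_moves_coordinates_not_ledgers(self):
        pot = make_potential("harmonic", k=50.0)
        ledger = HillsLedger()
        ledger.append(Hill(1.0, [0.0], [0.1], 1.0))
        ri = self.replica(300.0, 1.0, pot, ledger)
        rj = self.replica(400.0, 0.0, pot)
        bias_before = ri.cv_bias
        assert pt_exchange(ri, rj, np.random.default_rng(2))
        assert ri.x[0] == 0.0 and rj.x[0] == 1.0
        assert ri.cv_bias is bias_before  # ledger stays with its rung

    def test_empirical_acceptance_matches_quadrature_oracle(self):
        # draw exact Boltzmann configurations for a harmonic well at two
        # temperatures; empirical swap acceptance must match the
        # analytically integrable rate
        k, ti, tj = 80.0, 300.0, 500.0
        pot = make_potential("harmonic", k=k)
        rng = np.random.default_rng(7)
        n = 100_000
        xi = rng.normal(0, math.sqrt(KB * ti / k), n)
        xj = rng.normal(0, math.sqrt(KB * tj / k), n)
        accepted = 0
        bi, bj = 1 / (KB * ti), 1 / (KB * tj)
        u = rng.random(n)
        delta = (bi - bj) * (0.5 * k * xj ** 2 - 0.5 * k * xi ** 2)
        accepted = np.sum(u < np.minimum(1.0, np.exp(delta)))
        want = pt_acceptance_quadrature(k, ti, tj, KB)
        sigma = math.sqrt(want * (1 - want) / n)
        assert abs(accepted / n - want) < 2 * sigma + 1e-3

    def test_mismatched_dimensions(self):
        pot = make_potential("harmonic", k=50.0)
        ri = Replica(300.0, np.zeros(1), np.zeros(1), pot)
        rj = Replica(305.0, np.zeros(2), np.zeros(2), pot)
        with pytest.raises(ValueError, match="dimensionality"):
            pt_exchange(ri, rj, np.random.default_rng(0))


class TestWtePrestage:
    def test_equal_temperatures_terminate_immediately(self):
        pot = make_potential("double_well_2d")
        ladder = ReplicaLadder(temperatures=(300.0,) * 4)
        res = wte_prestage(ladder, pot, WTEParams(), seed=1)
        assert res.achieved_rate == 1.0
        # stops at the first rate check: only minimal deposition
        assert len(res.ledgers[0]) < 0.05 * WTEParams().max_hills_per_replica

    def test_default_energy_width_recorded(self):
        pot = make_potential("double_well_2d")
        ladder = ReplicaLadder()
        res = wte_prestage(ladder, pot, WTEParams(), seed=2)
        assert res.achieved_rate >= 0.15
        sig = res.ledgers[0].sigmas
        assert np.all(sig == 100.0)

    def test_energy_bias_broadens_fluctuations(self):
        # paired fixed-seed runs: depositing energy hills must broaden
        # the potential-energy distribution at the cold rung
        pot = make_potential("double_well_2d", barrier=8.0)
        ladder = ReplicaLadder(temperatures=(300.0, 310.0))

        def energy_variance(wte):
            pt = ParallelTempering(pot, ladder, seed=3, dt=0.02,
                                   wte=wte, record_every=5)
            pt.run(40_000)
            x = pt.trajectory(0).cvs
            burn = len(x) // 4
            return float(np.var(pot.energy(x[burn:])))

        var_biased = energy_variance(
            WTEParams(energy_hill_height=2.0, energy_sigma=5.0))
        var_plain = energy_variance(None)
        assert var_biased >= var_plain

    def test_unreachable_target_raises_with_rate(self):
        pot = make_potential("double_well_2d")
        ladder = ReplicaLadder(temperatures=(300.0, 2000.0),
                               exchange_period=2.0)
        wte = WTEParams(target_rate=0.99, max_hills_per_replica=30)
        with pytest.raises(RuntimeError, match="achieved"):
            wte_prestage(ladder, pot, wte, seed=4)


class TestSteeredRun:
    def test_stationary_target_fluctuates_about_start(self):
        pot = make_potential("double_well_1d")
        traj = steered_run(pot, [-0.5], [-0.5], 20_000, spring_k=5e3, seed=0)
        assert abs(traj.cvs[:, 0].mean() + 0.5) < 0.02

    def test_stiff_spring_reaches_target(self):
        pot = make_potential("double_well_1d", barrier=12.0)
        k = 1e4
        traj = steered_run(pot, [-0.5], [0.5], 50_000, spring_k=k, seed=1)
        sigma = math.sqrt(KB * 300.0 / k)
        assert abs(traj.cvs[-1, 0] - 0.5) < 2 * sigma + 0.05

    def test_distance_to_target_decreases(self):
        pot = make_potential("double_well_1d", barrier=12.0)
        traj = steered_run(pot, [-0.5], [0.5], 50_000, spring_k=1e4, seed=2)
        d = traj.aux["dist_to_target"]
        assert d[-1] < d[0] / 5

    def test_zero_steps_with_distinct_target(self):
        pot = make_potential("double_well_1d")
        with pytest.raises(ValueError, match="zero-step"):
            steered_run(pot, [-0.5], [0.5], 0)


class TestLadder:
    def test_default_is_eleven_rungs(self):
        ladder = ReplicaLadder()
        assert len(ladder) == 11
        assert ladder.temperatures[0] == 300.0
        assert ladder.temperatures[-1] == 382.0

    def test_single_rung_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ReplicaLadder(temperatures=(300.0,))

    def test_decreasing_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            ReplicaLadder(temperatures=(300.0, 290.0))
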