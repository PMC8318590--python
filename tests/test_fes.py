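import numpy as np
import pytest

from ptmetad import (FESGrid, GridAxis, Hill, HillsLedger, MetaDParams,
                     Trajectory, convergence_report, find_minima,
                     free_energy_difference, make_potential,
                     minimum_energy_path, reweight_project, sum_hills)
from ptmetad.constants import KB, KJ_PER_KCAL
from ptmetad.fes import KB_KCAL
from ptmetad.potentials import MUELLER_BROWN_MINIMA
from ptmetad.synthetic import HillsStreamSpec, make_hills_stream

from oracles import direct_gaussian_sum, minimax_barrier_reference


def grid_fes(values, mask=None, lo=-1.0, hi=1.0):
    """FESGrid from a raw value array (1D or 2D)."""
    values = np.asarray(values, dtype=float)
    axes = [GridAxis(f"cv{k+1}", lo, hi, n)
            for k, n in enumerate(values.shape)]
    return FESGrid(axes=axes, values=values, mask=mask)


class TestSumHills:
    def test_empty_ledger_flat_surface(self):
        ledger = HillsLedger(cv_names=["cv1"])
        fes = sum_hills(ledger, axes=[GridAxis("cv1", -1, 1, 64)])
        assert np.all(fes.values == 0.0)

    def test_single_hill_plateau_level(self):
        # far from a single hill the min-shifted FES plateaus at
        # (f/(f-1)) * height
        f = 15.0
        ledger = HillsLedger(params=MetaDParams(w0=4.0, bias_factor=f))
        ledger.append(Hill(1.0, [0.0], [0.05], 3.0))
        fes = sum_hills(ledger, axes=[GridAxis("cv1", -2, 2, 401)])
        plateau = f / (f - 1) * 3.0 / KJ_PER_KCAL
        assert fes.values[0] == pytest.approx(plateau, rel=1e-6)
        assert fes.values.min() == 0.0

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        f = 15.0
        ledger = HillsLedger(params=MetaDParams(w0=4.0, bias_factor=f))
        for t in range(1, 51):
            ledger.append(Hill(float(t), rng.uniform(-1, 1, 2),
                               rng.uniform(0.05, 0.2, 2),
                               rng.uniform(0.5, 4.0)))
        axes = [GridAxis("cv1", -1.5, 1.5, 64), GridAxis("cv2", -1.5, 1.5, 64)]
        fes = sum_hills(ledger, axes=axes)
        # compare interpolated F at random off-grid points with the
        # direct Gaussian sum (rescaled and shifted identically)
        vgrid = np.array([[direct_gaussian_sum([x, y], ledger.centers,
                                               ledger.sigmas, ledger.heights)
                           for y in axes[1].nodes] for x in axes[0].nodes])
        want = -f / (f - 1) * vgrid / KJ_PER_KCAL
        want -= want.min()
        np.testing.assert_allclose(fes.values, want, rtol=1e-6, atol=1e-9)

    def test_additivity_before_shift(self):
        rng = np.random.default_rng(4)
        axes = [GridAxis("cv1", -1, 1, 64)]

        def ledger_from(times):
            led = HillsLedger(params=MetaDParams(bias_factor=15.0))
            for t in times:
                led.append(Hill(float(t), rng.uniform(-1, 1, 1), [0.1], 1.0))
            return led

        a = ledger_from(range(1, 21))
        b = ledger_from(range(21, 41))
        ab = HillsLedger(params=a.params)
        for h in a.hills + b.hills:
            ab.append(h)
        va = ab.bias_at(axes[0].nodes[:, None])
        vb = (a.bias_at(axes[0].nodes[:, None])
              + b.bias_at(axes[0].nodes[:, None]))
        np.testing.assert_allclose(va, vb, rtol=1e-12)

    def test_projection_consistent_with_direct_1d(self):
        # separable 2D ledger: marginalising y must equal the direct 1D
        # reconstruction built from the x-components alone
        rng = np.random.default_rng(5)
        led2 = HillsLedger(params=MetaDParams(bias_factor=15.0),
                           cv_names=["cv1", "cv2"])
        led1 = HillsLedger(params=MetaDParams(bias_factor=15.0),
                           cv_names=["cv1"])
        # hills aligned on y=0 with a very wide y-sigma are effectively 1D
        for t in range(1, 31):
            c = rng.uniform(-1, 1)
            h = rng.uniform(0.5, 2.0)
            led2.append(Hill(float(t), [c, 0.0], [0.1, 1e4], h))
            led1.append(Hill(float(t), [c], [0.1], h))
        axes2 = [GridAxis("cv1", -1, 1, 96), GridAxis("cv2", -0.5, 0.5, 32)]
        proj = sum_hills(led2, axes=axes2, projection=["cv1"])
        direct = sum_hills(led1, axes=[axes2[0]])
        np.testing.assert_allclose(proj.values, direct.values, atol=1e-8)

    def test_unknown_projection_axis(self):
        ledger = HillsLedger()
        ledger.append(Hill(1.0, [0.0], [0.1], 1.0))
        with pytest.raises(ValueError):
            sum_hills(ledger, axes=[GridAxis("cv1", -1, 1, 16)],
                      projection=["nope"])


class TestConvergence:
    def test_converging_stream_passes(self):
        ledger = make_hills_stream(HillsStreamSpec("converging", seed=1))
        rep = convergence_report(ledger, threshold=2.5)
        assert rep.converged
        assert rep.max_delta < 0.1

    def test_drifting_stream_fails(self):
        ledger = make_hills_stream(HillsStreamSpec("drifting", seed=1))
        rep = convergence_report(ledger, threshold=2.5)
        assert not rep.converged
        assert rep.max_delta > 2.5

    def test_boundary_equals_threshold_passes(self):
        # the <= convention: max_delta exactly at the threshold converges
        ledger = make_hills_stream(HillsStreamSpec("drifting", seed=2))
        probe = convergence_report(ledger, threshold=0.0)
        at = convergence_report(ledger, threshold=probe.max_delta)
        below = convergence_report(ledger,
                                   threshold=probe.max_delta * (1 - 1e-9))
        assert at.converged
        assert not below.converged

    def test_window_defaults_to_trailing_tenth(self):
        ledger = make_hills_stream(HillsStreamSpec("converging", length=100))
        rep = convergence_report(ledger, window=1e9)
        assert rep.window == pytest.approx(0.1 * ledger.span)

    def test_diffusive_cv_counts_quartile_crossings(self):
        times = np.arange(200.0)
        osc = np.where(np.arange(200) % 20 < 10, -1.0, 1.0)
        traj = Trajectory(times=times, cvs=osc[:, None], cv_names=["cv1"])
        ledger = make_hills_stream(HillsStreamSpec("converging", length=200))
        rep = convergence_report(ledger, cv_series=traj)
        assert rep.diffusivity["cv1"] >= 1

    def test_empty_ledger_rejected(self):
        with pytest.raises(ValueError):
            convergence_report(HillsLedger(cv_names=["cv1"]))


class TestReweight:
    def test_zero_bias_reduces_to_histogram(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.1, 4000)
        traj = Trajectory(times=np.arange(len(x), dtype=float),
                          cvs=x[:, None], cv_names=["cv1"])
        axis = GridAxis("cv1", -0.4, 0.4, 17)
        fes = reweight_project(traj, x, 300.0, [axis])
        hist, _ = np.histogram(x, bins=np.concatenate(
            [axis.nodes - axis.spacing / 2,
             [axis.nodes[-1] + axis.spacing / 2]]))
        want = -KB * 300.0 * np.log(np.where(hist > 0, hist, np.nan))
        want = (want - np.nanmin(want)) / KJ_PER_KCAL
        np.testing.assert_allclose(fes.values[fes.mask], want[hist > 0],
                                   rtol=1e-9)

    def test_all_frames_one_bin(self):
        traj = Trajectory(times=[0.0, 1.0], cvs=np.zeros((2, 1)),
                          cv_names=["cv1"])
        fes = reweight_project(traj, np.zeros(2), 300.0,
                               [GridAxis("cv1", -1, 1, 5)])
        assert fes.mask.sum() == 1
        assert fes.values[fes.mask][0] == 0.0

    def test_empty_bins_flagged_not_zero(self):
        traj = Trajectory(times=[0.0, 1.0], cvs=np.array([[-0.9], [0.9]]),
                          cv_names=["cv1"])
        fes = reweight_project(traj, np.array([-0.9, 0.9]), 300.0,
                               [GridAxis("cv1", -1, 1, 11)])
        assert np.isnan(fes.values[~fes.mask]).all()
        assert fes.mask.sum() == 2


class TestFindMinima:
    def test_single_parabola_one_basin(self):
        x = np.linspace(-1, 1, 101)
        basins = find_minima(grid_fes(5.0 * x ** 2), min_depth=0.1)
        assert len(basins) == 1
        assert basins[0].minimum == (50,)
        assert basins[0].depth == 0.0

    def test_two_well_depth_difference(self):
        x = np.linspace(-1.5, 1.5, 301)
        f = 8.0 * (np.abs(x) - 1.0) ** 2  # wells at ±1, barrier 8 at 0
        f[x > 0] += 2.0                   # right well raised by 2.0
        basins = find_minima(grid_fes(f, lo=-1.5, hi=1.5), min_depth=0.5)
        assert len(basins) == 2
        assert basins[1].depth - basins[0].depth == pytest.approx(2.0)

    def test_flat_surface_no_basins(self):
        basins = find_minima(grid_fes(np.zeros(64)), min_depth=0.1)
        assert basins == []

    def test_members_partition_sampled_nodes(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(20, 20))
        fes = grid_fes(z - z.min())
        basins = find_minima(fes, min_depth=0.0)
        all_members = [m for b in basins for m in b.members]
        assert len(all_members) == 400
        assert len(set(all_members)) == 400

    def test_mueller_brown_recovers_three_minima(self):
        pot = make_potential("mueller_brown")
        n = 128
        gx = np.linspace(-1.5, 1.2, n)
        gy = np.linspace(-0.5, 2.0, n)
        xx, yy = np.meshgrid(gx, gy, indexing="ij")
        u = pot.energy(np.stack([xx, yy], axis=-1))
        u = np.minimum(u - u.min(), 300.0)  # cap the high-energy rim
        axes = [GridAxis("x", -1.5, 1.2, n), GridAxis("y", -0.5, 2.0, n)]
        basins = find_minima(FESGrid(axes=axes, values=u), min_depth=5.0)
        assert len(basins) == 3
        cell = np.array([gx[1] - gx[0], gy[1] - gy[0]])
        found = np.array([b.coords for b in basins])
        for target in MUELLER_BROWN_MINIMA:
            d = np.abs(found - target).min(axis=0)
            assert np.all(d <= cell + 1e-9)


class TestFreeEnergyDifference:
    def two_well(self):
        x = np.linspace(-1.5, 1.5, 301)
        f = 8.0 * (np.abs(x) - 1.0) ** 2
        f[x > 0] += 2.0
        fes = grid_fes(f, lo=-1.5, hi=1.5)
        return fes, find_minima(fes, min_depth=0.5)

    def test_same_basin_zero(self):
        fes, basins = self.two_well()
        assert free_energy_difference(fes, basins[0], basins[0]) == 0.0

    def test_min_to_min_offset(self):
        fes, basins = self.two_well()
        assert free_energy_difference(fes, basins[0], basins[1]) == \
            pytest.approx(2.0)

    def test_integrated_favours_wide_shallow_well(self):
        # deep narrow vs shallow wide: min-to-min prefers the deep well,
        # the integrated difference can invert because of basin entropy
        x = np.linspace(0, 10, 1001)
        f = np.full_like(x, 6.0)
        narrow = (x > 0.9) & (x < 1.1)
        f[narrow] = 25.0 * (x[narrow] - 1.0) ** 2
        wide = (x > 4) & (x < 9)
        f[wide] = 0.7 + 0.15 * (x[wide] - 6.5) ** 2
        fes = grid_fes(f, lo=0, hi=10)
        basins = find_minima(fes, min_depth=1.0)
        assert len(basins) == 2
        mm = free_energy_difference(fes, basins[0], basins[1], "min-to-min")
        integ = free_energy_difference(fes, basins[0], basins[1], "integrated")
        assert mm > 0          # second basin's minimum lies higher
        assert integ < mm      # entropy of the wide basin reduces the gap

    def test_overlapping_basins_rejected(self):
        fes, basins = self.two_well()
        import dataclasses
        fake = dataclasses.replace(basins[1], members=basins[0].members)
        with pytest.raises(ValueError, match="overlap"):
            free_energy_difference(fes, basins[0], fake)


class TestMinimumEnergyPath:
    def test_single_node_path(self):
        fes = grid_fes(np.arange(25.0).reshape(5, 5))
        path = minimum_energy_path(fes, (2, 2), (2, 2))
        assert path.nodes == [(2, 2)]
        assert path.barrier == fes.values[2, 2]

    def test_flat_surface_deterministic(self):
        fes = grid_fes(np.zeros((6, 6)))
        p1 = minimum_energy_path(fes, (0, 0), (5, 5))
        p2 = minimum_energy_path(fes, (0, 0), (5, 5))
        assert p1.barrier == 0.0
        assert p1.nodes == p2.nodes
        assert len(p1.nodes) == 6  # diagonal moves allowed

    def test_two_channel_surface_picks_lower_saddle(self):
        f = np.full((8, 8), 10.0)
        f[0, :] = 1.0          # top channel, saddle 3
        f[0, 4] = 3.0
        f[7, :] = 1.0          # bottom channel, saddle 5
        f[7, 4] = 5.0
        f[:, 0] = 0.0          # left and right wells connect the channels
        f[:, 7] = 0.0
        fes = grid_fes(f)
        path = minimum_energy_path(fes, (3, 0), (3, 7))
        assert path.barrier == pytest.approx(3.0)
        assert any(n[0] <= 1 for n in path.nodes)  # crossed the top channel

    def test_matches_levelset_oracle_on_random_grids(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            vals = rng.uniform(0, 10, (8, 8))
            vals -= vals.min()
            fes = grid_fes(vals)
            start, end = (0, 0), (7, 7)
            path = minimum_energy_path(fes, start, end)
            want = minimax_barrier_reference(fes.values, fes.mask, start, end)
            assert path.barrier == pytest.approx(want, rel=1e-12)
            assert path.barrier >= max(fes.values[start], fes.values[end])

    def test_unsampled_nodes_are_impassable(self):
        vals = np.zeros((5, 5))
        mask = np.ones((5, 5), dtype=bool)
        mask[:, 2] = False  # wall splits the grid
        vals[:, 2] = np.nan
        fes = grid_fes(vals, mask=mask)
        with pytest.raises(ValueError, match="no connected"):
            minimum_energy_path(fes, (2, 0), (2, 4))
        with pytest.raises(ValueError, match="unsampled"):
            minimum_energy_path(fes, (0, 2), (2, 4))

    def test_barrier_monotone_under_coarsening(self):
        # nested grids of a fixed analytic surface whose crest column
        # (x = 0) is a node of every grid: a coarser grid samples a
        # subset of that column's y nodes, so its barrier cannot drop
        # below the finer grid's
        pot = make_potential("double_well_2d", barrier=10.0, ky=8.0)
        barriers = []
        for n in (129, 65, 33):
            gx = np.linspace(-1.0, 1.0, n)
            gy = np.linspace(-0.9, 1.0, n)
            xx, yy = np.meshgrid(gx, gy, indexing="ij")
            u = pot.energy(np.stack([xx, yy], axis=-1))
            shift = u.min()  # FESGrid re-zeroes; compare on the common scale
            axes = [GridAxis("x", -1.0, 1.0, n), GridAxis("y", -1.0, 1.0, n)]
            fes = FESGrid(axes=axes, values=u - shift)
            start = fes.nearest_node([-0.5, 0.0])
            end = fes.nearest_node([0.5, 0.0])
            barriers.append(minimum_energy_path(fes, start, end).barrier
                            + shift)
        assert barriers[0] <= barriers[1] + 1e-12 <= barriers[2] + 1e-12
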