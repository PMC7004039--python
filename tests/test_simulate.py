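"""Integration front-end: determinism, step-size robustness, simplex
invariants, fire-event semantics and the Model/Results facade."""

import numpy as np
import pytest

from firesucc import (ABANDONED_FIELD, SMALL_MIXED, FireVegetationModel,
                      PlantTypeSet, RunConfig, equilibrium_no_fire, integrate)


class TestDeterminism:
    def test_identical_seed_identical_run(self, params):
        runs = [integrate(RunConfig(duration=600, seed=77), params)
                for _ in range(2)]
        (t1, l1), (t2, l2) = runs
        assert t1.df.equals(t2.df)
        assert l1.df.equals(l2.df)

    def test_different_seed_different_fires(self, params):
        _, l1 = integrate(RunConfig(duration=2000, seed=1), params)
        _, l2 = integrate(RunConfig(duration=2000, seed=2), params)
        assert not np.array_equal(l1.times, l2.times)


class TestNumerics:
    def test_no_fire_endpoint_matches_oracle_single_type_start(self, params):
        for b0 in [(0.3, 0, 0, 0, 0, 0), (0, 0, 0, 0, 0, 0.3)]:
            traj, log = integrate(
                RunConfig(duration=1000, fires=False, b0=b0), params)
            assert len(log) == 0
            # from a single-type start only that type (or none) persists
            eq = equilibrium_no_fire(params)
            i = int(np.nonzero(b0)[0][0])
            solo = max(0.0, 1 - params.m[i] / params.c[i])
            assert traj.covers()[-1][i] == pytest.approx(solo, abs=1e-3)

    def test_halving_dt_leaves_endpoint_unchanged(self, params):
        ends = []
        for dt in (1 / 365, 1 / 730):
            traj, _ = integrate(RunConfig(duration=1000, fires=False,
                                          b0=SMALL_MIXED, dt=dt), params)
            ends.append(traj.covers()[-1])
        assert np.abs(ends[0] - ends[1]).max() < 1e-6

    def test_simplex_respected_along_stochastic_run(self, params):
        traj, _ = integrate(RunConfig(duration=3000, seed=5,
                                      b0=ABANDONED_FIELD), params)
        B = traj.covers()
        assert B.min() >= 0
        assert B.sum(axis=1).max() <= 1 + 1e-6

    def test_invalid_initial_covers_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(duration=10, b0=(0.5,) * 6)
        with pytest.raises(ValueError):
            RunConfig(duration=-5)


class TestFireEvents:
    def test_log_rows_obey_retention_fractions(self, params):
        _, log = integrate(RunConfig(duration=5000, seed=9), params)
        assert len(log) > 0
        r = np.asarray(params.r)
        for ev in log.events():
            np.testing.assert_allclose(ev.post_cover, r * ev.pre_cover,
                                       atol=1e-12)
            assert ev.interval >= 2.0

    def test_two_year_minimum_under_extreme_hazard(self):
        p = PlantTypeSet(flam_mult=50.0)
        _, log = integrate(RunConfig(duration=200, seed=3,
                                     b0=(0, 0, 0, 0, 0, 0.9)), p)
        assert len(log) > 10
        assert log.intervals.min() >= 2.0
        # a sizeable share of intervals sits at the clamped floor
        assert np.mean(log.intervals <= 2.0 + 2 / 365) > 0.2

    def test_scheduled_burns_kill_seeders_and_spare_resprouters(self, params):
        traj, log = integrate(
            RunConfig(duration=30, b0=(0.2, 0.1, 0.1, 0.1, 0.1, 0.1),
                      scheduled_fires=(10.0,), fires=False), params)
        assert len(log) == 1 and log.times[0] == pytest.approx(10.0, abs=1e-6)
        ev = log.events()[0]
        assert np.all(ev.post_cover[1:5] == 0)
        assert ev.post_cover[0] == pytest.approx(0.9 * ev.pre_cover[0])

    def test_repeated_burns_before_maturity_eliminate_pine(self, params):
        traj, _ = integrate(
            RunConfig(duration=60, b0=(0.01, 0.3, 0.05, 0.05, 0.05, 0.05),
                      scheduled_fires=(5.0, 10.0), fires=False), params)
        assert np.all(traj.at(np.arange(11, 60))[:, 1] < 1e-9)

    def test_mature_stand_reseeds_after_single_burn(self, params):
        traj, _ = integrate(
            RunConfig(duration=40, b0=(0.01, 0.3, 0.05, 0.05, 0.05, 0.05),
                      scheduled_fires=(15.0,), fires=False), params)
        assert traj.at(25.0)[1] > 0.01  # pines re-established from the bank


class TestTrajectoryHelpers:
    def test_windows_and_crossings(self, params):
        traj, _ = integrate(RunConfig(duration=300, fires=False,
                                      b0=SMALL_MIXED), params)
        assert traj.first_crossing("Q", 0.5) == pytest.approx(105, abs=2)
        assert traj.first_crossing("Q", 2.0) is None
        m = traj.mean_cover(250, 300)
        assert 0 < m[0] <= 1
        with pytest.raises(ValueError):
            traj.mean_cover(500, 600)


class TestModelFacade:
    def test_results_object_round_trip(self, params, rules):
        model = FireVegetationModel(params, rules)
        res = model.simulate(duration=800, seed=4)
        s = res.summary()
        assert "state" in s and "final cover" in s
        assert res.classify() in {"forest", "open shrubland", "mixed"}
        np.testing.assert_allclose(res.final_cover(),
                                   res.trajectory.final_cover())

    def test_equilibrium_shortcut(self, params):
        model = FireVegetationModel(params)
        np.testing.assert_allclose(model.equilibrium(),
                                   equilibrium_no_fire(params))

    def test_plot_smoke(self, params):
        import matplotlib
        matplotlib.use("Agg")
        res = FireVegetationModel(params).simulate(duration=50, seed=0)
        ax = res.plot()
        assert len(ax.lines) >= 6
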