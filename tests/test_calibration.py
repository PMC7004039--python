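"""Calibration: objective and H2 semantics, annealing behaviour and the
Monte-Carlo uncertainty envelope."""

import numpy as np
import pandas as pd
import pytest

from firesucc import (ObservationSet, OldFieldCalibration, anneal,
                      goodness_h2, mc_uncertainty, objective)
from firesucc.calibration import (COVER_COLS, AnnealSchedule,
                                  FirePlotCalibration, _norm_sse)
from firesucc.synthetic import SynthSpec, generate_fireplots, generate_oldfield

FREE = tuple(f"c{i}" for i in range(1, 6))
FAST = AnnealSchedule(n_steps=600, cooling=0.99)


@pytest.fixture(scope="module")
def exact_obs():
    return generate_oldfield(SynthSpec(n_sites=40, noise_sigma=0.0, seed=5))


@pytest.fixture(scope="module")
def noisy_obs():
    return generate_oldfield(SynthSpec(n_sites=40, noise_sigma=0.05, seed=5))


class TestObservationSet:
    def test_schema_violations_rejected(self, exact_obs):
        with pytest.raises(ValueError, match="missing columns"):
            ObservationSet(df=exact_obs.df.drop(columns=["cover_Q"]))
        bad = exact_obs.df.copy()
        bad.loc[0, "time_yr"] = -1
        with pytest.raises(ValueError, match="non-negative"):
            ObservationSet(df=bad)
        bad = exact_obs.df.copy()
        bad.loc[0, "cover_Q"] = 1.2
        with pytest.raises(ValueError):
            ObservationSet(df=bad)

    def test_mild_oversum_renormalized_gross_rejected(self, exact_obs):
        df = exact_obs.df.copy()
        df.loc[:, COVER_COLS] = 0.17  # sum 1.02: renormalize
        obs = ObservationSet(df=df)
        assert obs.df[COVER_COLS].sum(axis=1).max() <= 1 + 1e-9
        df2 = exact_obs.df.copy()
        df2.loc[:, COVER_COLS] = 0.2  # sum 1.2: reject
        with pytest.raises(ValueError, match="exceeds 1"):
            ObservationSet(df=df2)


class TestObjective:
    def test_zero_at_generating_parameters(self, exact_obs):
        truth = [exact_obs.meta["true_params"].c[i] for i in range(5)]
        assert objective(truth, FREE, exact_obs) == pytest.approx(0, abs=1e-12)
        assert goodness_h2(0.0, exact_obs) == 1.0

    def test_positive_under_noise(self, noisy_obs):
        truth = [noisy_obs.meta["true_params"].c[i] for i in range(5)]
        assert objective(truth, FREE, noisy_obs) > 0

    def test_constant_mean_predictor_scores_h2_zero(self, noisy_obs):
        cov = noisy_obs.df[COVER_COLS].to_numpy()
        means = cov.mean(axis=0)
        sse, _ = _norm_sse(noisy_obs.df,
                           lambda df: np.tile(means, (len(df), 1)))
        assert goodness_h2(sse, noisy_obs) == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_record_order_and_doubling(self, noisy_obs):
        truth = [noisy_obs.meta["true_params"].c[i] for i in range(5)]
        base = objective(truth, FREE, noisy_obs)
        shuffled = ObservationSet(
            df=noisy_obs.df.sample(frac=1, random_state=0)
            .reset_index(drop=True))
        assert objective(truth, FREE, shuffled) == pytest.approx(base)
        doubled_df = pd.concat([noisy_obs.df, noisy_obs.df],
                               ignore_index=True)
        doubled = ObservationSet(df=doubled_df)
        assert objective(truth, FREE, doubled) == pytest.approx(2 * base)

    def test_fireplot_objective_zero_at_truth(self):
        obs = generate_fireplots(SynthSpec(noise_sigma=0.0, seed=2))
        assert objective([0.014, 0.4, 0.22], ("C_conv", "r6", "c6"), obs) \
            == pytest.approx(0, abs=1e-10)


class TestAnneal:
    def test_recovers_quadratic_bowl_minimum(self):
        target = np.array([0.3, -0.2])
        res = anneal(lambda x: float(((x - target) ** 2).sum()),
                     [(-1, 1), (-1, 1)], seed=0,
                     schedule=AnnealSchedule(n_steps=2000, cooling=0.995))
        assert np.abs(res.x - target).max() < 1e-2

    def test_same_seed_identical_trace(self):
        runs = [anneal(lambda x: float((x ** 2).sum()), [(-1, 1)] * 2,
                       seed=42, schedule=FAST) for _ in range(2)]
        assert runs[0].trace.equals(runs[1].trace)
        assert np.array_equal(runs[0].x, runs[1].x)

    def test_best_ever_never_worse_than_trace(self):
        res = anneal(lambda x: float((x ** 2).sum()), [(-2, 2)] * 3,
                     seed=1, schedule=FAST)
        assert res.fun <= res.trace["f"].min() + 1e-15
        assert (res.trace["best"].diff().dropna() <= 1e-15).all()

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ValueError, match="not finite"):
            anneal(lambda x: float("nan"), [(0, 1)], seed=0, schedule=FAST)


class TestRecovery:
    def test_noise_free_recovery_bias_below_one_percent(self, exact_obs):
        res = OldFieldCalibration(exact_obs).fit(
            seed=0, schedule=AnnealSchedule(n_steps=3000, cooling=0.998))
        truth = np.array(exact_obs.meta["true_params"].c[:5])
        est = np.array([res.theta[n] for n in FREE])
        assert np.abs(est - truth).max() / truth.min() < 0.01
        assert res.h2 == pytest.approx(1.0, abs=1e-3)

    def test_fit_summary_mentions_h2(self, exact_obs):
        res = OldFieldCalibration(exact_obs).fit(seed=0, schedule=FAST)
        assert "H2" in res.summary()
        assert res.h2 <= 1.0


class TestMCUncertainty:
    def test_envelope_contains_best_fit_and_collapses_without_noise(
            self, exact_obs):
        env = mc_uncertainty(exact_obs, n_draws=2, seed=0,
                             schedule=AnnealSchedule(n_steps=3000,
                                                     cooling=0.998),
                             noise_sigma=0.0)
        assert np.all(env["lo"] <= env["best"] + 1e-12)
        assert np.all(env["best"] <= env["hi"] + 1e-12)
        # noise-free data: every bootstrap subset lies on the same
        # trajectory, so converged refits collapse onto the best fit
        assert (env["hi"] - env["lo"]).max() < 0.05

    def test_too_few_draws_rejected(self, exact_obs):
        with pytest.raises(ValueError, match="at least 2"):
            mc_uncertainty(exact_obs, n_draws=1)


class TestFirePlotCalibration:
    def test_free_parameters_are_fire_response_constants(self):
        obs = generate_fireplots(SynthSpec(noise_sigma=0.0, seed=2))
        cal = FirePlotCalibration(obs)
        assert cal.free == ("C_conv", "r6", "c6")
        assert np.isfinite(cal._objective(np.array([0.014, 0.4, 0.22])))
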