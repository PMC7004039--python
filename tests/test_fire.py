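"""Fire engine: hazard, waiting-time sampling, instantaneous fire effects,
seed banks and post-fire establishment rates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from firesucc import (EcosystemState, PlantTypeSet, SeedBankRules, apply_fire,
                      fire_hazard, postfire_alpha, sample_next_fire,
                      seedbank_step)


class TestFireHazard:
    @pytest.mark.parametrize("b, expected", [
        (np.zeros(6), 1e-4),                                # bare ground
        (np.array([0, 0, 0, 0, 0, 1.0]), 0.1 + 1e-4),       # grass monoculture
        (np.array([0.9, 0, 0, 0, 0, 0.05]), 0.9 / 400 + 0.05 / 10 + 1e-4),
    ])
    def test_hazard_values(self, params, b, expected):
        assert fire_hazard(b, params) == pytest.approx(expected, rel=1e-12)

    def test_bare_ground_return_time_is_ten_thousand_years(self, params):
        assert 1.0 / fire_hazard(np.zeros(6), params) == pytest.approx(1e4)

    @given(arrays(float, 6, elements=st.floats(0.0, 1 / 6)),
           st.floats(0.1, 5.0))
    def test_vegetation_term_scales_with_flammability_multiplier(self, b, k):
        p1 = PlantTypeSet()
        pk = PlantTypeSet(flam_mult=k)
        veg1 = fire_hazard(b, p1) - p1.epsilon
        vegk = fire_hazard(b, pk) - pk.epsilon
        assert vegk == pytest.approx(k * veg1, rel=1e-9, abs=1e-15)


class TestSampleNextFire:
    def test_constant_hazard_reproduces_exponential_mean(self):
        rng = np.random.default_rng(7)
        draws = [sample_next_fire(lambda t: 0.01, rng, 0.0, dt=0.25)
                 for _ in range(10_000)]
        assert 95 < np.mean(draws) < 105

    def test_huge_hazard_clamped_to_two_years(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert sample_next_fire(lambda t: 50.0, rng, 100.0) == 102.0

    def test_bare_ground_mean_interval_near_1e4(self, params):
        rng = np.random.default_rng(3)
        eps = params.epsilon
        draws = [sample_next_fire(lambda t: eps, rng, 0.0, dt=50.0)
                 for _ in range(400)]
        assert np.mean(draws) == pytest.approx(1e4, rel=0.15)

    def test_reproducible_given_seed(self):
        a = sample_next_fire(lambda t: 0.05, np.random.default_rng(11), 0.0)
        b = sample_next_fire(lambda t: 0.05, np.random.default_rng(11), 0.0)
        assert a == b


class TestApplyFire:
    def test_covers_scaled_by_retention_fractions(self, params, rules):
        state = EcosystemState(b=np.array([0.5, 0.2, 0.1, 0, 0, 0.1]))
        out = apply_fire(state, params, rules)
        np.testing.assert_allclose(out.b, [0.45, 0, 0, 0, 0, 0.04])
        assert out.tau_fire == 0.0

    def test_mature_pine_stand_releases_canopy_bank(self, params, rules):
        state = EcosystemState(b=np.array([0, 0.6, 0, 0, 0, 0]),
                               tau_fire=30.0)
        out = apply_fire(state, params, rules)
        assert out.S[0] == pytest.approx(0.6)

    def test_young_pine_stand_has_no_seed_bank(self, params, rules):
        state = EcosystemState(b=np.array([0, 0.6, 0, 0, 0, 0]), tau_fire=5.0)
        out = apply_fire(state, params, rules)
        assert out.S[0] == 0.0

    @given(arrays(float, 6, elements=st.floats(0.0, 1 / 6)))
    def test_fire_never_increases_cover_nor_decreases_free_space(self, b):
        p, r = PlantTypeSet(), SeedBankRules()
        out = apply_fire(EcosystemState(b=b), p, r)
        assert np.all(out.b <= b + 1e-15)
        assert 1 - out.b.sum() >= 1 - b.sum() - 1e-15

    def test_shrub_banks_unchanged_at_event(self, params, rules):
        state = EcosystemState(b=np.full(6, 0.1), S=np.array([0, 1, 2, 3.0]),
                               tau_fire=50.0)
        out = apply_fire(state, params, rules)
        np.testing.assert_allclose(out.S[1:], [1, 2, 3])


class TestSeedbankStep:
    def test_pure_decay_is_exponential(self, rules):
        state = EcosystemState(b=np.zeros(6), S=np.array([0, 2.0, 1.0, 0.5]),
                               tau_fire=50.0)
        S = seedbank_step(state, rules, dt=3.0)
        np.testing.assert_allclose(
            S[1:], np.array([2.0, 1.0, 0.5]) * np.exp(-0.2 * 3.0))

    def test_constant_cover_approaches_production_over_decay(self, rules):
        b = np.zeros(6)
        b[2:5] = 0.3
        state = EcosystemState(b=b, S=np.zeros(4), tau_fire=50.0)
        S = state.S
        for _ in range(200):
            state = EcosystemState(b=b, S=S, tau_fire=50.0)
            S = seedbank_step(state, rules, dt=1.0)
        assert np.allclose(S[1:], 0.3 * rules.shrub_production_rate
                           / rules.shrub_decay_rate, rtol=1e-6)

    def test_pine_bank_expires_after_viability_window(self, rules):
        state = EcosystemState(b=np.zeros(6), S=np.array([0.6, 0, 0, 0]),
                               tau_fire=0.0)
        assert seedbank_step(state, rules, dt=1.5)[0] == 0.6  # still viable
        state = EcosystemState(b=np.zeros(6), S=np.array([0.6, 0, 0, 0]),
                               tau_fire=1.5)
        assert seedbank_step(state, rules, dt=1.0)[0] == 0.0  # > 2 yr

    def test_nonpositive_dt_rejected(self, rules):
        state = EcosystemState(b=np.zeros(6))
        with pytest.raises(ValueError):
            seedbank_step(state, rules, dt=0.0)


class TestPostfireAlpha:
    def test_single_pine_bank_collapses_to_conversion_rate(self, params):
        alpha = postfire_alpha(np.array([0.5, 0, 0, 0]), params)
        assert alpha[1] == pytest.approx(params.C_conv)
        assert np.all(alpha[[0, 2, 3, 4, 5]] == 0)

    def test_empty_banks_give_zero_alpha(self, params):
        assert np.all(postfire_alpha(np.zeros(4), params) == 0)

    @given(arrays(float, 4, elements=st.floats(0.0, 10.0)))
    def test_partition_of_unity(self, S):
        """Total seeder establishment is either 0 (no germinable seed) or
        exactly the conversion parameter C."""
        p = PlantTypeSet()
        alpha = postfire_alpha(S, p)
        assert alpha[0] == 0 and alpha[5] == 0
        total = alpha.sum()
        if (np.asarray(p.gamma)[1:5] * S).sum() > 0:
            assert total == pytest.approx(p.C_conv, rel=1e-12)
        else:
            assert total == 0

    def test_negative_banks_rejected(self, params):
        with pytest.raises(ValueError):
            postfire_alpha(np.array([-0.1, 0, 0, 0]), params)
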