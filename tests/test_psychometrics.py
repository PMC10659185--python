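"""Psychometric fitting, bootstrap PSE, and episode conditioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

from critlearn import (
    CORRECT, LARGE, SMALL, STIM_LEVELS,
    Episode, bootstrap_pse, condition_on_episode, episode_pair_map,
    fit_psychometric, history_effect_table,
)

LEVELS = np.array(STIM_LEVELS, dtype=float)


def curve_counts(mu, sigma, n_per_level):
    p = ndtr((LEVELS - mu) / sigma)
    n = np.full(5, n_per_level)
    return n, np.round(n * p).astype(int)


class TestFit:
    def test_recovers_generating_curve(self):
        n, k = curve_counts(0.3, 1.0, 10_000)
        fit = fit_psychometric(LEVELS, n, k)
        assert fit.pse == pytest.approx(0.30, abs=0.02)
        assert fit.slope_sd == pytest.approx(1.0, abs=0.05)

    def test_symmetric_proportions_give_zero_pse(self):
        n, k = curve_counts(0.0, 1.2, 5000)
        assert fit_psychometric(LEVELS, n, k).pse == pytest.approx(0.0, abs=0.01)

    def test_lapse_variant_nests_the_plain_fit(self):
        n, k = curve_counts(0.2, 1.1, 5000)
        plain = fit_psychometric(LEVELS, n, k)
        full = fit_psychometric(LEVELS, n, k, include_lapse=True)
        assert full.pse == pytest.approx(plain.pse, abs=0.03)
        assert full.guess <= 0.02 and full.lapse <= 0.02

    def test_all_identical_responses_flagged_non_identifiable(self):
        n = np.full(5, 100)
        fit = fit_psychometric(LEVELS, n, n)  # every response 'large'
        assert not fit.identifiable and np.isnan(fit.pse)

    @settings(max_examples=25, deadline=None)
    @given(shift=st.floats(-1.5, 1.5))
    def test_pse_is_shift_equivariant(self, shift):
        n, k = curve_counts(0.1, 1.0, 4000)
        base = fit_psychometric(LEVELS, n, k).pse
        moved = fit_psychometric(LEVELS + shift, n, k).pse
        assert moved - base == pytest.approx(shift, abs=0.02)


class TestBootstrap:
    def test_default_resample_count(self, rng):
        n, k = curve_counts(0.0, 1.0, 200)
        fit = bootstrap_pse(LEVELS, n, k, n_boot=50, rng=rng)
        assert fit.n_boot == 50 and np.isfinite(fit.boot_mean_pse)
        import inspect
        assert inspect.signature(bootstrap_pse).parameters["n_boot"].default == 5000

    def test_degenerate_step_data_has_no_resampling_variance(self, rng):
        n = np.full(5, 100_000)
        k = np.array([0, 0, 50_000, 100_000, 100_000])
        fit = bootstrap_pse(LEVELS, n, k, n_boot=40, rng=rng)
        assert abs(fit.boot_mean_pse - fit.pse) < 1e-3

    def test_bootstrap_sd_shrinks_like_root_n(self, rng):
        sizes = np.array([200, 800, 3200, 12800])
        sds = []
        for n_per in sizes:
            n = np.full(5, n_per)
            p = ndtr((LEVELS - 0.2) / 1.1)
            k = rng.binomial(n, p)
            sds.append(bootstrap_pse(LEVELS, n, k, n_boot=400, rng=rng).boot_sd_pse)
        slope = np.polyfit(np.log(sizes), np.log(sds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestConditioning:
    def test_offset_respects_run_boundaries_and_partitions(self, base_trials):
        ep = Episode(0, LARGE, CORRECT)
        retro = condition_on_episode(base_trials, ep, -1)
        pro = condition_on_episode(base_trials, ep, +1)
        # a toi on the first/last trial of a run contributes nothing
        toi = base_trials[(base_trials.stimulus == 0)
                          & (base_trials.choice == LARGE)
                          & (base_trials.feedback == CORRECT)]
        n_first = (toi.trial == 0).sum()
        n_last = (toi.trial == base_trials.trial.max()).sum()
        assert len(retro) == len(toi) - n_first
        assert len(pro) == len(toi) - n_last

    def test_all_episodes_partition_the_successor_trials(self, base_trials):
        total = sum(len(condition_on_episode(base_trials, ep, +1))
                    for ep in Episode.all_episodes())
        has_successor = (base_trials.trial < base_trials.trial.max()).sum()
        assert total == has_successor

    def test_successor_stimuli_follow_the_block_transition_law(self, base_trials):
        # within-block randomization means the next trial repeats the current
        # level only across a block edge: P(same) = (1/5)(1/5) = 0.04 and
        # P(other) = 4/5 * 1/4 + 1/25 = 0.24, independent of choice/feedback
        sub = condition_on_episode(base_trials, Episode(0, LARGE, CORRECT), +1)
        counts = sub.stimulus.value_counts().reindex([-2, -1, 0, 1, 2], fill_value=0)
        n = len(sub)
        for lv, p in [(-2, 0.24), (-1, 0.24), (0, 0.04), (1, 0.24), (2, 0.24)]:
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts[lv] - n * p) < 4 * sd + 3

    def test_empty_selection_returns_empty_frame(self, base_trials):
        # stimulus -2 chosen 'large' with 'correct' feedback is possible but
        # filtering an impossible pattern must not raise
        t = base_trials[base_trials.stimulus == 2].head(0)
        out = condition_on_episode(t, Episode(0, SMALL, CORRECT), +1)
        assert len(out) == 0


class TestHistoryTableAndPairMap:
    def test_table_has_all_cells_and_directions(self, base_trials, rng):
        tab = history_effect_table(base_trials, n_boot=0, rng=rng)
        assert len(tab) == 20 * 3
        sub = tab[tab.direction == "subtractive"].set_index(["stimulus", "choice", "feedback"])
        pro = tab[tab.direction == "prospective"].set_index(["stimulus", "choice", "feedback"])
        retro = tab[tab.direction == "retrospective"].set_index(["stimulus", "choice", "feedback"])
        diff = pro.pse - retro.pse
        ok = sub.pse.notna()
        assert np.allclose(sub.pse[ok], diff[ok], equal_nan=True)

    def test_sparse_cells_are_missing_not_imputed(self, base_trials, rng):
        tab = history_effect_table(base_trials, n_boot=0, min_trials=10 ** 9, rng=rng)
        assert tab.pse.isna().all()

    def test_pair_map_columns_are_conditional_distributions(self, base_trials):
        maps = episode_pair_map(base_trials)
        for direction in ("retrospective", "prospective"):
            sums = maps[direction].sum(axis=0, skipna=True)
            observed = maps[direction].notna().any(axis=0)
            assert np.allclose(sums[observed], 1.0, atol=1e-9)

    def test_reversed_trial_order_swaps_directions(self, base_trials):
        fwd = episode_pair_map(base_trials)
        rev = episode_pair_map(base_trials.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(fwd["prospective"], rev["retrospective"])

    def test_base_agent_pairs_factorize_over_choice_and_feedback(self, base_trials):
        # without updating, the successor episode depends on the current trial
        # only through the block-design stimulus transition: columns sharing a
        # toi stimulus but differing in choice/feedback must agree within
        # binomial error
        maps = episode_pair_map(base_trials)
        pro = maps["prospective"]
        eps = Episode.all_episodes()
        counts = {e.label: len(condition_on_episode(base_trials, e, +1))
                  for e in eps}
        for s in (-1, 0, 1):
            cols = [e.label for e in eps
                    if e.stimulus == s and counts[e.label] >= 300]
            for a, b in zip(cols, cols[1:]):
                diff = (pro[a] - pro[b]).to_numpy()
                p = ((pro[a] + pro[b]) / 2).to_numpy()
                se = np.sqrt(np.clip(p * (1 - p), 1e-9, None)
                             * (1 / counts[a] + 1 / counts[b]))
                ok = ~np.isnan(diff)
                assert (np.abs(diff[ok]) < 5 * se[ok] + 0.02).all()
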