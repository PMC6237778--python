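"""Constant/variable error decomposition and the matched-pair statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cuefuse.errors as err
from cuefuse._streams import substream
from cuefuse.validation import simulate_cohort_table


class TestConstantError:
    def test_perfect_responses_have_zero_bias(self):
        assert err.constant_error([10, 20], [10, 20]) == pytest.approx(0.0)

    def test_multiplicative_offset_recovered(self):
        t = np.array([10.0, 20.0, 30.0])
        assert err.constant_error(t, t * np.e**0.1) == pytest.approx(0.1)

    def test_mean_of_log_errors(self):
        assert err.constant_error([10.0, 10.0],
                                  [10.0 * np.e**0.2, 10.0]) == pytest.approx(0.1)

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            err.constant_error([], [])
        with pytest.raises(ValueError):
            err.constant_error([10.0], [-1.0])


class TestVariableError:
    def test_residuals_squared(self):
        t = np.array([10.0, 10.0])
        r = np.array([10.0 * np.e**0.2, 10.0])
        np.testing.assert_allclose(err.variable_error(t, r, 0.1), [0.01, 0.01])

    def test_bias_matched_response_has_zero_ve(self):
        t = np.array([15.0, 25.0])
        np.testing.assert_allclose(err.variable_error(t, t * np.e**0.3, 0.3),
                                   [0.0, 0.0], atol=1e-15)

    def test_ce_minimizes_mean_squared_log_error(self):
        # the constant-error correction is the least-squares constant shift
        rng = substream(0, "ce")
        t = np.exp(rng.uniform(np.log(10), np.log(35), 200))
        r = t * np.exp(rng.normal(0.05, 0.2, 200))
        ce = err.constant_error(t, r)
        best = err.variable_error(t, r, ce).mean()
        for shift in np.linspace(ce - 0.5, ce + 0.5, 101):
            assert err.variable_error(t, r, shift).mean() >= best - 1e-12

    def test_unit_conversion_to_sd_percent(self):
        # VE of 0.01 log units^2 = SD of 10.5% of the target distance
        assert 100 * err.ve_to_sd_fraction(0.01) == pytest.approx(10.5, abs=0.05)


class TestSummaries:
    def test_one_cell_per_participant_session_type(self, ideal_table):
        s = err.summarize_errors(ideal_table)
        assert len(s) == 12 * 3 * 3  # 108 bias corrections
        assert (s["n_trials"] > 0).all()
        assert (s["mean_variable_error"] >= 0).all()

    def test_perfect_table_all_zero(self, tiny_table):
        s = err.summarize_errors(tiny_table)
        np.testing.assert_allclose(s["constant_error"], 0.0, atol=1e-15)
        np.testing.assert_allclose(s["mean_variable_error"], 0.0, atol=1e-15)

    def test_row_order_invariance(self, ideal_table):
        shuffled = ideal_table.sample(frac=1.0, random_state=0)
        a = err.summarize_errors(ideal_table)
        b = err.summarize_errors(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_residuals_center_at_zero_within_cells(self, ideal_table):
        df = err.add_log_errors(ideal_table)
        centered = df.groupby(["participant_id", "session", "trial_type"]) \
            .apply(lambda g: (g["log_error"] - g["ce"]).mean(),
                   include_groups=False)
        np.testing.assert_allclose(centered, 0.0, atol=1e-12)


class TestBestSingleCue:
    def _summaries(self, audio_ve, visual_ve):
        return pd.DataFrame({
            "participant_id": ["P01"] * 2, "session": [3] * 2,
            "trial_type": ["audio", "visual"],
            "mean_variable_error": [audio_ve, visual_ve],
            "constant_error": [0.0, 0.0], "n_trials": [83, 83],
        })

    def test_lower_ve_wins(self):
        assert err.best_single_cue(self._summaries(0.010, 0.020),
                                   "P01", 3) == "audio"
        assert err.best_single_cue(self._summaries(0.020, 0.010),
                                   "P01", 3) == "visual"

    def test_tie_breaks_toward_audio(self):
        assert err.best_single_cue(self._summaries(0.010, 0.010),
                                   "P01", 3) == "audio"

    def test_missing_modality_rejected(self):
        s = self._summaries(0.01, 0.02).iloc[:1]
        with pytest.raises(ValueError, match="missing visual"):
            err.best_single_cue(s, "P01", 3)


class TestPairing:
    def test_pair_counts_match_design(self, ideal_table):
        df = err.add_log_errors(ideal_table)
        assert len(err.pair_av_vs_best(df)) == 2736
        assert len(err.pair_av_vs_best(df[df.session == 3])) == 996
        assert len(err.pair_av_vs_best(df[df.session == 4])) == 744

    def test_single_triplet_single_pair(self, tiny_table):
        noisy = tiny_table.copy()
        noisy["response_m"] = noisy["response_m"] * np.exp(
            np.linspace(-0.1, 0.1, len(noisy)))
        df = err.add_log_errors(noisy)
        summaries = err.summarize_errors(df)
        pairs = err.pair_av_vs_best(df[df.triplet_id == "t0"], summaries)
        assert len(pairs) == 1

    def test_optimal_reference_below_best_reference(self, ideal_table):
        df = err.add_log_errors(ideal_table)
        best = err.pair_av_vs_best(df).set_index(
            ["participant_id", "session", "triplet_id"])
        opt = err.pair_av_vs_optimal(df).set_index(
            ["participant_id", "session", "triplet_id"])
        joined = best.join(opt, lsuffix="_best", rsuffix="_opt")
        assert (joined["ref_ve_opt"] <= joined["ref_ve_best"] + 1e-15).all()

    def test_optimal_reference_cell_mean_is_optimal_variance(self, ideal_table):
        df = err.add_log_errors(ideal_table)
        summaries = err.summarize_errors(df)
        pairs = err.pair_av_vs_optimal(df, summaries)
        cellmeans = pairs.groupby(["participant_id", "session"])["ref_ve"].mean()
        wide = summaries.pivot_table(index=["participant_id", "session"],
                                     columns="trial_type",
                                     values="mean_variable_error")
        expected = err.optimal_variance(wide["audio"].to_numpy(),
                                        wide["visual"].to_numpy())
        np.testing.assert_allclose(cellmeans.to_numpy(), expected, rtol=1e-10)


class TestSignRank:
    def test_exact_small_sample(self):
        # brute force over the 2^3 sign assignments puts all mass one-sided
        res = err.signrank_test([1.0, 2.0, 3.0])
        assert res.p == pytest.approx(0.25)
        assert res.method == "exact"

    def test_antisymmetric_differences_z_zero(self):
        res = err.signrank_test([-1.0, 1.0])
        assert res.z == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        res = err.signrank_test([0.0, 0.0, 1.0, 2.0, 3.0])
        assert res.n == 3
        assert res.p == pytest.approx(0.25)

    def test_all_zero_is_degenerate(self):
        res = err.signrank_test([0.0, 0.0])
        assert (res.z, res.p) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_normal_approximation_tracks_enumeration(self, seed):
        rng = substream(seed, "signrank")
        d = rng.normal(0.3, 1.0, 20)
        exact = err.signrank_test(d)
        z = exact.z
        approx_p = 2 * stats.norm.sf(abs(z))
        assert approx_p == pytest.approx(exact.p, abs=0.02)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_agrees_with_scipy_wilcoxon(self, seed):
        # independent implementation check on tie-free data
        rng = substream(seed, "wilcoxon")
        d = rng.normal(0.2, 1.0, 18)
        ours = err.signrank_test(d)
        ref = stats.wilcoxon(d, alternative="two-sided", method="exact")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = substream(5, "big")
        d = rng.normal(0.2, 1.0, 200)
        res = err.signrank_test(d)
        assert res.method == "approx"
        ref = stats.wilcoxon(d, alternative="two-sided", method="approx",
                             correction=True)
        assert res.p == pytest.approx(ref.pvalue, rel=0.05)


class TestVeChange:
    def _pairs(self, ref, av):
        return pd.DataFrame({"ref_ve": ref, "av_ve": av})

    def test_point_estimate_arithmetic(self):
        p = self._pairs([0.012] * 4, [0.010] * 4)
        eff, _ = err.ve_change(p, n_boot=100, seed=0)
        assert eff == pytest.approx(100 * (1 - 0.010 / 0.012))

    def test_degenerate_bootstrap_ci_is_point(self):
        p = self._pairs([0.012] * 6, [0.010] * 6)
        eff, (lo, hi) = err.ve_change(p, n_boot=200, seed=0)
        assert lo == pytest.approx(eff) and hi == pytest.approx(eff)

    def test_seeded_determinism(self):
        rng = substream(0, "vc")
        p = self._pairs(rng.chisquare(1, 50) * 0.01, rng.chisquare(1, 50) * 0.008)
        a = err.ve_change(p, n_boot=500, seed=3)
        b = err.ve_change(p, n_boot=500, seed=3)
        assert a == b

    def test_zero_mean_ve_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            err.ve_change(self._pairs([0.0] * 4, [0.0] * 4), n_boot=100)


class TestOptimalVariance:
    def test_equal_variances_halve(self):
        assert err.optimal_variance(2.0, 2.0) == pytest.approx(1.0)

    def test_worked_example(self):
        assert err.optimal_variance(1.0, 4.0) == pytest.approx(0.8)

    def test_never_exceeds_smaller_input(self):
        rng = substream(0, "opt")
        for _ in range(50):
            a, b = rng.uniform(0.1, 10, 2)
            assert err.optimal_variance(a, b) <= min(a, b)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            err.optimal_variance(0.0, 1.0)


class TestPipelineBehavior:
    """End-to-end discriminant validity on simulated cohorts."""

    def test_ideal_observers_beat_best_single_cue(self, ideal_table):
        c = err.paired_contrast(ideal_table, "best", n_boot=500, seed=0)
        assert c.p < 0.001 and c.z > 0
        assert 0 < c.ve_change_pct < 100
        assert c.ci95[0] <= c.ve_change_pct <= c.ci95[1]

    def test_switchers_show_no_combination_benefit(self):
        table, _, _ = simulate_cohort_table(policy="switch", p_visual=0.5,
                                            seed=21, sessions=(3,),
                                            triplet_counts={3: 83})
        c = err.paired_contrast(table, "best", n_boot=500, seed=0)
        # no integration: the bimodal VE cannot fall below the best cue
        assert c.z < 2.0
        assert not (c.p < 0.01 and c.z > 0)

    def test_visual_reliance_tracks_reliability(self, ideal_table):
        rel = err.visual_reliance(ideal_table)
        merged = rel[rel.session.isin((3, 5))]
        narrow = merged[merged.visual_sd_log < merged.visual_sd_log.median()]
        wide = merged[merged.visual_sd_log > merged.visual_sd_log.median()]
        # responses hug the visual center more when the cue is reliable
        assert narrow["reliance"].mean() < wide["reliance"].mean()

    def test_reliance_zero_when_responses_equal_center(self, tiny_table):
        t = tiny_table.copy()
        av = t.trial_type == "audiovisual"
        t.loc[av, "response_m"] = t.loc[av, "visual_center_m"]
        rel = err.visual_reliance(t)
        assert rel["reliance"].iloc[0] == pytest.approx(0.0)

    def test_manipulation_check_strongly_positive(self, ideal_table):
        r, n = err.manipulation_check(ideal_table, "visual")
        assert n == 24
        assert r > 0.7

    def test_total_error_equals_ve_when_unbiased(self, tiny_table):
        t = tiny_table.copy()
        rng = substream(2, "te")
        noise = np.exp(rng.normal(0, 0.1, len(t)))
        t["response_m"] = np.clip(t["target_m"] * noise, 10, 35)
        # remove each cell's bias so CE = 0, then total error = variable error
        df = err.add_log_errors(t)
        df2 = df.drop(columns=["log_error", "ce", "ve"])
        df2["response_m"] = np.exp(np.log(df["response_m"]) - df["ce"])
        df2 = err.add_log_errors(df2)
        np.testing.assert_allclose(df2["log_error"] ** 2, df2["ve"],
                                   atol=1e-12)

    def test_mean_ve_mode_gives_one_pair_per_participant(self, ideal_table):
        res = err.alternative_error_metrics(ideal_table, "mean_ve",
                                            n_boot=200, seed=0)
        assert res.n_pairs == 12

    def test_unknown_mode_rejected(self, ideal_table):
        with pytest.raises(ValueError, match="unknown mode"):
            err.alternative_error_metrics(ideal_table, "median")
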