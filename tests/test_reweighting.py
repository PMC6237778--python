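"""Hierarchical reweighting model: posterior, sampler, recovery."""

import numpy as np
import pytest
from scipy import stats

from cuefuse._streams import substream
from cuefuse.reweighting import (PRIORS, McmcConfig, ReweightingData,
                                 _CellStats, fit_reweighting, log_posterior,
                                 label_swap_check, summarize_reweighting)

Phi = stats.norm.cdf
Phi_inv = stats.norm.ppf


def make_synthetic_data(w3, r_effects, directions, tau=100.0, n_trials=83,
                        seed=0, sd_va=0.15):
    """Simulate directly from the generative model: Y = W V + (1-W) A +
    Normal(0, precision tau), with W5 linked through the probit shift."""
    rng = substream(seed, "synthdata")
    participants = [f"P{i + 1:02d}" for i in range(len(w3))]
    s3, s5 = [], []
    for i in range(len(w3)):
        sign = 1.0 if directions[i] == "increased" else -1.0
        w5 = Phi(Phi_inv(w3[i]) + sign * r_effects[i])
        for w, cells in ((w3[i], s3), (w5, s5)):
            a = rng.uniform(np.log(12), np.log(30), n_trials)
            v = a + rng.normal(0, sd_va, n_trials)
            y = w * v + (1 - w) * a + rng.normal(0, 1 / np.sqrt(tau), n_trials)
            e, d = y - a, v - a
            cells.append(_CellStats(n_trials, float(e @ e), float(e @ d),
                                    float(d @ d)))
    signs = np.array([1.0 if d == "increased" else -1.0 for d in directions])
    return ReweightingData(participants, signs, s3, s5)


@pytest.fixture(scope="module")
def small_config():
    return McmcConfig(n_chains=2, n_samples=2500, n_burnin=1000, seed=17)


class TestProbitLink:
    def test_zero_effect_keeps_weight(self):
        assert Phi(Phi_inv(0.5) + 0.0) == pytest.approx(0.5)

    def test_shift_to_95th_percentile(self):
        # W3 = 0.5 shifted by 1.6449 on the probit scale lands at 0.95
        assert Phi(Phi_inv(0.5) + 1.6449) == pytest.approx(0.95, abs=1e-4)


@pytest.fixture(scope="module")
def data():
    return make_synthetic_data([0.6, 0.4], [0.3, 0.3],
                               ["increased", "decreased"], seed=1)


class TestLogPosterior:
    def test_finite_at_prior_draws(self, data):
        rng = substream(3, "prior")
        for _ in range(20):
            params = {
                "W3": rng.uniform(0.01, 0.99, 2),
                "R": rng.normal(0, 1, 2),
                "tau3": rng.exponential(1000, 2) + 1e-6,
                "tau5": rng.exponential(1000, 2) + 1e-6,
                "M": rng.normal(0, 1),
                "T": rng.exponential(1000) + 1e-6,
            }
            assert np.isfinite(log_posterior(params, data))

    @pytest.mark.parametrize("corrupt", [
        {"W3": np.array([0.0, 0.5])},
        {"W3": np.array([1.0, 0.5])},
        {"tau3": np.array([-1.0, 2.0])},
        {"T": -0.1},
    ])
    def test_outside_support_rejected(self, data, corrupt):
        params = {"W3": np.array([0.5, 0.5]), "R": np.zeros(2),
                  "tau3": np.ones(2), "tau5": np.ones(2), "M": 0.0, "T": 1.0}
        params.update(corrupt)
        assert log_posterior(params, data) == -np.inf

    def test_prior_on_group_precision_has_mean_1000(self):
        # Exponential given by its rate 0.001
        assert PRIORS["T"].mean() == pytest.approx(1000.0)
        assert PRIORS["tau"].mean() == pytest.approx(1000.0)


class TestSamplerCorrectness:
    def test_tau_posterior_matches_conjugate_form(self, small_config):
        # reduced conjugate sub-model: V = A (so the weight drops out of
        # the likelihood) makes the tau posterior an exact Gamma
        rng = substream(5, "conj")
        n = 40
        e = rng.normal(0, 0.1, n)
        see = float(e @ e)
        cell = _CellStats(n, see, 0.0, 0.0)
        data = ReweightingData(["P01", "P02"], np.array([1.0, -1.0]),
                               [cell, cell], [cell, cell])
        post = fit_reweighting(data, small_config)
        draws = post.flat("tau3")[:, 0]
        shape, rate = 1.0 + n / 2.0, 0.001 + see / 2.0
        ks = stats.kstest(draws[::25], "gamma", args=(shape, 0, 1 / rate))
        assert ks.pvalue > 0.01

    def test_probit_and_uniform_sampling_agree(self):
        data = make_synthetic_data([0.7] * 4, [0.0] * 4,
                                   ["increased", "decreased"] * 2, seed=2)
        base = dict(n_chains=2, n_samples=2000, n_burnin=800, seed=3)
        p1 = fit_reweighting(data, McmcConfig(**base, probit_sampling=True))
        p2 = fit_reweighting(data, McmcConfig(**base, probit_sampling=False))
        w1 = p1.flat("W3").mean(axis=0)
        w2 = p2.flat("W3").mean(axis=0)
        np.testing.assert_allclose(w1, w2, atol=0.05)


class TestRecovery:
    def test_weights_recovered_and_covered(self, small_config):
        true_w = np.array([0.7] * 6 + [0.3] * 6)
        dirs = ["increased", "decreased"] * 6
        data = make_synthetic_data(true_w, [0.5] * 12, dirs, tau=100.0,
                                   seed=7)
        post = fit_reweighting(data, small_config)
        s = summarize_reweighting(post)
        per = s["participants"]
        errs = per["W3_mean"].to_numpy() - true_w
        assert np.mean(np.abs(errs)) < 0.1
        covered = ((per["W3_lo"] <= true_w) & (true_w <= per["W3_hi"])).mean()
        assert covered >= 0.75
        # true reweighting: the M interval excludes zero
        assert s["M_interval"][0] > 0
        assert s["n_predicted_direction"] >= 10

    def test_null_reweighting_interval_contains_zero(self, small_config):
        data = make_synthetic_data([0.6] * 12, [0.0] * 12,
                                   ["increased", "decreased"] * 6, seed=8)
        post = fit_reweighting(data, small_config)
        lo, hi = post.m_interval()
        assert lo < 0 < hi

    def test_extreme_weight_reachable(self, small_config):
        # a near-pure cue-selection observer: posterior mass concentrates
        # near the boundary rather than being repelled from it
        data = make_synthetic_data([0.02] * 6, [0.0] * 6,
                                   ["increased", "decreased"] * 3, seed=9)
        post = fit_reweighting(data, small_config)
        assert post.flat("W3").mean() < 0.1

    def test_w5_is_deterministic_probit_transform(self, small_config):
        data = make_synthetic_data([0.6, 0.4], [0.3, 0.2],
                                   ["increased", "decreased"], seed=10)
        post = fit_reweighting(data, McmcConfig(n_chains=1, n_samples=500,
                                                n_burnin=300, seed=4))
        w3, w5, r = (post.flat(k) for k in ("W3", "W5", "R"))
        expect = Phi(Phi_inv(w3) + post.signs[None, :] * r)
        np.testing.assert_allclose(w5, expect, atol=1e-12)

    def test_convergence_diagnostics_reported(self, small_config):
        data = make_synthetic_data([0.5] * 4, [0.2] * 4,
                                   ["increased", "decreased"] * 2, seed=11)
        post = fit_reweighting(data, small_config)
        assert set(post.rhat) == {"W3", "W5", "R", "tau3", "tau5", "M", "T"}
        assert max(post.rhat.values()) < 1.05


class TestLabelSwap:
    def test_swap_nulls_the_effect(self):
        cfg = McmcConfig(n_chains=2, n_samples=2000, n_burnin=800, seed=12)
        true_w = np.array([0.65] * 12)
        dirs = ["increased"] * 6 + ["decreased"] * 6
        data = make_synthetic_data(true_w, [0.5] * 12, dirs, seed=13)
        report = label_swap_check(data, cfg)
        lo0, hi0 = report["original"]["M_interval"]
        lo1, hi1 = report["swapped"]["M_interval"]
        assert lo0 > 0  # consistent data: interval excludes zero
        assert lo1 < 0 < hi1  # swapped labels: interval includes zero

    def test_swap_is_involution(self):
        cfg = McmcConfig(n_chains=1, n_samples=400, n_burnin=200, seed=14)
        dirs = ["increased"] * 6 + ["decreased"] * 6
        data = make_synthetic_data([0.6] * 12, [0.3] * 12, dirs, seed=15)
        swap = (data.participants[3:6], data.participants[9:12])
        r1 = label_swap_check(data, cfg, swap=swap)
        signs = np.array([-s if p in set(swap[0]) | set(swap[1]) else s
                          for p, s in zip(data.participants, data.signs)])
        swapped = ReweightingData(data.participants, signs, data.s3, data.s5)
        r2 = label_swap_check(swapped, cfg, swap=swap)
        # swapping twice reproduces the original fit under the same seed
        assert r2["swapped"]["M_mean"] == pytest.approx(
            r1["original"]["M_mean"])

    def test_needs_both_groups(self):
        data = make_synthetic_data([0.6] * 4, [0.3] * 4, ["increased"] * 4,
                                   seed=16)
        with pytest.raises(ValueError, match=">= 6 participants"):
            label_swap_check(data, McmcConfig(n_chains=1, n_samples=200,
                                              n_burnin=100, seed=0))
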