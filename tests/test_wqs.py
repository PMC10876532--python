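"""Quantization, constrained weight estimation and bootstrap aggregation."""

import numpy as np
import pandas as pd
import pytest

from pmpanel import SyntheticConfig, fit_wqs_bootstrap, generate_panel, quantize
from pmpanel.wqs import WQSFit, estimate_weights_single, influential_constituents
from pmpanel.constants import CONSTITUENTS


class TestQuantize:
    def test_twenty_values_ten_bins(self):
        qm = quantize(pd.DataFrame({"x": np.arange(1.0, 21.0)}), q=10)
        expected = np.repeat(np.arange(10.0), 2)
        np.testing.assert_array_equal(qm.scores[:, 0], expected)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2, 1, 200)
        a = quantize(pd.DataFrame({"x": x}), q=10).scores
        b = quantize(pd.DataFrame({"x": np.log(x)}), q=10).scores
        np.testing.assert_array_equal(a, b)

    def test_tie_rule_keeps_bins_equal(self):
        # 50% ties at one value: ordinal ranking splits the tied block across
        # bins by row position, so occupancy stays exactly equal.
        x = np.concatenate([np.full(50, 5.0), np.arange(50.0)])
        qm = quantize(pd.DataFrame({"x": x}), q=10)
        occ = np.bincount(qm.scores[:, 0].astype(int), minlength=10)
        np.testing.assert_array_equal(occ, np.full(10, 10))
        assert qm.scores.sum() == 100 * 4.5  # total rank mass preserved

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            quantize(pd.DataFrame({"SO4": np.ones(100)}), q=10)


def _toy_wqs_data(seed, n=3000, causal=0, beta=0.35, copy_col=None):
    """Deciles from independent lognormals; counts driven by one column."""
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(0, 1, size=(n, 15))
    if copy_col is not None:
        raw[:, copy_col[1]] = raw[:, copy_col[0]]
    Q = quantize(pd.DataFrame(raw, columns=list(CONSTITUENTS))).scores
    Z = rng.normal(size=(n, 2))
    off = np.log(rng.integers(200, 2000, n).astype(float))
    eta = np.log(0.02) + beta * Q[:, causal] + 0.05 * Z[:, 0] + off
    y = rng.poisson(np.exp(eta)).astype(float)
    return Q, Z, y, off


class TestSingleFit:
    def test_causal_constituent_dominates(self):
        hits = 0
        Q, Z, y, off = _toy_wqs_data(1)
        rng = np.random.default_rng(5)
        full = estimate_weights_single(Q, Z, y, off, rng=rng)
        for _ in range(10):
            idx = rng.integers(0, len(y), len(y))
            fit = estimate_weights_single(
                Q[idx], Z[idx], y[idx], off[idx], x0=full["x"]
            )
            hits += fit["weights"][0] > 0.5
        assert hits >= 8

    def test_duplicated_column_weight_sum_stable(self):
        sums = []
        for seed in (1, 2, 3, 4):
            Q, Z, y, off = _toy_wqs_data(seed, causal=0, copy_col=(0, 1))
            fit = estimate_weights_single(
                Q, Z, y, off, rng=np.random.default_rng(seed)
            )
            sums.append(fit["weights"][0] + fit["weights"][1])
        assert max(sums) - min(sums) < 0.2  # pair sum stable within +-0.1

    def test_permuted_outcome_null_beta(self):
        Q, Z, y, off = _toy_wqs_data(3)
        rng = np.random.default_rng(9)
        betas = []
        for _ in range(8):
            perm = rng.permutation(len(y))
            fit = estimate_weights_single(Q, Z, y[perm], off[perm], rng=rng)
            betas.append(fit["beta1"])
        betas = np.array(betas)
        assert abs(betas.mean()) < 3 * betas.std(ddof=1) / np.sqrt(len(betas)) + 0.01


class TestBootstrap:
    @pytest.fixture(scope="class")
    def wqs_panel(self):
        cfg = SyntheticConfig(seed=11, count_model="wqs", n_zips=1200)
        return generate_panel(cfg)

    def test_deterministic_and_simplex(self, wqs_panel):
        panel, _ = wqs_panel
        a = fit_wqs_bootstrap(panel, "non_respiratory", B=2, seed=3)
        b = fit_wqs_bootstrap(panel, "non_respiratory", B=2, seed=3)
        pd.testing.assert_series_equal(a.weights, b.weights)
        assert a.beta_index == b.beta_index
        assert (a.weights >= 0).all()
        assert a.weights.sum() == pytest.approx(1.0, abs=1e-8)
        assert a.bootstrap_weights.shape == (2, 15)

    def test_recovers_planted_weights(self, wqs_panel):
        panel, truth = wqs_panel
        fit = fit_wqs_bootstrap(panel, "non_respiratory", B=20, seed=1)
        top3 = set(fit.weights.nlargest(3).index)
        assert top3 == {"SO4", "Ni", "Cu"}
        w_true = pd.Series(
            truth.config.true_wqs_weights, index=list(CONSTITUENTS)
        )
        # the generating tail is a 12-way tie, which caps the achievable
        # Spearman of even a perfect estimator at sqrt(137/280) ~ 0.6995
        # (tied ranks average; the tie block contributes no signal)
        rho = fit.weights.corr(w_true, method="spearman")
        assert rho >= 0.95 * np.sqrt(137 / 280)
        # absolute recovery of the influential weights
        for name in ("SO4", "Ni", "Cu"):
            assert abs(fit.weights[name] - w_true[name]) < 0.05

    def test_all_noise_panel_spreads_weight(self):
        # outcome independent of every constituent (and no latent ZIP
        # frailty, which at small n can masquerade as a mixture signal)
        maxima = []
        for seed in range(21, 31):
            cfg = SyntheticConfig(
                seed=seed, count_model="wqs", n_zips=400, rate_frailty_sd=0.0,
                true_rr_per_decile={o: 1.0 for o in
                                    ("non_respiratory", "cns", "intestinal",
                                     "urinary", "septicemia")},
            )
            panel, _ = generate_panel(cfg)
            fit = fit_wqs_bootstrap(panel, "non_respiratory", B=50, seed=seed)
            maxima.append(fit.weights.max())
        assert np.mean(maxima) < 0.25

    def test_b_must_be_at_least_two(self, wqs_panel):
        panel, _ = wqs_panel
        with pytest.raises(ValueError, match="bootstrap"):
            fit_wqs_bootstrap(panel, "non_respiratory", B=1)


class TestInfluence:
    def _fit_with_weights(self, w):
        w = pd.Series(w, index=list(CONSTITUENTS))
        return w / w.sum()

    def test_uniform_flags_none(self):
        w = self._fit_with_weights(np.full(15, 1.0))
        assert influential_constituents(w) == []

    def test_single_dominant(self):
        w = np.full(15, 0.1 / 14)
        w[0] = 0.9
        assert influential_constituents(self._fit_with_weights(w)) == ["EC"]

    def test_three_reported_constituents(self):
        w = np.full(15, (1 - 0.308 - 0.225 - 0.153) / 12)
        names = list(CONSTITUENTS)
        w[names.index("SO4")] = 0.308
        w[names.index("Ni")] = 0.225
        w[names.index("Cu")] = 0.153
        flagged = influential_constituents(self._fit_with_weights(w))
        assert sorted(flagged) == ["Cu", "Ni", "SO4"]


class TestTrainSplit:
    def test_split_fit_valid_and_distinct(self):
        cfg = SyntheticConfig(seed=31, count_model="wqs", n_zips=150)
        panel, _ = generate_panel(cfg)
        full = fit_wqs_bootstrap(panel, "non_respiratory", B=4, seed=2)
        split = fit_wqs_bootstrap(
            panel, "non_respiratory", B=4, seed=2, train_frac=0.6
        )
        assert split.weights.sum() == pytest.approx(1.0, abs=1e-8)
        assert split.final_fit.n_obs < full.final_fit.n_obs
        with pytest.raises(ValueError, match="train_frac"):
            fit_wqs_bootstrap(panel, "non_respiratory", B=4, train_frac=1.5)
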