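"""Stratification, Ward clustering, NMF and tracer labeling."""

import numpy as np
import pandas as pd
import pytest

from pmpanel import (
    SyntheticConfig,
    fit_nmf,
    generate_panel,
    label_sources,
    massify_and_scale,
    mean_profiles,
    ward_cluster,
)
from pmpanel.constants import CONSTITUENTS, UNASSIGNED
from pmpanel.sources import stratify

from _oracles import hungarian_cosine_match


def _profile_frame(values):
    return pd.DataFrame(
        {"x": values}, index=[f"Z{i}" for i in range(len(values))]
    )


class TestMeanProfiles:
    def test_single_year_period_is_identity(self, small_panel):
        panel, _ = small_panel
        prof = mean_profiles(panel, (2000, 2000))
        one = panel[panel.year == 2000].set_index("zip_id")[list(CONSTITUENTS)]
        pd.testing.assert_frame_equal(prof, one.sort_index())

    def test_two_year_mean(self):
        panel = pd.DataFrame(
            {
                "zip_id": ["A", "A"],
                "year": [2000, 2001],
                **{c: [2.0, 4.0] for c in CONSTITUENTS},
            }
        )
        prof = mean_profiles(panel, (2000, 2001))
        assert (prof.loc["A"] == 3.0).all()

    def test_row_order_invariance(self, small_panel):
        panel, _ = small_panel
        shuffled = panel.sample(frac=1, random_state=0)
        pd.testing.assert_frame_equal(
            mean_profiles(panel, (2000, 2005)),
            mean_profiles(shuffled, (2000, 2005)),
        )


class TestWard:
    def test_two_well_separated_groups(self):
        labels = ward_cluster(_profile_frame([0.0, 1.0, 10.0, 11.0]), k=2)
        assert labels["Z0"] == labels["Z1"]
        assert labels["Z2"] == labels["Z3"]
        assert labels["Z0"] != labels["Z2"]

    def test_k_equals_n_singletons(self):
        labels = ward_cluster(_profile_frame([0.0, 5.0, 10.0]), k=3)
        assert labels.nunique() == 3

    def test_duplicated_rows_cocluster(self):
        vals = [0.0, 0.0, 8.0, 8.0, 20.0, 20.0]
        labels = ward_cluster(_profile_frame(vals), k=3)
        assert labels["Z0"] == labels["Z1"]
        assert labels["Z2"] == labels["Z3"]
        assert labels["Z4"] == labels["Z5"]

    def test_k_larger_than_rows(self):
        with pytest.raises(ValueError, match="exceeds"):
            ward_cluster(_profile_frame([0.0, 1.0]), k=3)

    def test_row_order_invariant_labels(self, small_panel):
        panel, _ = small_panel
        prof = mean_profiles(panel, (2000, 2005))
        a = ward_cluster(prof, k=3)
        b = ward_cluster(prof.sample(frac=1, random_state=1), k=3)
        pd.testing.assert_series_equal(a, b.sort_index())


class TestStratify:
    def test_every_row_in_exactly_one_stratum(self, small_panel):
        panel, _ = small_panel
        strat = stratify(panel)
        assert len(strat.table) == len(panel)
        assert not strat.table.duplicated(["zip_id", "year"]).any()
        assert len(strat.strata) == 9


class TestNMF:
    def test_exact_rank_two_factorization(self):
        rng = np.random.default_rng(0)
        W0 = rng.gamma(2, 1, size=(15, 2))
        H0 = rng.gamma(2, 1, size=(200, 2))
        X = H0 @ W0.T
        _, _, rel = fit_nmf(X, 2, seed=0, n_init=5)
        assert rel < 1e-5

    def test_rank_one_recovers_direction(self):
        rng = np.random.default_rng(1)
        w0 = rng.gamma(2, 1, size=15)
        X = np.outer(rng.gamma(2, 1, 300), w0)
        loadings, scores, _ = fit_nmf(X, 1, seed=0, n_init=3)
        cos = float(
            loadings[:, 0] @ w0 / (np.linalg.norm(loadings[:, 0]) * np.linalg.norm(w0))
        )
        assert cos > 0.9999
        assert (scores >= 0).all()

    def test_unit_sum_loading_convention(self):
        rng = np.random.default_rng(2)
        X = rng.gamma(2, 1, size=(100, 15))
        loadings, scores, _ = fit_nmf(X, 3, seed=0, n_init=3)
        np.testing.assert_allclose(loadings.sum(axis=0), 1.0, atol=1e-10)
        # reconstruction: scores @ loadings.T approximates X
        assert np.linalg.norm(X - scores @ loadings.T) / np.linalg.norm(X) < 0.5

    def test_planted_loadings_recovered(self):
        cfg = SyntheticConfig(seed=13, n_zips=100, noise_cv=0.2)
        panel, truth = generate_panel(cfg)
        X = panel[list(CONSTITUENTS)].to_numpy()
        loadings, _, _ = fit_nmf(X, 5, seed=3)
        cos = hungarian_cosine_match(loadings, np.asarray(cfg.loading_matrix))
        assert (cos > 0.9).sum() >= 4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_nmf(-np.ones((10, 15)), 2)
        with pytest.raises(ValueError, match="k="):
            fit_nmf(np.ones((4, 15)), 4)


class TestLabels:
    def _uniform(self, k=4):
        return np.full((15, k), 1.0 / 15)

    def test_nickel_vanadium_factor_is_oil(self):
        W = self._uniform(3).copy() * 0.2
        i = {c: j for j, c in enumerate(CONSTITUENTS)}
        W[i["Ni"], 0] = 0.5
        W[i["V"], 0] = 0.3
        W = W / W.sum(axis=0)
        labels = label_sources(W)
        assert labels[0] == "oil combustion"

    def test_uniform_loadings_unassigned(self):
        assert label_sources(self._uniform()) == [UNASSIGNED] * 4

    def test_greedy_resolves_competing_sulfate_factors(self):
        i = {c: j for j, c in enumerate(CONSTITUENTS)}
        W = np.full((15, 2), 0.01)
        W[i["SO4"], 0] = 0.6
        W[i["NH4"], 0] = 0.2
        W[i["SO4"], 1] = 0.4
        W[i["NO3"], 1] = 0.4
        W = W / W.sum(axis=0)
        labels = label_sources(W)
        assert labels[0] == "coal burning"
        assert labels[1] == "regionally transported nitrate"


class TestMassify:
    def test_scale_invariance_of_sd_series(self):
        rng = np.random.default_rng(3)
        W = rng.dirichlet(np.ones(15), size=2).T
        H = rng.gamma(2, 1, size=(100, 2))
        mass1, scaled1, _ = massify_and_scale(W, H)
        mass2, scaled2, _ = massify_and_scale(W, 2 * H)
        np.testing.assert_allclose(mass2, 2 * mass1)
        np.testing.assert_allclose(scaled2, scaled1)
        np.testing.assert_allclose(np.nanstd(scaled1, axis=0), 1.0, atol=1e-8)

    def test_constant_factor_flagged(self):
        W = np.full((15, 1), 1.0 / 15)
        H = np.full((50, 1), 3.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            mass, scaled, keep = massify_and_scale(W, H)
        np.testing.assert_allclose(mass, 3.0)
        assert not keep[0]
        assert np.isnan(scaled).all()

    def test_mass_closure_on_exact_factorization(self):
        rng = np.random.default_rng(4)
        W0 = rng.dirichlet(np.ones(15), size=2).T * np.array([3.0, 1.5])
        H0 = rng.gamma(2, 1, size=(300, 2))
        X = H0 @ W0.T
        loadings, scores, _ = fit_nmf(
            X, 2, seed=0, n_init=5, max_iter=50_000, tol=1e-12
        )
        mass, _, _ = massify_and_scale(loadings, scores)
        np.testing.assert_allclose(mass.sum(axis=1), X.sum(axis=1), rtol=1e-6)


class TestMassifyRegress:
    def test_regress_matches_unit_sum_on_exact_factorization(self):
        rng = np.random.default_rng(5)
        W0 = rng.dirichlet(np.ones(15), size=3).T * np.array([3.0, 1.5, 0.8])
        H0 = rng.gamma(2, 1, size=(400, 3))
        X = H0 @ W0.T
        loadings, scores, _ = fit_nmf(X, 3, seed=0, n_init=5,
                                      max_iter=20_000, tol=1e-10)
        m_unit, _, _ = massify_and_scale(loadings, scores)
        m_reg, _, _ = massify_and_scale(loadings, scores, X=X, method="regress")
        np.testing.assert_allclose(m_reg, m_unit, rtol=1e-2)

    def test_regress_requires_x(self):
        with pytest.raises(ValueError, match="requires"):
            massify_and_scale(np.ones((15, 2)) / 15, np.ones((10, 2)),
                              method="regress")
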