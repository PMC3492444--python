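"""Bolstered-error estimation and the 3-gene linear classifier search."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adsig import classifier as cf


def _data(rng, n_genes=20, n_a=9, n_b=4, planted=(), offset=3.0):
    D = rng.normal(size=(n_genes, n_a + n_b))
    for g in planted:
        D[g, :n_a] += offset
    values = pd.DataFrame(D, index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{i}" for i in range(n_a + n_b)])
    labels = np.array(["CP"] * n_a + ["P"] * n_b)
    return values, labels


class TestKernelWidths:
    def test_alpha3_is_sqrt_of_chi2_median(self):
        # frozen numeric value of the chi-square(3) median's square root
        assert cf.alpha_d(3) == pytest.approx(1.5381722544550522, rel=1e-12)

    def test_widths_are_mean_nn_distance_over_alpha(self, rng):
        X = rng.normal(size=(6, 3))
        y = np.array(["a"] * 3 + ["b"] * 3)
        sig = cf.kernel_widths(X, y)
        for cls, rows in (("a", X[:3]), ("b", X[3:])):
            d = np.sqrt(((rows[:, None] - rows[None]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            expected = d.min(axis=1).mean() / cf.alpha_d(3)
            assert sig[cls] == pytest.approx(expected)

    def test_coincident_points_floored_with_warning(self):
        X = np.zeros((4, 3))
        X[2:] += 1.0
        y = np.array(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="coincident"):
            sig = cf.kernel_widths(X, y)
        assert sig["a"] > 0 and sig["b"] > 0


class TestBolsteredError:
    def test_point_on_surface_contributes_half(self):
        clf = cf.LinearClassifier(("a", "b", "c"), np.array([1.0, 0.0, 0.0]), 0.0)
        X = np.array([[0.0, 0, 0], [5.0, 0, 1], [-5.0, 0, 0], [-5.0, 1, 0]])
        y = np.array([1, 1, -1, -1])
        est = cf.bolstered_error(clf, X, y, sigma={1: 0.5, -1: 0.5})
        # on-surface point: Phi(0) = 1/2; the rest are 10 sigma away
        assert est.epsilon == pytest.approx(0.5 / 4, abs=1e-6)

    def test_sigma_to_zero_recovers_resubstitution(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([1] * 5 + [-1] * 5)
        clf = cf.LinearClassifier(("a", "b", "c"), rng.normal(size=3), 0.1)
        f = clf.decision(X)
        resub = float((np.where(f >= 0, 1, -1) != y).mean())
        est = cf.bolstered_error(clf, X, y, sigma={1: 1e-14, -1: 1e-14})
        assert est.epsilon == pytest.approx(resub, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_closed_form_matches_monte_carlo(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3))
        y = np.array([1] * 4 + [-1] * 4)
        X[:4] += rng.uniform(0, 2)
        clf = cf.LinearClassifier(("a", "b", "c"), rng.normal(size=3),
                                  float(rng.normal()))
        closed = cf.bolstered_error(clf, X, y)
        mc = cf.bolstered_error(clf, X, y, method="monte_carlo",
                                mc_draws=40_000, seed=seed)
        se = np.sqrt(max(closed.epsilon * (1 - closed.epsilon), 1e-6) / mc.mc_draws)
        assert abs(closed.epsilon - mc.epsilon) <= 3 * se + 3 / mc.mc_draws

    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(9, 3))
        y = np.array([1] * 5 + [-1] * 4)
        w = rng.normal(size=3)
        clf = cf.LinearClassifier(("a", "b", "c"), w, 0.3)
        R = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        clf_rot = cf.LinearClassifier(("a", "b", "c"), R @ w, 0.3)
        e1 = cf.bolstered_error(clf, X, y)
        e2 = cf.bolstered_error(clf_rot, X @ R.T, y)
        assert e1.epsilon == pytest.approx(e2.epsilon, rel=1e-9)

    def test_uniform_rescaling_invariance(self, rng):
        X = rng.normal(size=(9, 3))
        y = np.array([1] * 5 + [-1] * 4)
        w = rng.normal(size=3)
        clf = cf.LinearClassifier(("a", "b", "c"), w, 0.3)
        clf_scaled = cf.LinearClassifier(("a", "b", "c"), w, 0.3 * 7.0)
        e1 = cf.bolstered_error(clf, X, y)
        e2 = cf.bolstered_error(clf_scaled, 7.0 * X, y)
        assert e1.epsilon == pytest.approx(e2.epsilon, rel=1e-9)


class TestPreselect:
    def test_dominant_feature_retained(self, rng):
        values, labels = _data(rng, n_genes=50, planted=(5,), offset=5.0)
        kept = cf.preselect_features(values, labels, target_count=10)
        assert "g5" in kept

    def test_target_beyond_feature_count_returns_all(self, rng):
        values, labels = _data(rng, n_genes=8)
        kept = cf.preselect_features(values, labels, target_count=100)
        assert sorted(kept) == sorted(values.index)

    def test_single_class_rejected(self, rng):
        values, _ = _data(rng)
        with pytest.raises(ValueError, match="class"):
            cf.preselect_features(values, np.array(["CP"] * 13), 5)

    def test_planted_trio_survives_halving_from_500(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            values, labels = _data(rng, n_genes=500, planted=(5, 117, 429))
            kept = set(cf.preselect_features(values, labels, target_count=200))
            hits += {"g5", "g117", "g429"} <= kept
        assert hits >= 9


class TestSearchTriplets:
    def test_exactly_three_candidates_gives_one_triplet(self, rng):
        values, labels = _data(rng, n_genes=3)
        out = cf.search_triplets(values, labels, top_k=5)
        assert len(out) == 1 and set(out[0].genes) == {"g0", "g1", "g2"}

    def test_separable_fixture_reaches_zero_resubstitution(self, rng):
        values, labels = _data(rng, planted=(2, 7, 11), offset=6.0)
        out = cf.search_triplets(values, labels, top_k=3)
        best = out[0]
        assert best.resubstitution_error == 0.0
        pred = cf.classify(best.classifier, values)
        expected = pd.Series(np.where(labels == "P", 1, -1), index=values.columns)
        assert (pred == expected).all()

    def test_oversized_search_guard(self, rng):
        values, labels = _data(rng, n_genes=30)
        with pytest.raises(ValueError, match="search too large"):
            cf.search_triplets(values, labels, max_combinations=100)

    def test_ranking_is_deterministic(self, rng):
        values, labels = _data(rng, planted=(2,), offset=2.0)
        a = cf.search_triplets(values, labels, top_k=5)
        b = cf.search_triplets(values, labels, top_k=5)
        assert [c.genes for c in a] == [c.genes for c in b]
        assert [c.bolstered_error for c in a] == [c.bolstered_error for c in b]

    def test_ranked_by_bolstered_then_margin(self, rng):
        values, labels = _data(rng, planted=(2, 7), offset=2.0)
        out = cf.search_triplets(values, labels, top_k=8)
        eps = [c.bolstered_error for c in out]
        assert eps == sorted(eps)

    def test_planted_genes_dominate_top_candidates(self, rng):
        """Every top-ranked triplet draws on the planted signature genes."""
        values, labels = _data(rng, n_genes=50, planted=(5, 17, 29), offset=3.0)
        out = cf.search_triplets(values, labels, top_k=5)
        planted = {"g5", "g17", "g29"}
        assert all(len(set(c.genes) & planted) >= 1 for c in out)


class TestClassify:
    def test_tie_goes_to_positive_class(self):
        clf = cf.LinearClassifier(("a", "b", "c"), np.array([1.0, 0, 0]), 0.0)
        samples = pd.DataFrame([[0.0], [1.0], [2.0]], index=["a", "b", "c"],
                               columns=["s0"])
        assert cf.classify(clf, samples)["s0"] == 1

    def test_missing_gene_rejected(self):
        clf = cf.LinearClassifier(("a", "b", "c"), np.array([1.0, 0, 0]), 0.0)
        samples = pd.DataFrame([[0.0], [1.0]], index=["a", "b"], columns=["s0"])
        with pytest.raises(ValueError, match="missing gene"):
            cf.classify(clf, samples)

    def test_agrees_with_naive_dot_product(self, rng):
        w, b = rng.normal(size=3), float(rng.normal())
        clf = cf.LinearClassifier(("a", "b", "c"), w, b)
        samples = pd.DataFrame(rng.normal(size=(3, 20)), index=["a", "b", "c"],
                               columns=[f"s{i}" for i in range(20)])
        got = cf.classify(clf, samples)
        for col in samples.columns:
            x = samples[col].to_numpy()
            naive = 1 if (w[0] * x[0] + w[1] * x[1] + w[2] * x[2] + b) >= 0 else -1
            assert got[col] == naive

    def test_training_labels_reproduced_on_separable_fit(self, rng):
        X = rng.normal(size=(10, 3))
        X[:5] += 4.0
        y = np.array([1.0] * 5 + [-1.0] * 5)
        clf = cf.fit_linear_classifier(X, y)
        assert clf.method == "max_margin"
        samples = pd.DataFrame(X.T, index=["x0", "x1", "x2"])
        clf2 = cf.LinearClassifier(("x0", "x1", "x2"), clf.w, clf.b)
        assert (cf.classify(clf2, samples).to_numpy() == y).all()
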