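"""PCA/Varimax, outliers, PLS-DA/VIP/Q², OPLS-DA, P-RDA, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from nmrmetab import multivariate as mv


@pytest.fixture(scope="module")
def class_data():
    """Two well-separated classes with a few informative features."""
    rng = np.random.default_rng(7)
    n = 40
    y = np.array(["A"] * 20 + ["B"] * 20)
    X = rng.normal(size=(n, 10))
    X[20:, :3] += 3.0
    return X, y


class TestPca:
    def test_collinear_data_one_component(self):
        x = np.linspace(0, 1, 12)
        X = np.column_stack([x, 2 * x])
        model = mv.pca(X, n_comp=1)
        total = np.var(X - X.mean(0), axis=0, ddof=1).sum()
        assert model.eigenvalues[0] == pytest.approx(total, rel=1e-10)

    def test_eigenvalue_sum_is_total_variance(self, rng):
        X = rng.normal(size=(15, 6))
        model = mv.pca(X, n_comp=5)
        # 5 of 6 possible comps; compare against the top-5 eigenvalue sum
        evals = np.sort(linalg.eigvalsh(np.cov(X.T)))[::-1]
        assert model.eigenvalues.sum() == pytest.approx(evals[:5].sum(), rel=1e-10)

    def test_scores_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(20, 5))
        model = mv.pca(X, n_comp=3)
        C = X - X.mean(0)
        evals, evecs = linalg.eigh(np.cov(X.T))
        order = np.argsort(evals)[::-1]
        oracle = C @ evecs[:, order[:3]]
        for k in range(3):  # eigenvectors defined up to sign
            s = np.sign(oracle[0, k] * model.scores[0, k]) or 1.0
            np.testing.assert_allclose(model.scores[:, k], s * oracle[:, k], atol=1e-8)

    def test_squared_cosines_in_unit_interval(self, rng):
        model = mv.pca(rng.normal(size=(25, 8)), n_comp=4)
        assert np.all(model.squared_cosines >= 0)
        assert np.all(model.squared_cosines <= 1)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            mv.pca(rng.normal(size=(5, 3)), n_comp=5)


class TestVarimax:
    def test_rotation_matrix_orthogonal(self, rng):
        model = mv.pca(rng.normal(size=(30, 8)), n_comp=3)
        _, T = mv.varimax_rotate(model)
        np.testing.assert_allclose(T.T @ T, np.eye(3), atol=1e-10)

    def test_communalities_preserved(self, rng):
        model = mv.pca(rng.normal(size=(30, 8)), n_comp=3)
        rotated, _ = mv.varimax_rotate(model)
        before = (mv.factor_loadings(model) ** 2).sum(axis=1)
        after = (mv.factor_loadings(rotated) ** 2).sum(axis=1)
        np.testing.assert_allclose(before, after, atol=1e-10)

    def test_fixed_point_of_double_rotation(self, rng):
        model = mv.pca(rng.normal(size=(40, 6)), n_comp=3)
        once, _ = mv.varimax_rotate(model)
        twice, T2 = mv.varimax_rotate(once)
        # already at the optimum: second rotation is sign/permutation only
        np.testing.assert_allclose(np.abs(T2), np.eye(3)[np.argmax(np.abs(T2), 0)].T @ np.eye(3), atol=1e-6)
        np.testing.assert_allclose(
            np.sort(np.abs(once.loadings).ravel()),
            np.sort(np.abs(twice.loadings).ravel()),
            atol=1e-6,
        )

    def test_single_component_noop_with_warning(self, rng):
        model = mv.pca(rng.normal(size=(10, 4)), n_comp=1)
        with pytest.warns(UserWarning):
            out, T = mv.varimax_rotate(model)
        assert out is model


class TestOutliers:
    def test_displaced_sample_flagged(self, rng):
        X = rng.normal(size=(30, 5))
        X[3] += 10.0  # 10 pooled SDs along every axis
        model = mv.pca(X, n_comp=2, sample_ids=[f"s{i}" for i in range(30)])
        assert "s3" in mv.detect_outliers(model)

    def test_false_positive_rate_near_alpha(self, rng):
        rates = []
        for _ in range(100):
            model = mv.pca(rng.normal(size=(100, 5)), n_comp=2)
            rates.append(len(mv.detect_outliers(model)) / 100)
        assert 0.01 <= np.mean(rates) <= 0.10

    def test_simulated_outlier_cohort(self, simulator):
        from nmrmetab import preprocess as pp
        from nmrmetab import synth
        from nmrmetab.effects import FOLD_CHANGES_CS

        spec = synth.CohortSpec(
            n_control=28, n_case=10, fold_changes=FOLD_CHANGES_CS, seed=3, n_outliers=1
        )
        spectra, _ = simulator.simulate(spec)
        table = pp.exclude_regions(pp.intelligent_bucket(spectra))
        m = pp.pareto_scale(pp.glog_transform(pp.cs_normalize(table)))
        model = mv.pca(m, n_comp=2)
        assert spectra[-1].sample_id in mv.detect_outliers(model)


class TestPlsda:
    def test_perfect_single_feature_r2(self, rng):
        y = np.array(["A"] * 10 + ["B"] * 10)
        X = np.column_stack([(y == "B").astype(float), rng.normal(size=20) * 1e-12])
        model = mv.plsda_fit(X, y, n_comp=1)
        assert model.r2y == pytest.approx(1.0, abs=1e-9)

    def test_score_orthogonality(self, class_data):
        X, y = class_data
        model = mv.plsda_fit(X, y, n_comp=3)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-9 * np.abs(np.diag(G)).max()

    def test_noise_features_get_small_weights(self, rng):
        y = np.array(["A"] * 100 + ["B"] * 100)
        signal = (y == "B").astype(float) + rng.normal(0, 0.1, 200)
        X = np.column_stack([signal] + [rng.normal(size=200) for _ in range(5)])
        model = mv.plsda_fit(X, y, n_comp=1)
        w = np.abs(model.weights[:, 0])
        assert w[0] == w.max()
        assert w[0] > 3 * w[1:].max()

    def test_single_class_rejected(self, rng):
        with pytest.raises(mv.DataError):
            mv.plsda_fit(rng.normal(size=(8, 3)), ["A"] * 8)


class TestVip:
    def test_single_feature_vip_is_one(self):
        y = np.array(["A", "A", "B", "B", "A", "B"])
        X = np.array([[0.1], [0.2], [1.0], [1.1], [0.15], [0.9]])
        model = mv.plsda_fit(X, y, n_comp=1)
        assert model.vip[0] == pytest.approx(1.0)

    def test_mean_square_vip_identity(self, class_data):
        X, y = class_data
        for n_comp in (1, 2, 3):
            model = mv.plsda_fit(X, y, n_comp=n_comp)
            assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-9)

    def test_informative_feature_ranks_first(self, rng):
        wins = 0
        for _ in range(50):
            y = np.array(["A"] * 15 + ["B"] * 15)
            X = rng.normal(size=(30, 10))
            X[:, 4] += 2.0 * (y == "B")
            model = mv.plsda_fit(X, y, n_comp=2)
            wins += int(np.argmax(model.vip) == 4)
        assert wins >= 47


class TestQ2AndPermutation:
    def test_exact_relation_gives_q2_one(self):
        y = np.array(["A"] * 10 + ["B"] * 10)
        X = np.column_stack([(y == "B").astype(float)])
        q2 = mv.cross_validate_q2(X, y, scheme="loo", n_comp=1)
        assert q2 == pytest.approx(1.0, abs=1e-9)

    def test_mean_prediction_gives_q2_zero(self):
        # predicting every held-out case by the grand mean: PRESS = TSS
        y = np.array([0.0, 1.0, 0.0, 1.0])
        press = ((y - y.mean()) ** 2).sum()
        tss = ((y - y.mean()) ** 2).sum()
        assert 1.0 - press / tss == 0.0

    def test_null_q2_nonpositive_on_average(self, rng):
        q2s = []
        for _ in range(50):
            X = rng.normal(size=(24, 8))
            y = np.array(["A"] * 12 + ["B"] * 12)
            q2s.append(mv.cross_validate_q2(X, y, scheme="kfold10", rng=rng))
        assert np.mean(q2s) <= 0.0

    def test_permutation_p_floor(self, class_data):
        X, y = class_data
        obs, p, null = mv.permutation_test(
            X, y, n_perm=99, rng=np.random.default_rng(0)
        )
        assert obs > 0.5
        assert p == pytest.approx(1 / 100)

    def test_planted_effects_q2_above_half(self, simulator):
        # cohorts carrying the published effect panel: Q2 comfortably
        # clears the 0.5 model-merit cut-off
        from nmrmetab import preprocess as pp
        from nmrmetab import synth
        from nmrmetab.effects import FOLD_CHANGES_CS

        above = 0
        for seed in range(10):
            spec = synth.CohortSpec(
                n_control=28, n_case=9, fold_changes=FOLD_CHANGES_CS, seed=seed
            )
            spectra, _ = simulator.simulate(spec)
            table = pp.exclude_regions(pp.intelligent_bucket(spectra))
            m = pp.pareto_scale(pp.glog_transform(pp.targeted_panel(spectra, table, values="cs")))
            q2 = mv.cross_validate_q2(m, m.groups, rng=np.random.default_rng(seed))
            above += q2 > 0.5
        assert above >= 9


class TestOplsda:
    def test_pcorr_extreme_for_perfect_feature(self, rng):
        y = np.array(["A"] * 12 + ["B"] * 12)
        base = (y == "B").astype(float)
        X = np.column_stack([base, rng.normal(size=24), rng.normal(size=24)])
        model = mv.oplsda_fit(X, y, n_orth=1)
        coords = mv.s_plot(model)
        assert abs(coords["p_corr"].iloc[0]) > 0.95

    def test_pcorr_bounded(self, class_data):
        X, y = class_data
        model = mv.oplsda_fit(X, y, n_orth=2)
        assert np.all(np.abs(model.p_corr) <= 1.0)

    def test_orthogonal_scores_uncorrelated_with_y(self, class_data):
        X, y = class_data
        model = mv.oplsda_fit(X, y, n_orth=2)
        yd = (np.asarray(y) == "B").astype(float)
        yc = yd - yd.mean()
        for k in range(model.orthogonal_scores.shape[1]):
            t_o = model.orthogonal_scores[:, k]
            r = (t_o @ yc) / (np.linalg.norm(t_o) * np.linalg.norm(yc))
            assert abs(r) < 1e-8

    def test_osc_improves_predictive_correlation(self, rng):
        # structured y-orthogonal noise: the orthogonal component absorbs
        # it, so the OPLS predictive score beats plain PLS component 1
        y = np.array(["A"] * 20 + ["B"] * 20)
        yd = (y == "B").astype(float)
        confound = rng.normal(size=40) * 4
        X = np.column_stack(
            [yd + 0.5 * confound + rng.normal(0, 0.3, 40) for _ in range(4)]
            + [confound + rng.normal(0, 0.3, 40) for _ in range(4)]
        )
        opls = mv.oplsda_fit(X, y, n_orth=1)
        pls = mv.plsda_fit(X, y, n_comp=1)
        yc = yd - yd.mean()

        def corr(t):
            return abs(t @ yc) / (np.linalg.norm(t) * np.linalg.norm(yc))

        assert corr(opls.predictive_scores) >= corr(pls.scores[:, 0]) - 1e-9


class TestPrda:
    @staticmethod
    def factors(rng, n, disease=None):
        return pd.DataFrame(
            {
                "disease": disease if disease is not None else rng.choice(["HC", "D"], n),
                "age": rng.uniform(3, 54, n),
                "gender": rng.choice(["M", "F"], n),
            }
        )

    def test_independent_factor_rarely_significant(self, rng):
        hits = 0
        for _ in range(100):
            X = rng.normal(size=(24, 6))
            f = self.factors(rng, 24)
            res = mv.prda_permutation(X, f, "age", n_perm=99, rng=rng)
            hits += res.p <= 0.05
        assert hits <= 12  # ~5% nominal

    def test_strong_effect_attains_permutation_floor(self, rng):
        n = 30
        disease = np.array(["HC"] * 15 + ["D"] * 15)
        X = rng.normal(size=(n, 5))
        X[disease == "D"] += 8.0
        f = self.factors(rng, n, disease=disease)
        res = mv.prda_permutation(X, f, "disease", n_perm=199, rng=rng)
        assert res.p == pytest.approx(1 / 200)

    def test_duplicate_conditioning_removes_effect(self, rng):
        n = 30
        disease = np.array(["HC"] * 15 + ["D"] * 15)
        X = rng.normal(size=(n, 5))
        X[disease == "D"] += 5.0
        f = pd.DataFrame({"disease": disease, "twin": disease.copy()})
        with pytest.raises(mv.DataError, match="confounded"):
            mv.prda_permutation(X, f, "disease", n_perm=49, rng=rng)


class TestAhc:
    def test_distance_matrix_symmetric_zero_diagonal(self, rng):
        D = mv.distance_matrix(rng.normal(size=(10, 4)))
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)

    def test_complete_linkage_heights_nondecreasing(self, rng):
        res = mv.ahc(rng.normal(size=(20, 5)))
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_two_planted_clusters_recovered(self, rng):
        for _ in range(20):
            X = rng.normal(size=(20, 4))
            X[10:] += 10.0  # 10-SD separation
            res = mv.ahc(X, n_clusters=2)
            labels = res.labels
            assert len(set(labels[:10])) == 1
            assert len(set(labels[10:])) == 1
            assert labels[0] != labels[-1]

    def test_newick_roundtrip_parses(self, rng):
        import io

        from Bio import Phylo

        res = mv.ahc(rng.normal(size=(6, 3)))
        nwk = mv.to_newick(res.linkage, [f"s{i}" for i in range(6)])
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert tree.count_terminals() == 6
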