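"""NIPALS PCA against an eigendecomposition oracle, plus diagnostic ranking."""

import numpy as np
import pytest

from isofrag.chemometrics import (
    mean_center,
    nipals_pca,
    pca_from_matrix,
    rank_diagnostics,
    restrict_range,
)
from isofrag.spectra import AlignedMatrix, SpectrumMeta, align_to_matrix, tic_normalize


def make_matrix(X, mzs=None, labels=None):
    X = np.asarray(X, float)
    mzs = np.arange(X.shape[1], dtype=float) + 100.0 if mzs is None else np.asarray(mzs)
    labels = labels or [f"s{i}" for i in range(X.shape[0])]
    metas = [SpectrumMeta(lab, 36.0, i, 895.04, 2) for i, lab in enumerate(labels)]
    return AlignedMatrix(mzs, X, metas)


def svd_oracle(X, k):
    """Independent reference: dense SVD with the same sign convention."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = np.zeros((X.shape[1], k))
    scores = np.zeros((X.shape[0], k))
    ev = np.zeros(k)
    total = (S**2).sum()
    for c in range(k):
        v = Vt[c]
        t = U[:, c] * S[c]
        i = np.argmax(np.abs(v))
        if v[i] < 0:
            v, t = -v, -t
        loadings[:, c] = v
        scores[:, c] = t
        ev[c] = 100.0 * S[c] ** 2 / total
    return scores, loadings, ev


class TestMeanCenter:
    def test_column_means_removed(self):
        m = make_matrix([[0.2, 1.0], [0.4, 3.0]])
        centred, means = mean_center(m)
        np.testing.assert_allclose(centred.X[:, 0], [-0.1, 0.1])
        np.testing.assert_allclose(means, [0.3, 2.0])
        assert np.abs(centred.X.mean(axis=0)).max() < 1e-12

    def test_idempotent(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(4, 3)))
        centred, _ = mean_center(m)
        again, means2 = mean_center(centred)
        np.testing.assert_allclose(again.X, centred.X, atol=1e-12)
        np.testing.assert_allclose(means2, 0.0, atol=1e-12)

    def test_constant_column_zeroed(self):
        m = make_matrix([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        centred, _ = mean_center(m)
        assert np.all(centred.X[:, 0] == 0.0)

    def test_single_row_is_error(self):
        with pytest.raises(ValueError):
            mean_center(make_matrix([[1.0, 2.0]]))


class TestNipals:
    def test_three_samples_two_components_explain_everything(self):
        """Centred 3-sample data has rank <= 2, so PC1+PC2 carry 100% of
        the variance — the signature of a three-spectrum PCA."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(3, 20))
        X -= X.mean(axis=0)
        model = nipals_pca(X, 2)
        assert model.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 20))
        X -= X.mean(axis=0)
        model = nipals_pca(X, 3, tol=1e-12, max_iter=100000)
        scores, loadings, ev = svd_oracle(X, 3)
        np.testing.assert_allclose(model.loadings, loadings, atol=1e-6)
        np.testing.assert_allclose(model.scores, scores, atol=1e-6)
        np.testing.assert_allclose(model.explained_variance_pct, ev, atol=1e-6)

    def test_zero_matrix_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            nipals_pca(np.zeros((4, 5)), 2)

    def test_component_budget_enforced(self):
        X = np.random.default_rng(0).normal(size=(3, 5))
        with pytest.raises(ValueError, match="n_components"):
            nipals_pca(X - X.mean(0), 3)

    def test_orthogonality(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 30))
        X -= X.mean(axis=0)
        model = nipals_pca(X, 4, tol=1e-12, max_iter=100000)
        L = model.loadings
        G = L.T @ L
        np.testing.assert_allclose(G, np.eye(4), atol=1e-8)
        S = model.scores.T @ model.scores
        np.testing.assert_allclose(S - np.diag(np.diag(S)), 0.0, atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(5, 12))
        X -= X.mean(axis=0)
        model = nipals_pca(X, 2)
        for c in range(2):
            col = model.loadings[:, c]
            assert col[np.argmax(np.abs(col))] > 0

    def test_reconstruction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 15))
        m = make_matrix(X)
        model = pca_from_matrix(m, 4, tol=1e-12, max_iter=100000)
        resid = (m.X - model.reconstruct()) ** 2
        total_ss = ((m.X - m.X.mean(0)) ** 2).sum()
        expected = total_ss * (1 - model.explained_variance_pct.sum() / 100)
        assert resid.sum() == pytest.approx(expected, abs=1e-6 * total_ss)

    def test_sample_permutation_permutes_scores_only(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 10))
        X -= X.mean(axis=0)
        perm = rng.permutation(6)
        a = nipals_pca(X, 2, tol=1e-12, max_iter=100000)
        b = nipals_pca(X[perm], 2, tol=1e-12, max_iter=100000)
        np.testing.assert_allclose(b.scores, a.scores[perm], atol=1e-8)
        np.testing.assert_allclose(b.loadings, a.loadings, atol=1e-8)


class TestRestrictRange:
    def test_keeps_only_window(self):
        m = make_matrix([[1.0, 2.0, 3.0]] * 2, mzs=[550.1, 700.2, 850.3])
        r = restrict_range(m, 600.0, 800.0)
        assert list(r.variable_mzs) == [700.2]

    def test_full_range_is_identity(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(3, 4)) ** 2)
        r = restrict_range(m, 0.0, 1e6)
        np.testing.assert_array_equal(r.X, m.X)

    def test_empty_selection_is_error(self):
        m = make_matrix([[1.0]] * 2, mzs=[500.0])
        with pytest.raises(ValueError):
            restrict_range(m, 600.0, 800.0)

    def test_restriction_sharpens_group_separation(self, scenario_run):
        """With dominant shared channels in 800-900 and diagnostics in
        600-800, PCA on the reduced window separates the isomers more
        cleanly (higher score silhouette) than full-range PCA."""
        from sklearn.metrics import silhouette_score

        series, _ = scenario_run
        spectra = [
            tic_normalize(s)
            for ser in series
            for s in ser.spectra
            if s.meta.voltage == 36.0
        ]
        full = align_to_matrix(spectra, tol=0.02)
        labels = [m.peptide_id for m in full.metas]
        sil = {}
        for name, mat in [("full", full), ("reduced", restrict_range(full, 600.0, 800.0))]:
            model = pca_from_matrix(mat, 2)
            sil[name] = silhouette_score(model.scores, labels)
        assert sil["reduced"] > sil["full"]


class TestRankDiagnostics:
    def test_collinear_variables_have_unit_cosine(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=6)
        X = np.column_stack([base, 3.0 * base, rng.normal(size=6)])
        m = make_matrix(X, labels=["a", "a", "a", "b", "b", "b"])
        model = pca_from_matrix(m, 2)
        rep = rank_diagnostics(model, ["a", "a", "a", "b", "b", "b"])
        assert rep.correlation.iloc[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_planted_channels_top_ranked(self, scenario_run):
        series, truth = scenario_run
        spectra = [
            tic_normalize(s)
            for ser in series
            for s in ser.spectra
            if s.meta.voltage == 36.0
        ]
        m = restrict_range(align_to_matrix(spectra, tol=0.02), 600.0, 800.0)
        model = pca_from_matrix(m, 2)
        labels = [mm.peptide_id for mm in m.metas]
        rep = rank_diagnostics(model, labels)
        for pid in truth.group_specific:
            planted = truth.diagnostics_at(pid, 36.0)["mz"].to_numpy()
            top = rep.top(pid, len(planted))["mz"].to_numpy()
            for mz in planted:
                assert np.any(np.abs(top - mz) < 0.05), (pid, mz)

    def test_specificity_bounded(self, scenario_run):
        series, _ = scenario_run
        spectra = [
            tic_normalize(s)
            for ser in series
            for s in ser.spectra
            if s.meta.voltage == 36.0
        ]
        m = align_to_matrix(spectra, tol=0.02)
        model = pca_from_matrix(m, 2)
        rep = rank_diagnostics(model, [mm.peptide_id for mm in m.metas])
        for t in rep.tables.values():
            assert t["specificity"].between(-1 - 1e-9, 1 + 1e-9).all()

    def test_single_group_is_error(self):
        X = np.random.default_rng(0).normal(size=(4, 5))
        m = make_matrix(X)
        model = pca_from_matrix(m, 2)
        with pytest.raises(ValueError, match="2 groups"):
            rank_diagnostics(model, ["a"] * 4)
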