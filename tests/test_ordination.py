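"""Correlation PCA and confidence ellipses against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tauscreen import correlation_pca, ellipse_membership, family_ellipse
from tauscreen.io import ValidationError
from tauscreen.ordination import ellipse_radius2, membership_table


def svd_oracle(matrix: pd.DataFrame):
    """Independent route: SVD of the column-standardized data."""
    X = matrix.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    return Z, eigvals, Vt.T, U * s


class TestCorrelationPca:
    def test_matches_svd_oracle_up_to_sign(self, random_matrix):
        result = correlation_pca(random_matrix)
        _, eigvals, loadings, scores = svd_oracle(random_matrix)
        assert np.allclose(result.eigenvalues[: len(eigvals)], eigvals, atol=1e-8)
        for j in range(loadings.shape[1]):
            ours = result.loadings.iloc[:, j].to_numpy()
            ref = loadings[:, j]
            sign = np.sign(ours @ ref)
            assert np.allclose(ours, sign * ref, atol=1e-8)
            assert np.allclose(
                result.scores.iloc[:, j].to_numpy(), sign * scores[:, j], atol=1e-8
            )

    def test_matches_sklearn_oracle(self, random_matrix):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        X = random_matrix.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = sklearn_pca(n_components=5).fit(Z)
        result = correlation_pca(random_matrix)
        assert np.allclose(result.eigenvalues, ref.explained_variance_, atol=1e-8)

    def test_variance_fractions_sum_to_one(self, random_matrix):
        result = correlation_pca(random_matrix)
        assert result.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(result.eigenvalues) <= 1e-10).all()
        assert (result.eigenvalues >= -1e-10).all()

    def test_loadings_orthonormal(self, random_matrix):
        L = correlation_pca(random_matrix).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_scores_reconstruct_standardized_data(self, random_matrix):
        result = correlation_pca(random_matrix)
        Z, *_ = svd_oracle(random_matrix)
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
        assert np.allclose(recon, Z, atol=1e-8)

    def test_two_perfectly_correlated_tissues_give_rank_one(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(2, 1, size=30)
        m = pd.DataFrame({"A": a, "B": 3.0 * a})  # identical standardized profiles
        result = correlation_pca(m)
        assert result.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert result.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_invariant_to_positive_column_rescaling(self, random_matrix):
        scaled = random_matrix * np.array([0.01, 1.0, 17.0, 250.0, 3.5])
        r1 = correlation_pca(random_matrix)
        r2 = correlation_pca(scaled)
        assert np.allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-10)
        assert np.allclose(np.abs(r1.scores), np.abs(r2.scores), atol=1e-8)

    def test_zero_variance_tissue_error_names_tissue(self, random_matrix):
        bad = random_matrix.copy()
        bad["tissue2"] = 4.0
        with pytest.raises(ValidationError, match="tissue2"):
            correlation_pca(bad)

    def test_too_few_transcripts_rejected(self, random_matrix):
        with pytest.raises(ValidationError, match=">= 3 transcripts"):
            correlation_pca(random_matrix.iloc[:2])


class TestEllipse:
    def test_chi_square_radius_closed_form(self):
        assert ellipse_radius2(0.70) == pytest.approx(-2.0 * np.log(0.30), rel=1e-12)
        assert ellipse_radius2(0.70) == pytest.approx(2.4079, abs=5e-5)

    def test_hotelling_radius_formula(self):
        m = 20
        expected = 2 * (m - 1) / (m - 2) * stats.f.ppf(0.70, 2, m - 2)
        assert ellipse_radius2(0.70, n_members=m, mode="hotelling") == pytest.approx(expected)
        assert ellipse_radius2(0.70, n_members=m, mode="hotelling") > ellipse_radius2(0.70)

    def _scores(self, rng, n=40):
        pts = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.6], [0.6, 1.0]], size=n)
        return pd.DataFrame(pts, columns=["PC1", "PC2"],
                            index=[f"t{i}" for i in range(n)])

    def test_center_is_inside_with_zero_distance(self, rng):
        scores = self._scores(rng)
        model = family_ellipse(scores, scores.index, (1, 2), 0.70, family="F")
        inside, d2 = ellipse_membership(model, model.center)
        assert inside[0] and d2[0] == pytest.approx(0.0, abs=1e-12)

    def test_boundary_point_counts_as_inside(self, rng):
        scores = self._scores(rng)
        model = family_ellipse(scores, scores.index, (1, 2), 0.70, family="F")
        # walk along an eigenvector to exactly r2
        w, v = np.linalg.eigh(model.covariance)
        point = model.center + v[:, 1] * np.sqrt(w[1] * model.r2)
        inside, d2 = ellipse_membership(model, point)
        assert d2[0] == pytest.approx(model.r2, rel=1e-9)
        assert inside[0]

    def test_monte_carlo_coverage_at_70_percent(self):
        rng = np.random.default_rng(2024)
        center = np.array([0.5, -1.0])
        cov = np.array([[1.5, -0.4], [-0.4, 0.8]])
        fit = rng.multivariate_normal(center, cov, size=4000)
        scores = pd.DataFrame(fit, columns=["PC1", "PC2"],
                              index=[f"t{i}" for i in range(len(fit))])
        model = family_ellipse(scores, scores.index, (1, 2), 0.70, family="F")
        fresh = rng.multivariate_normal(center, cov, size=10_000)
        inside, _ = ellipse_membership(model, fresh)
        assert 0.68 <= inside.mean() <= 0.72

    def test_membership_affine_equivariant(self, rng):
        scores = self._scores(rng)
        A = np.array([[2.0, 0.7], [-0.3, 1.4]])
        b = np.array([5.0, -3.0])
        mapped = pd.DataFrame(scores.to_numpy() @ A.T + b, columns=scores.columns,
                              index=scores.index)
        m1 = family_ellipse(scores, scores.index, (1, 2), 0.70, family="F")
        m2 = family_ellipse(mapped, mapped.index, (1, 2), 0.70, family="F")
        queries = rng.normal(size=(50, 2)) * 3
        in1, _ = ellipse_membership(m1, queries)
        in2, _ = ellipse_membership(m2, queries @ A.T + b)
        assert (in1 == in2).all()

    def test_collinear_members_rejected(self):
        pts = np.array([[i, 2.0 * i] for i in range(10)], dtype=float)
        scores = pd.DataFrame(pts, columns=["PC1", "PC2"],
                              index=[f"t{i}" for i in range(10)])
        with pytest.raises(ValidationError, match="singular"):
            family_ellipse(scores, scores.index, (1, 2), 0.70, family="F")

    def test_fewer_than_three_members_rejected(self, rng):
        scores = self._scores(rng, n=2)
        with pytest.raises(ValidationError, match=">= 3 members"):
            family_ellipse(scores, scores.index, (1, 2), 0.70, family="F")


class TestMembershipTable:
    def test_one_ellipse_per_family_per_pair(self, paper_shaped_fixture):
        expression, annotation, _ = paper_shaped_fixture
        from tauscreen import filter_by_median

        kept, _ = filter_by_median(expression, 2.0)
        pca = correlation_pca(kept)
        table = membership_table(pca, annotation.loc[kept.index, "family"])
        assert set(table["pc_pair"]) == {"PC1/PC2", "PC2/PC3"}
        assert len(table) == 2 * len(kept)
        # roughly the configured share of each family sits inside its ellipse
        assert 0.5 < table["inside"].mean() < 0.95
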