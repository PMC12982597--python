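"""Spatial-association tests: alignment, PCA, WLS, bootstrap null, filter."""

import numpy as np
import pandas as pd
import pytest

from centrex import association
from centrex.association import (
    AlignedGeneData,
    chance_likelihood,
    donor_autocorrelation,
    filter_genes,
    gene_association,
    pca_regressors,
    weighted_regression,
)


def make_aligned(X, y, w=None, gene="G"):
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.ones(len(y)) if w is None else np.asarray(w, float)
    return AlignedGeneData(gene_symbol=gene, X=X, y=y, w=w,
                           donor_ids=[f"d{i}" for i in range(X.shape[1])])


class TestPCA:
    def test_identical_columns_one_component(self, rng):
        col = rng.normal(size=20)
        X = np.tile(col[:, None], (1, 6))
        scores, k, ratio = pca_regressors(X)
        assert k == 1
        assert ratio[0] == pytest.approx(1.0)

    def test_orthogonal_equal_variance_needs_both(self):
        # two orthogonal, equal-variance columns: one PC explains 50% < 95%
        X = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        _, k, ratio = pca_regressors(X)
        assert k == 2
        assert ratio[0] == pytest.approx(0.5)

    def test_matches_eigendecomposition(self, rng):
        X = rng.normal(size=(30, 6))
        scores, k, ratio = pca_regressors(X)
        Xc = X - X.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        evals = evals[::-1]
        np.testing.assert_allclose(ratio, evals / evals.sum(), atol=1e-12)
        # scores reproduce projections onto leading eigenvectors up to sign
        proj = Xc @ evecs[:, ::-1][:, :k]
        for j in range(k):
            assert (np.allclose(scores[:, j], proj[:, j], atol=1e-8)
                    or np.allclose(scores[:, j], -proj[:, j], atol=1e-8))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pca_regressors(np.ones((10, 3)))


class TestWeightedRegression:
    def test_perfect_fit(self, rng):
        X = rng.normal(size=(25, 6))
        scores, _, _ = pca_regressors(X)
        y = 2.0 * scores[:, 0] - 1.0
        r2, r2_adj = weighted_regression(y, scores, np.ones(25))
        assert r2 == pytest.approx(1.0)
        assert r2_adj == pytest.approx(1.0)

    def test_uniform_weights_equal_ols(self, rng):
        n = 30
        S = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        r2_w, adj_w = weighted_regression(y, S, np.full(n, 3.7))
        # closed-form OLS R^2
        A = np.hstack([np.ones((n, 1)), S])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        r2_ols = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r2_w == pytest.approx(r2_ols, abs=1e-10)
        assert adj_w == pytest.approx(1 - (1 - r2_ols) * (n - 1) / (n - 3 - 1), abs=1e-10)

    def test_matches_statsmodels_wls(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 40
        S = rng.normal(size=(n, 2))
        y = 0.5 * S[:, 0] + rng.normal(size=n)
        w = rng.uniform(0.5, 4.0, size=n)
        r2, _ = weighted_regression(y, S, w)
        fit = sm.WLS(y, sm.add_constant(S), weights=w).fit()
        assert r2 == pytest.approx(fit.rsquared, abs=1e-10)

    def test_null_adjusted_r2_nonpositive_on_average(self, rng):
        vals = []
        for _ in range(200):
            S = rng.normal(size=(20, 3))
            y = rng.normal(size=20)
            _, adj = weighted_regression(y, S, np.ones(20))
            vals.append(adj)
        assert np.mean(vals) < 0.05

    def test_underdetermined_flagged(self, rng):
        S = rng.normal(size=(4, 3))
        with pytest.raises(ValueError, match="undefined"):
            weighted_regression(rng.normal(size=4), S, np.ones(4))


class TestChanceLikelihood:
    def test_perfect_fit_gives_zero(self, rng):
        X = rng.normal(size=(30, 6))
        scores, _, _ = pca_regressors(X)
        aligned = make_aligned(X, scores[:, 0])
        assert chance_likelihood(aligned, n_boot=500, rng=3) == 0.0

    def test_counting_rule(self, rng):
        """chance likelihood = (# null R^2 > observed) / n_boot, strict >."""
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        aligned = make_aligned(X, y)
        scores, _, _ = pca_regressors(X)
        r2_obs, _ = weighted_regression(y, scores, aligned.w)
        cl = chance_likelihood(aligned, n_boot=400, rng=11, r2_observed=r2_obs)
        # recompute with the same stream through the private batched path
        from centrex.association import _batched_null_r2

        null = _batched_null_r2(X - X.mean(0), y, aligned.w, 400,
                                np.random.default_rng(11), 0.95)
        assert cl == (null > r2_obs).sum() / 400

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(25, 5))
        aligned = make_aligned(X, rng.normal(size=25))
        a = chance_likelihood(aligned, n_boot=300, rng=42)
        b = chance_likelihood(aligned, n_boot=300, rng=42)
        assert a == b

    def test_scale_invariance(self, rng):
        X = rng.normal(size=(30, 5))
        y = X.mean(1) + 0.3 * rng.normal(size=30)
        w = rng.uniform(1, 5, size=30)
        r1 = gene_association(make_aligned(X, y, w), n_boot=200, rng=5)
        r2 = gene_association(make_aligned(X, 4.2 * y, w), n_boot=200, rng=5)
        assert r1.r2_adjusted == pytest.approx(r2.r2_adjusted, abs=1e-10)
        assert r1.chance_likelihood == r2.chance_likelihood
        assert r1.direction == r2.direction


class TestDonorAutocorrelation:
    def test_identical_columns(self, rng):
        col = rng.normal(size=15)
        assert donor_autocorrelation(np.tile(col[:, None], (1, 4))) == pytest.approx(1.0)

    def test_negated_pair(self, rng):
        col = rng.normal(size=15)
        X = np.column_stack([col, -col])
        assert donor_autocorrelation(X) == pytest.approx(-1.0)

    def test_matches_pairwise_oracle(self, rng):
        X = rng.normal(size=(20, 6))
        expected = np.mean([
            np.corrcoef(X[:, i], X[:, j])[0, 1]
            for i in range(6) for j in range(i + 1, 6)
        ])
        assert donor_autocorrelation(X) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_skipped(self, rng):
        X = np.column_stack([rng.normal(size=10), np.ones(10), rng.normal(size=10)])
        vals = donor_autocorrelation(X)
        expected = np.corrcoef(X[:, 0], X[:, 2])[0, 1]
        assert vals == pytest.approx(expected)


class TestFilter:
    def _df(self, cl, ac, r2):
        return pd.DataFrame(
            [{"gene": "G", "r2_adjusted": r2, "direction": 1,
              "chance_likelihood": cl, "autocorrelation": ac,
              "n_components": 1, "passes_filter": False}]
        )

    def test_boundary_pass(self):
        assert filter_genes(self._df(0.0009, 0.2, 0.15)) == ["G"]

    def test_chance_likelihood_strict(self):
        assert filter_genes(self._df(0.001, 0.9, 0.9)) == []

    def test_empty(self):
        assert filter_genes(pd.DataFrame(columns=association.RESULT_COLUMNS)) == []


class TestAlignUnits:
    def _setup(self, rng, shared=True, n=8):
        """Two donors on a 6^3 grid; full finite map so nothing is dropped."""
        from centrex import ahba
        from conftest import make_tmap

        t = rng.normal(size=(6, 6, 6)) + 5.0
        cm = make_tmap(t, voxel_size=2.0)
        coords = rng.uniform(-5, 5, size=(n, 3))
        bundles, images = [], {}
        for d in ("d1", "d2"):
            c = coords if shared else rng.uniform(-5, 5, size=(n, 3))
            sample_ids = [f"{d}_s{i}" for i in range(n)]
            expr = pd.DataFrame(rng.normal(size=(3, n)),
                                index=["G0", "G1", "G2"], columns=sample_ids)
            b = ahba.DonorExpressionBundle(
                donor_id=d, expression=expr,
                probe_to_gene=pd.Series({}, dtype=object),
                sample_coords=pd.DataFrame(c, index=sample_ids, columns=["x", "y", "z"]),
                gene_level=True,
            )
            b = ahba.normalize_donor(b)
            bundles.append(b)
            images[d] = ahba.sample_image_at_coords(cm, b.sample_coords, 5.0)
        return cm, bundles, images

    def test_per_sample_mode_reproduces_sample_matrix(self, rng):
        cm, bundles, images = self._setup(rng, shared=True)
        units = association.align_units(bundles, images, cm, mode="per_sample")
        d = units.gene_data("G0")
        assert d.X.shape == (8, 2)
        np.testing.assert_allclose(
            np.sort(d.X[:, 0]), np.sort(bundles[0].expression.loc["G0"].to_numpy())
        )

    def test_parcel_mean_is_sample_mean(self, rng):
        from centrex.grids import mm_to_voxel

        cm, bundles, images = self._setup(rng, shared=False, n=20)
        units = association.align_units(bundles, images, cm, parcel_edge_voxels=3)
        b = bundles[0]
        vox = np.rint(mm_to_voxel(b.sample_coords.to_numpy(), cm.affine)).astype(int)
        keys = np.array(["_".join(map(str, t)) for t in np.floor(vox / 3).astype(int)])
        unit = units.donor_expr["d1"].columns[units.donor_expr["d1"].loc["G1"].notna()][0]
        members = b.expression.columns[keys == unit]
        np.testing.assert_allclose(
            units.donor_expr["d1"].loc["G1", unit],
            b.expression.loc["G1", members].mean(),
            atol=1e-12,
        )
        # weight of a unit = total contributing samples over all donors
        w_expected = units.provenance.loc[units.provenance.unit == unit, "n_samples"].sum()
        assert units.w.loc[unit] == w_expected

    def test_matches_groupby_oracle(self, rng):
        from centrex.grids import mm_to_voxel

        cm, bundles, images = self._setup(rng, shared=False, n=20)
        units = association.align_units(bundles, images, cm, parcel_edge_voxels=2)
        b = bundles[0]
        vox = np.rint(mm_to_voxel(b.sample_coords.to_numpy(), cm.affine)).astype(int)
        keys = ["_".join(map(str, t)) for t in np.floor(vox / 2).astype(int)]
        expected = (
            pd.Series(b.expression.loc["G2"].to_numpy(), index=keys)
            .groupby(level=0).mean()
        )
        got = units.donor_expr["d1"].loc["G2"].dropna()
        pd.testing.assert_series_equal(
            got.sort_index(), expected.sort_index(),
            check_names=False, atol=1e-12, rtol=0,
        )
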