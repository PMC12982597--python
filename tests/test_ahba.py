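"""Donor-bundle preparation tests: probe selection, normalization, window sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from centrex import ahba
from conftest import make_tmap


def bundle_from(donor_id, expr: dict, coords: dict, probe_to_gene: dict):
    samples = list(coords)
    return ahba.DonorExpressionBundle(
        donor_id=donor_id,
        expression=pd.DataFrame(expr, index=samples).T,
        probe_to_gene=pd.Series(probe_to_gene),
        sample_coords=pd.DataFrame(
            [coords[s] for s in samples], index=samples, columns=["x", "y", "z"]
        ),
    )


@pytest.fixture
def two_probe_bundles():
    base = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    coords = {f"s{i}": (-5.0 - i, 0.0, 0.0) for i in range(5)}
    expr = {"pA": base, "pB": np.exp(base)}
    return [bundle_from("d1", expr, coords, {"pA": "G1", "pB": "G1"})]


class TestProbeSelection:
    def test_single_probe_gene(self):
        b = bundle_from("d1", {"p1": np.arange(4.0)},
                        {f"s{i}": (-1.0, 0, 0) for i in range(4)}, {"p1": "G"})
        assert ahba.select_representative_probe([b], "G") == "p1"

    def test_least_skewed_probe_wins(self, two_probe_bundles):
        # pA symmetric (skew 0), pB = exp(pA) positively skewed
        assert stats.skew(np.exp([-2, -1, 0, 1, 2.0]), bias=False) > 0.5
        assert ahba.select_representative_probe(two_probe_bundles, "G1") == "pA"

    def test_tie_broken_by_probe_id(self):
        vals = np.array([0.0, 1.0, 2.0, 3.0])
        coords = {f"s{i}": (-1.0, 0, 0) for i in range(4)}
        b = bundle_from("d1", {"pz": vals, "pa": vals.copy()}, coords,
                        {"pz": "G", "pa": "G"})
        assert ahba.select_representative_probe([b], "G") == "pa"

    def test_missing_gene_raises(self, two_probe_bundles):
        with pytest.raises(KeyError):
            ahba.select_representative_probe(two_probe_bundles, "NOPE")

    def test_invariant_to_donor_and_sample_permutation(self, rng):
        coords_a = {f"s{i}": (-1.0 - i, 0, 0) for i in range(6)}
        e1 = {"p1": rng.normal(size=6), "p2": rng.exponential(size=6)}
        e2 = {"p1": rng.normal(size=6), "p2": rng.exponential(size=6)}
        b1 = bundle_from("d1", e1, coords_a, {"p1": "G", "p2": "G"})
        b2 = bundle_from("d2", e2, coords_a, {"p1": "G", "p2": "G"})
        pick = ahba.select_representative_probe([b1, b2], "G")
        assert ahba.select_representative_probe([b2, b1], "G") == pick
        perm = rng.permutation(6)
        b1p = bundle_from("d1", {k: v[perm] for k, v in e1.items()}, coords_a,
                          {"p1": "G", "p2": "G"})
        assert ahba.select_representative_probe([b1p, b2], "G") == pick


class TestNormalize:
    def _gene_bundle(self, rows: dict, n=None):
        n = n or len(next(iter(rows.values())))
        coords = {f"s{i}": (-1.0, float(i), 0) for i in range(n)}
        b = bundle_from("d1", rows, coords, {k: k for k in rows})
        b.gene_level = True
        return b

    def test_z_of_123(self):
        out = ahba.normalize_donor(self._gene_bundle({"G": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out.expression.loc["G"].to_numpy(), [-1, 0, 1])
        assert out.normalized

    def test_constant_gene_flagged_missing(self):
        out = ahba.normalize_donor(self._gene_bundle({"G": [2.0, 2.0, 2.0]}))
        assert out.expression.loc["G"].isna().all()

    def test_mean_zero_sd_one(self, rng):
        rows = {f"G{i}": rng.normal(3, 2, size=10) for i in range(5)}
        out = ahba.normalize_donor(self._gene_bundle(rows))
        z = out.expression.to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            ahba.normalize_donor(self._gene_bundle({"G": [1.0]}))


class TestRestrictHemisphere:
    def test_all_left_retained(self):
        b = bundle_from("d", {"p": np.arange(3.0)},
                        {f"s{i}": (-10.0, 0, 0) for i in range(3)}, {"p": "G"})
        assert ahba.restrict_left_hemisphere(b).n_samples == 3

    def test_midline_excluded(self):
        b = bundle_from("d", {"p": np.arange(3.0)},
                        {"s0": (-1.0, 0, 0), "s1": (0.0, 0, 0), "s2": (1.0, 0, 0)},
                        {"p": "G"})
        out = ahba.restrict_left_hemisphere(b)
        assert list(out.expression.columns) == ["s0"]

    def test_matches_bruteforce_filter(self, rng):
        xs = rng.uniform(-10, 10, size=20)
        coords = {f"s{i}": (float(x), 0.0, 0.0) for i, x in enumerate(xs)}
        b = bundle_from("d", {"p": rng.normal(size=20)}, coords, {"p": "G"})
        out = ahba.restrict_left_hemisphere(b)
        expected = [s for s, c in coords.items() if c[0] < 0]
        assert list(out.expression.columns) == expected

    def test_empty_retention_errors(self):
        b = bundle_from("d", {"p": np.arange(2.0)},
                        {"s0": (1.0, 0, 0), "s1": (2.0, 0, 0)}, {"p": "G"})
        with pytest.raises(ValueError, match="left"):
            ahba.restrict_left_hemisphere(b)


class TestSampleImage:
    def test_single_voxel_window_identity(self, rng):
        t = rng.normal(size=(5, 5, 5))
        cm = make_tmap(t, voxel_size=2.0)
        # window edge 2 mm around an exact voxel centre -> that voxel only
        coords = pd.DataFrame([[-4.0, -4.0, -4.0], [0.0, 0.0, 0.0]],
                              index=["a", "b"], columns=["x", "y", "z"])
        out = ahba.sample_image_at_coords(cm, coords, window_mm=2.0)
        assert out.loc["a", "raw"] == pytest.approx(t[0, 0, 0])
        assert out.loc["b", "raw"] == pytest.approx(t[2, 2, 2])
        assert out["n_voxels_in_window"].tolist() == [1, 1]

    def test_matches_bruteforce_window_oracle(self, rng):
        t = rng.normal(size=(6, 6, 6))
        t[rng.random((6, 6, 6)) < 0.3] = np.nan  # sub-threshold voxels missing
        cm = make_tmap(t, voxel_size=2.0)
        coords = pd.DataFrame(rng.uniform(-5, 5, size=(15, 3)),
                              index=[f"s{i}" for i in range(15)],
                              columns=["x", "y", "z"])
        out = ahba.sample_image_at_coords(cm, coords, window_mm=5.0)
        aff = cm.affine
        for s in coords.index:
            p = coords.loc[s].to_numpy()
            vals = []
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        center = aff[:3, :3] @ [i, j, k] + aff[:3, 3]
                        if np.all(np.abs(center - p) <= 2.5) and np.isfinite(t[i, j, k]):
                            vals.append(t[i, j, k])
            if vals:
                assert out.loc[s, "raw"] == pytest.approx(np.mean(vals))
                assert out.loc[s, "n_voxels_in_window"] == len(vals)
            else:
                assert not out.loc[s, "retained"]

    def test_translation_equivariance(self, rng):
        t = rng.normal(size=(5, 5, 5))
        cm1 = make_tmap(t, voxel_size=2.0)
        cm2 = make_tmap(t, voxel_size=2.0)
        cm2.affine = cm2.affine.copy()
        cm2.affine[:3, 3] += np.array([3.0, -7.0, 1.0])
        coords = pd.DataFrame(rng.uniform(-4, 4, size=(10, 3)),
                              index=[f"s{i}" for i in range(10)],
                              columns=["x", "y", "z"])
        shifted = coords + np.array([3.0, -7.0, 1.0])
        out1 = ahba.sample_image_at_coords(cm1, coords, 5.0)
        out2 = ahba.sample_image_at_coords(cm2, shifted, 5.0)
        np.testing.assert_allclose(out1["raw"], out2["raw"], atol=1e-12)

    def test_constant_map_degenerate(self):
        cm = make_tmap(np.full((4, 4, 4), 2.0))
        coords = pd.DataFrame([[-2.0, 0, 0], [2.0, 0, 0]], index=["a", "b"],
                              columns=["x", "y", "z"])
        with pytest.raises(ValueError, match="constant"):
            ahba.sample_image_at_coords(cm, coords, 5.0)

    def test_all_empty_windows_error(self):
        t = np.full((4, 4, 4), np.nan)
        cm = make_tmap(t)
        coords = pd.DataFrame([[0.0, 0, 0]], index=["a"], columns=["x", "y", "z"])
        with pytest.raises(ValueError, match="outside"):
            ahba.sample_image_at_coords(cm, coords, 5.0)


def test_pipeline_order_restrict_then_normalize(rng):
    """z-scores are computed on the retained (left) samples only."""
    n = 8
    xs = np.array([-3.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 3.0])
    coords = {f"s{i}": (float(xs[i]), 0, 0) for i in range(n)}
    vals = rng.normal(size=n)
    b = bundle_from("d", {"G": vals}, coords, {"G": "G"})
    b.gene_level = True
    out = ahba.normalize_donor(ahba.restrict_left_hemisphere(b))
    left = vals[:4]
    expected = (left - left.mean()) / left.std(ddof=1)
    np.testing.assert_allclose(out.expression.loc["G"].to_numpy(), expected)
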