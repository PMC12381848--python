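"""Grid occupancy, relative fraction, density overlap, entropy and KDE."""

import numpy as np
import pytest

from confscape.landscape import (
    bin_projection,
    density_overlap,
    entropy_across_replicates,
    exclusive_coverage,
    exclusive_regions,
    kde_density,
    overlap_table,
    overlap_uncertainty,
    projection_entropy,
    relative_fraction_map,
)
from confscape.projection import Projection


def make_projection(points_per_label: dict[str, np.ndarray]) -> Projection:
    coords = np.concatenate(list(points_per_label.values()))
    labels = np.concatenate(
        [np.repeat(lab, len(pts)) for lab, pts in points_per_label.items()]
    )
    return Projection(coords=coords, labels=labels)


def grid_centers(n: int) -> np.ndarray:
    """n*n points, one at the center of each bin of an n-by-n grid over [0,1]^2."""
    c = (np.arange(n) + 0.5) / n
    gx, gy = np.meshgrid(c, c)
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    # corner anchors so the bounding box is exactly [0,1]^2
    return np.concatenate([[[0.0, 0.0]], pts[1:-1], [[1.0, 1.0]]])


class TestBinning:
    def test_one_point_per_bin_gives_unit_counts(self):
        proj = make_projection({"m": grid_centers(27)})
        occ = bin_projection(proj, (27, 27), min_count=1)
        assert (occ.totals == 1).all()
        F = relative_fraction_map(occ, "m")
        assert np.all(F == 1.0)

    def test_counts_match_per_point_loop_oracle(self, rng):
        pts = rng.uniform(size=(500, 2))
        proj = make_projection({"a": pts[:250], "b": pts[250:]})
        occ = bin_projection(proj, (9, 9), min_count=1)
        # brute-force binning oracle
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        expect = {k: np.zeros((9, 9), int) for k in ("a", "b")}
        for i, (x, y) in enumerate(pts):
            ix = min(int((x - lo[0]) / (hi[0] - lo[0]) * 9), 8)
            iy = min(int((y - lo[1]) / (hi[1] - lo[1]) * 9), 8)
            expect["a" if i < 250 else "b"][ix, iy] += 1
        for k in expect:
            assert np.array_equal(occ.counts[k], expect[k])

    def test_degenerate_cloud_rejected(self):
        proj = make_projection({"m": np.tile([[0.3, 0.4]], (10, 1))})
        with pytest.raises(ValueError, match="degenerate"):
            bin_projection(proj)

    def test_min_count_masks_sparse_bins(self, rng):
        pts = np.concatenate([np.tile([[0.1, 0.1]], (5, 1)), [[0.9, 0.9]]])
        occ = bin_projection(make_projection({"m": pts}), (4, 4), min_count=3)
        assert occ.valid.sum() == 1  # only the 5-point bin survives


class TestRelativeFraction:
    def test_simple_proportions(self):
        pts_a = np.tile([[0.1, 0.1]], (3, 1))
        pts_b = np.concatenate([np.tile([[0.1, 0.1]], (1, 1)), np.tile([[0.9, 0.9]], (3, 1))])
        occ = bin_projection(make_projection({"A": pts_a, "B": pts_b}), (3, 3), min_count=1)
        FA = relative_fraction_map(occ, "A")
        FB = relative_fraction_map(occ, "B")
        assert FA[0, 0] == pytest.approx(0.75) and FB[0, 0] == pytest.approx(0.25)

    def test_sole_model_has_unit_fraction_everywhere(self, rng):
        occ = bin_projection(make_projection({"m": rng.uniform(size=(300, 2))}), (5, 5), 1)
        F = relative_fraction_map(occ, "m")
        assert np.all(F[~np.isnan(F)] == 1.0)

    def test_balanced_mixture_is_half_everywhere(self, rng):
        pts = rng.uniform(size=(400, 2))
        occ = bin_projection(make_projection({"a": pts, "b": pts}), (5, 5), 1)
        F = relative_fraction_map(occ, "a")
        assert np.allclose(F[~np.isnan(F)], 0.5)

    def test_fractions_sum_to_one_per_bin(self, rng):
        proj = make_projection(
            {k: rng.uniform(size=(200, 2)) for k in ("a", "b", "c")}
        )
        occ = bin_projection(proj, (6, 6), min_count=1)
        total = sum(
            np.nan_to_num(relative_fraction_map(occ, k), nan=0.0) for k in ("a", "b", "c")
        )
        occupied = occ.valid & (occ.totals > 0)
        assert np.allclose(total[occupied], 1.0)

    def test_unknown_label_rejected(self, rng):
        occ = bin_projection(make_projection({"m": rng.uniform(size=(50, 2))}), (3, 3), 1)
        with pytest.raises(KeyError):
            relative_fraction_map(occ, "nope")


class TestDensityOverlap:
    def test_self_overlap_is_exactly_one(self, rng):
        occ = bin_projection(
            make_projection({"a": rng.uniform(size=(100, 2)), "b": rng.uniform(size=(100, 2))}),
            (5, 5), 1,
        )
        assert density_overlap(occ, "a", "a") == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_give_zero(self):
        a = np.tile([[0.05, 0.05]], (10, 1))
        b = np.tile([[0.95, 0.95]], (10, 1))
        occ = bin_projection(make_projection({"a": a, "b": b}), (4, 4), 1)
        assert density_overlap(occ, "a", "b") == 0.0

    def test_three_model_table_matches_hand_coded_sum(self, rng):
        proj = make_projection({k: rng.uniform(size=(150, 2)) for k in ("a", "b", "c")})
        occ = bin_projection(proj, (5, 5), min_count=2)
        table = overlap_table(occ)
        # independent brute-force evaluation over bins
        for w, z in (("a", "b"), ("a", "c"), ("b", "c")):
            fw, fz = [], []
            for ix in range(5):
                for iy in range(5):
                    if not occ.valid[ix, iy] or occ.totals[ix, iy] == 0:
                        continue
                    fw.append(occ.counts[w][ix, iy] / occ.totals[ix, iy])
                    fz.append(occ.counts[z][ix, iy] / occ.totals[ix, iy])
            fw = np.array(fw) / np.sqrt(np.sum(np.square(fw)))
            fz = np.array(fz) / np.sqrt(np.sum(np.square(fz)))
            assert table.loc[w, z] == pytest.approx(float(fw @ fz), abs=1e-12)
        mat = table.to_numpy()
        assert np.allclose(mat, mat.T) and np.allclose(np.diag(mat), 1.0)
        assert mat.min() >= 0.0 and mat.max() <= 1.0 + 1e-12

    def test_model_without_valid_mass_is_an_error(self):
        a = np.tile([[0.05, 0.05]], (10, 1))
        lonely = np.array([[0.95, 0.95]])  # below min_count, no valid bin
        occ = bin_projection(make_projection({"a": a, "b": lonely}), (4, 4), min_count=3)
        with pytest.raises(ValueError, match="no mass"):
            density_overlap(occ, "a", "b")


class TestOverlapUncertainty:
    def test_identical_single_bin_models_have_zero_std(self):
        a = np.tile([[0.05, 0.05]], (30, 1))
        b = np.tile([[0.05, 0.05]], (30, 1))
        anchor = np.tile([[0.95, 0.95]], (30, 1))
        proj = make_projection({"a": a, "b": b, "anchor": anchor})
        point, std = overlap_uncertainty(proj, (4, 4), min_count=3, n_boot=20, seed=0)
        assert point.loc["a", "b"] == pytest.approx(1.0)
        assert std.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_mean_consistent_with_point_estimate(self, rng):
        proj = make_projection(
            {"a": rng.normal(0.4, 0.15, (300, 2)), "b": rng.normal(0.6, 0.15, (300, 2))}
        )
        point, std = overlap_uncertainty(proj, (6, 6), min_count=2, n_boot=40, seed=1)
        assert std.loc["a", "b"] > 0
        assert abs(point.loc["a", "b"] - 0.5) < 0.5  # sane scale
        # resampled mean should sit within a few std of the point estimate
        assert std.loc["a", "b"] < 0.2

    def test_minimal_two_resamples_complete(self, rng):
        proj = make_projection({"a": rng.uniform(size=(50, 2)), "b": rng.uniform(size=(50, 2))})
        point, std = overlap_uncertainty(proj, (4, 4), min_count=1, n_boot=2, seed=2)
        assert np.isfinite(std.to_numpy()).all()


class TestProjectionEntropy:
    def test_uniform_729_bins_reaches_h_max(self):
        proj = make_projection({"m": grid_centers(27)})
        occ = bin_projection(proj, (27, 27), min_count=1)
        rep = projection_entropy(occ, "m")
        assert rep["entropy"] == pytest.approx(np.log(729), abs=1e-9)
        assert rep["normalized"] == pytest.approx(1.0)

    def test_single_bin_gives_zero_entropy(self):
        pts = np.concatenate([np.tile([[0.1, 0.1]], (20, 1)), [[0.9, 0.9]]])
        occ = bin_projection(make_projection({"m": pts[:-1], "anchor": pts[-1:]}), (3, 3), 1)
        assert projection_entropy(occ, "m")["entropy"] == 0.0

    def test_two_equal_bins_give_ln2(self):
        pts = np.concatenate([np.tile([[0.1, 0.1]], (10, 1)), np.tile([[0.9, 0.9]], (10, 1))])
        occ = bin_projection(make_projection({"m": pts}), (3, 3), 1)
        assert projection_entropy(occ, "m")["entropy"] == pytest.approx(np.log(2), abs=1e-12)

    def test_merging_bins_never_increases_entropy(self, rng):
        pts = rng.uniform(size=(800, 2)) ** 2  # non-uniform cloud
        proj = make_projection({"m": pts})
        h27 = projection_entropy(bin_projection(proj, (27, 27), 1), "m")["entropy"]
        h9 = projection_entropy(bin_projection(proj, (9, 9), 1), "m")["entropy"]
        h3 = projection_entropy(bin_projection(proj, (3, 3), 1), "m")["entropy"]
        assert h3 <= h9 <= h27

    def test_empty_model_rejected(self, rng):
        occ = bin_projection(make_projection({"m": rng.uniform(size=(20, 2))}), (3, 3), 1)
        with pytest.raises(KeyError):
            projection_entropy(occ, "ghost")


class TestEntropyAcrossReplicates:
    def test_identical_replicates_have_zero_std(self, rng):
        proj = make_projection({"a": rng.uniform(size=(100, 2)), "b": rng.uniform(size=(100, 2))})
        table = entropy_across_replicates([proj, proj, proj], (5, 5), 1)
        assert (table["std_normalized_entropy"] < 1e-14).all()

    def test_broad_vs_narrow_ordering_in_every_replicate(self, rng):
        tables = []
        for rep in range(4):
            broad = rng.uniform(size=(200, 2))
            narrow = 0.45 + 0.1 * rng.uniform(size=(200, 2))
            tables.append(make_projection({"broad": broad, "narrow": narrow}))
        table = entropy_across_replicates(tables, (8, 8), 1)
        assert (
            table.loc["broad", "mean_normalized_entropy"]
            > table.loc["narrow", "mean_normalized_entropy"]
        )

    def test_inconsistent_labels_rejected(self, rng):
        a = make_projection({"x": rng.uniform(size=(30, 2))})
        b = make_projection({"y": rng.uniform(size=(30, 2))})
        with pytest.raises(ValueError, match="labels"):
            entropy_across_replicates([a, b], (3, 3), 1)


class TestKDE:
    def test_bimodal_cloud_has_maxima_at_both_centers(self):
        r = np.random.default_rng(17)
        c1 = r.normal(0.0, 0.05, (100, 2))
        c2 = r.normal(1.0, 0.05, (100, 2))
        proj = make_projection({"m": np.concatenate([c1, c2])})
        dens = kde_density(proj)
        # each cluster's densest point lies at its own center, and the two
        # modes carry comparable density
        peak1 = proj.coords[:100][np.argmax(dens[:100])]
        peak2 = proj.coords[100:][np.argmax(dens[100:])]
        assert np.linalg.norm(peak1 - 0.0) < 0.15
        assert np.linalg.norm(peak2 - 1.0) < 0.15
        assert min(dens[:100].max(), dens[100:].max()) > 0.5 * dens.max()

    def test_densest_point_near_gaussian_centroid(self):
        r = np.random.default_rng(0)
        pts = r.normal(0.0, 1.0, (2000, 2))
        proj = make_projection({"m": pts})
        bandwidth = 0.5
        dens = kde_density(proj, bandwidth=bandwidth)
        peak = proj.coords[np.argmax(dens)]
        assert np.linalg.norm(peak - pts.mean(axis=0)) < bandwidth

    def test_density_integrates_to_one(self, rng):
        pts = rng.normal(0.0, 1.0, (400, 2))
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(pts.T)
        g = np.linspace(-6, 6, 121)
        gx, gy = np.meshgrid(g, g)
        vals = kde(np.stack([gx.ravel(), gy.ravel()]))
        integral = vals.sum() * (g[1] - g[0]) ** 2
        assert integral == pytest.approx(1.0, rel=0.02)

    def test_zero_variance_cloud_rejected(self):
        proj = Projection(coords=np.tile([[0.5, 0.5]], (10, 1)))
        with pytest.raises(ValueError):
            kde_density(proj)


class TestExclusiveRegions:
    def test_exclusive_bins_found_and_coverage_counted(self):
        a = np.tile([[0.05, 0.05]], (20, 1))
        b = np.tile([[0.95, 0.95]], (20, 1))
        proj = make_projection({"a": a, "b": b})
        occ = bin_projection(proj, (4, 4), min_count=3)
        labeled, n_comp = exclusive_regions(occ, "a")
        assert n_comp == 1
        assert exclusive_coverage(occ, proj, "a") == pytest.approx(1.0)
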