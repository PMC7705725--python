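"""SSIM, single-linkage clustering and nearest-control profiles, each
checked against an independent oracle (brute-force sliding window,
minimum-spanning-tree linkage, sort-based quantiles)."""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.sparse.csgraph import minimum_spanning_tree

from lesionscope import (
    cut_groups,
    linkage_single,
    nearest_control_profile,
    ssim_pair,
    summarize_groups,
)
from lesionscope import BrainVolume, masked_slicewise_similarity
from lesionscope.lesion_similarity import RegionMask, SimilarityResult

# ---------------------------------------------------------------------------
# brute-force SSIM oracle: explicit double loop over pixels with the same
# Gaussian kernel (radius = int(3.5 sigma + 0.5)) and reflective padding
# ---------------------------------------------------------------------------


def _gauss_kernel(sigma: float) -> np.ndarray:
    radius = int(3.5 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    w /= w.sum()
    return np.outer(w, w)


def _ssim_bruteforce(a, b, sigma, dynamic_range, k1=0.01, k2=0.03):
    kern = _gauss_kernel(sigma)
    r = kern.shape[0] // 2
    # edge-repeating reflection (a b c | c b a), matching the filter's pads
    ap = np.pad(a, r, mode="symmetric")
    bp = np.pad(b, r, mode="symmetric")
    c1, c2 = (k1 * dynamic_range) ** 2, (k2 * dynamic_range) ** 2
    out = np.empty_like(a, dtype=float)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            wa = ap[i : i + 2 * r + 1, j : j + 2 * r + 1]
            wb = bp[i : i + 2 * r + 1, j : j + 2 * r + 1]
            mu_a = (kern * wa).sum()
            mu_b = (kern * wb).sum()
            va = (kern * wa * wa).sum() - mu_a**2
            vb = (kern * wb * wb).sum() - mu_b**2
            cov = (kern * wa * wb).sum() - mu_a * mu_b
            out[i, j] = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
                (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
            )
    return out.mean(), out


class TestSsimPair:
    def test_identity_gives_exactly_one(self, rng):
        img = rng.random((24, 20))
        mean, smap = ssim_pair(img, img, window_sigma=2.0, dynamic_range=1.0)
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(smap, 1.0, atol=1e-12)

    @pytest.mark.parametrize("a,b", [(0.3, 0.7), (1.0, 1.0), (0.0, 0.5)])
    def test_constant_images_match_closed_form(self, a, b):
        """Variance terms cancel; every pixel hits the luminance formula."""
        img_a = np.full((16, 16), a)
        img_b = np.full((16, 16), b)
        L = 1.0
        c1 = (0.01 * L) ** 2
        expected = (2 * a * b + c1) / (a * a + b * b + c1)
        mean, smap = ssim_pair(img_a, img_b, window_sigma=3.0, dynamic_range=L)
        assert np.allclose(smap, expected, atol=1e-12)
        assert mean == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        mean, smap = ssim_pair(a, b, window_sigma=2.0, dynamic_range=1.0)
        mean_o, smap_o = _ssim_bruteforce(a, b, 2.0, 1.0)
        assert np.abs(smap - smap_o).max() < 1e-10
        assert mean == pytest.approx(mean_o, abs=1e-10)

    def test_symmetry(self, rng):
        a, b = rng.random((12, 14)), rng.random((12, 14))
        m_ab, _ = ssim_pair(a, b, 2.0, 1.0)
        m_ba, _ = ssim_pair(b, a, 2.0, 1.0)
        assert m_ab == pytest.approx(m_ba, abs=1e-12)

    def test_shape_mismatch_and_bad_range_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            ssim_pair(rng.random((4, 4)), rng.random((5, 4)), 2.0, 1.0)
        with pytest.raises(ValueError, match="dynamic_range"):
            ssim_pair(rng.random((4, 4)), rng.random((4, 4)), 2.0, 0.0)


# ---------------------------------------------------------------------------
# masked slice-wise similarity
# ---------------------------------------------------------------------------


def _toy_mask(shape=(6, 20, 22), ap_range=(1, 4)) -> RegionMask:
    left = np.zeros(shape, dtype=bool)
    right = np.zeros(shape, dtype=bool)
    left[ap_range[0] : ap_range[1], 4:15, 2:9] = True
    right[ap_range[0] : ap_range[1], 4:15, 13:20] = True
    return RegionMask(left=left, right=right, ap_range=ap_range)


class TestMaskedSlicewiseSimilarity:
    @pytest.fixture(scope="class")
    def cohort(self):
        rng = np.random.default_rng(5)
        vols = [
            BrainVolume(voxels=rng.random((6, 20, 22)), subject_id=f"s{i}")
            for i in range(3)
        ]
        vols.append(BrainVolume(voxels=vols[0].voxels.copy(), subject_id="dup"))
        return vols

    def test_duplicate_volume_pair_scores_one(self, cohort):
        res = masked_slicewise_similarity(cohort, _toy_mask(), window_sigma=1.5)
        assert res.sbar[0, 3] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self, cohort):
        res = masked_slicewise_similarity(cohort, _toy_mask(), window_sigma=1.5)
        assert np.allclose(res.sbar, res.sbar.T, atol=1e-12)
        assert np.allclose(np.diag(res.sbar), 1.0, atol=1e-12)
        assert np.all(res.sbar <= 1.0 + 1e-12)

    def test_sbar_is_slice_mean_of_bilateral_ssim(self, cohort):
        """Explicit-loop oracle: recompute from ssim_pair on the crops."""
        mask = _toy_mask()
        res = masked_slicewise_similarity(
            cohort, mask, window_sigma=1.5, dynamic_range=1.0
        )
        i, j = 0, 2
        per_slice = []
        for z in range(*mask.ap_range):
            vals = []
            for s, side in enumerate((mask.left, mask.right)):
                (d0, d1), (m0, m1) = mask.bounding_boxes[z][s]
                a = cohort[i].voxels[z, d0:d1, m0:m1]
                b = cohort[j].voxels[z, d0:d1, m0:m1]
                vals.append(ssim_pair(a, b, 1.5, 1.0)[0])
            per_slice.append(0.5 * (vals[0] + vals[1]))
        assert np.allclose(res.per_slice[:, i, j], per_slice, atol=1e-12)
        assert res.sbar[i, j] == pytest.approx(np.mean(per_slice), abs=1e-12)

    def test_mean_over_subrange(self, cohort):
        mask = _toy_mask()
        res = masked_slicewise_similarity(cohort, mask, window_sigma=1.5)
        sub = res.mean_over(2, 3)
        assert np.allclose(sub, res.per_slice[1:].mean(axis=0), atol=1e-12)

    def test_empty_slice_inside_range_rejected(self):
        left = np.zeros((6, 20, 22), dtype=bool)
        right = np.zeros((6, 20, 22), dtype=bool)
        left[1:4, 4:15, 2:9] = True
        right[1:3, 4:15, 13:20] = True  # slice 3 empty on the right
        with pytest.raises(ValueError, match="empty"):
            RegionMask(left=left, right=right, ap_range=(1, 4))


# ---------------------------------------------------------------------------
# single linkage
# ---------------------------------------------------------------------------


def _mst_single_linkage_heights(d: np.ndarray) -> np.ndarray:
    """Single-linkage merge heights = sorted MST edge weights."""
    mst = minimum_spanning_tree(d).toarray()
    return np.sort(mst[mst > 0])


class TestLinkageSingle:
    def test_worked_three_point_example(self):
        s = 1.0 - np.array(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]]
        )
        dend = linkage_single(s)
        (a0, b0, h0, n0), (a1, b1, h1, n1) = dend.merges
        assert (a0, b0, h0, n0) == (0, 1, pytest.approx(0.1), 2)
        assert (a1, b1, n1) == (2, 3, 3)
        assert h1 == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(20))
    def test_heights_match_mst_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.random((8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = linkage_single(1.0 - d)
        heights = np.array([m[2] for m in dend.merges])
        assert np.allclose(np.sort(heights), _mst_single_linkage_heights(d), atol=1e-12)
        assert np.all(np.diff(heights) >= -1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_partitions_match_scipy(self, seed):
        """Cutting at every k agrees with scipy's single linkage."""
        rng = np.random.default_rng(100 + seed)
        d = rng.random((10, 10))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = linkage_single(1.0 - d)
        z = hierarchy.linkage(d[np.triu_indices(10, 1)], method="single")
        for k in (2, 3, 5):
            ours = cut_groups(dend, k).labels
            ref = hierarchy.fcluster(z, t=k, criterion="maxclust")
            # same partition up to label permutation
            pairs_ours = ours[:, None] == ours[None, :]
            pairs_ref = ref[:, None] == ref[None, :]
            assert np.array_equal(pairs_ours, pairs_ref)

    def test_non_symmetric_input_rejected(self, rng):
        s = rng.random((4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            linkage_single(s)


class TestCutGroups:
    @pytest.fixture(scope="class")
    def dend(self):
        s = 1.0 - np.array(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]]
        )
        return linkage_single(s)

    def test_k1_single_group(self, dend):
        assert np.array_equal(cut_groups(dend, 1).labels, [0, 0, 0])

    def test_kn_singletons(self, dend):
        assert np.array_equal(cut_groups(dend, 3).labels, [0, 1, 2])

    def test_k2_splits_worked_example(self, dend):
        assert np.array_equal(cut_groups(dend, 2).labels, [0, 0, 1])

    def test_invalid_k_rejected(self, dend):
        for k in (0, 4):
            with pytest.raises(ValueError):
                cut_groups(dend, k)

    def test_tie_at_cut_flagged(self):
        d = np.array(
            [[0.0, 0.2, 0.5, 0.5],
             [0.2, 0.0, 0.5, 0.5],
             [0.5, 0.5, 0.0, 0.5],
             [0.5, 0.5, 0.5, 0.0]]
        )
        dend = linkage_single(1.0 - d)
        assert cut_groups(dend, 2).tie_at_cut
        assert not cut_groups(dend, 3).tie_at_cut


# ---------------------------------------------------------------------------
# nearest-control profiles
# ---------------------------------------------------------------------------


def _toy_result() -> SimilarityResult:
    """3 slices x 3 subjects (2 controls c0, c1 + 1 lesion l0)."""
    per_slice = np.array(
        [
            [[1.0, 0.9, 0.3], [0.9, 1.0, 0.4], [0.3, 0.4, 1.0]],
            [[1.0, 0.8, 0.5], [0.8, 1.0, 0.2], [0.5, 0.2, 1.0]],
            [[1.0, 0.7, 0.6], [0.7, 1.0, 0.7], [0.6, 0.7, 1.0]],
        ]
    )
    return SimilarityResult(
        per_slice=per_slice,
        sbar=per_slice.mean(axis=0),
        ids=["c0", "c1", "l0"],
        slice_index=np.array([10, 11, 12]),
        window_sigma=2.0,
        dynamic_range=1.0,
    )


class TestNearestControlProfile:
    def test_two_controls_profile_is_mutual_similarity(self):
        profile = nearest_control_profile(_toy_result(), ["c0", "c1"], ["l0"])
        # controls exclude self: each control's only comparator is the other
        assert np.allclose(profile.values[0], [0.9, 0.8, 0.7])
        assert np.allclose(profile.values[1], [0.9, 0.8, 0.7])

    def test_lesion_profile_is_max_over_controls(self):
        profile = nearest_control_profile(_toy_result(), ["c0", "c1"], ["l0"])
        assert np.allclose(profile.values[2], [0.4, 0.5, 0.7])

    def test_duplicate_of_control_scores_one_everywhere(self):
        res = _toy_result()
        res.per_slice[:, 0, 2] = res.per_slice[:, 2, 0] = 1.0  # l0 == c0
        profile = nearest_control_profile(res, ["c0", "c1"], ["l0"])
        assert np.allclose(profile.values[2], 1.0)

    def test_single_control_rejected(self):
        with pytest.raises(ValueError, match="2 controls"):
            nearest_control_profile(_toy_result(), ["c0"], ["c1", "l0"])

    def test_non_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            nearest_control_profile(_toy_result(), ["c0", "c1"], [])


class TestSummarizeGroups:
    def test_five_point_quartiles(self):
        res = _toy_result()
        profile = nearest_control_profile(res, ["c0", "c1"], ["l0"])
        profile.values = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        profile.ids = ["a", "b", "c", "d", "e"]
        profile.control_ids = ["a", "b", "c", "d", "e"]
        profile.lesion_ids = []
        profile.slice_index = np.array([0])
        df = summarize_groups(profile)
        row = df[df.group == "control"].iloc[0]
        assert (row["median"], row.q25, row.q75) == (3.0, 2.0, 4.0)

    def test_matches_sort_based_quantiles(self, rng):
        res = _toy_result()
        profile = nearest_control_profile(res, ["c0", "c1"], ["l0"])
        vals = rng.random((7, 3))
        profile.values = vals
        profile.ids = [f"s{i}" for i in range(7)]
        profile.control_ids = profile.ids[:4]
        profile.lesion_ids = profile.ids[4:]
        df = summarize_groups(profile)

        def sort_quantile(x, q):  # inclusive linear interpolation
            x = np.sort(x)
            pos = q * (len(x) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(x) - 1)
            return x[lo] + (pos - lo) * (x[hi] - x[lo])

        for _, row in df.iterrows():
            group_rows = vals[:4] if row.group == "control" else vals[4:]
            col = list(profile.slice_index).index(row["slice"])
            assert row["median"] == pytest.approx(sort_quantile(group_rows[:, col], 0.5))
            assert row.q25 == pytest.approx(sort_quantile(group_rows[:, col], 0.25))
            assert row.q75 == pytest.approx(sort_quantile(group_rows[:, col], 0.75))

    def test_single_subject_group_has_zero_iqr(self):
        profile = nearest_control_profile(_toy_result(), ["c0", "c1"], ["l0"])
        df = summarize_groups(profile)
        lesion = df[df.group == "lesion"]
        assert np.allclose(lesion.q25, lesion["median"])
        assert np.allclose(lesion.q75, lesion["median"])
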