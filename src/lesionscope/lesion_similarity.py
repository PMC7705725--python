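"""Lesion quantification by masked slice-wise structural similarity.

For every pair of co-registered brains, the structural similarity index
(SSIM) is computed on each virtual coronal slice restricted to a generous
hippocampal-region mask, separately for the left and right sides, and
pooled with equal weight per side.  The slice-averaged similarity matrix
S-bar feeds single-linkage hierarchical clustering of the dissimilarity
1 - S-bar; cutting the merge tree into k groups separates lesioned from
intact brains.  Nearest-control profiles (per subject and slice, the
maximum similarity to any control brain, self excluded for controls) with
per-group median and interquartile-range summaries trace the lesion's
anatomical extent.

SSIM local statistics use a Gaussian weighting window; the map is

    ((2 mu_a mu_b + C1)(2 cov_ab + C2)) /
    ((mu_a^2 + mu_b^2 + C1)(sigma_a^2 + sigma_b^2 + C2))

with C1 = (k1 L)^2, C2 = (k2 L)^2 and L the dynamic range.  The mean SSIM
is the unweighted mean of the map over all crop pixels (reflective padding
for the local statistics).  The window sigma defaults to 50 px scaled by
(mask ML span) / 1000 px, so small synthetic slices use a neighborhood
comparable, relative to the masked region's size, to a 50 px sigma on
full-scan slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic_cohort import BrainVolume, GroundTruth

__all__ = [
    "RegionMask",
    "SimilarityResult",
    "Dendrogram",
    "GroupCut",
    "NearestControlProfile",
    "ssim_pair",
    "make_region_mask",
    "masked_slicewise_similarity",
    "linkage_single",
    "cut_groups",
    "nearest_control_profile",
    "summarize_groups",
]

_GAUSS_TRUNCATE = 3.5
_SIGMA_REF = 50.0 / 1000.0  # 50 px per 1000 px of crop width


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


def _gauss(img: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma, mode="reflect", truncate=_GAUSS_TRUNCATE)


def ssim_pair(
    img_a: np.ndarray,
    img_b: np.ndarray,
    window_sigma: float,
    dynamic_range: float,
    k1: float = 0.01,
    k2: float = 0.03,
) -> tuple[float, np.ndarray]:
    """SSIM between two equally shaped 2D grayscale images.

    Local means, variances and covariance are Gaussian-weighted with the
    given sigma (truncated at 3.5 sigma, reflective padding).  Returns the
    unweighted mean over all pixels and the full SSIM map.
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must have identical shapes")
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    mu_a, mu_b = _gauss(a, window_sigma), _gauss(b, window_sigma)
    var_a = _gauss(a * a, window_sigma) - mu_a * mu_a
    var_b = _gauss(b * b, window_sigma) - mu_b * mu_b
    cov = _gauss(a * b, window_sigma) - mu_a * mu_b
    ssim_map = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2)
    )
    return float(ssim_map.mean()), ssim_map


# ---------------------------------------------------------------------------
# Region mask
# ---------------------------------------------------------------------------


@dataclass
class RegionMask:
    """Binary 3D region (reference grid) split into left/right sides.

    ``ap_range`` is the half-open AP slice interval the mask covers;
    ``bounding_boxes[z]`` holds the per-slice (DV, ML) crop boxes for each
    side as ((d0, d1), (m0, m1)) half-open index ranges.
    """

    left: np.ndarray
    right: np.ndarray
    ap_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("side masks must share a shape")
        z0, z1 = self.ap_range
        for z in range(z0, z1):
            if not (self.left[z].any() and self.right[z].any()):
                raise ValueError(f"mask empty on slice {z} inside declared AP range")
        self.bounding_boxes = {
            z: tuple(self._bbox(side[z]) for side in (self.left, self.right))
            for z in range(z0, z1)
        }

    @staticmethod
    def _bbox(mask2d: np.ndarray) -> tuple[tuple[int, int], tuple[int, int]]:
        rows = np.flatnonzero(mask2d.any(axis=1))
        cols = np.flatnonzero(mask2d.any(axis=0))
        return (int(rows[0]), int(rows[-1]) + 1), (int(cols[0]), int(cols[-1]) + 1)

    @property
    def combined(self) -> np.ndarray:
        return self.left | self.right

    @property
    def ml_span(self) -> int:
        """Overall ML extent of the bilateral mask (smoothing-scale ref)."""
        cols = np.flatnonzero(self.combined.any(axis=(0, 1)))
        return int(cols[-1] - cols[0] + 1)


def make_region_mask(
    truth: GroundTruth, margin: int = 4, ap_trim: int = 1
) -> RegionMask:
    """Generous hippocampal-region mask from a template subject's layer.

    Dilates the template's ground-truth layer mask by ``margin`` voxels and
    splits it at the volume midline.  ``ap_trim`` drops the outermost AP
    slices of the layer span, where the dilated region may not yet cover
    both sides.
    """
    mask = ndimage.binary_dilation(truth.layer_mask, iterations=margin)
    n_ml = mask.shape[2]
    mid = int(round((n_ml - 1) / 2.0))
    left = mask.copy()
    left[:, :, mid:] = False
    right = mask.copy()
    right[:, :, :mid + 1] = False
    ap_any = np.flatnonzero((left.any(axis=(1, 2))) & (right.any(axis=(1, 2))))
    z0, z1 = int(ap_any[0]) + ap_trim, int(ap_any[-1]) + 1 - ap_trim
    return RegionMask(left=left, right=right, ap_range=(z0, z1))


# ---------------------------------------------------------------------------
# Slice-wise similarity
# ---------------------------------------------------------------------------


@dataclass
class SimilarityResult:
    """Per-slice and slice-averaged pairwise SSIM matrices."""

    per_slice: np.ndarray  # (n_slices, n, n)
    sbar: np.ndarray       # (n, n)
    ids: list[str]
    slice_index: np.ndarray
    window_sigma: float
    dynamic_range: float

    def __post_init__(self) -> None:
        for m in list(self.per_slice) + [self.sbar]:
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError("similarity matrices must be symmetric")
        if not np.allclose(np.diag(self.sbar), 1.0, atol=1e-9):
            raise ValueError("similarity diagonal must be 1")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.sbar, index=self.ids, columns=self.ids).to_csv(
            path, float_format="%.10g"
        )

    def mean_over(self, z_lo: int, z_hi: int) -> np.ndarray:
        """Average similarity matrix over the AP slices in [z_lo, z_hi]."""
        sel = (self.slice_index >= z_lo) & (self.slice_index <= z_hi)
        if not sel.any():
            raise ValueError("no slices in the requested AP range")
        return self.per_slice[sel].mean(axis=0)


def masked_slicewise_similarity(
    volumes: list[BrainVolume],
    mask: RegionMask,
    window_sigma: float | None = None,
    dynamic_range: float | None = None,
    k1: float = 0.01,
    k2: float = 0.03,
) -> SimilarityResult:
    """Pairwise SSIM per virtual slice on the masked crops, both sides.

    Every AP slice in the mask range contributes one left and one right
    crop (the mask's per-slice bounding boxes); the two sides are pooled
    with equal weight into that slice's matrix, and S-bar is the arithmetic
    mean over slices.  Each unordered pair is computed once; the diagonal
    is exactly 1.
    """
    n = len(volumes)
    ids = [v.subject_id or f"s{i}" for i, v in enumerate(volumes)]
    z0, z1 = mask.ap_range
    slice_ids = np.arange(z0, z1)

    # crops per (slice, side, subject)
    crops: list[list[np.ndarray]] = []
    for z in slice_ids:
        for s in range(2):
            (d0, d1), (m0, m1) = mask.bounding_boxes[int(z)][s]
            crops.append([v.voxels[z, d0:d1, m0:m1].astype(np.float64) for v in volumes])
    if window_sigma is None:
        window_sigma = _SIGMA_REF * mask.ml_span
    if dynamic_range is None:
        vmax = max(float(c.max()) for group in crops for c in group)
        vmin = min(float(c.min()) for group in crops for c in group)
        dynamic_range = vmax - vmin
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2

    n_slices = len(slice_ids)
    per_slice = np.ones((n_slices, n, n))
    for g, group in enumerate(crops):
        zi = g // 2
        mus = [_gauss(c, window_sigma) for c in group]
        e2s = [_gauss(c * c, window_sigma) for c in group]
        for i in range(n):
            var_i = e2s[i] - mus[i] ** 2
            for j in range(i + 1, n):
                var_j = e2s[j] - mus[j] ** 2
                cov = _gauss(group[i] * group[j], window_sigma) - mus[i] * mus[j]
                smap = ((2 * mus[i] * mus[j] + c1) * (2 * cov + c2)) / (
                    (mus[i] ** 2 + mus[j] ** 2 + c1) * (var_i + var_j + c2)
                )
                val = float(smap.mean())
                if g % 2 == 0:  # first side of this slice
                    per_slice[zi, i, j] = val
                else:
                    per_slice[zi, i, j] = 0.5 * (per_slice[zi, i, j] + val)
                    per_slice[zi, j, i] = per_slice[zi, i, j]
    sbar = per_slice.mean(axis=0)
    return SimilarityResult(
        per_slice=per_slice,
        sbar=sbar,
        ids=ids,
        slice_index=slice_ids,
        window_sigma=float(window_sigma),
        dynamic_range=float(dynamic_range),
    )


# ---------------------------------------------------------------------------
# Single-linkage clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Ordered single-linkage merge list over 1 - similarity.

    ``merges[k] = (a, b, height, size)`` uses scipy-style cluster indexing:
    leaves are 0..n-1 and the cluster created by merge k gets index n + k;
    a < b within each merge.  Heights are nondecreasing.
    """

    merges: list[tuple[int, int, float, int]]
    n_leaves: int
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.merges) != max(self.n_leaves - 1, 0):
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")
        heights = [m[2] for m in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("single-linkage merge heights must be nondecreasing")

    def to_scipy_linkage(self) -> np.ndarray:
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"leaf_ids": self.leaf_ids,
                 "merges": [[a, b, h, s] for a, b, h, s in self.merges]},
                indent=1,
            )
        )


def linkage_single(sbar: np.ndarray, leaf_ids: list[str] | None = None) -> Dendrogram:
    """Single-linkage merge tree of the dissimilarity D = 1 - S-bar.

    Iteratively merges the nearest pair of clusters with the update
    d(A u B, C) = min(d(A, C), d(B, C)).  Ties break deterministically on
    the smallest (a, b) cluster-index pair.
    """
    s = np.asarray(sbar, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    n = s.shape[0]
    ids = leaf_ids if leaf_ids is not None else [str(i) for i in range(n)]
    d = 1.0 - s
    np.fill_diagonal(d, np.inf)

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster index -> size
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = n + step
        size = active[a] + active[b]
        merges.append((a, b, float(h), size))
        del active[a], active[b]
        for c in list(active):
            key_ac = (min(a, c), max(a, c))
            key_bc = (min(b, c), max(b, c))
            dist[(c, new)] = min(dist.pop(key_ac), dist.pop(key_bc))
        dist.pop((a, b))
        active[new] = size
    return Dendrogram(merges=merges, n_leaves=n, leaf_ids=ids)


@dataclass
class GroupCut:
    """Leaf group labels from cutting a dendrogram into k groups."""

    labels: np.ndarray
    k: int
    tie_at_cut: bool


def cut_groups(dendrogram: Dendrogram, k: int) -> GroupCut:
    """Cut by removing the k-1 largest-height merges.

    Because single-linkage heights are nondecreasing, this keeps the first
    n - k merges; connected components become groups, numbered stably by
    smallest member id.  Equal heights straddling the cut are resolved by
    merge order and flagged.
    """
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValueError("need 1 <= k <= n")
    keep = dendrogram.merges[: n - k]
    tie = False
    if 0 < n - k < len(dendrogram.merges):
        tie = np.isclose(dendrogram.merges[n - k - 1][2], dendrogram.merges[n - k][2])

    parent = list(range(n + len(keep)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _, _) in enumerate(keep):
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new

    roots = [find(i) for i in range(n)]
    label_of_root: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i in range(n):  # ascending leaf id => stable numbering
        r = roots[i]
        if r not in label_of_root:
            label_of_root[r] = len(label_of_root)
        labels[i] = label_of_root[r]
    return GroupCut(labels=labels, k=k, tie_at_cut=bool(tie))


# ---------------------------------------------------------------------------
# Nearest-control profiles
# ---------------------------------------------------------------------------


@dataclass
class NearestControlProfile:
    """Per subject and slice, the maximum similarity to any control brain.

    For control subjects the maximization excludes the subject itself
    (otherwise controls trivially score 1).
    """

    values: np.ndarray  # (n_subjects, n_slices)
    ids: list[str]
    control_ids: list[str]
    lesion_ids: list[str]
    slice_index: np.ndarray

    def group_values(self, group: str) -> np.ndarray:
        sel = self.control_ids if group == "control" else self.lesion_ids
        rows = [self.ids.index(i) for i in sel]
        return self.values[rows]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.slice_index)
        df = df.rename_axis("subject").reset_index().melt(
            id_vars="subject", var_name="slice", value_name="value"
        )
        df.to_csv(path, index=False, float_format="%.10g")


def nearest_control_profile(
    result: SimilarityResult, control_ids: list[str], lesion_ids: list[str]
) -> NearestControlProfile:
    """Most-similar-control value per subject per virtual slice."""
    if sorted(control_ids + lesion_ids) != sorted(result.ids):
        raise ValueError("control_ids + lesion_ids must partition the cohort")
    if len(control_ids) < 2:
        raise ValueError("need at least 2 controls (controls need a comparator)")
    control_rows = [result.ids.index(c) for c in control_ids]
    n = len(result.ids)
    n_slices = result.per_slice.shape[0]
    values = np.empty((n, n_slices))
    for i in range(n):
        comparators = [c for c in control_rows if c != i]
        values[i] = result.per_slice[:, i, comparators].max(axis=1)
    return NearestControlProfile(
        values=values,
        ids=result.ids,
        control_ids=list(control_ids),
        lesion_ids=list(lesion_ids),
        slice_index=result.slice_index,
    )


def summarize_groups(profile: NearestControlProfile) -> pd.DataFrame:
    """Per-slice median and quartiles per group.

    Quantiles use the inclusive linear-interpolation definition
    (numpy's default ``method='linear'``).
    """
    rows = []
    for group in ("control", "lesion"):
        vals = profile.group_values(group)
        if vals.size == 0:
            continue
        q25, med, q75 = np.percentile(vals, [25, 50, 75], axis=0)
        for z, m, lo, hi in zip(profile.slice_index, med, q25, q75):
            rows.append({"group": group, "slice": int(z), "median": m, "q25": lo, "q75": hi})
    return pd.DataFrame(rows)
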