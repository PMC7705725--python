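"""Rigid alignment of brain volumes into a shared reference frame.

Volumes are placed in a common coordinate system by a closed-form
landmark-based rigid fit (Kabsch / orthogonal Procrustes, rotation +
translation only) followed by trilinear resampling onto the reference grid.
Two landmark detectors are provided: hippocampal-layer landmarks (anterior
tip of the bright cell layer and the lateral extreme at the AP level where
its dorsal and ventral components fuse, per hemisphere) used by the
electrode coordinate frame, and brain-outline landmarks (centroid plus the
six poles of the thresholded brain mask) used to register whole brains --
including lesioned ones, whose internal layer landmarks no longer exist.

Coordinates are 0-based voxel indices; world = index * pitch at voxel
centers.  All detectors threshold on order statistics of the intensity
distribution, so they are invariant to global affine intensity rescaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic_cohort import BrainVolume

__all__ = [
    "RigidTransform",
    "LandmarkSet",
    "LandmarksNotFoundError",
    "estimate_rigid",
    "resample_to_reference",
    "detect_anatomical_landmarks",
    "detect_brain_outline_landmarks",
    "landmarks_from_layer_mask",
    "brain_mask",
    "layer_threshold",
    "split_outer_inner",
    "save_landmarks_csv",
    "load_landmarks_csv",
    "save_transform_json",
    "load_transform_json",
]

_ORTHO_TOL = 1e-8


class LandmarksNotFoundError(RuntimeError):
    """Raised when no above-threshold layer structure can be located."""


@dataclass(frozen=True)
class RigidTransform:
    """y = R x + t mapping source voxel coordinates into the reference grid."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-7):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation.T, translation=-self.rotation.T @ self.translation
        )


@dataclass
class LandmarkSet:
    """Named 3D points (AP, DV, ML) with a coordinate-space tag."""

    points: dict[str, np.ndarray] = field(default_factory=dict)
    space: str = "voxel"

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}

    @property
    def names(self) -> list[str]:
        return list(self.points.keys())

    def array(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else sorted(self.points)
        return np.array([self.points[n] for n in names])

    def __len__(self) -> int:
        return len(self.points)


def estimate_rigid(src: LandmarkSet, dst: LandmarkSet) -> RigidTransform:
    """Least-squares rigid transform (no scaling, no reflection) src -> dst.

    Classic Kabsch solution: SVD of the centered cross-covariance with the
    determinant sign fix so the optimum over proper rotations is returned.
    Requires >= 3 shared, non-collinear correspondences.
    """
    names = sorted(set(src.points) & set(dst.points))
    if len(names) < 3:
        raise ValueError("need at least 3 shared landmarks")
    p = src.array(names)
    q = dst.array(names)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    s = np.linalg.svd(pc, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("landmarks are collinear or degenerate")
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = q.mean(axis=0) - rot @ p.mean(axis=0)
    return RigidTransform(rotation=rot, translation=trans)


def resample_to_reference(
    volume: BrainVolume,
    transform: RigidTransform,
    reference_shape: tuple[int, int, int] | None = None,
    fill_value: float = 0.0,
) -> BrainVolume:
    """Trilinear resampling of ``volume`` onto the reference grid.

    ``transform`` maps source voxel coordinates into the reference frame;
    each reference voxel samples the source at the inverse-mapped location.
    Out-of-domain voxels take ``fill_value``.
    """
    shape = reference_shape or volume.shape
    inv = transform.inverse()
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
    src = inv.rotation @ idx + inv.translation[:, None]
    out = ndimage.map_coordinates(
        volume.voxels.astype(np.float64), src, order=1, mode="constant", cval=fill_value
    ).reshape(shape)
    return BrainVolume(
        voxels=out.astype(np.float32),
        voxel_pitch=volume.voxel_pitch,
        subject_id=volume.subject_id,
        provenance=volume.provenance,
    )


# ---------------------------------------------------------------------------
# Landmark extraction
# ---------------------------------------------------------------------------


def _slice_clusters(mask2d: np.ndarray, min_cluster: int) -> list[np.ndarray]:
    """4-connected components of a (DV, ML) slice with >= min_cluster pixels."""
    labels, n = ndimage.label(mask2d, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    comps = []
    if n:
        counts = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if counts[lab] >= min_cluster:
                comps.append(np.argwhere(labels == lab))
    return comps


def split_outer_inner(
    comps: list[np.ndarray],
    mid: float,
    side: int,
    n_dv: int,
    inner_fraction: float = 0.85,
    dorsal_cut_fraction: float = 0.18,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Classify slice components into the outer sheet vs. inner structures.

    Components reaching the dorsal surface (min DV below
    ``dorsal_cut_fraction`` of the grid) are electrode shafts traversing
    cortex and are discarded.  Of the rest, components whose lateral
    extent from the midline falls below ``inner_fraction`` of the slice
    maximum belong to the inner (dentate) sheet; the others are the outer
    hippocampal layer (dorsal and/or ventral components).
    """
    kept = [pix for pix in comps if pix[:, 0].min() >= dorsal_cut_fraction * n_dv]
    if not kept:
        return [], []
    extents = [float((side * (pix[:, 1] - mid)).max()) for pix in kept]
    lat_max = max(extents)
    outer = [pix for pix, e in zip(kept, extents) if e >= inner_fraction * lat_max]
    inner = [pix for pix, e in zip(kept, extents) if e < inner_fraction * lat_max]
    return outer, inner


def landmarks_from_layer_mask(
    mask: np.ndarray, ml_mid: float | None = None, min_cluster: int = 5,
    split_persistence: int = 3,
) -> dict[str, np.ndarray]:
    """Layer landmarks from a boolean layer mask, per hemisphere.

    ``tip_{side}``: centroid of the anterior-most AP slice whose pixels form
    a 4-connected cluster of >= ``min_cluster`` pixels.  ``fusion_{side}``:
    on the first AP slice where the side's dorsal and ventral components
    (previously >= 2 clusters) merge into one, the lateral-most pixel.
    Component counting considers the outer sheet only (the inner dentate
    sheet and electrode shafts are filtered by :func:`split_outer_inner`),
    and the dorsal/ventral split must persist for ``split_persistence``
    consecutive slices before a merge counts as the fusion -- a single
    noise-fragmented slice must not fake an early fusion.
    Points are (AP, DV, ML) voxel coordinates.
    """
    n_ml = mask.shape[2]
    mid = (n_ml - 1) / 2.0 if ml_mid is None else ml_mid
    out: dict[str, np.ndarray] = {}
    for side, name in ((-1, "left"), (+1, "right")):
        half = mask.copy()
        if side < 0:
            half[:, :, int(np.floor(mid)) + 1 :] = False
        else:
            half[:, :, : int(np.ceil(mid))] = False

        occupied = np.flatnonzero(half.any(axis=(1, 2)))
        n_dv = mask.shape[1]
        tip = None
        counts: dict[int, int] = {}
        slices_pixels: dict[int, list[np.ndarray]] = {}
        for z in occupied:
            comps, _ = split_outer_inner(
                _slice_clusters(half[z], min_cluster), mid, side, n_dv
            )
            counts[z] = len(comps)
            slices_pixels[z] = comps
            if tip is None and comps:
                pix = np.vstack(comps)
                tip = np.array([float(z), pix[:, 0].mean(), pix[:, 1].mean()])
        if tip is None:
            raise LandmarksNotFoundError(f"no layer structure on the {name} side")

        fusion = None
        seen_split = False
        run = 0
        for z in occupied:
            c = counts[z]
            if c >= 2:
                run += 1
                if run >= split_persistence:
                    seen_split = True
            else:
                run = 0
            if seen_split and c == 1:
                pix = slices_pixels[z][0]
                offs = side * (pix[:, 1] - mid)
                j = int(np.argmax(offs))
                fusion = np.array([float(z), float(pix[j, 0]), float(pix[j, 1])])
                break
        if fusion is None:
            raise LandmarksNotFoundError(
                f"dorsal/ventral fusion not found on the {name} side"
            )
        out[f"tip_{name}"] = tip
        out[f"fusion_{name}"] = fusion
    return out


def brain_mask(volume: BrainVolume) -> np.ndarray:
    """Largest connected component above an Otsu threshold (air vs. tissue)."""
    from skimage.filters import threshold_otsu

    thr = threshold_otsu(volume.voxels)
    mask = volume.voxels > thr
    labels, n = ndimage.label(mask)
    if n == 0:
        raise LandmarksNotFoundError("no brain structure above the Otsu threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def layer_threshold(volume: BrainVolume, intensity_ratio_threshold: float = 0.75) -> float:
    """Intensity cut separating the bright cell layer from tissue.

    Statistics are restricted to the brain interior -- the Otsu brain mask
    eroded past the skull shell -- so ``lo = median`` sits in the tissue
    bulk and ``hi = p98`` lands in the cell-layer band (robust to the far
    brighter but much sparser electrode rods).  The cut
    ``lo + ratio * (hi - lo)`` is built from order statistics only, so it
    is invariant to global affine intensity rescaling.  Raises
    :class:`LandmarksNotFoundError` when the bright tail is not separable
    from the tissue noise (no layer present).
    """
    mask = brain_mask(volume)
    iters = max(3, int(round(0.05 * min(volume.shape))))
    interior = ndimage.binary_erosion(mask, iterations=iters)
    inside = volume.voxels[interior if interior.any() else mask]
    lo = float(np.median(inside))
    hi = float(np.percentile(inside, 98.0))
    mad = float(np.median(np.abs(inside - lo)))
    if hi - lo <= 6.0 * 1.4826 * mad:
        raise LandmarksNotFoundError("no layer brighter than tissue at this threshold")
    return lo + intensity_ratio_threshold * (hi - lo)


def detect_anatomical_landmarks(
    volume: BrainVolume, intensity_ratio_threshold: float = 0.75, min_cluster: int = 5,
    electrode_exclusion_factor: float = 2.0,
) -> LandmarkSet:
    """Detect the layer tip and fusion landmarks from intensities.

    Thresholds the volume with :func:`layer_threshold` and applies the same
    geometric rule as the generator's ground truth
    (:func:`landmarks_from_layer_mask`).  Voxels brighter than
    ``electrode_exclusion_factor`` times the layer threshold are electrode
    metal, not tissue, and are excluded.
    """
    thr = layer_threshold(volume, intensity_ratio_threshold)
    mask = (volume.voxels >= thr) & (volume.voxels <= electrode_exclusion_factor * thr)
    points = landmarks_from_layer_mask(mask, min_cluster=min_cluster)
    return LandmarkSet(points=points, space="voxel")


def detect_brain_outline_landmarks(volume: BrainVolume, slab: float = 1.5) -> LandmarkSet:
    """Whole-brain landmarks: mask centroid plus six axis poles.

    The brain mask is the largest connected component above an Otsu
    threshold (air vs. tissue).  Each pole is the centroid of the mask
    voxels within ``slab`` voxels of the extreme along one axis direction.
    Robust to internal lesions, which do not touch the outline.
    """
    coords = np.argwhere(brain_mask(volume)).astype(float)
    points = {"centroid": coords.mean(axis=0)}
    axis_names = ("ap", "dv", "ml")
    for ax in range(3):
        for direction, tag in ((-1, "min"), (+1, "max")):
            vals = coords[:, ax]
            extreme = vals.min() if direction < 0 else vals.max()
            sel = coords[np.abs(vals - extreme) <= slab]
            points[f"{axis_names[ax]}_{tag}"] = sel.mean(axis=0)
    return LandmarkSet(points=points, space="voxel")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_landmarks_csv(landmarks: LandmarkSet, path: str | Path) -> None:
    rows = [
        {"name": k, "ap": v[0], "dv": v[1], "ml": v[2], "space": landmarks.space}
        for k, v in landmarks.points.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_landmarks_csv(path: str | Path) -> LandmarkSet:
    df = pd.read_csv(path)
    points = {r["name"]: np.array([r["ap"], r["dv"], r["ml"]]) for _, r in df.iterrows()}
    space = str(df["space"].iloc[0]) if "space" in df and len(df) else "voxel"
    return LandmarkSet(points=points, space=space)


def save_transform_json(transform: RigidTransform, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "rotation": transform.rotation.tolist(),
                "translation": transform.translation.tolist(),
            },
            indent=1,
        )
    )


def load_transform_json(path: str | Path) -> RigidTransform:
    d = json.loads(Path(path).read_text())
    return RigidTransform(
        rotation=np.asarray(d["rotation"]), translation=np.asarray(d["translation"])
    )
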