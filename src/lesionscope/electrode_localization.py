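"""Normalized anatomical coordinate frame and electrode mapping.

A per-hemisphere 2D frame is anchored to two easily visible layer
landmarks: the center of the most anterior portion of the CA1 cell layer
(the origin) and the lateral extent of the cell layer at the AP level where
its dorsal and ventral portions fuse (the (1,1) point).  The frame is a
per-axis affine map -- AP and ML are scaled independently -- which is the
only map fully determined by those two constraints; the dorsal-ventral
axis is deliberately excluded because electrodes move along it during
recordings.  Layer curves (lateral hippocampal layer and medial dentate
layer, anterior to posterior), detected electrode tips, and cannula-layout
matching all live in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .alignment import LandmarkSet, layer_threshold, split_outer_inner
from .synthetic_cohort import BrainVolume, CannulaLayout

__all__ = [
    "Frame2D",
    "LayerCurves",
    "ElectrodeSet",
    "MatchResult",
    "make_frame",
    "frame_from_landmarks",
    "normalize_points",
    "extract_layer_curves",
    "detect_electrode_tips",
    "match_cannula",
]


@dataclass(frozen=True)
class Frame2D:
    """Per-axis affine (AP, ML) frame: origin -> (0,0), unit -> (1,1)."""

    origin: tuple[float, float]
    unit: tuple[float, float]
    side: str = "right"

    def __post_init__(self) -> None:
        for axis, name in ((0, "AP"), (1, "ML")):
            if self.unit[axis] == self.origin[axis]:
                raise ValueError(f"degenerate frame: zero scale along the {name} axis")

    def normalize(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        o = np.asarray(self.origin)
        u = np.asarray(self.unit)
        return (pts - o) / (u - o)

    def denormalize(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        o = np.asarray(self.origin)
        u = np.asarray(self.unit)
        return pts * (u - o) + o


def make_frame(origin, unit, side: str = "right") -> Frame2D:
    return Frame2D(origin=tuple(map(float, origin)), unit=tuple(map(float, unit)), side=side)


def frame_from_landmarks(landmarks: LandmarkSet, side: str = "right") -> Frame2D:
    """Frame from tip_{side} / fusion_{side} points of a landmark set."""
    tip = landmarks.points[f"tip_{side}"]
    fusion = landmarks.points[f"fusion_{side}"]
    return make_frame((tip[0], tip[2]), (fusion[0], fusion[2]), side=side)


def normalize_points(points: np.ndarray, frame: Frame2D) -> np.ndarray:
    """Apply the frame's per-axis affine map; order preserved."""
    return frame.normalize(points)


# ---------------------------------------------------------------------------
# Layer curves
# ---------------------------------------------------------------------------


@dataclass
class LayerCurves:
    """Sampled (AP, ML) polylines of the cell layers, anterior to posterior.

    ``lateral`` follows the lateral aspect of the hippocampal cell layer,
    ``medial`` the medial aspect of the inner dentate layer; both in
    normalized frame coordinates (``*_vox`` keeps raw voxel coordinates).
    AP is strictly increasing along each polyline; slices where the sheet
    was not found are recorded as gaps, never interpolated.
    """

    subject_id: str
    side: str
    lateral: np.ndarray
    medial: np.ndarray
    lateral_vox: np.ndarray
    medial_vox: np.ndarray

    def __post_init__(self) -> None:
        for curve in (self.lateral, self.medial):
            if len(curve) > 1 and not np.all(np.diff(curve[:, 0]) > 0):
                raise ValueError("curve AP coordinates must be strictly increasing")


def extract_layer_curves(
    volume: BrainVolume,
    frame: Frame2D,
    intensity_ratio_threshold: float = 0.7,
    side: str | None = None,
    min_cluster: int = 5,
    inner_fraction: float = 0.85,
    dorsal_cut_fraction: float = 0.18,
    electrode_exclusion_factor: float = 2.0,
) -> LayerCurves:
    """Trace the lateral layer curve and the medial dentate curve.

    Per AP slice and hemisphere, above-threshold pixels are grouped into
    8-connected components; components reaching the dorsal surface
    (min DV < ``dorsal_cut_fraction`` of the grid) are electrode shafts and
    are dropped.  Components whose lateral extent is below
    ``inner_fraction`` of the side's maximum belong to the inner (dentate)
    sheet: the medial curve takes their medial-most pixel, the lateral
    curve the lateral-most pixel of the outer components.  Missing sheets
    leave gaps.
    """
    side = side or frame.side
    s = +1 if side == "right" else -1
    thr = layer_threshold(volume, intensity_ratio_threshold)
    # upper cut: electrode metal is far brighter than any cell layer
    mask = (volume.voxels >= thr) & (volume.voxels <= electrode_exclusion_factor * thr)
    n_ap, n_dv, n_ml = mask.shape
    mid = (n_ml - 1) / 2.0

    lat_rows, med_rows = [], []
    for z in range(n_ap):
        half = mask[z].copy()
        if s > 0:
            half[:, : int(np.ceil(mid))] = False
        else:
            half[:, int(np.floor(mid)) + 1 :] = False
        labels, n = ndimage.label(half, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            continue
        comps = []
        counts = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if counts[lab] >= min_cluster:
                comps.append(np.argwhere(labels == lab))
        outer, inner = split_outer_inner(
            comps, mid, s, n_dv,
            inner_fraction=inner_fraction, dorsal_cut_fraction=dorsal_cut_fraction,
        )
        if outer:
            pix = np.vstack(outer)
            offs = s * (pix[:, 1] - mid)
            lat_rows.append((float(z), float(pix[np.argmax(offs), 1])))
        if inner:
            pix = np.vstack(inner)
            offs = s * (pix[:, 1] - mid)
            med_rows.append((float(z), float(pix[np.argmin(offs), 1])))

    lat_vox = np.asarray(lat_rows) if lat_rows else np.empty((0, 2))
    med_vox = np.asarray(med_rows) if med_rows else np.empty((0, 2))
    lat = frame.normalize(lat_vox) if len(lat_vox) else lat_vox
    med = frame.normalize(med_vox) if len(med_vox) else med_vox
    return LayerCurves(
        subject_id=volume.subject_id, side=side,
        lateral=lat, medial=med, lateral_vox=lat_vox, medial_vox=med_vox,
    )


# ---------------------------------------------------------------------------
# Electrode detection
# ---------------------------------------------------------------------------


@dataclass
class ElectrodeSet:
    """Detected electrode tip centroids with optional slot labels."""

    tips: np.ndarray  # (n, 3) (AP, DV, ML) voxel coordinates
    ambiguous: np.ndarray  # (n,) bool
    labels: list[str | None] = field(default_factory=list)
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.tips = np.asarray(self.tips, dtype=float).reshape(-1, 3)
        self.ambiguous = np.asarray(self.ambiguous, dtype=bool).reshape(-1)
        if not self.labels:
            self.labels = [None] * len(self.tips)
        assigned = [l for l in self.labels if l is not None]
        if len(assigned) != len(set(assigned)):
            raise ValueError("assigned labels must be unique")

    def tips_2d(self) -> np.ndarray:
        return self.tips[:, [0, 2]]

    def __len__(self) -> int:
        return len(self.tips)


def detect_electrode_tips(
    volume: BrainVolume,
    intensity_quantile: float = 0.998,
    min_voxels: int = 10,
    max_footprint: float = 3.5,
) -> ElectrodeSet:
    """Detect bright electrode rods and their ventral tips.

    Voxels above the given intensity quantile form 26-connected components;
    components with >= ``min_voxels`` voxels are kept.  The tip is the
    centroid of a component's ventral-most voxel layer.  Components whose
    horizontal footprint exceeds ``max_footprint`` voxels along AP or ML
    are flagged ambiguous (likely merged rods).  An empty set is allowed.
    """
    vox = volume.voxels
    thr = float(np.quantile(vox, intensity_quantile))
    mask = vox > thr
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    tips, flags = [], []
    for lab in range(1, n + 1):
        pix = np.argwhere(labels == lab)
        if len(pix) < min_voxels:
            continue
        dv_max = pix[:, 1].max()
        bottom = pix[pix[:, 1] == dv_max]
        tips.append(bottom.mean(axis=0))
        extent_ap = pix[:, 0].max() - pix[:, 0].min()
        extent_ml = pix[:, 2].max() - pix[:, 2].min()
        flags.append(bool(max(extent_ap, extent_ml) > max_footprint))
    tips_arr = np.asarray(tips) if tips else np.empty((0, 3))
    order = np.lexsort(tips_arr[:, ::-1].T) if len(tips_arr) else np.array([], dtype=int)
    return ElectrodeSet(
        tips=tips_arr[order] if len(tips_arr) else tips_arr,
        ambiguous=np.asarray(flags, dtype=bool)[order] if flags else np.array([], dtype=bool),
        threshold=thr,
    )


# ---------------------------------------------------------------------------
# Cannula matching
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    """Slot-to-detection assignment under a fitted similarity transform."""

    assignment: dict[str, int]
    unmatched_slots: list[str]
    unmatched_detections: list[int]
    scale: float
    rotation: float  # radians
    translation: np.ndarray
    residual: float


def _similarity_from_two(p1, p2, q1, q2):
    """2D similarity (scale, rotation, translation) mapping p1->q1, p2->q2."""
    dp = p2 - p1
    dq = q2 - q1
    scale = np.linalg.norm(dq) / np.linalg.norm(dp)
    ang = np.arctan2(dq[1], dq[0]) - np.arctan2(dp[1], dp[0])
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    trans = q1 - scale * rot @ p1
    return scale, ang, rot, trans


def _umeyama_2d(p: np.ndarray, q: np.ndarray):
    """Least-squares similarity (no reflection) p -> q."""
    mp, mq = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - mp, q - mq
    h = pc.T @ qc / len(p)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    dd = np.diag([1.0, d])
    rot = vt.T @ dd @ u.T
    var_p = (pc**2).sum() / len(p)
    scale = float(np.trace(np.diag(s) @ dd) / var_p)
    trans = mq - scale * rot @ mp
    ang = float(np.arctan2(rot[1, 0], rot[0, 0]))
    return scale, ang, rot, trans


def _greedy_assign(slots: np.ndarray, dets: np.ndarray) -> list[tuple[int, int, float]]:
    """Globally greedy nearest-neighbor pairs (slot index, det index, dist)."""
    dists = np.linalg.norm(slots[:, None, :] - dets[None, :, :], axis=2)
    pairs = []
    used_s: set[int] = set()
    used_d: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(dists, axis=None), dists.shape))[0]
    for i, j in order:
        if i in used_s or j in used_d:
            continue
        pairs.append((int(i), int(j), float(dists[i, j])))
        used_s.add(int(i))
        used_d.add(int(j))
        if len(used_s) == len(slots) or len(used_d) == len(dets):
            break
    return pairs


def _farthest_pair(points: np.ndarray) -> tuple[int, int]:
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    return int(i), int(j)


def match_cannula(detected: np.ndarray, layout: CannulaLayout) -> MatchResult:
    """Assign detected (AP, ML) electrode centroids to cannula slots.

    Fits the similarity transform (rotation + translation + uniform scale)
    from the occupied slot grid to the detections, then assigns greedily by
    nearest neighbor under the fitted transform.  The correspondence search
    seeds from the two mutually farthest points of each set (both
    pairings are tried; the lower-residual one wins) and is refined by a
    least-squares similarity fit on the greedy assignment.  Surplus
    detections and empty/unfilled slots are flagged.
    """
    dets = np.atleast_2d(np.asarray(detected, dtype=float))
    if len(dets) < 2:
        raise ValueError("need at least 2 detected points")
    slots = layout.positions()
    slot_labels = [s.label for s in layout.occupied]

    s_a, s_b = _farthest_pair(slots)
    d_a, d_b = _farthest_pair(dets)
    best = None
    for (i1, i2) in ((d_a, d_b), (d_b, d_a)):
        scale, ang, rot, trans = _similarity_from_two(slots[s_a], slots[s_b], dets[i1], dets[i2])
        mapped = (scale * (rot @ slots.T)).T + trans
        pairs = _greedy_assign(mapped, dets)
        resid = float(np.mean([d for _, _, d in pairs]))
        if best is None or resid < best[0]:
            best = (resid, pairs)
    _, pairs = best

    # refine with a least-squares similarity over the assigned pairs
    si = np.array([i for i, _, _ in pairs])
    di = np.array([j for _, j, _ in pairs])
    scale, ang, rot, trans = _umeyama_2d(slots[si], dets[di])
    mapped = (scale * (rot @ slots.T)).T + trans
    pairs = _greedy_assign(mapped, dets)

    assignment = {slot_labels[i]: j for i, j, _ in pairs}
    matched_d = {j for _, j, _ in pairs}
    unmatched_slots = [lab for k, lab in enumerate(slot_labels) if lab not in assignment]
    unmatched_dets = [j for j in range(len(dets)) if j not in matched_d]
    resid = float(np.sqrt(np.mean([d**2 for _, _, d in pairs])))
    return MatchResult(
        assignment=assignment,
        unmatched_slots=unmatched_slots,
        unmatched_detections=unmatched_dets,
        scale=scale,
        rotation=ang,
        translation=trans,
        residual=resid,
    )


def curves_to_frame(curves: LayerCurves) -> pd.DataFrame:
    """Tidy table (subject, side, which, ap_norm, ml_norm) of a curve set."""
    rows = []
    for which, arr in (("lateral", curves.lateral), ("medial", curves.medial)):
        for ap, ml in arr:
            rows.append(
                {"subject": curves.subject_id, "side": curves.side,
                 "which": which, "ap_norm": ap, "ml_norm": ml}
            )
    return pd.DataFrame(rows)
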