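"""End-to-end orchestration: simulate -> align -> quantify -> report.

Three runnable pipelines mirror the study's quantitative analyses:

* ``run_lesion_pipeline`` -- synthetic cohort, whole-brain rigid alignment,
  masked slice-wise SSIM, single-linkage clustering of 1 - SSIM with a
  k-group cut, and nearest-control profiles with median/IQR summaries.
* ``run_electrode_pipeline`` -- control layer curves in the normalized
  2D frame, plus electrode detection, normalization and cannula matching
  for an implanted subject.
* ``run_theta_pipeline`` -- synthetic LFP session, pairwise theta phase
  offsets, optionally joined with the normalized electrode coordinates.

Every random draw routes through the config's master seed, so reports
regenerate bit-identically; no stage consumes ground-truth surgery labels
except the generator itself and the final evaluation/reporting step.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment as al
from . import electrode_localization as el
from . import lesion_similarity as ls
from . import synthetic_cohort as sc
from . import theta_phase as tp

__all__ = [
    "RunConfig",
    "LesionReport",
    "ElectrodeReport",
    "ThetaReport",
    "run_lesion_pipeline",
    "run_electrode_pipeline",
    "run_theta_pipeline",
    "group_purity",
]

log = logging.getLogger("lesionscope")

_TEMPLATE_SPAWN_KEY = 10**6  # reserved subject index for the reference template


@dataclass
class RunConfig:
    """Single config driving all pipeline stages."""

    cohort: sc.CohortConfig = field(default_factory=sc.CohortConfig)
    mask_margin: int = 4
    ssim_sigma: float | None = None
    cluster_k: int = 2
    theta: sc.PhaseOffsetSpec = field(default_factory=sc.PhaseOffsetSpec)
    electrode_tip_depth_frac: float = 0.24  # DV fraction: just dorsal to the layer
    out_dir: str | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")
        if self.master_seed != self.cohort.master_seed:
            self.cohort = dataclasses.replace(self.cohort, master_seed=self.master_seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = sc.CohortConfig(**kwargs["cohort"])
        if "theta" in kwargs:
            t = dict(kwargs["theta"])
            if "offsets" in t:
                t["offsets"] = np.asarray(t["offsets"], dtype=float)
            kwargs["theta"] = sc.PhaseOffsetSpec(**t)
        return cls(**kwargs)


def _reference_template(config: RunConfig) -> tuple[sc.BrainVolume, sc.GroundTruth]:
    """Noise- and jitter-free template defining the reference grid/mask."""
    cc = dataclasses.replace(
        config.cohort, noise_sd=0.0, pose_jitter_deg=0.0, pose_jitter_vox=0.0
    )
    ss = np.random.SeedSequence(config.master_seed, spawn_key=(_TEMPLATE_SPAWN_KEY,))
    return sc.generate_brain_volume(cc, int(ss.generate_state(1)[0]), subject_id="template")


def _align_cohort(
    volumes: list[sc.BrainVolume], reference: sc.BrainVolume
) -> tuple[list[sc.BrainVolume], list[al.RigidTransform]]:
    """Whole-brain rigid alignment of every volume onto the reference grid."""
    ref_lm = al.detect_brain_outline_landmarks(reference)
    aligned, transforms = [], []
    for vol in volumes:
        lm = al.detect_brain_outline_landmarks(vol)
        t = al.estimate_rigid(lm, ref_lm)
        aligned.append(al.resample_to_reference(vol, t, reference.shape))
        transforms.append(t)
    return aligned, transforms


def group_purity(labels_true: list[str], group_labels: np.ndarray) -> int:
    """Number of subjects whose group contains a single surgery label."""
    pure = 0
    for g in np.unique(group_labels):
        members = [labels_true[i] for i in np.flatnonzero(group_labels == g)]
        if len(set(members)) == 1:
            pure += len(members)
    return pure


@dataclass
class LesionReport:
    ids: list[str]
    labels: list[str]
    similarity: ls.SimilarityResult
    dendrogram: ls.Dendrogram
    groups: ls.GroupCut
    profile: ls.NearestControlProfile
    summary: pd.DataFrame
    lesion_slice_range: tuple[int, int]
    n_pure: int
    metadata: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.similarity.to_csv(out / "sbar.csv")
        self.dendrogram.to_json(out / "dendrogram.json")
        pd.DataFrame({"subject": self.ids, "label": self.labels,
                      "group": self.groups.labels}).to_csv(out / "groups.csv", index=False)
        self.profile.to_csv(out / "profile.csv")
        self.summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")
        (out / "metadata.json").write_text(json.dumps(self.metadata, indent=1, sort_keys=True))


def run_lesion_pipeline(config: RunConfig) -> LesionReport:
    """Generate, align and quantify a lesion cohort end to end."""
    t0 = time.time()
    cohort = sc.generate_cohort(config.cohort)
    log.info("stage=generate n=%d elapsed=%.1fs", len(cohort.subjects), time.time() - t0)

    template_vol, template_truth = _reference_template(config)
    aligned, _ = _align_cohort(cohort.volumes, template_vol)
    log.info("stage=align elapsed=%.1fs", time.time() - t0)

    mask = ls.make_region_mask(template_truth, margin=config.mask_margin)
    sim = ls.masked_slicewise_similarity(aligned, mask, window_sigma=config.ssim_sigma)
    log.info("stage=ssim sigma=%.3g elapsed=%.1fs", sim.window_sigma, time.time() - t0)

    # targeted AP interval (dorsal + dorsal-intermediate) on the reference
    # grid: the clustering averages similarity over this lesioned portion,
    # while profiles span the full mask range to show the distal convergence
    ap_any = np.flatnonzero(template_truth.layer_mask.any(axis=(1, 2)))
    a0, a1 = float(ap_any[0]), float(ap_any[-1])
    lo, hi = config.cohort.lesion_ap_extent
    lesion_range = (int(np.ceil(a0 + lo * (a1 - a0))), int(np.floor(a0 + hi * (a1 - a0))))

    sbar_targeted = sim.mean_over(*lesion_range)
    dend = ls.linkage_single(sbar_targeted, leaf_ids=sim.ids)
    groups = ls.cut_groups(dend, config.cluster_k)

    control_ids = [s.truth.subject_id for s in cohort.subjects if s.truth.label == "control"]
    lesion_ids = [s.truth.subject_id for s in cohort.subjects if s.truth.label == "lesion"]
    profile = ls.nearest_control_profile(sim, control_ids, lesion_ids)
    summary = ls.summarize_groups(profile)
    n_pure = group_purity(cohort.labels, groups.labels)

    metadata = {
        "master_seed": config.master_seed,
        "n_control": config.cohort.n_control,
        "n_lesion": config.cohort.n_lesion,
        "grid_shape": list(config.cohort.grid_shape),
        "ssim_sigma": sim.window_sigma,
        "dynamic_range": sim.dynamic_range,
        "cluster_k": config.cluster_k,
        "n_pure": n_pure,
    }
    report = LesionReport(
        ids=cohort.ids, labels=cohort.labels, similarity=sim, dendrogram=dend,
        groups=groups, profile=profile, summary=summary,
        lesion_slice_range=lesion_range, n_pure=n_pure, metadata=metadata,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


@dataclass
class ElectrodeReport:
    curves: list[el.LayerCurves]          # per control subject
    implant_curves: el.LayerCurves
    electrodes: el.ElectrodeSet
    tips_normalized: np.ndarray
    match: el.MatchResult | None
    band_check: pd.DataFrame
    metadata: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.concat([el.curves_to_frame(c) for c in self.curves + [self.implant_curves]]
                  ).to_csv(out / "curves.csv", index=False, float_format="%.10g")
        pd.DataFrame(
            {"label": self.electrodes.labels,
             "ap_norm": self.tips_normalized[:, 0], "ml_norm": self.tips_normalized[:, 1],
             "ambiguous": self.electrodes.ambiguous}
        ).to_csv(out / "electrodes.csv", index=False, float_format="%.10g")
        self.band_check.to_csv(out / "band_check.csv", index=False, float_format="%.10g")
        (out / "metadata.json").write_text(json.dumps(self.metadata, indent=1, sort_keys=True))


def _band_check(
    control_curves: list[el.LayerCurves], implant: el.LayerCurves, n_bins: int = 10
) -> pd.DataFrame:
    """Does the implant's lateral curve sit inside the control band?

    Bins normalized AP; within each bin the band is the [min, max] range
    of all control curve points, and the implant's per-bin mean normalized
    ML is checked against it.
    """
    all_ap = np.concatenate([c.lateral[:, 0] for c in control_curves])
    edges = np.linspace(all_ap.min(), all_ap.max(), n_bins + 1)
    rows = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        ctrl_ml = np.concatenate(
            [c.lateral[(c.lateral[:, 0] >= lo) & (c.lateral[:, 0] <= hi), 1]
             for c in control_curves]
        )
        sel = (implant.lateral[:, 0] >= lo) & (implant.lateral[:, 0] <= hi)
        if ctrl_ml.size == 0 or not sel.any():
            continue
        imp = float(implant.lateral[sel, 1].mean())
        lo_b, hi_b = float(ctrl_ml.min()), float(ctrl_ml.max())
        rows.append(
            {"ap_lo": lo, "ap_hi": hi, "band_min": lo_b, "band_max": hi_b,
             "implant_ml": imp, "inside": bool(lo_b <= imp <= hi_b)}
        )
    return pd.DataFrame(rows)


def run_electrode_pipeline(config: RunConfig) -> ElectrodeReport:
    """Layer curves for controls plus electrode mapping for an implant.

    All pixel-level extraction runs on the raw (unresampled) volumes: the
    per-subject normalized frame -- anchored to the layer tip and fusion
    landmarks -- is what places different brains in a common space, so no
    intensity resampling is needed (and thin structures stay crisp).
    """
    cc = config.cohort
    controls = []
    for i in range(cc.n_control):
        ss = sc.subject_seed(cc.master_seed, i)
        seed = int(ss.generate_state(1)[0])
        vol, truth = sc.generate_brain_volume(cc, seed, subject_id=f"C{i:02d}")
        controls.append(sc.Subject(vol, truth))
    if len(controls) < 2:
        raise ValueError("need >= 2 control subjects for the layer-curve band")

    # implanted subject: control geometry + electrode rods
    ss = sc.subject_seed(cc.master_seed, _TEMPLATE_SPAWN_KEY + 1)
    vol, truth = sc.generate_brain_volume(cc, int(ss.generate_state(1)[0]), subject_id="implant")
    layout = sc.default_cannula_layout(cc)
    tip_depth = config.electrode_tip_depth_frac * cc.grid_shape[1]
    implant_vol, implant_truth = sc.insert_electrodes(
        vol, truth, layout, tip_depth, electrode_intensity=cc.electrode_intensity
    )

    curves = []
    for subject in controls:
        lm = al.detect_anatomical_landmarks(subject.volume)
        frame = el.frame_from_landmarks(lm, side="right")
        curves.append(el.extract_layer_curves(subject.volume, frame))

    lm = al.detect_anatomical_landmarks(implant_vol)
    frame = el.frame_from_landmarks(lm, side="right")
    implant_curves = el.extract_layer_curves(implant_vol, frame)

    electrodes = el.detect_electrode_tips(implant_vol)
    tips_norm = (
        el.normalize_points(electrodes.tips_2d(), frame)
        if len(electrodes)
        else np.empty((0, 2))
    )
    match = el.match_cannula(electrodes.tips_2d(), layout) if len(electrodes) >= 2 else None
    if match is not None:
        by_det = {j: lab for lab, j in match.assignment.items()}
        electrodes.labels = [by_det.get(j) for j in range(len(electrodes))]
    band = _band_check(curves, implant_curves)

    metadata = {
        "master_seed": config.master_seed,
        "n_control": cc.n_control,
        "n_electrodes_inserted": len(layout.occupied),
        "n_electrodes_detected": len(electrodes),
        "match_residual": None if match is None else match.residual,
    }
    report = ElectrodeReport(
        curves=curves, implant_curves=implant_curves, electrodes=electrodes,
        tips_normalized=tips_norm, match=match, band_check=band, metadata=metadata,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


@dataclass
class ThetaReport:
    offsets: tp.PhaseOffsetMatrix
    table: pd.DataFrame
    metadata: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.offsets.offsets).to_csv(
            out / "offsets.csv", index=False, float_format="%.10g"
        )
        self.table.to_csv(out / "offsets_by_channel.csv", index=False, float_format="%.10g")
        (out / "metadata.json").write_text(json.dumps(self.metadata, indent=1, sort_keys=True))


def run_theta_pipeline(
    config: RunConfig, electrode_report: ElectrodeReport | None = None
) -> ThetaReport:
    """Synthesize a session and estimate the pairwise theta offsets.

    When an electrode report is given, channel k is joined with the k-th
    detected electrode (sorted anterior to posterior), giving the
    offset-vs-location table of the normalized-frame map.
    """
    ss = np.random.SeedSequence(config.master_seed, spawn_key=(_TEMPLATE_SPAWN_KEY + 2,))
    lfp, speed = sc.generate_lfp_session(config.theta, seed=int(ss.generate_state(1)[0]))
    result = tp.pairwise_theta_offsets(lfp, speed)
    rel = result.relative_to_reference()
    table = pd.DataFrame({"channel": np.arange(result.n_channels), "offset_rad": rel})
    if electrode_report is not None and len(electrode_report.electrodes) >= result.n_channels:
        tips = electrode_report.tips_normalized[: result.n_channels]
        table["ap_norm"] = tips[:, 0]
        table["ml_norm"] = tips[:, 1]
    metadata = {
        "master_seed": config.master_seed,
        "theta_freq": config.theta.theta_freq,
        "snr": None if np.isinf(config.theta.snr) else config.theta.snr,
        "duration": config.theta.duration,
        "n_periods": len(result.period_durations),
        "numtaps": tp.design_theta_bandpass(tp.FilterSpec()).numtaps,
    }
    report = ThetaReport(offsets=result, table=table, metadata=metadata)
    if config.out_dir:
        report.write(config.out_dir)
    return report
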