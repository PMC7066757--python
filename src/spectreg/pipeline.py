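"""End-to-end orchestration: preprocess -> register -> analyze -> validate.

The in-memory entry point is :func:`process_cohort`, which takes pre/post
scan pairs, runs intra-subject affine registration per subject, registers
every subject to a designated reference (affine + B-spline), concatenates
the transforms, normalizes uptake, and produces per-subject difference maps
and the cohort aggregate map in reference space together with the DSC and
landmark validation report.

:func:`run_preprocess` / :func:`run_full_pipeline` are the disk-based
counterparts driven by a tabular cohort manifest; each subject is isolated
so one corrupt dataset never invalidates the others, and every output
directory carries a provenance record (config snapshot, seeds, version).
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

from . import __version__ as _version
from .analysis import (
    DEFAULT_ROI_DIMS,
    DEFAULT_ROI_OFFSET_MM,
    AggregateMap,
    DifferenceMap,
    aggregate_map,
    build_normalization_roi,
    difference_map,
    normalize_uptake,
)
from .image import (
    PairedScan,
    VolumetricImage,
    read_paired_scan,
    reflect_sagittal,
    resample,
    write_image,
    write_landmarks,
)
from .preprocess import (
    DEFAULT_BONE_LOW_HU,
    DEFAULT_MARGIN_MM,
    DEFAULT_PROSTHESIS_LOW_HU,
    VOI_LANDMARKS,
    BoneMask,
    build_voi,
    crop,
    segment_bone,
)
from .registration import (
    RegistrationConfig,
    register_inter,
    register_intra,
    resample_moving,
)
from .transforms import AffineTransform, compose, save_transform
from .validation import (
    LandmarkError,
    StatTestReport,
    compare_dsc_prepost,
    dice,
    landmark_error,
)

__all__ = [
    "PipelineSubject",
    "SubjectReport",
    "CohortOutcome",
    "default_config",
    "load_config",
    "preprocess_scan",
    "process_cohort",
    "run_preprocess",
    "run_full_pipeline",
]

log = logging.getLogger("spectreg")

TARGET_SPACING = (0.98, 0.98, 3.0)


def default_config() -> dict:
    """Full pipeline configuration; registration sections hold the tuned defaults."""
    return {
        "preprocess": {
            "target_spacing": list(TARGET_SPACING),
            "margin_mm": list(DEFAULT_MARGIN_MM),
            "bone_low_hu": DEFAULT_BONE_LOW_HU,
            "prosthesis_low_hu": DEFAULT_PROSTHESIS_LOW_HU,
        },
        "affine": RegistrationConfig.affine_defaults().to_dict(),
        "bspline": RegistrationConfig.bspline_defaults().to_dict(),
        "analysis": {
            "roi_dims": list(DEFAULT_ROI_DIMS),
            "roi_offset_mm": DEFAULT_ROI_OFFSET_MM,
        },
        "pipeline": {"bone": "femur", "seed": 0},
    }


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and an override mapping."""
    cfg = default_config()

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        with open(path) as fh:
            merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        merge(cfg, overrides)
    return cfg


def _registration_config(section: dict) -> RegistrationConfig:
    d = dict(section)
    for key in ("smoothing_factors", "grid_spacing_voxels", "grid_multipliers", "clip_percentiles"):
        if key in d and d[key] is not None:
            d[key] = tuple(tuple(v) if isinstance(v, (list, tuple)) else v for v in d[key]) \
                if key in ("smoothing_factors", "grid_multipliers") else tuple(d[key])
    return RegistrationConfig(**d)


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess_scan(scan: PairedScan, target_spacing=TARGET_SPACING) -> PairedScan:
    """Resample both modalities to the common grid and enforce left laterality."""
    ct = resample(scan.ct, target_spacing, "linear")
    spect = resample(scan.spect, target_spacing, "linear")
    out = dataclasses.replace(scan, ct=ct, spect=spect)
    return reflect_sagittal(out)


# ---------------------------------------------------------------------------
# In-memory cohort processing


@dataclass
class PipelineSubject:
    subject_id: str
    preop: PairedScan
    postop: PairedScan
    is_reference: bool = False
    resolution_class: str = ""


@dataclass
class SubjectReport:
    subject_id: str
    bone: str
    dsc_pre: float
    dsc_post: float
    landmark_error: LandmarkError | None
    dsc_inter_pre: float = float("nan")
    dsc_inter_post: float = float("nan")
    landmark_error_inter: LandmarkError | None = None
    error: str = ""

    def rows(self) -> list[dict]:
        base = {
            "subject": self.subject_id,
            "bone": self.bone,
            "dsc_pre": self.dsc_pre,
            "dsc_post": self.dsc_post,
            "dsc_inter_pre": self.dsc_inter_pre,
            "dsc_inter_post": self.dsc_inter_post,
            "error": self.error,
        }
        if self.landmark_error is None:
            return [base]
        return [{**base, **row} for row in self.landmark_error.table()]


@dataclass
class CohortOutcome:
    aggregate: AggregateMap | None
    difference_maps: list[DifferenceMap]
    reports: list[SubjectReport]
    wilcoxon: StatTestReport | None
    reference_id: str
    reference_grid: VolumetricImage | None
    transforms: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            rows.extend(r.rows())
        return pd.DataFrame(rows)


def _mask_image(mask: BoneMask) -> VolumetricImage:
    return VolumetricImage(mask.mask.astype(float), mask.spacing, mask.origin, "SPECT")


def _grid_like(mask: BoneMask) -> VolumetricImage:
    return VolumetricImage(
        np.zeros(mask.shape, dtype=np.float32), mask.spacing, mask.origin, "SPECT"
    )


def warp_mask(mask: BoneMask, transform, grid: VolumetricImage) -> BoneMask:
    """Binary mask pulled onto ``grid`` through ``transform`` (nearest neighbour)."""
    warped = resample_moving(_mask_image(mask), transform, grid, "nearest")
    return BoneMask(
        np.asarray(warped.voxels) > 0.5, grid.spacing, grid.origin,
        bone=mask.bone, prosthesis_excluded=mask.prosthesis_excluded,
    )


def _validity(moving: VolumetricImage, transform, grid: VolumetricImage) -> np.ndarray:
    ones = VolumetricImage(
        np.ones(moving.shape, dtype=np.float32), moving.spacing, moving.origin, "SPECT"
    )
    return np.asarray(resample_moving(ones, transform, grid, "linear").voxels) > 0.5


def _intra_validation(intra, postop, preop, bone) -> tuple[float, float, LandmarkError]:
    fixed_bm = intra.extras["fixed_bone_mask"]
    moving_bm = intra.extras["moving_bone_mask"]
    grid = _grid_like(fixed_bm)
    identity = AffineTransform.identity()
    dsc_pre = dice(fixed_bm, warp_mask(moving_bm, identity, grid)).dsc
    dsc_post = dice(fixed_bm, warp_mask(moving_bm, intra.transform, grid)).dsc
    names = [n for n in VOI_LANDMARKS[bone] if n in preop.landmarks and n in postop.landmarks]
    mapped = preop.landmarks.subset(names).map(intra.transform.inverse().apply)
    lerr = landmark_error(postop.landmarks.subset(names), mapped, postop.ct.spacing, names)
    return dsc_pre, dsc_post, lerr


def process_cohort(
    subjects,
    bone: str = "femur",
    config_affine: RegistrationConfig | None = None,
    config_bspline: RegistrationConfig | None = None,
    roi_dims=DEFAULT_ROI_DIMS,
    roi_offset_mm: float = DEFAULT_ROI_OFFSET_MM,
    preprocess: bool = True,
    target_spacing=TARGET_SPACING,
    run_inter: bool = True,
) -> CohortOutcome:
    """Run the full workflow over an in-memory cohort.

    ``subjects`` is a sequence of objects with ``subject_id``, ``preop``,
    ``postop`` and ``is_reference`` attributes.  With a single subject the
    inter-subject step is skipped and the difference map stays in that
    subject's own space.
    """
    config_affine = config_affine or RegistrationConfig.affine_defaults()
    config_bspline = config_bspline or RegistrationConfig.bspline_defaults()
    subjects = list(subjects)
    if not subjects:
        raise ValueError("empty cohort")
    notes: list[str] = []
    reference = next((s for s in subjects if getattr(s, "is_reference", False)), subjects[0])

    processed: dict[str, dict] = {}
    reports: list[SubjectReport] = []
    for i, subj in enumerate(subjects):
        sid = subj.subject_id
        t_start = time.time()
        try:
            pre = preprocess_scan(subj.preop, target_spacing) if preprocess else subj.preop
            post = preprocess_scan(subj.postop, target_spacing) if preprocess else subj.postop
            cfg = dataclasses.replace(config_affine, seed=config_affine.seed + i)
            intra = register_intra(post, pre, bone, cfg)
            dsc_pre, dsc_post, lerr = _intra_validation(intra, post, pre, bone)
            roi_post = build_normalization_roi(
                post.landmarks["FKC"], post.spect, roi_dims, roi_offset_mm
            )
            post_norm = normalize_uptake(post.spect, roi_post)
            roi_pre = build_normalization_roi(
                pre.landmarks["FKC"], pre.spect, roi_dims, roi_offset_mm
            )
            pre_norm = normalize_uptake(pre.spect, roi_pre)
            processed[sid] = {
                "pre": pre,
                "post": post,
                "intra": intra,
                "post_norm": post_norm,
                "pre_norm": pre_norm,
                "normalization_means": {
                    "pre_roi_mean": float(np.asarray(pre.spect.voxels)[roi_pre.slices].mean()),
                    "post_roi_mean": float(np.asarray(post.spect.voxels)[roi_post.slices].mean()),
                },
            }
            reports.append(SubjectReport(sid, bone, dsc_pre, dsc_post, lerr))
            log.info("intra %s done in %.1fs (DSC %.3f -> %.3f)", sid, time.time() - t_start,
                     dsc_pre, dsc_post)
        except Exception as exc:
            log.warning("subject %s failed: %s", sid, exc)
            reports.append(
                SubjectReport(sid, bone, float("nan"), float("nan"), None, error=str(exc))
            )

    ok_ids = list(processed)
    if not ok_ids:
        return CohortOutcome(None, [], reports, None, reference.subject_id, None,
                             notes=["all subjects failed"])

    transforms: dict[str, dict] = {sid: {"intra": processed[sid]["intra"].transform}
                                   for sid in ok_ids}

    # --- reference space and inter-subject step ---
    ref_id = reference.subject_id if reference.subject_id in processed else ok_ids[0]
    ref_post = processed[ref_id]["post"]
    voi_ref = build_voi(ref_post.landmarks, bone, ref_post.ct)
    ref_grid = crop(ref_post.ct, voi_ref)
    single = len(ok_ids) == 1 or not run_inter
    if single:
        notes.append("inter-subject step skipped (single subject or disabled)")

    dmaps: list[DifferenceMap] = []
    for j, sid in enumerate(ok_ids):
        entry = processed[sid]
        t_intra = entry["intra"].transform
        if sid == ref_id or single:
            t_inter = AffineTransform.identity()
        else:
            cfg_a = dataclasses.replace(config_affine, seed=config_affine.seed + 100 + j)
            cfg_b = dataclasses.replace(config_bspline, seed=config_bspline.seed + 100 + j)
            inter = register_inter(ref_post, entry["post"], bone, cfg_a, cfg_b)
            t_inter = inter.transform
            rep = next(r for r in reports if r.subject_id == sid)
            ref_bm = inter.extras["fixed_bone_mask"]
            rep.dsc_inter_pre = dice(
                ref_bm, warp_mask(inter.extras["moving_bone_mask"],
                                  AffineTransform.identity(), ref_grid)
            ).dsc
            rep.dsc_inter_post = dice(
                ref_bm, warp_mask(inter.extras["moving_bone_mask"], t_inter, ref_grid)
            ).dsc
            names = [n for n in VOI_LANDMARKS[bone] if n in entry["post"].landmarks]
            # inter transform maps reference space into the subject's post space
            mapped = entry["post"].landmarks.subset(names).map(
                lambda p: _numeric_inverse(t_inter, p)
            )
            rep.landmark_error_inter = landmark_error(
                ref_post.landmarks.subset(names), mapped, ref_grid.spacing, names
            )
        transforms[sid]["inter"] = t_inter
        full = compose(t_inter, t_intra)
        post_in_ref = resample_moving(entry["post_norm"], t_inter, ref_grid, "linear")
        pre_in_ref = resample_moving(entry["pre_norm"], full, ref_grid, "linear")
        valid = _validity(entry["post_norm"], t_inter, ref_grid) & _validity(
            entry["pre_norm"], full, ref_grid
        )
        dmaps.append(
            difference_map(
                post_in_ref, pre_in_ref, sid, valid,
                provenance=entry["normalization_means"],
            )
        )

    agg = aggregate_map(dmaps)
    intra_ok = [r for r in reports if not r.error]
    wil = None
    if len(intra_ok) >= 5:
        wil = compare_dsc_prepost(
            [r.dsc_pre for r in intra_ok], [r.dsc_post for r in intra_ok]
        )
    else:
        notes.append("fewer than 5 subjects; paired DSC test not run")
    return CohortOutcome(agg, dmaps, reports, wil, ref_id, ref_grid, transforms, notes)


def _numeric_inverse(transform, points, iterations: int = 30):
    """Invert an arbitrary (smooth) transform by fixed-point iteration."""
    if isinstance(transform, AffineTransform):
        return transform.inverse().apply(points)
    y = np.atleast_2d(np.asarray(points, dtype=float))
    x = y.copy()
    for _ in range(iterations):
        x = x + (y - transform.apply(x))
    return x if np.asarray(points).ndim > 1 else x[0]


# ---------------------------------------------------------------------------
# Manifest-driven disk pipeline


def _read_manifest(manifest) -> pd.DataFrame:
    if isinstance(manifest, pd.DataFrame):
        df = manifest.copy()
    else:
        df = pd.read_csv(manifest, sep=None, engine="python")
    required = {"subject_id", "timepoint", "ct", "spect", "landmarks", "laterality"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    if "reference" not in df.columns:
        df["reference"] = 0
    if "resolution_class" not in df.columns:
        df["resolution_class"] = ""
    return df


def _load_subjects(df: pd.DataFrame) -> tuple[list[PipelineSubject], list[dict]]:
    subjects, failures = [], []
    for sid, group in df.groupby("subject_id", sort=True):
        try:
            scans = {}
            for _, row in group.iterrows():
                scans[row["timepoint"]] = read_paired_scan(
                    row["ct"], row["spect"], row["landmarks"],
                    laterality=row["laterality"], timepoint=row["timepoint"],
                    subject_id=str(sid),
                )
            if "preop" not in scans or "postop" not in scans:
                raise ValueError(f"subject {sid} needs both preop and postop rows")
            subjects.append(
                PipelineSubject(
                    str(sid), scans["preop"], scans["postop"],
                    is_reference=bool(group["reference"].max()),
                    resolution_class=str(group["resolution_class"].iloc[0]),
                )
            )
        except Exception as exc:
            log.warning("subject %s skipped: %s", sid, exc)
            failures.append({"subject": str(sid), "error": str(exc)})
    refs = [s for s in subjects if s.is_reference]
    if len(refs) > 1:
        raise ValueError("manifest designates more than one reference subject")
    return subjects, failures


def _provenance(config: dict, extra: dict | None = None) -> dict:
    return {
        "software": f"spectreg {_version}",
        "config": config,
        **(extra or {}),
    }


def run_preprocess(manifest, out_dir, config: dict | None = None) -> dict:
    """Resample, reflect, build VOIs and bone masks for every manifest subject.

    Outputs one directory per subject/timepoint with the resampled pair,
    landmarks, per-bone VOI JSON, bone-mask NIfTI and a sidecar log; a
    failing subject is skipped and recorded, the run continues.
    """
    config = config or default_config()
    pp = config["preprocess"]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects, failures = _load_subjects(_read_manifest(manifest))
    done = []
    for subj in subjects:
        try:
            for tp, scan in (("preop", subj.preop), ("postop", subj.postop)):
                scan = preprocess_scan(scan, tuple(pp["target_spacing"]))
                d = out_dir / subj.subject_id / tp
                d.mkdir(parents=True, exist_ok=True)
                write_image(scan.ct, d / "ct.nii.gz")
                write_image(scan.spect, d / "spect.nii.gz")
                write_landmarks(scan.landmarks, d / "landmarks.txt")
                for bone in VOI_LANDMARKS:
                    voi = build_voi(scan.landmarks, bone, scan.ct, tuple(pp["margin_mm"]))
                    ct_voi = crop(scan.ct, voi)
                    bm = segment_bone(
                        ct_voi, pp["bone_low_hu"], pp["prosthesis_low_hu"], bone=bone
                    )
                    write_image(_mask_image(bm), d / f"mask_{bone}.nii.gz")
                    (d / f"voi_{bone}.json").write_text(json.dumps({
                        "bone": bone, "lower": list(voi.lower), "upper": list(voi.upper),
                        "margin_mm": list(pp["margin_mm"]),
                        "bone_low_hu": pp["bone_low_hu"],
                        "prosthesis_low_hu": pp["prosthesis_low_hu"],
                        "prosthesis_excluded": bm.prosthesis_excluded,
                    }, indent=1))
            done.append(subj.subject_id)
        except Exception as exc:
            log.warning("preprocess failed for %s: %s", subj.subject_id, exc)
            failures.append({"subject": subj.subject_id, "error": str(exc)})
    status = {"done": done, "failures": failures, "partial": bool(failures)}
    (out_dir / "provenance.json").write_text(
        json.dumps(_provenance(config, {"status": status}), indent=1)
    )
    return status


def run_full_pipeline(manifest, out_dir, config: dict | None = None) -> CohortOutcome:
    """Manifest in, aggregate map + validation report out."""
    config = config or default_config()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects, failures = _load_subjects(_read_manifest(manifest))
    if not subjects:
        raise ValueError("no usable subjects in the manifest")
    pipe = config["pipeline"]
    outcome = process_cohort(
        subjects,
        bone=pipe.get("bone", "femur"),
        config_affine=_registration_config(config["affine"]),
        config_bspline=_registration_config(config["bspline"]),
        roi_dims=tuple(config["analysis"]["roi_dims"]),
        roi_offset_mm=config["analysis"]["roi_offset_mm"],
        target_spacing=tuple(config["preprocess"]["target_spacing"]),
    )
    grid = outcome.reference_grid
    if outcome.aggregate is not None and grid is not None:
        for name, vol in (
            ("aggregate_mean", outcome.aggregate.mean),
            ("aggregate_count", outcome.aggregate.count.astype(float)),
            ("aggregate_std", outcome.aggregate.std),
        ):
            write_image(
                VolumetricImage(vol, grid.spacing, grid.origin, "SPECT"),
                out_dir / f"{name}.nii.gz",
            )
        for dmap in outcome.difference_maps:
            d = out_dir / dmap.subject_id
            d.mkdir(exist_ok=True)
            write_image(
                VolumetricImage(dmap.values, dmap.spacing, dmap.origin, "SPECT"),
                d / "difference_ref.nii.gz",
            )
    for sid, tdict in outcome.transforms.items():
        d = out_dir / sid
        d.mkdir(exist_ok=True)
        for kind, t in tdict.items():
            save_transform(t, d / f"transform_{kind}.json")
    outcome.report_frame().to_csv(out_dir / "report.csv", index=False)
    stats = {
        "wilcoxon_dsc_prepost": dataclasses.asdict(outcome.wilcoxon)
        if outcome.wilcoxon else None,
        "notes": outcome.notes,
        "failures": failures,
        "reference": outcome.reference_id,
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(_provenance(config, {"results": stats}), indent=1)
    )
    return outcome
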