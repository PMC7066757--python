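"""Quantitative registration validation.

Two pass/fail criteria mirror the platform's validation battery:

* volumetric agreement — Dice similarity coefficient between the fixed and
  registered bone masks, with DSC > 80% counting as success;
* landmark agreement — per-axis voxel-index differences between
  corresponding anatomical landmarks, which must stay within (2; 2; 0)
  voxels so that both points fall in the same SPECT voxel (the SPECT/CT
  resolution ratio is about 5 in-plane but the slice thickness already
  matches).

Cohort-level statistics (Wilcoxon signed-rank for pre- vs post-registration
DSC, Mann-Whitney U for the resolution effect, Kolmogorov-Smirnov normality
pre-check) delegate to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .image import LandmarkSet
from .preprocess import BoneMask

__all__ = [
    "DSCResult",
    "LandmarkError",
    "StatTestReport",
    "DSC_SUCCESS_THRESHOLD",
    "LANDMARK_THRESHOLD_VOXELS",
    "PRIMARY_LANDMARKS",
    "dice",
    "landmark_error",
    "compare_dsc_prepost",
    "compare_dsc_by_resolution",
    "export_overlays",
]

DSC_SUCCESS_THRESHOLD = 0.80
LANDMARK_THRESHOLD_VOXELS = (2, 2, 0)
#: Landmarks reported in the primary validation table.
PRIMARY_LANDMARKS = ("FKC", "FME", "FLE", "FTP")


@dataclass
class DSCResult:
    dsc: float
    size_a: int
    size_b: int
    overlap: int
    context: dict = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return self.dsc > DSC_SUCCESS_THRESHOLD


def dice(mask_a: BoneMask, mask_b: BoneMask, context: dict | None = None) -> DSCResult:
    """Exact integer-count DSC = 2|A∩B| / (|A|+|B|); 0 when both masks are empty."""
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"grid mismatch: {mask_a.shape} vs {mask_b.shape}")
    a = mask_a.mask
    b = mask_b.mask
    na, nb = int(a.sum()), int(b.sum())
    inter = int((a & b).sum())
    dsc = 0.0 if na + nb == 0 else 2.0 * inter / (na + nb)
    return DSCResult(dsc, na, nb, inter, context or {})


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5)


@dataclass
class LandmarkError:
    """Per-landmark per-axis voxel-index differences and the (2, 2, 0) verdict."""

    names: tuple
    voxel_differences: np.ndarray  # (n, 3) nonnegative integers
    world_differences_mm: np.ndarray  # (n, 3) signed mm
    threshold: tuple = LANDMARK_THRESHOLD_VOXELS

    @property
    def per_landmark_pass(self) -> np.ndarray:
        return np.all(self.voxel_differences <= np.asarray(self.threshold), axis=1)

    @property
    def passed(self) -> bool:
        return bool(np.all(self.per_landmark_pass))

    def table(self) -> list[dict]:
        rows = []
        for i, name in enumerate(self.names):
            rows.append(
                {
                    "landmark": name,
                    "dx_voxels": int(self.voxel_differences[i, 0]),
                    "dy_voxels": int(self.voxel_differences[i, 1]),
                    "dz_voxels": int(self.voxel_differences[i, 2]),
                    "pass": bool(self.per_landmark_pass[i]),
                    "primary": name in PRIMARY_LANDMARKS,
                }
            )
        return rows


def landmark_error(
    reference_landmarks: LandmarkSet,
    mapped_landmarks: LandmarkSet,
    spacing,
    names=None,
) -> LandmarkError:
    """Voxel-index landmark differences |Δ| / spacing, rounded half away from zero."""
    names = tuple(names) if names is not None else tuple(reference_landmarks.names())
    for n in names:
        if n not in reference_landmarks or n not in mapped_landmarks:
            raise ValueError(f"landmark {n} missing from one of the sets")
    ref = reference_landmarks.as_array(names)
    mapped = mapped_landmarks.as_array(names)
    world = mapped - ref
    voxels = _round_half_away(world / np.asarray(spacing, dtype=float)).astype(int)
    return LandmarkError(names, voxels, world)


@dataclass
class StatTestReport:
    test: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05
    normality_p: float | None = None
    note: str = ""


def compare_dsc_prepost(pre_values, post_values, alpha: float = 0.05) -> StatTestReport:
    """Two-sided Wilcoxon signed-rank test of registration's effect on DSC.

    A Kolmogorov-Smirnov normality check of the paired differences is
    reported alongside (the non-parametric test is used regardless).  All-tied
    pairs give p = 1 by convention.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"paired lists must have equal length ({len(pre)} vs {len(post)})")
    diffs = post - pre
    if np.std(diffs) > 0:
        z = (diffs - diffs.mean()) / diffs.std(ddof=1)
        normality_p = float(stats.kstest(z, "norm").pvalue)
    else:
        normality_p = None
    if np.all(diffs == 0):
        return StatTestReport(
            "wilcoxon_signed_rank", 0.0, 1.0, False, alpha, normality_p,
            note="all paired differences are zero; no effect detectable",
        )
    res = stats.wilcoxon(post, pre, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    return StatTestReport(
        "wilcoxon_signed_rank", float(res.statistic), p, p < alpha, alpha, normality_p
    )


def compare_dsc_by_resolution(group_same, group_diff, alpha: float = 0.05) -> StatTestReport:
    """Two-sided Mann-Whitney U test of a CT-resolution effect on DSC."""
    a = np.asarray(group_same, dtype=float)
    b = np.asarray(group_diff, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    return StatTestReport("mann_whitney_u", float(res.statistic), p, p < alpha, alpha)


def export_overlays(fixed, registered, slices, out_prefix) -> list[str]:
    """Checkerboard and contour-overlay PNGs for qualitative slice review.

    ``slices`` are axial (z) indices; returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fvol = np.asarray(fixed.voxels, dtype=float)
    rvol = np.asarray(registered.voxels, dtype=float)
    if fvol.shape != rvol.shape:
        raise ValueError("fixed and registered images must share one grid")
    paths = []
    tiles = 8
    for z in slices:
        f = fvol[:, :, z]
        r = rvol[:, :, z]
        tx = (np.arange(f.shape[0])[:, None] // max(1, f.shape[0] // tiles)) % 2
        ty = (np.arange(f.shape[1])[None, :] // max(1, f.shape[1] // tiles)) % 2
        checker = np.where((tx + ty) % 2 == 0, f, r)
        fig, axes = plt.subplots(1, 2, figsize=(8, 4))
        axes[0].imshow(checker.T, cmap="gray", origin="lower")
        axes[0].set_title(f"checkerboard z={z}")
        axes[1].imshow(f.T, cmap="gray", origin="lower")
        level = 0.5 * (f.max() + f.min())
        axes[1].contour(r.T, levels=[level], colors="r", linewidths=0.8)
        axes[1].set_title(f"contour overlay z={z}")
        for ax in axes:
            ax.axis("off")
        path = f"{out_prefix}_z{z}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
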