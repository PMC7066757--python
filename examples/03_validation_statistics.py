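"""The quantitative validation toolkit on small, fully transparent inputs.

Shows the exact-count Dice similarity coefficient, the (2, 2, 0)-voxel
landmark rule at the common 0.98 x 0.98 x 3 mm grid, and the two cohort
statistics (Wilcoxon signed-rank for pre- vs post-registration DSC,
Mann-Whitney U for a CT-resolution effect) with p-values small enough to
check against hand enumeration.
"""

import numpy as np

from spectreg import LandmarkSet, dice, landmark_error
from spectreg.preprocess import BoneMask
from spectreg.validation import compare_dsc_by_resolution, compare_dsc_prepost

# --- Dice on a constructed 3x3x3 pair: |A|=4, |B|=6, overlap 3 ---
a = np.zeros((3, 3, 3), dtype=bool)
b = np.zeros((3, 3, 3), dtype=bool)
a.ravel()[[0, 1, 2, 3]] = True
b.ravel()[[1, 2, 3, 10, 11, 12]] = True
res = dice(BoneMask(a, (1, 1, 1), (0, 0, 0)), BoneMask(b, (1, 1, 1), (0, 0, 0)))
print(f"DSC = 2*{res.overlap}/({res.size_a}+{res.size_b}) = {res.dsc}")

# --- landmark rule: 1.96 mm in-plane is exactly 2 voxels (pass boundary),
#     3 mm out-of-plane is 1 slice (fail: the z threshold is 0) ---
ref = LandmarkSet({"FKC": (50.0, 50.0, 100.0)})
spacing = (0.98, 0.98, 3.0)
for offset, label in (((1.96, 0, 0), "1.96 mm in x"), ((0, 0, 3.0), "3 mm in z")):
    mapped = LandmarkSet({"FKC": np.add((50.0, 50.0, 100.0), offset)})
    err = landmark_error(ref, mapped, spacing)
    print(f"{label:>14}: voxel diff {err.voxel_differences[0].tolist()} -> "
          f"{'pass' if err.passed else 'fail'}")

# --- exact small-sample statistics ---
pre = [0.70, 0.72, 0.74, 0.76, 0.78, 0.80]
post = [p + d for p, d in zip(pre, [0.10, 0.11, 0.12, 0.13, 0.14, 0.15])]
rep = compare_dsc_prepost(pre, post)
print(f"\nWilcoxon, 6 uniform improvements: p = {rep.p_value:.5f} "
      f"(= 2/64, every sign pattern enumerated)")

rep = compare_dsc_by_resolution([0.90, 0.91, 0.92, 0.93], [0.70, 0.71, 0.72, 0.73])
print(f"Mann-Whitney, fully separated 4 vs 4: p = {rep.p_value:.5f} "
      f"(= 2/70, all C(8,4) rank splits enumerated)")
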