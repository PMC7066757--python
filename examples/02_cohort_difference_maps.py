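"""Cohort workflow: normalize uptake, map differences into reference space.

Generates a small synthetic cohort in which every subject carries the same
post-operative-only uptake focus below the tibial implant, runs the full
workflow (intra-subject affine, inter-subject affine + B-spline to the
reference subject, uptake normalization, voxel-wise post-minus-pre
difference, cohort averaging), and checks that the aggregate map peaks at
the injected focus.
"""

import numpy as np

from spectreg import PhantomSpec, RegistrationConfig
from spectreg.phantom import default_postop_hotspot, generate_cohort
from spectreg.pipeline import process_cohort

spec = PhantomSpec(shape=(80, 80, 48), spacing=(1.96, 1.96, 5.0))
cohort = generate_cohort(3, spec, seed=4)
print(f"cohort of {len(cohort)} subjects; reference: "
      f"{next(s.subject_id for s in cohort if s.is_reference)}")

outcome = process_cohort(
    cohort,
    config_affine=RegistrationConfig.affine_defaults(seed=0, max_iterations=400),
    config_bspline=RegistrationConfig.bspline_defaults(seed=0, max_iterations=150),
)

print("\nper-subject validation (femur):")
for rep in outcome.reports:
    print(f"  {rep.subject_id}: DSC {100 * rep.dsc_pre:.1f} % -> "
          f"{100 * rep.dsc_post:.1f} %, landmarks "
          f"{'pass' if rep.landmark_error.passed else 'FAIL'}")

agg = outcome.aggregate
grid = outcome.reference_grid
peak_idx = np.unravel_index(np.argmax(agg.mean), agg.mean.shape)
peak_world = grid.index_to_world(np.asarray(peak_idx, dtype=float))
truth = np.asarray(default_postop_hotspot(spec)[0])
print(f"\naggregate map peak: {np.round(peak_world, 1)} mm "
      f"(value {agg.mean.max():.2f} normalized units)")
print(f"injected focus:     {np.round(truth, 1)} mm")
print(f"localization error: {np.round(np.abs(peak_world - truth), 1)} mm "
      f"(one SPECT voxel is 4.79 mm)")
print("\npositive aggregate values mark where osteoblastic activity rose"
      "\nafter surgery, averaged over the co-registered cohort")
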