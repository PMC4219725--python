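"""Spill-in-free VOI erosion on a single brain phantom.

Builds one healthy-volunteer phantom at 2-mm resolution, derives the
35%-of-maximum GM/WM masks, erodes each away from the other tissue using
the 8-mm scanner PSF (tau = 0.05), and compares how well the raw and
eroded white-matter VOIs recover the programmed WM uptake.
"""

from petquant import (PSFModel, PhantomSpec, binarize_tissue_map,
                      compute_suv, make_phantom_subject, spillin_free_pair,
                      voi_mean)

s = make_phantom_subject(PhantomSpec(seed=0), 0, "HV")
rec = s.record
print(f"subject {rec.subject_id}: age {rec.age}, dose {rec.injected_dose_mbq}"
      f" MBq, weight {rec.body_weight_kg} kg")

gm = binarize_tissue_map(s.gm_prob, 0.35, region_name="gm")
wm = binarize_tissue_map(s.wm_prob, 0.35, region_name="wm")
psf = PSFModel(fwhm_mm=8.0)
pair = spillin_free_pair(gm, wm, psf, tau=0.05)
print(f"GM mask: {gm.voxel_count} -> {pair.gm_free.voxel_count} voxels "
      f"after erosion")
print(f"WM mask: {wm.voxel_count} -> {pair.wm_free.voxel_count} voxels "
      f"after erosion")

suv = compute_suv(s.pet_activity, rec.injected_dose_mbq, rec.body_weight_kg)
truth = s.true_uptake["wm"] * s.calibration
raw, _ = voi_mean(suv, wm)
free, _ = voi_mean(suv, pair.wm_free)
print(f"\nprogrammed WM SUV (truth): {truth:.4f}")
print(f"raw WM VOI mean:           {raw:.4f}  "
      f"(bias {100 * (raw / truth - 1):+.2f}%)")
print(f"spill-in-free WM VOI mean: {free:.4f}  "
      f"(bias {100 * (free / truth - 1):+.2f}%)")
print("\nThe raw VOI overshoots because the 8-mm PSF spills gray-matter "
      "signal\ninto boundary WM voxels; discarding voxels with a blurred-GM "
      "fraction\nabove 5% removes most of that contamination.")
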