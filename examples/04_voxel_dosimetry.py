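"""Run the full measurement chain and compute MIRD voxel absorbed doses.

Segmentation -> registration -> calibration against co-imaged standards ->
per-voxel activity at biopsy time -> cumulated activity (extrapolated to
infinity under physical Ra-223 decay) -> D = A_tilde * Delta * phi / mass,
with the 50-um bone-tissue interface as its own compartment.
"""

from dardose import PhantomConfig, RA223_CHAIN, delta_constant
from dardose.pipeline import run_pipeline, train_default_classifier, truth_dose_reference

print(f"Delta (chain mean alpha energy): {delta_constant(RA223_CHAIN):.3e} J/(Bq*s)")

cfg = PhantomConfig(seed=11)
clf = train_default_classifier(cfg, n_sections=6, seed=5000)
res = run_pipeline(cfg, clf=clf)

print(f"calibration: floored {res.activity.n_floored} sub-background voxels; "
      f"detection limit {res.activity.limit_of_detection_bq * 1e6:.1f} uBq/voxel")
print()
print(res.stats[["compartment", "n_voxels", "mean_dose_gy", "max_dose_gy",
                 "sd_dose_gy"]].to_string(index=False,
                                          float_format=lambda v: f"{v:.1f}"))

ref_dose, ref_masks = truth_dose_reference(cfg, res.truth)
ref_mean = ref_dose.gy_per_voxel[ref_masks.interface].mean()
est_mean = res.stats.set_index("compartment").loc["interface", "mean_dose_gy"]
print()
print(f"interface mean dose, pipeline vs truth: {est_mean:.1f} vs {ref_mean:.1f} Gy "
      f"({100 * (est_mean / ref_mean - 1):+.1f}%)")
# The interface receives by far the highest dose; the soft-tissue core the
# lowest - the spatial pattern that voxel-level dosimetry exists to expose
# and that a whole-sample average would erase.
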