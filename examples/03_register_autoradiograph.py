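"""Recover the histology-to-DAR misalignment by mutual information.

The autoradiograph is acquired in its own frame, off by an unknown
similarity transform (scale, rotation, translation).  A coarse estimate
from foreground moments is refined by maximizing the mutual information of
the joint intensity histogram; the phantom knows the true transform, so the
recovery error can be measured exactly.
"""

import numpy as np

from dardose import PhantomConfig, make_phantom
from dardose.pipeline import truth_labelmap
from dardose.registration import coarse_register, downsample_to_dar, refine_register

cfg = PhantomConfig(seed=11)  # default misalignment: scale 1.02, 5 deg, (6, -3) px
_, dar, truth = make_phantom(cfg)

hist_down = downsample_to_dar(truth_labelmap(truth, cfg.hist_pitch_um).labels,
                              cfg.hist_pitch_um, cfg.dar_pitch_um, labels=True)
init = coarse_register(hist_down, dar)
res = refine_register(hist_down, dar, init)

t, tt = res.transform, truth.transform_true
p = np.array([tt.center])
disp = float(np.linalg.norm(t.map_points(p) - tt.map_points(p)))

print(f"true transform   : scale {tt.scale:.4f}, {tt.rotation_deg:+.2f} deg, "
      f"t=({tt.translation[0]:+.2f}, {tt.translation[1]:+.2f}) px")
print(f"coarse estimate  : scale {init.scale:.4f}, {init.rotation_deg:+.2f} deg")
print(f"refined estimate : scale {t.scale:.4f}, {t.rotation_deg:+.2f} deg, "
      f"t=({t.translation[0]:+.2f}, {t.translation[1]:+.2f}) px")
print(f"mutual information: {res.mi_initial:.3f} -> {res.mi_final:.3f} nats "
      f"({res.n_evaluations} evaluations)")
print(f"residual displacement at section center: {disp:.3f} DAR px "
      f"(= {disp * cfg.dar_pitch_um:.1f} um)")
# Sub-0.5-px residuals keep the 50-um interface band aligned to well within
# one DAR voxel, which is what the compartment dosimetry requires.
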