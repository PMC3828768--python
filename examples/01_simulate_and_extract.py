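"""Generate a synthetic TI recording and extract its ROI traces.

Renders a short frame stack in which the abdomen region's brightness follows
the planted ventilatory oscillation, then recovers that oscillation by plain
ROI averaging and compares it to the ground truth.
"""

import numpy as np

from tipulse import SynthConfig, default_rois, generate_frames, roi_brightness

cfg = SynthConfig.preset("ti_visual", seed=1, duration_s=60.0,
                         stimulus_times_s=(30.0,))
stack, truth = generate_frames(cfg)
rois = default_rois()

abdomen = roi_brightness(stack, rois["abdomen"])
control = roi_brightness(stack, rois["control"])

corr = np.corrcoef(abdomen.values, truth.r_clean)[0, 1]
print(f"frames: {stack.n_frames} at {stack.fps} fps, {stack.shape[0]}x{stack.shape[1]} px")
print(f"abdomen trace vs planted oscillation: r = {corr:.4f}")
print(f"control-region sd: {control.values.std():.3f} grey levels")
# The abdomen trace reproduces the planted ventilation almost exactly, while
# the control region carries nothing but residual pixel noise.
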