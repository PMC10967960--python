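"""Segment the vitreous/RPE and compute VIT/RPE relative intensity.

VIT/RPE — mean vitreous intensity over mean RPE intensity per B-scan,
averaged over the stack — is a gain-independent proxy for vitreous
turbidity.  Here we recover a phantom's designed ratio from noisy frames.
"""

import numpy as np

from octvit import PhantomConfig, eye_vit_rpe, generate_phantom, segment_stack

config = PhantomConfig(n_frames=4, seed=2)
stack, truth = generate_phantom(config)

segs = segment_stack(stack)
seg = segs[0]
err = np.sqrt(np.mean((seg.ilm_row - truth.ilm_rows[0]) ** 2.0))
print(f"frame 0 ILM located at mean row {seg.ilm_row.mean():.1f} "
      f"(RMS error vs truth: {err:.2f} rows)")

result = eye_vit_rpe(stack, segs)
print(f"per-frame VIT/RPE: {[round(r, 4) for r in result.per_frame_ratio]}")
print(f"eye mean VIT/RPE:  {result.eye_mean:.4f}  (designed {truth.designed_vit_rpe:.4f})")
# The eye mean sits within ~0.005 of the designed ratio; residual offset
# comes from speckle clipping and the bright blobs included in the vitreous.
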