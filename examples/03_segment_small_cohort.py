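"""Train a small multi-atlas model on synthetic phantoms and segment a test scan.

Runs the whole chain at a reduced 32³ scale so it finishes in under a minute:
template building, atlas warping, per-atlas voxel networks, correlation-ranked
selection, weighted score fusion and the posterior-probability threshold.
"""

import dataclasses

from hippoatlas import (
    PhantomSpec,
    SegmentationConfig,
    build_template,
    dice,
    make_phantom,
    normalize_intensity,
    segment_subject,
    train_atlases,
    volume_of,
)

base = PhantomSpec(
    shape=(32, 32, 32), volume_left_mm3=700.0, volume_right_mm3=700.0,
    noise_sd=0.01, bias_amplitude=0.0, max_translation=1.0, max_rotation_deg=2.0,
)
train = [make_phantom(dataclasses.replace(base, seed=s)) for s in (21, 22, 23)]
test_scan, truth_left, truth_right = make_phantom(dataclasses.replace(base, seed=77))

template = build_template([normalize_intensity(v) for v, _, _ in train], iterations=1)
config = SegmentationConfig(m_atlases=3, cv_repeats=1, apply_bias_correction=False, nonlinear_iterations=3)
entries, context = train_atlases(
    [v for v, _, _ in train],
    {"left": [m for _, m, _ in train], "right": [m for _, _, m in train]},
    template, config, seed=0,
)

result = segment_subject(test_scan, entries, template, context, config)
for side, res, truth in (("left", result.left, truth_left), ("right", result.right, truth_right)):
    warped_truth = result.mask_to_template(truth, template.volume.shape)
    print(
        f"{side:5s}: volume {res.volume_mm3:6.1f} mm³ (truth {volume_of(truth):6.1f}), "
        f"dice {dice(res.mask, warped_truth):.3f}, threshold t = {res.threshold.threshold:.3f} "
        f"(S={res.threshold.sensitivity:.3f}, s={res.threshold.specificity:.3f}, P(H)={res.threshold.prior:.3f})"
    )

# The threshold t is the posterior probability that a voxel flagged by the
# fused classifier really is hippocampus; only voxels scoring above it are
# kept. Dice measures overlap with the generator's ground truth in template
# space. At this toy scale (700 mm³ structures on a 32³ grid) Dice around
# 0.6 is expected; the full 64³ configuration reaches 0.9.
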