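"""Sample specular-free patches from a liver and build feature vectors.

The liver is divided into random non-overlapping square patches; patches
whose mean luminance leaves the liver's interquartile range (glare or
shadow) are rejected and redrawn. Each patch becomes Lab colour
histograms plus per-channel local-binary-pattern texture histograms.
"""

import numpy as np

from steatolens import FeatureConfig, build_features, calibrate_image
from steatolens.features import ClinicalScaler
from steatolens.patching import plan_patches, sample_patches
from steatolens.synthetic import GeneratorConfig, render_case, sample_donor

cfg = GeneratorConfig()
donor, hs = sample_donor(cfg, np.random.default_rng(1), hs=20.0)
case = render_case(cfg, donor, hs, seed=21)

lab = calibrate_image(case.image, case.card_roi)
plan = plan_patches(int(case.mask.sum()))
patches = sample_patches(case.mask, lab, plan, seed=0)

print(f"liver area {case.mask.sum()} px -> plan: {plan.n_patches} patches of {plan.side}px")
print(f"accepted {len(patches)} patches; mean L* range "
      f"{min(p.mean_L for p in patches):.1f}-{max(p.mean_L for p in patches):.1f}")

img_cfg = FeatureConfig()
vec = build_features(patches[0], img_cfg).vector
print(f"image-feature vector length: {vec.size} (3x32 colour + 3x256 LBP bins)")

clin_cfg = FeatureConfig(use_clinical=True)
scaler = ClinicalScaler.fit([donor])
vec = build_features(patches[0], clin_cfg, donor=donor, scaler=scaler).vector
print(f"with standardized donor biochemistry appended: {vec.size}")
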