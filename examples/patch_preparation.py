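"""Prepare training patches from an annotated ROI, two ways.

Shows the two patching protocols — dense 51x51 crops on a stride of 7 with a
center-pixel class label (patch-classification training) and non-overlapping
256x256 tiles with one-hot per-pixel labels (fully-convolutional training) —
plus rotation augmentation and tile recombination.
"""

import numpy as np

from henorm import patches, synthetic

params = synthetic.SceneParams(height=300, width=300, n_nuclei=40)
scene = synthetic.generate_scene(params, seed=5)
image = synthetic.render(scene)

center = patches.extract_center_patches(image, scene.labels, size=51, stride=7)
print(f"center-label patches from 300x300 at 51/7: {len(center)} "
      f"(formula: {patches.center_patch_count(300, 300, 51, 7)})")
labels = [p.center_label for p in center]
print("center-class counts (background, boundary, nuclei):",
      [labels.count(k) for k in range(3)])

aug = patches.augment_rotations(center[0])
print(f"rotation augmentation: 1 patch -> {len(aug)} "
      f"(center label unchanged: {set(p.center_label for p in aug)})")

dense = patches.extract_dense_patches(image, scene.labels, size=128)
print(f"dense 128x128 tiles: {len(dense)} "
      f"(trailing 44-pixel strips discarded)")
probs, covered = patches.recombine(dense, (300, 300))
restored = np.argmax(probs, axis=-1)
print("recombination restores labels on covered area:",
      bool(np.array_equal(restored[covered], scene.labels[covered].astype(int))))
print(f"covered fraction: {covered.mean():.3f}")
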