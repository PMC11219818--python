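"""Generate a small synthetic wheat-field dataset and inspect it.

Scenes are textured backgrounds with oriented, awn-streaked elliptical
spikes of mixed maturity under a random illumination gain; each spike's
tight bounding box is the ground truth.  The dataset lands on disk as
PNG images + YOLO-txt labels + a JSON manifest, and is a pure function
of (config, seed).
"""

import tempfile
from pathlib import Path

from spikedet.synthetic import (
    FieldSceneConfig, SplitSpec, generate_dataset, generate_scene,
    split_dataset,
)

cfg = FieldSceneConfig(image_size=352)  # field-like density: ~43 spikes/scene
scene = generate_scene(cfg, seed=0)
print(f"one scene: {scene.pixels.shape[1]}x{scene.pixels.shape[0]} px, "
      f"{len(scene.boxes)} spikes")
b = scene.boxes[0]
print(f"first box: ({b.x_min:.1f}, {b.y_min:.1f})-({b.x_max:.1f}, {b.y_max:.1f}) "
      f"-> {b.width:.0f}x{b.height:.0f} px")

out = Path(tempfile.mkdtemp()) / "wheat_demo"
manifest = generate_dataset(cfg, n_images=12, out_dir=out, seed=1)
print(f"\ndataset: {manifest['n_images']} images, {manifest['n_boxes']} boxes "
      f"-> {out}")

train, val, test = split_dataset(manifest["n_images"], SplitSpec(seed=1))
print(f"8:1:1 split sizes: {len(train)}/{len(val)}/{len(test)} "
      "(train gets floor(0.8 n), val floor(0.1 n), test the remainder)")
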