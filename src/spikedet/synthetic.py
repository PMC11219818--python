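"""Synthetic wheat-field scenes with ground-truth boxes.

Scenes emulate the statistical character of field imagery of wheat
canopies — dense, partially occluded, elongated spikes of mixed maturity
photographed under variable illumination — without claiming visual
realism.  A scene is a textured soil/canopy background (smoothed
low-frequency colour field plus pixel grain) onto which oriented ellipses
are painted; each ellipse carries awn-like streak texture along its major
axis and a colour drawn from a green-to-gold maturity palette, the whole
frame is scaled by a per-scene illumination gain, and a tight axis-aligned
box around each rendered spike is recorded.

Everything is a pure function of (config, seed): the same seed reproduces
bit-identical pixels and boxes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import ellipse as _ellipse

from .metrics import GroundTruthBox, load_yolo_boxes, save_yolo_boxes

__all__ = [
    "FieldSceneConfig", "AnnotatedImage", "SplitSpec", "EASY_PRESET",
    "generate_scene", "generate_dataset", "split_dataset",
    "read_yolo_labels", "write_yolo_labels", "load_dataset_manifest",
    "load_corpus_stats", "export_coco",
]

# green -> gold maturity palette (RGB, 0-255)
_DEFAULT_PALETTE = (
    (96, 128, 48), (128, 144, 56), (168, 156, 64),
    (196, 168, 80), (214, 182, 96), (226, 198, 120),
)


@dataclass
class FieldSceneConfig:
    """Statistical description of one synthetic scene.

    ``spike_count`` is (mean, dispersion) of a negative-binomial count
    (dispersion -> inf degenerates to Poisson); ``spike_axes`` gives pixel
    ranges for the ellipse semi-major and semi-minor axes;
    ``occlusion_fraction`` caps the allowed overlap of a new spike's box
    with already-placed boxes; ``illumination_gain`` is the range of the
    per-scene brightness multiplier.
    """

    image_size: int = 352
    spike_count: tuple = (43.0, 20.0)           # mean, dispersion (field-like density)
    spike_axes: tuple = ((14.0, 26.0), (5.0, 10.0))  # (major, minor) semi-axis ranges
    orientation: tuple = (-math.pi / 2, math.pi / 2)
    occlusion_fraction: float = 0.3
    illumination_gain: tuple = (0.6, 1.3)
    maturity_palette: tuple = _DEFAULT_PALETTE
    background_texture: tuple = (8, 18.0)       # coarse grid cells, grain sigma
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size too small")
        if not 0 <= self.occlusion_fraction < 1:
            raise ValueError("occlusion_fraction must be in [0, 1)")


# large, sparse, unoccluded spikes: the easy regime used for smoke training
EASY_PRESET = FieldSceneConfig(
    image_size=160,
    spike_count=(5.0, 1e9),
    spike_axes=((16.0, 26.0), (9.0, 15.0)),
    orientation=(-0.5, 0.5),
    occlusion_fraction=0.0,
    illumination_gain=(0.85, 1.15),
    background_texture=(6, 8.0),
)


@dataclass
class AnnotatedImage:
    pixels: np.ndarray              # (H, W, 3) uint8
    boxes: list
    image_id: str = ""
    mask: np.ndarray | None = None  # (H, W) bool spike-foreground mask
    warnings: list = field(default_factory=list)


@dataclass
class SplitSpec:
    ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if len(self.ratios) != 3 or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must be three values summing to 1")


def _background(size: int, spec: tuple, rng: np.random.Generator) -> np.ndarray:
    cells, grain = spec
    base = np.array((88, 96, 52), dtype=np.float64)  # soil/canopy tone
    coarse = rng.normal(0, 28.0, (int(cells), int(cells), 3))
    reps = math.ceil(size / cells)
    low = np.kron(coarse, np.ones((reps, reps, 1)))[:size, :size]
    # cheap separable smoothing of the blocky low-frequency field
    k = max(3, reps // 2 * 2 + 1)
    kernel = np.ones(k) / k
    for ax in (0, 1):
        low = np.apply_along_axis(
            lambda m: np.convolve(m, kernel, mode="same"), ax, low)
    img = base + low + rng.normal(0, grain, (size, size, 3))
    return img


def _sample_count(mean: float, dispersion: float, rng) -> int:
    if mean <= 0:
        return 0
    if dispersion >= 1e8:
        return int(rng.poisson(mean))
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _box_overlap_frac(box, others) -> float:
    x0, y0, x1, y1 = box
    area = (x1 - x0) * (y1 - y0)
    worst = 0.0
    for o in others:
        iw = min(x1, o[2]) - max(x0, o[0])
        ih = min(y1, o[3]) - max(y0, o[1])
        if iw > 0 and ih > 0:
            worst = max(worst, iw * ih / area)
    return worst


def generate_scene(cfg: FieldSceneConfig, seed: int | None = None) -> AnnotatedImage:
    """Render one scene; deterministic given (cfg, seed)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    size = cfg.image_size
    img = _background(size, cfg.background_texture, rng)

    target = _sample_count(*cfg.spike_count, rng)
    mask = np.zeros((size, size), dtype=bool)
    boxes: list[GroundTruthBox] = []
    corners: list[tuple] = []
    warnings: list[str] = []
    attempts_per_spike = 25
    (amin, amax), (bmin, bmax) = cfg.spike_axes
    placed = 0
    for _ in range(target):
        ok = False
        for _ in range(attempts_per_spike):
            a = rng.uniform(amin, amax)
            b = rng.uniform(bmin, max(bmin, min(bmax, a)))
            theta = rng.uniform(*cfg.orientation)
            # tight bounds of a rotated ellipse
            half_w = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
            half_h = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
            cx = rng.uniform(half_w + 1, size - half_w - 1)
            cy = rng.uniform(half_h + 1, size - half_h - 1)
            box = (cx - half_w, cy - half_h, cx + half_w, cy + half_h)
            if cfg.occlusion_fraction == 0 and corners:
                if _box_overlap_frac(box, corners) > 0:
                    continue
            elif corners and _box_overlap_frac(box, corners) > cfg.occlusion_fraction:
                continue
            ok = True
            break
        if not ok:
            continue
        color = np.array(cfg.maturity_palette[rng.integers(len(cfg.maturity_palette))],
                         dtype=np.float64)
        color = color * rng.uniform(0.85, 1.15)
        # skimage's ellipse rotation is counter-clockwise in (row, col)
        rr, cc = _ellipse(cy, cx, b, a, shape=(size, size), rotation=-theta)
        # awn-like streaks: brightness stripes along the major axis
        u = (cc - cx) * math.cos(theta) + (rr - cy) * math.sin(theta)
        v = -(cc - cx) * math.sin(theta) + (rr - cy) * math.cos(theta)
        stripes = 0.75 + 0.25 * np.cos(v * (2 * math.pi / max(2.0, b / 1.5)))
        tip = 1.0 - 0.25 * (np.abs(u) / max(a, 1e-6)) ** 2
        shade = (stripes * tip)[:, None]
        img[rr, cc] = color * shade + rng.normal(0, 6.0, (len(rr), 3))
        mask[rr, cc] = True
        boxes.append(GroundTruthBox(*box, class_id=0))
        corners.append(box)
        placed += 1
    if placed < target:
        warnings.append(f"placed {placed}/{target} spikes (density infeasible)")

    gain = rng.uniform(*cfg.illumination_gain)
    # mild vignette-style gradient: one side of the field catches more light
    gx = np.linspace(-1, 1, size)[None, :] * rng.uniform(-0.15, 0.15)
    gy = np.linspace(-1, 1, size)[:, None] * rng.uniform(-0.15, 0.15)
    img = img * gain * (1.0 + gx + gy)[:, :, None]
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedImage(pixels=pixels, boxes=boxes, mask=mask,
                          warnings=warnings)


def generate_dataset(cfg: FieldSceneConfig, n_images: int, out_dir,
                     seed: int = 0) -> dict:
    """Write PNG images, YOLO-txt labels and a JSON manifest; returns manifest."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(entropy=seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_images)]
    entries = []
    total_boxes = 0
    for i, s in enumerate(child_seeds):
        scene = generate_scene(cfg, seed=s)
        image_id = f"scene_{i:05d}"
        scene.image_id = image_id
        iio.imwrite(out / "images" / f"{image_id}.png", scene.pixels)
        write_yolo_labels(out / "labels" / f"{image_id}.txt", scene.boxes,
                          cfg.image_size)
        entries.append({"image_id": image_id, "n_boxes": len(scene.boxes),
                        "seed": s, "warnings": scene.warnings})
        total_boxes += len(scene.boxes)
    manifest = {
        "config": {**asdict(cfg)},
        "seed": seed,
        "n_images": n_images,
        "n_boxes": total_boxes,
        "image_size": cfg.image_size,
        "images": entries,
    }
    text = json.dumps(manifest, indent=2, default=list)
    (out / "manifest.json").write_text(text)
    return json.loads(text)  # JSON-canonical form, identical to a later load


def load_dataset_manifest(dataset_dir) -> dict:
    return json.loads((Path(dataset_dir) / "manifest.json").read_text())


def export_coco(dataset_dir, out_path=None) -> dict:
    """Export a generated dataset's annotations as COCO-dialect JSON."""
    root = Path(dataset_dir)
    manifest = load_dataset_manifest(root)
    size = manifest["image_size"]
    images, annotations = [], []
    ann_id = 1
    for i, e in enumerate(manifest["images"]):
        images.append({"id": i, "file_name": f"images/{e['image_id']}.png",
                       "width": size, "height": size})
        for b in read_yolo_labels(root / "labels" / f"{e['image_id']}.txt", size):
            annotations.append({
                "id": ann_id, "image_id": i, "category_id": b.class_id,
                "bbox": [b.x_min, b.y_min, b.width, b.height],
                "area": b.area, "iscrowd": 0})
            ann_id += 1
    doc = {"images": images, "annotations": annotations,
           "categories": [{"id": 0, "name": "wheat-spike"}]}
    if out_path is not None:
        Path(out_path).write_text(json.dumps(doc))
    return doc


def load_corpus_stats() -> dict:
    """Published image/box statistics of the merged real wheat-spike corpus.

    The corpus itself (field photographs from the public wheat-head
    detection collections) is not distributed; only its printed summary
    statistics ship with the package, as the reference point for the 8:1:1
    split convention.
    """
    from importlib import resources

    return json.loads(resources.files("spikedet.data")
                      .joinpath("wheat_corpus_stats.json").read_text())


def split_dataset(n: int, spec: SplitSpec | None = None):
    """Seeded 8:1:1-style partition into (train, val, test) id tuples.

    Sizes are ``floor(r_train*n)``, ``floor(r_val*n)`` and the remainder —
    the floor rule that maps 11,451 items to the canonical 9160/1145/1146.
    """
    spec = spec or SplitSpec()
    if n < 3:
        raise ValueError("need at least 3 items to split")
    n_train = int(math.floor(spec.ratios[0] * n))
    n_val = int(math.floor(spec.ratios[1] * n))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train = tuple(int(i) for i in perm[:n_train])
    val = tuple(int(i) for i in perm[n_train:n_train + n_val])
    test = tuple(int(i) for i in perm[n_train + n_val:])
    return train, val, test


def read_yolo_labels(path, image_size) -> list:
    """Read a YOLO-txt label file into pixel-space ground-truth boxes."""
    return load_yolo_boxes(path, image_size, kind="gt")


def write_yolo_labels(path, boxes, image_size):
    save_yolo_boxes(path, boxes, image_size)
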