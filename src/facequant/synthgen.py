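"""Synthetic labeled face images with ground-truth landmarks.

Real screening imagery of the kind this pipeline targets is private
clinical data, so the package ships a parametric generator instead.  Each
face is a grayscale template (elliptical head, eye/nose/mouth primitives)
rendered consistently with a jittered 68-point landmark set.  "Case"
faces additionally receive a constant intensity elevation of height
``effect_amplitude`` inside a configurable set of facial areas (default:
nose and both cheeks), mimicking a class whose discriminative signal
concentrates in specific regions.  I.i.d. Gaussian pixel noise of
standard deviation ``noise_sd`` is added everywhere.

Rasters are float arrays with nominal range [0, 1]; they are not clipped,
so the planted regional contrast is exactly ``effect_amplitude`` in
expectation (and exactly, pixel for pixel, when noise is zero).

The module also generates saliency heatmaps directly (Gaussian blobs of
configurable peak weight per region), so the quantification stages are
testable without a trained network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import faceregions
from .faceregions import REGION_NAMES
from .landmarks import LandmarkSet, template_landmarks

CASE = "case"
CONTROL = "control"

DEFAULT_EFFECT_REGIONS = frozenset({"nose", "left-cheek", "right-cheek"})


@dataclass(frozen=True)
class SynthFaceParams:
    """Generator settings; the defaults define the reference study conditions."""

    image_size: int = 224
    n_case: int = 100
    n_control: int = 200
    effect_regions: frozenset = DEFAULT_EFFECT_REGIONS
    effect_amplitude: float = 0.5
    noise_sd: float = 0.05
    landmark_jitter: float = 0.01  # per-point noise sd, fraction of image size
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64 (facial regions degenerate below)")
        if self.n_case < 0 or self.n_control < 0:
            raise ValueError("n_case and n_control must be >= 0")
        if not 0.0 <= self.effect_amplitude <= 1.0:
            raise ValueError("effect_amplitude must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.effect_regions) - set(REGION_NAMES)
        if unknown:
            raise ValueError(f"unknown effect regions: {sorted(unknown)}")
        object.__setattr__(self, "effect_regions", frozenset(self.effect_regions))


@dataclass
class SynthDataset:
    images: list  # (H, W) float32 rasters
    landmarks: list  # LandmarkSet per image
    labels: list  # CASE / CONTROL per image
    manifest: pd.DataFrame  # columns: id, label, seed

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "SynthDataset":
        idx = list(idx)
        return SynthDataset(
            images=[self.images[i] for i in idx],
            landmarks=[self.landmarks[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            manifest=self.manifest.iloc[idx].reset_index(drop=True),
        )

    def label_array(self) -> np.ndarray:
        """Labels as integers: case = 1, control = 0."""
        return np.array([1 if l == CASE else 0 for l in self.labels], dtype=np.int64)


def jittered_landmarks(params: SynthFaceParams, rng: np.random.Generator) -> LandmarkSet:
    base = template_landmarks(params.image_size)
    s = params.image_size
    pts = base.points.copy()
    center = pts.mean(axis=0)
    # small similarity perturbation: +-3% scale, +-2 degrees, +-1% translation
    scale = 1.0 + rng.uniform(-0.03, 0.03)
    theta = rng.uniform(-np.pi / 90, np.pi / 90)
    shift = rng.uniform(-0.01, 0.01, size=2) * s
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    pts = (pts - center) @ rot.T * scale + center + shift
    pts += rng.normal(0.0, params.landmark_jitter * s, size=pts.shape)
    pts = np.clip(pts, 0, s - 1)
    return LandmarkSet(points=pts, image_size=s)


def _render_base_face(landmarks: LandmarkSet) -> np.ndarray:
    """Template face raster: bright elliptical head on dark background with
    darker eye/nose/mouth primitives placed at the landmark positions."""
    s = landmarks.image_size
    ys, xs = np.mgrid[0:s, 0:s].astype(float)
    img = np.full((s, s), 0.15, dtype=np.float64)

    pts = landmarks.points
    jaw = pts[0:17]
    cx, cy = pts.mean(axis=0)
    half_w = (jaw[:, 0].max() - jaw[:, 0].min()) / 2
    top = pts[17:27][:, 1].min() - 0.25 * half_w  # forehead above the brows
    bottom = jaw[:, 1].max()
    cy_head = (top + bottom) / 2
    half_h = (bottom - top) / 2
    head = ((xs - cx) / half_w) ** 2 + ((ys - cy_head) / half_h) ** 2 <= 1.0
    img[head] = 0.65

    def dark_disc(center, radius, value):
        d2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2
        img[d2 <= radius**2] = value

    eye_r = pts[36:42].mean(axis=0)
    eye_l = pts[42:48].mean(axis=0)
    eye_rad = np.linalg.norm(pts[39] - pts[36]) / 2
    dark_disc(eye_r, eye_rad, 0.25)
    dark_disc(eye_l, eye_rad, 0.25)
    dark_disc(pts[33], 0.8 * eye_rad, 0.45)  # nose tip shading
    mouth_c = pts[48:60].mean(axis=0)
    mouth_w = np.linalg.norm(pts[54] - pts[48]) / 2
    in_mouth = ((xs - mouth_c[0]) / mouth_w) ** 2 + ((ys - mouth_c[1]) / (0.4 * mouth_w)) ** 2 <= 1
    img[in_mouth] = 0.35
    return img


def generate_face(params: SynthFaceParams, label: str, rng: np.random.Generator):
    """One synthetic face raster plus its ground-truth landmarks.

    For ``label == "case"`` a constant elevation of ``effect_amplitude``
    is added inside the effect-region polygons of this face's own
    partition; noise is added everywhere for both classes.
    """
    if label not in (CASE, CONTROL):
        raise ValueError(f"label must be {CASE!r} or {CONTROL!r}")
    landmarks = jittered_landmarks(params, rng)
    img = _render_base_face(landmarks)
    if label == CASE and params.effect_amplitude > 0 and params.effect_regions:
        partition = faceregions.partition_face(landmarks)
        for name in sorted(params.effect_regions):
            m = faceregions.region_mask(partition, name).mask
            img[m] += params.effect_amplitude
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return img.astype(np.float32), landmarks


def generate_dataset(params: SynthFaceParams) -> SynthDataset:
    """n_case + n_control faces, bit-reproducible from ``params.seed``."""
    root = np.random.SeedSequence(params.seed)
    n = params.n_case + params.n_control
    children = root.spawn(n)
    labels = [CASE] * params.n_case + [CONTROL] * params.n_control
    images, lms, records = [], [], []
    for i, (label, ss) in enumerate(zip(labels, children)):
        face_seed = int(ss.generate_state(1)[0] % (2**31))
        img, lm = generate_face(params, label, np.random.default_rng(face_seed))
        images.append(img)
        lms.append(lm)
        records.append({"id": f"img{i:05d}", "label": label, "seed": face_seed})
    return SynthDataset(images=images, landmarks=lms, labels=labels,
                        manifest=pd.DataFrame(records, columns=["id", "label", "seed"]))


def generate_heatmap(landmarks: LandmarkSet, region_weights: dict,
                     blob_scale: float | None = None, seed: int = 0,
                     background_noise: float = 0.0,
                     partition: faceregions.RegionPartition | None = None) -> np.ndarray:
    """Synthetic saliency map: one Gaussian blob per weighted region.

    Each blob is centered at a point inside the region (its polygon's
    representative point), has peak equal to the region's weight and
    width ``blob_scale`` (default 6% of the image size).  Optional
    nonnegative background noise is added before re-normalizing the
    maximum to at most 1.
    """
    unknown = set(region_weights) - set(REGION_NAMES)
    if unknown:
        raise KeyError(f"unknown region names: {sorted(unknown)}")
    for name, w in region_weights.items():
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"weight for {name!r} must lie in [0, 1]")
    s = landmarks.image_size
    if blob_scale is None:
        blob_scale = 0.06 * s
    heat = np.zeros((s, s))
    if any(w > 0 for w in region_weights.values()):
        if partition is None:
            partition = faceregions.partition_face(landmarks)
        ys, xs = np.mgrid[0:s, 0:s].astype(float)
        for name in sorted(region_weights):
            w = region_weights[name]
            if w <= 0:
                continue
            p = partition.polygon(name).representative_point()
            d2 = (xs - p.x) ** 2 + (ys - p.y) ** 2
            heat = np.maximum(heat, w * np.exp(-d2 / (2 * blob_scale**2)))
    if background_noise > 0:
        rng = np.random.default_rng(seed)
        heat = heat + rng.uniform(0, background_noise, size=heat.shape)
    peak = heat.max()
    if peak > 1.0:
        heat = heat / peak
    return heat


def split_dataset(dataset: SynthDataset, train_fraction: float = 0.7, seed: int = 0):
    """Global shuffled train/test split: train size = floor(fraction * N).

    The split is over the merged pool, not stratified per class, so the
    realized class balance of each side fluctuates around the pool's.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    return dataset.subset(order[:n_train]), dataset.subset(order[n_train:])


def save_dataset(dataset: SynthDataset, out_dir) -> None:
    """Write PNG images, per-image landmark JSON sidecars and a CSV manifest."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for img, lm, rec in zip(dataset.images, dataset.landmarks, dataset.manifest.to_dict("records")):
        stem = rec["id"]
        png = out / f"{stem}.png"
        iio.imwrite(png, (np.clip(img, 0, 1) * 255).astype(np.uint8))
        (out / f"{stem}.json").write_text(json.dumps(lm.to_dict()))
        paths.append(png.name)
    manifest = dataset.manifest.assign(path=paths)
    manifest.to_csv(out / "manifest.csv", index=False)


def load_dataset(in_dir) -> SynthDataset:
    import imageio.v3 as iio

    root = Path(in_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    images, lms, labels = [], [], []
    for rec in manifest.to_dict("records"):
        images.append(iio.imread(root / rec["path"]).astype(np.float32) / 255.0)
        lms.append(LandmarkSet.from_dict(json.loads((root / f"{rec['id']}.json").read_text())))
        labels.append(rec["label"])
    return SynthDataset(images=images, landmarks=lms, labels=labels,
                        manifest=manifest[["id", "label", "seed"]].copy())
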