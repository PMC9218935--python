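"""Synthetic segmentation datasets, augmentation, and raster/manifest I/O.

Three regimes emulate the shape statistics of common binary medical
segmentation tasks so that training and evaluation need no download:

* ``mass`` (128x128 default): one soft-edged bright ellipse with a textured
  interior on a noisy, optionally shaded background — mammographic
  mass-like.
* ``nodule`` (64x64 default): one to three small bright discs on a dark
  noisy background — lung-nodule-like.
* ``ventricle`` (256x256 default): a bright blood pool inside a
  medium-bright myocardial ring, yielding two nested ground-truth masks
  (endocardium = inner disc, epicardium = outer disc), trained and
  evaluated independently.

Masks are the exact generating geometry. All objects are placed inside the
inscribed circle of the canvas so that 45-degree rotations never clip
foreground. Generation is a pure function of the configuration and seed.

Images are stored as 8- or 16-bit grayscale PNG, masks as {0,255} PNG, and
the dataset layout is described by a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SyntheticConfig",
    "DatasetManifest",
    "ManifestRecord",
    "SegmentationPair",
    "generate",
    "generate_arrays",
    "augment",
    "augment_pair",
    "read_pair",
    "write_pair",
    "read_mask",
    "load_arrays",
]

REGIME_DEFAULTS = {
    "mass": dict(image_size=128, object_count_range=(1, 1), radius_range=(18, 36),
                 foreground_contrast=0.45, noise_sd=0.08, background_gradient=True),
    "nodule": dict(image_size=64, object_count_range=(1, 3), radius_range=(3, 8),
                   foreground_contrast=0.5, noise_sd=0.08, background_gradient=False),
    "ventricle": dict(image_size=256, object_count_range=(1, 1), radius_range=(24, 44),
                      foreground_contrast=0.5, noise_sd=0.06,
                      background_gradient=False),
}


@dataclass(frozen=True)
class SyntheticConfig:
    regime: str = "mass"
    n_images: int = 100
    image_size: int | None = None  # per-regime default when None
    object_count_range: tuple | None = None
    radius_range: tuple | None = None
    foreground_contrast: float | None = None
    noise_sd: float | None = None
    background_gradient: bool | None = None
    edge_width: float = 1.5  # soft-edge width in pixels; 0 = hard edge
    texture: float = 0.15  # multiplicative interior texture amplitude
    train_fraction: float = 0.7
    bit_depth: int = 8
    seed: int = 0

    def resolved(self) -> "SyntheticConfig":
        if self.regime not in REGIME_DEFAULTS:
            raise ValueError(f"unknown regime {self.regime!r}; "
                             f"known: {sorted(REGIME_DEFAULTS)}")
        d = dict(REGIME_DEFAULTS[self.regime])
        if self.image_size is not None and self.radius_range is None:
            # keep object geometry proportional when the canvas is resized
            ratio = self.image_size / d["image_size"]
            d["radius_range"] = tuple(
                max(2.0, r * ratio) for r in d["radius_range"]
            )
        fills = {k: (getattr(self, k) if getattr(self, k) is not None else v)
                 for k, v in d.items()}
        cfg = dataclasses.replace(self, **fills)
        if cfg.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if cfg.radius_range[1] >= cfg.image_size // 2 - 2:
            raise ValueError(
                f"radius_range {cfg.radius_range} does not fit in a "
                f"{cfg.image_size}px canvas (objects must stay inside the "
                "inscribed circle)"
            )
        return cfg

    @property
    def mask_names(self) -> tuple:
        return ("endocardium", "epicardium") if self.regime == "ventricle" \
            else ("mask",)


@dataclass
class ManifestRecord:
    image: str
    masks: dict
    split: str = "train"
    provenance: str = "original"


@dataclass
class DatasetManifest:
    root: Path
    records: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def split(self, tag: str) -> list:
        return [r for r in self.records if r.split == tag]

    def save(self, path=None) -> Path:
        path = Path(path) if path else Path(self.root) / "manifest.json"
        payload = {
            "meta": self.meta,
            "records": [dataclasses.asdict(r) for r in self.records],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        path = Path(path)
        payload = json.loads(path.read_text())
        return cls(root=path.parent,
                   records=[ManifestRecord(**r) for r in payload["records"]],
                   meta=payload.get("meta", {}))

    def validate(self) -> None:
        seen_splits: dict[str, str] = {}
        for r in self.records:
            paths = [r.image, *r.masks.values()]
            for p in paths:
                if not (Path(self.root) / p).exists():
                    raise FileNotFoundError(p)
            if r.image in seen_splits and seen_splits[r.image] != r.split:
                raise ValueError(f"{r.image} appears in two splits")
            seen_splits[r.image] = r.split


@dataclass
class SegmentationPair:
    image: np.ndarray  # (H, W) uint8 or uint16
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    prediction: np.ndarray | None = None  # (H, W) float in [0, 1]


# ---------------------------------------------------------------------------
# geometry helpers


def _grid(size):
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    return x + 0.5, y + 0.5


def _soft_edge(signed_dist, width):
    """1 inside (signed_dist <= 0), 0 outside, smooth over ``width`` px."""
    if width <= 0:
        return (signed_dist <= 0).astype(np.float64)
    return 1.0 / (1.0 + np.exp(signed_dist / (width / 4.0)))


def _place_center(rng, size, extent):
    """Uniform center such that the object (radius ``extent``) stays within
    the inscribed circle minus a 2 px margin."""
    max_off = size / 2.0 - 2.0 - extent
    if max_off < 0:
        raise ValueError(f"object extent {extent} too large for canvas {size}")
    while True:
        off = rng.uniform(-max_off, max_off, size=2)
        if np.hypot(*off) <= max_off:
            return size / 2.0 + off


def _smooth_noise(rng, size, scale=6.0):
    n = ndimage.gaussian_filter(rng.standard_normal((size, size)), scale)
    sd = n.std()
    return n / sd if sd > 0 else n


def _mass_sample(cfg, rng):
    s = cfg.image_size
    x, y = _grid(s)
    a = rng.uniform(*cfg.radius_range)
    b = a * rng.uniform(0.6, 1.0)
    theta = rng.uniform(0.0, np.pi)
    cx, cy = _place_center(rng, s, a)
    dx, dy = x - cx, y - cy
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    r = np.sqrt(u**2 + v**2)
    mask = (r <= 1.0).astype(np.uint8)
    fg = cfg.foreground_contrast * _soft_edge((r - 1.0) * min(a, b), cfg.edge_width)
    if cfg.texture > 0:
        fg = fg * (1.0 + cfg.texture * _smooth_noise(rng, s, 4.0))
    img = np.full((s, s), 0.25)
    if cfg.background_gradient:
        phi = rng.uniform(0.0, 2 * np.pi)
        img += 0.08 * ((x * np.cos(phi) + y * np.sin(phi)) / s)
    img += fg
    return img, {"mask": mask}


def _nodule_sample(cfg, rng):
    s = cfg.image_size
    x, y = _grid(s)
    img = np.full((s, s), 0.15)
    mask = np.zeros((s, s), dtype=np.uint8)
    lo, hi = cfg.object_count_range
    for _ in range(int(rng.integers(lo, hi + 1))):
        r0 = rng.uniform(*cfg.radius_range)
        cx, cy = _place_center(rng, s, r0)
        r = np.hypot(x - cx, y - cy) - r0
        mask |= (r <= 0).astype(np.uint8)
        img += cfg.foreground_contrast * _soft_edge(r, cfg.edge_width)
    return img, {"mask": mask}


def _ventricle_sample(cfg, rng):
    s = cfg.image_size
    x, y = _grid(s)
    r_epi = rng.uniform(*cfg.radius_range)
    r_endo = r_epi * rng.uniform(0.55, 0.75)
    cx, cy = _place_center(rng, s, r_epi)
    r = np.hypot(x - cx, y - cy)
    endo = (r <= r_endo).astype(np.uint8)
    epi = (r <= r_epi).astype(np.uint8)
    c = cfg.foreground_contrast
    img = np.full((s, s), 0.2)
    img += 0.7 * c * _soft_edge(r - r_epi, cfg.edge_width)  # myocardium ring
    img += 0.8 * c * _soft_edge(r - r_endo, cfg.edge_width)  # bright blood pool
    return img, {"endocardium": endo, "epicardium": epi}


_SAMPLERS = {"mass": _mass_sample, "nodule": _nodule_sample,
             "ventricle": _ventricle_sample}


def generate_arrays(config: SyntheticConfig):
    """Generate the dataset in memory.

    Returns ``(images, masks)`` where images is (N, 1, S, S) float32 in
    [0, 1] (already quantized to the configured bit depth) and masks maps
    each mask name to a (N, 1, S, S) uint8 array.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    sampler = _SAMPLERS[cfg.regime]
    levels = 2**cfg.bit_depth - 1
    imgs, masks = [], {k: [] for k in cfg.mask_names}
    for _ in range(cfg.n_images):
        img, ms = sampler(cfg, rng)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        img = np.clip(img, 0.0, 1.0)
        img = np.round(img * levels) / levels  # quantize as stored on disk
        imgs.append(img.astype(np.float32))
        for k in cfg.mask_names:
            masks[k].append(ms[k])
    images = np.stack(imgs)[:, None]
    return images, {k: np.stack(v)[:, None] for k, v in masks.items()}


def generate(config: SyntheticConfig, out_dir) -> DatasetManifest:
    """Generate a dataset on disk: PNG images and masks plus a JSON
    manifest with a disjoint train/test split (``train_fraction``)."""
    cfg = config.resolved()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    images, masks = generate_arrays(cfg)
    n_train = int(round(cfg.n_images * cfg.train_fraction))
    manifest = DatasetManifest(
        root=out,
        meta={"config": {**dataclasses.asdict(cfg)}, "regime": cfg.regime},
    )
    dtype = np.uint8 if cfg.bit_depth == 8 else np.uint16
    levels = 2**cfg.bit_depth - 1
    for i in range(cfg.n_images):
        img = (images[i, 0] * levels).round().astype(dtype)
        rec_masks = {}
        for k in cfg.mask_names:
            mpath = f"masks/img_{i:04d}_{k}.png"
            _write_gray((masks[k][i, 0] * 255).astype(np.uint8), out / mpath)
            rec_masks[k] = mpath
        ipath = f"images/img_{i:04d}.png"
        _write_gray(img, out / ipath)
        manifest.records.append(ManifestRecord(
            image=ipath, masks=rec_masks,
            split="train" if i < n_train else "test",
        ))
    manifest.save()
    return manifest


# ---------------------------------------------------------------------------
# raster I/O


def _write_gray(arr, path):
    if arr.dtype == np.uint16:
        im = Image.fromarray(arr)  # pillow stores uint16 as 16-bit grayscale
    else:
        im = Image.fromarray(arr.astype(np.uint8), mode="L")
    im.save(path)


def _read_gray(path):
    im = Image.open(path)
    arr = np.array(im)
    if arr.dtype == np.int32:  # 16-bit PNG decoded as mode I
        arr = arr.astype(np.uint16)
    return arr


def read_mask(path) -> np.ndarray:
    arr = _read_gray(path)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValueError(f"mask {path} is not binary (values {vals[:6]})")
    return (arr > 0).astype(np.uint8)


def read_pair(image_path, mask_path) -> SegmentationPair:
    """Read an image/mask pair; masks are stored as {0,255} and returned
    as {0,1}."""
    return SegmentationPair(image=_read_gray(image_path),
                            mask=read_mask(mask_path))


def write_pair(pair: SegmentationPair, image_path, mask_path) -> None:
    _write_gray(pair.image, image_path)
    _write_gray((pair.mask.astype(np.uint8) * 255), mask_path)


# ---------------------------------------------------------------------------
# augmentation: original + 7 clockwise 45-degree rotations + two flips


def _rotate(arr, angle_cw, order):
    if angle_cw % 90 == 0:
        return np.rot90(arr, k=-(angle_cw // 90)).copy()
    return ndimage.rotate(arr.astype(np.float64), -angle_cw, reshape=False,
                          order=order, mode="constant", cval=0.0)


AUGMENT_TAGS = ("orig", "rot45", "rot90", "rot135", "rot180", "rot225",
                "rot270", "rot315", "hflip", "vflip")


def augment_pair(image: np.ndarray, mask: np.ndarray):
    """The ten augmented versions of a square image/mask pair: the original,
    seven clockwise rotations in 45-degree steps, a horizontal and a
    vertical flip. Images are interpolated bilinearly, masks with nearest
    neighbor and re-binarized; 45-degree rotations zero-fill the corners.
    """
    if image.shape[0] != image.shape[1]:
        raise ValueError(f"augmentation requires square images, got {image.shape}")
    info = np.iinfo(image.dtype)
    out = [("orig", image.copy(), mask.copy())]
    for k in range(1, 8):
        angle = 45 * k
        img = _rotate(image, angle, order=1)
        img = np.clip(np.round(img), info.min, info.max).astype(image.dtype)
        m = (_rotate(mask, angle, order=0) >= 0.5).astype(np.uint8)
        out.append((f"rot{angle}", img, m))
    out.append(("hflip", np.fliplr(image).copy(), np.fliplr(mask).copy()))
    out.append(("vflip", np.flipud(image).copy(), np.flipud(mask).copy()))
    return out


def augment(manifest: DatasetManifest, subset: str = "train") -> DatasetManifest:
    """Expand the given split of a dataset tenfold on disk (the identical
    transform is applied to the image and every mask); other splits pass
    through unchanged. Returns a new manifest in the same root."""
    root = Path(manifest.root)
    new = DatasetManifest(root=root, meta={**manifest.meta, "augmented": subset})
    for rec in manifest.records:
        if rec.split != subset:
            new.records.append(rec)
            continue
        image = _read_gray(root / rec.image)
        masks = {k: read_mask(root / p) for k, p in rec.masks.items()}
        variants = {k: augment_pair(image, m) for k, m in masks.items()}
        n_tags = len(next(iter(variants.values())))
        for t in range(n_tags):
            tag = AUGMENT_TAGS[t]
            if tag == "orig":
                new.records.append(rec)
                continue
            stem = Path(rec.image).stem
            ipath = f"images/{stem}_{tag}.png"
            img_t = variants[next(iter(variants))][t][1]
            _write_gray(img_t, root / ipath)
            rec_masks = {}
            for k in masks:
                mpath = f"masks/{stem}_{tag}_{k}.png"
                _write_gray(variants[k][t][2] * 255, root / mpath)
                rec_masks[k] = mpath
            new.records.append(ManifestRecord(
                image=ipath, masks=rec_masks, split=subset,
                provenance="augmented",
            ))
    new.save()
    return new


# ---------------------------------------------------------------------------
# array loading for the runtime


def load_arrays(manifest: DatasetManifest, split="train", target=None):
    """Load a manifest split as float32 batch arrays: images scaled to
    [0, 1], the chosen mask (default: the record's first) as {0,1}."""
    recs = manifest.split(split)
    root = Path(manifest.root)
    xs, ys = [], []
    for r in recs:
        img = _read_gray(root / r.image)
        scale = float(np.iinfo(img.dtype).max)
        key = target or next(iter(r.masks))
        xs.append(img.astype(np.float32) / scale)
        ys.append(read_mask(root / r.masks[key]).astype(np.float32))
    if not xs:
        return (np.zeros((0, 1, 1, 1), np.float32),) * 2
    return np.stack(xs)[:, None], np.stack(ys)[:, None]
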