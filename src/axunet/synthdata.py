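"""Synthetic lesion images and the training augmentation suite.

The generator emulates the regime of endoscopic lesion benchmarks: each
sample carries 1..k smooth star-convex blobs — ellipses whose radius is
modulated by a low-order random harmonic series — rendered at low contrast
with Gaussian-blurred (fuzzy) boundaries on a textured, tissue-toned
background.  The binary mask records the blob interiors *before* blurring,
and an edge band is derived from the mask with the Canny operator, so every
sample provides image, mask and edge supervision.

Generation is fully deterministic from ``(seed, index)``.

Augmentation follows the training recipe: random rotation, horizontal and
vertical flips, random crop-and-resize and random elastic deformation are
applied identically to image, mask and edge (nearest-neighbour for the
label maps); then exactly one occlusion — cutout, coarse dropout, grid
distortion or grid dropout — is applied to the image only, so the
supervision always remains truthful.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw

from .losses import LossConfig, canny_edge_mask

__all__ = [
    "SynthConfig",
    "SegSample",
    "gen_sample",
    "augment",
    "flip_h",
    "flip_v",
    "rotate",
    "crop_resize",
    "elastic",
    "write_dataset",
    "load_dataset",
]


@dataclass
class SynthConfig:
    """Study conditions of the synthetic task.

    Defaults model low-contrast, fuzzy-edged lesions: an intensity gap of
    0.35 between lesion and background, 2-px boundary blur, and both
    low-frequency tissue texture and per-pixel noise scaled by
    ``texture_noise_sigma``.
    """

    image_size: int = 64
    lesion_count_range: tuple[int, int] = (1, 3)
    radius_range: tuple[float, float] = (0.10, 0.26)   # fraction of image
    boundary_harmonics: int = 4
    boundary_amplitude: float = 0.22
    contrast: float = 0.35
    edge_blur_sigma: float = 2.0
    texture_noise_sigma: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if self.lesion_count_range[0] < 1:
            raise ValueError("at least one lesion per image")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")


@dataclass
class SegSample:
    image: np.ndarray   # float32 [3,H,W] in [0,1]
    mask: np.ndarray    # uint8 [H,W] in {0,1}
    edge: np.ndarray    # uint8 [H,W] in {0,1}


_BASE_TINT = np.array([0.62, 0.44, 0.38], dtype=np.float32)   # tissue tone
_LESION_TINT = np.array([1.0, 0.92, 0.88], dtype=np.float32)  # slightly redder


def _draw_blob(rng: np.random.Generator, size: int, cfg: SynthConfig) -> np.ndarray:
    """Rasterize one star-convex blob as a binary mask."""
    cx, cy = rng.uniform(0.18 * size, 0.82 * size, 2)
    r = rng.uniform(*cfg.radius_range) * size
    aspect = rng.uniform(0.65, 1.45)
    tilt = rng.uniform(0.0, np.pi)
    amps = rng.uniform(0.0, cfg.boundary_amplitude, cfg.boundary_harmonics)
    phases = rng.uniform(0.0, 2 * np.pi, cfg.boundary_harmonics)
    phi = np.linspace(0.0, 2 * np.pi, 181)
    wobble = 1.0 + sum(
        a / (m + 1) * np.cos((m + 2) * phi + p)
        for m, (a, p) in enumerate(zip(amps, phases))
    )
    rad = np.maximum(r * wobble, 1.0)
    ex, ey = rad * np.cos(phi) * aspect, rad * np.sin(phi) / aspect
    x = cx + ex * np.cos(tilt) - ey * np.sin(tilt)
    y = cy + ex * np.sin(tilt) + ey * np.cos(tilt)
    rr, cc = skdraw.polygon(y, x, shape=(size, size))
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


def gen_sample(cfg: SynthConfig, index: int) -> SegSample:
    """Deterministically generate sample ``index`` under ``cfg``."""
    rng = np.random.default_rng([int(cfg.seed), int(index)])
    size = cfg.image_size
    for _ in range(100):
        k = int(rng.integers(cfg.lesion_count_range[0], cfg.lesion_count_range[1] + 1))
        mask = np.zeros((size, size), dtype=np.uint8)
        for _ in range(k):
            mask |= _draw_blob(rng, size, cfg)
        frac = mask.mean()
        if 0.0 < frac < 0.9:
            break
    else:
        raise RuntimeError("could not draw a valid mask in 100 attempts")

    # background: tissue tone + low-frequency texture + per-pixel noise
    tint = _BASE_TINT + rng.uniform(-0.06, 0.06, 3).astype(np.float32)
    lum = np.ones((size, size), dtype=np.float32)
    if cfg.texture_noise_sigma > 0:
        lowfreq = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, (size, size)), sigma=size / 8.0
        )
        lf = lowfreq.std()
        if lf > 0:
            lum += (2.0 * cfg.texture_noise_sigma / lf) * lowfreq.astype(np.float32)
    image = tint[:, None, None] * lum[None]

    # lesion: contrast offset through the blurred (fuzzy) boundary
    soft = mask.astype(np.float32)
    if cfg.edge_blur_sigma > 0:
        soft = ndimage.gaussian_filter(soft, sigma=cfg.edge_blur_sigma)
    image += cfg.contrast * soft[None] * _LESION_TINT[:, None, None]

    if cfg.texture_noise_sigma > 0:
        image += rng.normal(0.0, cfg.texture_noise_sigma, image.shape).astype(np.float32)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    edge = canny_edge_mask(mask, LossConfig())
    return SegSample(image=image, mask=mask, edge=edge)


# ----------------------------------------------------------------------
# geometric transforms (applied identically to image, mask and edge)
def flip_h(s: SegSample) -> SegSample:
    return SegSample(s.image[:, :, ::-1].copy(), s.mask[:, ::-1].copy(),
                     s.edge[:, ::-1].copy())


def flip_v(s: SegSample) -> SegSample:
    return SegSample(s.image[:, ::-1].copy(), s.mask[::-1].copy(),
                     s.edge[::-1].copy())


def rotate(s: SegSample, angle: float) -> SegSample:
    """Rotate by ``angle`` degrees; label maps use nearest-neighbour."""
    if angle % 90 == 0:
        k = int(angle // 90) % 4
        return SegSample(
            np.rot90(s.image, k, axes=(1, 2)).copy(),
            np.rot90(s.mask, k).copy(),
            np.rot90(s.edge, k).copy(),
        )
    img = np.stack([
        ndimage.rotate(c, angle, reshape=False, order=1, mode="reflect")
        for c in s.image
    ])
    msk = ndimage.rotate(s.mask, angle, reshape=False, order=0, mode="constant")
    edg = ndimage.rotate(s.edge, angle, reshape=False, order=0, mode="constant")
    return SegSample(np.clip(img, 0, 1).astype(np.float32),
                     msk.astype(np.uint8), edg.astype(np.uint8))


def crop_resize(s: SegSample, top: int, left: int, crop: int) -> SegSample:
    """Crop a ``crop``² window at (top, left) and resize back to full size."""
    size = s.mask.shape[0]
    sl = (slice(top, top + crop), slice(left, left + crop))
    ys = np.clip((np.arange(size) + 0.5) * crop / size - 0.5, 0, crop - 1)
    yn = np.minimum(np.round(ys).astype(int), crop - 1)
    y0 = np.floor(ys).astype(int)
    y1 = np.minimum(y0 + 1, crop - 1)
    wy = (ys - y0).astype(np.float32)

    def bilinear(plane):
        a = plane[np.ix_(y0, y0)] * (1 - wy)[:, None] * (1 - wy)[None]
        a += plane[np.ix_(y1, y0)] * wy[:, None] * (1 - wy)[None]
        a += plane[np.ix_(y0, y1)] * (1 - wy)[:, None] * wy[None]
        a += plane[np.ix_(y1, y1)] * wy[:, None] * wy[None]
        return a

    img = np.stack([bilinear(c[sl].astype(np.float32)) for c in s.image])
    msk = s.mask[sl][np.ix_(yn, yn)]
    edg = s.edge[sl][np.ix_(yn, yn)]
    return SegSample(np.clip(img, 0, 1).astype(np.float32),
                     msk.astype(np.uint8), edg.astype(np.uint8))


def elastic(s: SegSample, rng: np.random.Generator,
            alpha: float | None = None, sigma: float | None = None) -> SegSample:
    """Random smooth warping; one displacement field for all three maps."""
    size = s.mask.shape[0]
    alpha = size * 0.08 if alpha is None else alpha
    sigma = size * 0.10 if sigma is None else sigma
    disp = np.stack([
        ndimage.gaussian_filter(rng.uniform(-1, 1, (size, size)), sigma) * alpha
        for _ in range(2)
    ])
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    coords = np.stack([yy + disp[0], xx + disp[1]])
    img = np.stack([
        ndimage.map_coordinates(c, coords, order=1, mode="reflect")
        for c in s.image
    ])
    msk = ndimage.map_coordinates(s.mask, coords, order=0, mode="constant")
    edg = ndimage.map_coordinates(s.edge, coords, order=0, mode="constant")
    return SegSample(np.clip(img, 0, 1).astype(np.float32),
                     msk.astype(np.uint8), edg.astype(np.uint8))


# ----------------------------------------------------------------------
# occlusions (image only; never touch the labels)
def _cutout(img, rng):
    size = img.shape[1]
    h = int(rng.integers(size // 8, size // 3 + 1))
    top = int(rng.integers(0, size - h + 1))
    left = int(rng.integers(0, size - h + 1))
    img = img.copy()
    img[:, top : top + h, left : left + h] = img.mean()
    return img


def _coarse_dropout(img, rng):
    size = img.shape[1]
    img = img.copy()
    for _ in range(int(rng.integers(4, 9))):
        h = int(rng.integers(2, max(3, size // 10)))
        top = int(rng.integers(0, size - h + 1))
        left = int(rng.integers(0, size - h + 1))
        img[:, top : top + h, left : left + h] = 0.0
    return img


def _grid_distortion(img, rng, cells: int = 4, limit: float = 0.25):
    size = img.shape[1]
    # per-cell random stretch of the sampling grid along each axis
    def warp_axis():
        steps = rng.uniform(1 - limit, 1 + limit, cells)
        knots = np.concatenate([[0.0], np.cumsum(steps)])
        knots *= (size - 1) / knots[-1]
        return np.interp(np.arange(size), np.linspace(0, size - 1, cells + 1), knots)

    cy, cx = warp_axis(), warp_axis()
    coords = np.stack(np.meshgrid(cy, cx, indexing="ij"))
    return np.stack([
        ndimage.map_coordinates(c, coords, order=1, mode="reflect") for c in img
    ]).astype(np.float32)


def _grid_dropout(img, rng):
    size = img.shape[1]
    cell = max(4, size // 8)
    off = int(rng.integers(0, cell))
    hole = max(1, int(cell * 0.4))
    img = img.copy()
    for top in range(off, size, cell):
        for left in range(off, size, cell):
            img[:, top : top + hole, left : left + hole] = 0.0
    return img


_OCCLUSIONS = (_cutout, _coarse_dropout, _grid_distortion, _grid_dropout)


def augment(s: SegSample, rng: np.random.Generator) -> SegSample:
    """One random draw of the full augmentation recipe."""
    if rng.random() < 0.5:
        s = flip_h(s)
    if rng.random() < 0.5:
        s = flip_v(s)
    if rng.random() < 0.7:
        s = rotate(s, float(rng.uniform(-30, 30)))
    if rng.random() < 0.5:
        size = s.mask.shape[0]
        crop = int(rng.integers(int(0.7 * size), size + 1))
        top = int(rng.integers(0, size - crop + 1))
        left = int(rng.integers(0, size - crop + 1))
        s = crop_resize(s, top, left, crop)
    if rng.random() < 0.5:
        s = elastic(s, rng)
    occ = _OCCLUSIONS[int(rng.integers(len(_OCCLUSIONS)))]
    return SegSample(occ(s.image, rng).astype(np.float32), s.mask, s.edge)


# ----------------------------------------------------------------------
# on-disk datasets
def write_dataset(cfg: SynthConfig, n: int, directory) -> dict:
    """Write ``n`` generated samples as PNG pairs plus a JSON manifest."""
    directory = os.fspath(directory)
    os.makedirs(os.path.join(directory, "images"), exist_ok=True)
    os.makedirs(os.path.join(directory, "masks"), exist_ok=True)
    pairs = []
    for i in range(n):
        s = gen_sample(cfg, i)
        img_rel = f"images/sample_{i:05d}.png"
        msk_rel = f"masks/sample_{i:05d}.png"
        img8 = np.round(s.image * 255).astype(np.uint8).transpose(1, 2, 0)
        Image.fromarray(img8).save(os.path.join(directory, img_rel))
        Image.fromarray(s.mask * 255).save(os.path.join(directory, msk_rel))
        pairs.append({"image": img_rel, "mask": msk_rel, "index": i})
    manifest = {"config": asdict(cfg), "n": n, "pairs": pairs}
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_dataset(directory) -> list[SegSample]:
    """Read a written dataset back; edge bands are re-derived from the masks."""
    directory = os.fspath(directory)
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    samples = []
    for pair in manifest["pairs"]:
        img = np.asarray(Image.open(os.path.join(directory, pair["image"])))
        msk = np.asarray(Image.open(os.path.join(directory, pair["mask"])))
        image = (img.astype(np.float32) / 255.0).transpose(2, 0, 1)
        mask = (msk >= 128).astype(np.uint8)
        samples.append(SegSample(image=image, mask=mask,
                                 edge=canny_edge_mask(mask, LossConfig())))
    return samples
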