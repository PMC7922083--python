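"""Mask-aware data augmentation.

Every training sample is first resized to the target side with its aspect
ratio retained (shorter side scaled, random square crop), then each
augmented variant applies a random sub-chain of four techniques: rotation
by an angle drawn from [0, 90] degrees, horizontal/vertical reflection,
elastic deformation on a fixed 10x10 control grid, and random gamma on the
image only.  Image and mask always receive the identical geometric
transform; masks are resampled nearest-neighbour so they stay binary.

With the default multiplier of 10 a training set of 800 images yields
8000 outputs (the originals plus nine variants each), reproducible
bytewise from the configuration seed.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
from scipy.ndimage import map_coordinates, rotate as nd_rotate
from skimage.transform import resize

from .config import AugmentConfig
from .phantom import SegmentationSample


def _finalize(image: np.ndarray, mask: np.ndarray, sid: str) -> SegmentationSample:
    sample = SegmentationSample(
        image=np.clip(image, 0.0, 1.0),
        mask=(np.asarray(mask) > 0.5).astype(np.uint8),
        id=sid,
    )
    sample.validate()
    return sample


def resize_preserve_aspect_random_crop(
    sample: SegmentationSample, side: int, rng: np.random.Generator
) -> SegmentationSample:
    """Scale the shorter side to ``side`` and take a random side x side crop."""
    h, w = sample.mask.shape
    if h <= 1 or w <= 1:
        raise ValueError("degenerate input dimensions")
    s = side / min(h, w)
    nh, nw = max(side, round(h * s)), max(side, round(w * s))
    if (nh, nw) == (h, w):
        image, mask = sample.image, sample.mask.astype(float)
    else:
        image = resize(sample.image, (nh, nw, 3), order=1, anti_aliasing=s < 1,
                       preserve_range=True)
        mask = resize(sample.mask.astype(float), (nh, nw), order=0,
                      anti_aliasing=False, preserve_range=True)
    top = int(rng.integers(0, nh - side + 1))
    left = int(rng.integers(0, nw - side + 1))
    return _finalize(
        image[top : top + side, left : left + side],
        mask[top : top + side, left : left + side],
        sample.id,
    )


def random_rotate(
    sample: SegmentationSample, rng: np.random.Generator, max_angle: float = 90.0
) -> SegmentationSample:
    """Rotate image (bilinear, reflect padding) and mask (nearest) jointly."""
    angle = float(rng.uniform(0.0, max_angle))
    if angle == 0.0:
        return sample
    image = nd_rotate(sample.image, angle, axes=(1, 0), reshape=False, order=1,
                      mode="reflect")
    mask = nd_rotate(sample.mask, angle, axes=(1, 0), reshape=False, order=0,
                     mode="reflect")
    return _finalize(image, mask, sample.id)


def random_reflect(
    sample: SegmentationSample,
    rng: np.random.Generator,
    horizontal: bool = True,
    vertical: bool = True,
) -> SegmentationSample:
    image, mask = sample.image, sample.mask
    if horizontal and rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if vertical and rng.random() < 0.5:
        image, mask = image[::-1], mask[::-1]
    return _finalize(image.copy(), mask.copy(), sample.id)


def reflect(sample: SegmentationSample, horizontal: bool = False,
            vertical: bool = False) -> SegmentationSample:
    """Deterministic reflection (an involution; used by tests and callers
    that need exact geometry)."""
    image, mask = sample.image, sample.mask
    if horizontal:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if vertical:
        image, mask = image[::-1], mask[::-1]
    return _finalize(image.copy(), mask.copy(), sample.id)


def elastic_deform(
    sample: SegmentationSample,
    rng: np.random.Generator,
    grid: int = 10,
    magnitude: float = 6.0,
) -> SegmentationSample:
    """Elastic deformation from a ``grid x grid`` lattice of i.i.d.
    displacement vectors, smoothly interpolated to a dense field; bicubic
    resampling for the image, nearest for the mask."""
    if magnitude == 0.0:
        return sample
    h, w = sample.mask.shape
    disp = rng.uniform(-magnitude, magnitude, size=(2, grid, grid))
    dy = resize(disp[0], (h, w), order=3, preserve_range=True)
    dx = resize(disp[1], (h, w), order=3, preserve_range=True)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coords = np.stack([yy + dy, xx + dx])
    image = np.stack(
        [
            map_coordinates(sample.image[:, :, c], coords, order=3, mode="reflect")
            for c in range(3)
        ],
        axis=-1,
    )
    mask = map_coordinates(sample.mask, coords, order=0, mode="reflect")
    return _finalize(image, mask, sample.id)


def random_gamma(
    sample: SegmentationSample,
    rng: np.random.Generator,
    gamma_range: tuple[float, float] = (0.7, 1.5),
) -> SegmentationSample:
    """Photometric-only: raise the image to a random power; mask untouched."""
    gamma = float(rng.uniform(*gamma_range))
    return _finalize(np.power(sample.image, gamma), sample.mask.copy(), sample.id)


def _augment_one(
    sample: SegmentationSample, config: AugmentConfig, rng: np.random.Generator,
    variant: int,
) -> SegmentationSample:
    out = resize_preserve_aspect_random_crop(sample, config.target_side, rng)
    if rng.random() < 0.5:
        out = random_rotate(out, rng, config.rotation_range)
    if rng.random() < 0.5:
        out = random_reflect(out, rng, config.flip_horizontal, config.flip_vertical)
    if rng.random() < 0.5:
        out = elastic_deform(out, rng, config.elastic_grid, config.elastic_magnitude)
    if rng.random() < 0.5:
        out = random_gamma(out, rng, config.gamma_range)
    return SegmentationSample(out.image, out.mask, f"{sample.id}_aug{variant:02d}")


def iter_augmented(
    samples: Iterable[SegmentationSample], config: AugmentConfig
) -> Iterator[SegmentationSample]:
    """Stream the augmented dataset: per input, the resized original then
    ``multiplier - 1`` randomized variants.  Fully determined by
    ``config.seed`` (per-sample child seeds, so streaming order == list)."""
    config.validate()
    for si, sample in enumerate(samples):
        base_rng = np.random.default_rng(np.random.SeedSequence([config.seed, si, 0]))
        original = resize_preserve_aspect_random_crop(
            sample, config.target_side, base_rng
        )
        yield original
        for v in range(1, config.multiplier):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, si, v]))
            yield _augment_one(sample, config, rng, v)


def augment_dataset(
    samples: list[SegmentationSample], config: AugmentConfig
) -> list[SegmentationSample]:
    """Materialised version of :func:`iter_augmented`;
    output count = len(samples) * multiplier."""
    return list(iter_augmented(samples, config))
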