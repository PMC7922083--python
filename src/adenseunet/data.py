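"""Dataset I/O and splitting for image/mask segmentation directories.

Datasets follow the common colonoscopy-benchmark layout: a root with an
``images/`` and a ``masks/`` directory holding same-named PNG/JPEG files.
Masks are binarized at the 8-bit midpoint (value > 127 is foreground) to be
robust to compression artefacts; evaluation-time resizing is deterministic
(aspect-preserving scale of the shorter side, centre crop), the stochastic
counterpart lives in :mod:`adenseunet.augment`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .phantom import SegmentationSample

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass(frozen=True)
class PairPaths:
    id: str
    image_path: Path
    mask_path: Path


@dataclass
class DatasetSplit:
    """Random partition of sample ids into train/validation/test."""

    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int
    ratios: tuple[float, float, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train": self.train,
                    "validation": self.validation,
                    "test": self.test,
                    "seed": self.seed,
                    "ratios": list(self.ratios),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        d = json.loads(Path(path).read_text())
        return cls(
            d["train"], d["validation"], d["test"], d["seed"], tuple(d["ratios"])
        )


def _index_dir(directory: Path) -> dict[str, Path]:
    files = {}
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in IMAGE_SUFFIXES:
            files[p.stem] = p
    return files


def discover_pairs(images_dir: str | Path, masks_dir: str | Path) -> list[PairPaths]:
    """Match image and mask files by basename, lexicographically ordered."""
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    for d in (images_dir, masks_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"not a directory: {d}")
    images = _index_dir(images_dir)
    masks = _index_dir(masks_dir)
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise ValueError(f"unpaired images/masks: {orphans}")
    return [PairPaths(k, images[k], masks[k]) for k in sorted(images)]


def _resize_center(arr: np.ndarray, side: int, order: int) -> np.ndarray:
    """Aspect-preserving scale of the shorter side to ``side`` + centre crop."""
    h, w = arr.shape[:2]
    if h <= 1 or w <= 1:
        raise ValueError("degenerate input dimensions")
    s = side / min(h, w)
    nh, nw = max(side, round(h * s)), max(side, round(w * s))
    out = resize(
        arr, (nh, nw) + arr.shape[2:], order=order, anti_aliasing=order > 0,
        preserve_range=True,
    )
    top, left = (nh - side) // 2, (nw - side) // 2
    return out[top : top + side, left : left + side]


def load_sample(pair: PairPaths, target_side: int | None = None) -> SegmentationSample:
    """Load one pair; image scaled to [0,1], mask binarized at >127."""
    image = np.asarray(iio.imread(pair.image_path))
    mask = np.asarray(iio.imread(pair.mask_path))
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    image = image[:, :, :3].astype(np.float64) / 255.0
    if mask.ndim == 3:
        mask = mask[:, :, 0]
    mask = (mask > 127).astype(np.uint8)
    if target_side is not None:
        image = np.clip(_resize_center(image, target_side, order=1), 0.0, 1.0)
        mask = _resize_center(mask, target_side, order=0).astype(np.uint8)
    sample = SegmentationSample(image=image, mask=mask, id=pair.id)
    sample.validate()
    return sample


def save_sample(sample: SegmentationSample, images_dir: str | Path,
                masks_dir: str | Path) -> None:
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    images_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(
        images_dir / f"{sample.id}.png",
        (np.clip(sample.image, 0, 1) * 255.0).round().astype(np.uint8),
    )
    iio.imwrite(masks_dir / f"{sample.id}.png", (sample.mask * 255).astype(np.uint8))


def split_dataset(
    ids: list[str],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Shuffled 80/10/10-style partition.

    Train gets floor(r_train * n), validation floor(r_val * n), test the
    remainder; re-running with the same seed reproduces membership exactly.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(ids)
    nonzero = sum(r > 0 for r in ratios)
    if n < nonzero:
        raise ValueError(f"need at least {nonzero} ids for {nonzero} nonzero ratios")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    return DatasetSplit(
        train=order[:n_train],
        validation=order[n_train : n_train + n_val],
        test=order[n_train + n_val :],
        seed=seed,
        ratios=tuple(ratios),
    )
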