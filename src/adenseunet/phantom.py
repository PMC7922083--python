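"""Synthetic colonoscopy-like phantom generator.

Produces RGB image / binary mask pairs that mimic the salient statistics of
colonoscopy frames — a pink-brown low-frequency mucosa texture, one or two
raised elliptical polyps with their own texture and smoothed borders, a few
saturated specular highlights, and radial vignetting — with pixel-exact
ground truth: the mask is the union of the generating ellipse interiors,
never re-segmented from the rendered image.

The generator exists to make the whole pipeline trainable and testable at
desk scale; it does not attempt photorealism.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .config import PhantomConfig

BASE_MUCOSA = np.array([0.80, 0.46, 0.42])
POLYP_TINT = np.array([0.88, 0.55, 0.48])


@dataclass
class SegmentationSample:
    """One RGB image in [0,1] (H, W, 3) with an aligned binary mask (H, W)."""

    image: np.ndarray
    mask: np.ndarray
    id: str
    meta: dict | None = None

    def validate(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask spatial dims must match the image")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be strictly {0, 1}-valued")


def _sample_rng(config: PhantomConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, index]))


def _low_freq_noise(rng, side: int, scale: float) -> np.ndarray:
    noise = gaussian_filter(rng.standard_normal((side, side)), sigma=scale)
    span = noise.max() - noise.min()
    if span > 0:
        noise = (noise - noise.min()) / span - 0.5
    return noise


def _ellipse_mask(side: int, cy, cx, a, b, angle) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_sample(config: PhantomConfig, index: int) -> SegmentationSample:
    """Render one phantom; fully determined by (config, index)."""
    config.validate()
    rng = _sample_rng(config, index)
    side = config.side
    lo, hi = config.axis_range()

    # mucosa background: tinted low-frequency texture
    image = np.empty((side, side, 3))
    base_noise = _low_freq_noise(rng, side, config.texture_scale)
    for ch in range(3):
        ripple = _low_freq_noise(rng, side, config.texture_scale / 3.0)
        image[:, :, ch] = BASE_MUCOSA[ch] * (1.0 + 0.35 * base_noise + 0.12 * ripple)

    # polyps: exact elliptical masks, smoothed appearance borders
    n = int(rng.integers(config.n_polyps[0], config.n_polyps[1] + 1))
    mask = np.zeros((side, side), dtype=np.uint8)
    polyps = []
    for _ in range(n):
        for _attempt in range(50):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            angle = rng.uniform(0.0, np.pi)
            margin = max(a, b) + 2.0
            if side - 2 * margin <= 1:
                continue
            cy = rng.uniform(margin, side - margin)
            cx = rng.uniform(margin, side - margin)
            break
        else:
            raise RuntimeError("infeasible polyp geometry for this configuration")
        ellipse = _ellipse_mask(side, cy, cx, a, b, angle)
        mask |= ellipse.astype(np.uint8)
        polyps.append(
            {"cy": cy, "cx": cx, "a": a, "b": b, "angle": float(angle)}
        )
        # raised appearance: soft alpha, distinct texture, dome shading
        alpha = gaussian_filter(ellipse.astype(float), sigma=2.5)
        tex = 1.0 + 0.25 * _low_freq_noise(rng, side, config.texture_scale / 4.0)
        yy, xx = np.mgrid[0:side, 0:side]
        r2 = ((xx - cx) / max(a, 1.0)) ** 2 + ((yy - cy) / max(b, 1.0)) ** 2
        dome = np.clip(1.15 - 0.35 * r2, 0.0, 1.3)
        polyp_rgb = POLYP_TINT[None, None, :] * (tex * dome)[:, :, None]
        image = image * (1.0 - alpha[:, :, None]) + polyp_rgb * alpha[:, :, None]

    # specular highlights
    n_spots = int(rng.integers(config.specular_spots[0], config.specular_spots[1] + 1))
    for _ in range(n_spots):
        sy, sx = rng.uniform(0, side, size=2)
        sr = rng.uniform(1.0, 0.02 * side + 1.5)
        yy, xx = np.mgrid[0:side, 0:side]
        spot = np.exp(-(((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * sr**2)))
        image += 0.9 * spot[:, :, None]

    # radial vignetting
    yy, xx = np.mgrid[0:side, 0:side]
    r = np.hypot(yy - side / 2, xx - side / 2) / (side / 2)
    image *= (1.0 - config.vignette_strength * np.clip(r, 0, 1.2) ** 2)[:, :, None]

    sample = SegmentationSample(
        image=np.clip(image, 0.0, 1.0),
        mask=mask,
        id=f"phantom_{index:05d}",
        meta={"polyps": polyps},
    )
    sample.validate()
    return sample


def make_samples(config: PhantomConfig, n: int, start: int = 0) -> list[SegmentationSample]:
    return [make_sample(config, i) for i in range(start, start + n)]


def make_dataset(n: int, out_dir: str | Path, config: PhantomConfig) -> dict:
    """Write ``n`` phantoms as 8-bit PNG pairs under ``out_dir`` in the
    images/ + masks/ same-basename layout, plus a JSON manifest."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n):
        sample = make_sample(config, i)
        iio.imwrite(
            out_dir / "images" / f"{sample.id}.png",
            (sample.image * 255.0).round().astype(np.uint8),
        )
        iio.imwrite(
            out_dir / "masks" / f"{sample.id}.png",
            (sample.mask * 255).astype(np.uint8),
        )
        entries.append(
            {
                "id": sample.id,
                "foreground_fraction": float(sample.mask.mean()),
                "polyps": sample.meta["polyps"],
            }
        )
    manifest = {
        "n": n,
        "config": dataclasses.asdict(config),
        "samples": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
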