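"""Deterministic synthetic fixtures.

Two families of test pairs, generated bit-reproducibly from a seed:

* **multi-focus pairs** — one sharp, textured ground-truth scene, with each
  source Gaussian-blurred on a complementary half (or disk) of the field.
  This emulates a camera with a limited depth of field, where out-of-focus
  regions are smoothed; the all-in-focus ground truth makes region-wise
  error assertions possible.
* **pseudo-multi-modal phantoms** — one blob phantom rendered under two
  disjoint intensity mappings, so each structure is visible in exactly one
  source, emulating complementary organ contrast across imaging modalities.

Texture is band-limited filtered noise, chosen so focus measures such as the
SML respond strongly to the sharp/blurred distinction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SynthSpec",
    "make_multifocus_pair",
    "make_multimodal_pair",
    "phantom_structures",
]


@dataclass(frozen=True)
class SynthSpec:
    size: tuple[int, int] = (256, 256)
    scene: str = "checker+texture"  # or "bars", "blob-phantom"
    blur_sigma: float = 3.0
    split: str = "left-right"  # or "disk-mask"
    noise_sigma: float = 0.0
    seed: int = 0


def _texture(shape, rng, lo=0.02, hi=0.25):
    """Band-limited filtered noise with unit-ish contrast."""
    noise = rng.standard_normal(shape)
    f = np.fft.rfft2(noise)
    fr = np.fft.fftfreq(shape[0])[:, None]
    fc = np.fft.rfftfreq(shape[1])[None, :]
    r = np.hypot(fr, fc)
    band = (r > lo) & (r < hi)
    tex = np.fft.irfft2(f * band, s=shape)
    tex /= max(np.abs(tex).max(), 1e-12)
    return tex


def _scene(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.size
    yy, xx = np.mgrid[0:rows, 0:cols]
    if spec.scene == "bars":
        base = 0.5 + 0.3 * np.sign(np.sin(2 * np.pi * xx / 16.0))
    elif spec.scene == "blob-phantom":
        base = _phantom(spec.size, phantom_structures(spec))
    else:  # checker + texture
        checker = ((yy // 32 + xx // 32) % 2).astype(float)
        base = 0.35 + 0.3 * checker
    gt = base + 0.3 * _texture(spec.size, rng)
    return np.clip(gt, 0.0, 1.0)


def _mask(spec: SynthSpec) -> np.ndarray:
    rows, cols = spec.size
    if spec.split == "disk-mask":
        yy, xx = np.mgrid[0:rows, 0:cols]
        r = np.hypot(yy - rows / 2, xx - cols / 2)
        return r <= min(rows, cols) / 3.0
    return np.broadcast_to(np.arange(cols)[None, :] < cols // 2, (rows, cols)).copy()


def make_multifocus_pair(spec: SynthSpec):
    """Return (a, b, gt, mask): a blurred inside ``mask``, b outside."""
    if spec.blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    rng = np.random.default_rng(spec.seed)
    gt = _scene(spec, rng)
    mask = _mask(spec)
    blurred = ndimage.gaussian_filter(gt, spec.blur_sigma, mode="reflect")
    a = np.where(mask, blurred, gt)
    b = np.where(mask, gt, blurred)
    if spec.noise_sigma > 0:
        a = np.clip(a + spec.noise_sigma * rng.standard_normal(spec.size), 0, 1)
        b = np.clip(b + spec.noise_sigma * rng.standard_normal(spec.size), 0, 1)
    return a, b, gt, mask


def phantom_structures(spec: SynthSpec) -> list[dict]:
    """Geometry of the phantom blobs for a given spec (deterministic).

    Blobs sit near the centres of a 3x2 grid (jittered), so structures never
    overlap; ``group`` alternates 0/1 and decides which source renders them.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.size
    blobs = []
    i = 0
    for gr in range(3):
        for gc in range(2):
            cy = (gr + 0.5) / 3 * rows + rng.uniform(-0.03, 0.03) * rows
            cx = (gc + 0.5) / 2 * cols + rng.uniform(-0.03, 0.03) * cols
            sy = rng.uniform(0.035, 0.06) * rows
            sx = rng.uniform(0.035, 0.06) * cols
            amp = rng.uniform(0.55, 0.9)
            blobs.append(
                {"cy": cy, "cx": cx, "sy": sy, "sx": sx, "amp": amp, "group": i % 2}
            )
            i += 1
    return blobs


def _phantom(size, blobs, groups=(0, 1), background=0.05):
    rows, cols = size
    yy, xx = np.mgrid[0:rows, 0:cols]
    img = np.full(size, background)
    for blob in blobs:
        if blob["group"] not in groups:
            continue
        img += blob["amp"] * np.exp(
            -(((yy - blob["cy"]) / blob["sy"]) ** 2 + ((xx - blob["cx"]) / blob["sx"]) ** 2)
        )
    return np.clip(img, 0.0, 1.0)


def make_multimodal_pair(spec: SynthSpec):
    """Two renderings of one phantom with disjoint visible structure sets."""
    if spec.scene != "blob-phantom":
        raise ValueError("multimodal pairs use the blob-phantom scene")
    blobs = phantom_structures(spec)
    a = _phantom(spec.size, blobs, groups=(0,))
    b = _phantom(spec.size, blobs, groups=(1,))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        a = np.clip(a + spec.noise_sigma * rng.standard_normal(spec.size), 0, 1)
        b = np.clip(b + spec.noise_sigma * rng.standard_normal(spec.size), 0, 1)
    return a, b
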