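"""End-to-end fusion pipeline.

Three steps: (1) NSCT-decompose both registered sources; (2) fuse the
low-pass bands by sparse coding over a PCA dictionary learned jointly from
this pair's low-pass patches, and fuse every directional high-pass band by
SML-MAX selection; (3) inverse-transform the fused coefficients.  The result
is clipped to [0, 1]; radiometry of unsaturated pixels is preserved.

Symmetric boundary handling wraps the entire chain: the sources are padded by
reflection, fused, and cropped, so the transform itself can stay periodic
(and exactly invertible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FusionConfig
from .dictionary import Dictionary, extract_patches, learn_dictionary
from .highpass import sml_max_fuse
from .lowpass import fuse_lowpass
from .nsct import nsct_decompose, nsct_reconstruct

__all__ = ["FusionResult", "fuse", "fuse_detailed", "fuse_color"]


@dataclass
class FusionResult:
    fused: np.ndarray
    #: per-pixel fraction of low-pass patches won by source A (after cropping)
    winner_map: np.ndarray
    dictionary: Dictionary
    config: FusionConfig


def _check_pair(img_a, img_b):
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"source shapes differ: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("sources contain non-finite pixels")
    return a, b


def fuse_detailed(
    img_a: np.ndarray,
    img_b: np.ndarray,
    cfg: FusionConfig | None = None,
    dictionary: Dictionary | None = None,
) -> FusionResult:
    """Fuse a registered grayscale pair, returning diagnostics as well."""
    cfg = (cfg or FusionConfig()).validate()
    a, b = _check_pair(img_a, img_b)
    if a.ndim != 2:
        raise ValueError("expected single-channel 2-D images")
    pad = cfg.boundary_pad if cfg.boundary == "symmetric" else 0
    pad = min(pad, a.shape[0] - 1, a.shape[1] - 1)
    if pad:
        a_w = np.pad(a, pad, mode="symmetric")
        b_w = np.pad(b, pad, mode="symmetric")
    else:
        a_w, b_w = a, b
    pyr_a = nsct_decompose(a_w, cfg.levels, cfg.directions, cfg.pyramid_filter, cfg.fan_filter)
    pyr_b = nsct_decompose(b_w, cfg.levels, cfg.directions, cfg.pyramid_filter, cfg.fan_filter)

    if dictionary is None:
        patches_a = extract_patches(pyr_a.lowpass, cfg.patch_size, cfg.stride, "A")
        patches_b = extract_patches(pyr_b.lowpass, cfg.patch_size, cfg.stride, "B")
        dictionary = learn_dictionary(
            patches_a,
            patches_b,
            n_clusters=cfg.n_clusters,
            delta=cfg.delta,
            seed=cfg.seed,
            max_train_patches=cfg.max_train_patches,
        )
    low_f, wins = fuse_lowpass(
        pyr_a.lowpass, pyr_b.lowpass, dictionary, cfg, return_winner_map=True
    )
    high_f = [
        [sml_max_fuse(ba, bb, cfg) for ba, bb in zip(lev_a, lev_b)]
        for lev_a, lev_b in zip(pyr_a.highpass, pyr_b.highpass)
    ]
    pyr_a.lowpass = low_f
    pyr_a.highpass = high_f
    fused = nsct_reconstruct(pyr_a)
    if pad:
        fused = fused[pad:-pad, pad:-pad]
        wins = wins[pad:-pad, pad:-pad]
    fused = np.clip(fused, 0.0, 1.0)
    return FusionResult(fused=fused, winner_map=wins, dictionary=dictionary, config=cfg)


def fuse(
    img_a: np.ndarray,
    img_b: np.ndarray,
    cfg: FusionConfig | None = None,
    dictionary: Dictionary | None = None,
) -> np.ndarray:
    """Fuse a registered grayscale pair into one image in [0, 1]."""
    return fuse_detailed(img_a, img_b, cfg, dictionary).fused


def _rgb_to_ycbcr(img: np.ndarray) -> np.ndarray:
    m = np.array(
        [[0.299, 0.587, 0.114], [-0.168736, -0.331264, 0.5], [0.5, -0.418688, -0.081312]]
    )
    out = img @ m.T
    out[..., 1:] += 0.5
    return out


def _ycbcr_to_rgb(img: np.ndarray) -> np.ndarray:
    ycc = img.copy()
    ycc[..., 1:] -= 0.5
    m = np.array([[1.0, 0.0, 1.402], [1.0, -0.344136, -0.714136], [1.0, 1.772, 0.0]])
    return ycc @ m.T


def fuse_color(
    img_a: np.ndarray, img_b: np.ndarray, cfg: FusionConfig | None = None
) -> np.ndarray:
    """Fuse a 3-channel pair.

    ``luma`` mode fuses the luminance channel and copies each pixel's chroma
    from the source whose low-pass patches dominated there; ``per_channel``
    fuses each channel independently.
    """
    cfg = (cfg or FusionConfig()).validate()
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("source shapes differ")
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError("expected 3-channel images")
    if cfg.color_mode == "per_channel":
        channels = [fuse(a[..., c], b[..., c], cfg) for c in range(3)]
        return np.stack(channels, axis=-1)
    ycc_a = _rgb_to_ycbcr(a)
    ycc_b = _rgb_to_ycbcr(b)
    res = fuse_detailed(ycc_a[..., 0], ycc_b[..., 0], cfg)
    take_a = (res.winner_map >= 0.5)[..., None]
    chroma = np.where(take_a, ycc_a[..., 1:], ycc_b[..., 1:])
    fused = np.concatenate([res.fused[..., None], chroma], axis=-1)
    return np.clip(_ycbcr_to_rgb(fused), 0.0, 1.0)
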