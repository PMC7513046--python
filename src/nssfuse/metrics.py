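"""Objective fusion-quality metrics.

Three widely used full-reference fusion metrics, each comparing a fused image
``f`` against both sources ``a`` and ``b``:

* ``mutual_information`` — MI(A;F) + MI(B;F) from joint intensity histograms
  (in bits); measures how much source information the fused image carries.
* ``q_abf`` — the Xydeas-Petrovic gradient-preservation index: Sobel edge
  strength and orientation transfer from each source to the fused image,
  weighted by source edge strength; in [0, 1].
* ``q_y`` — Yang's structural-similarity switching metric: where the sources
  agree structurally the local SSIMs are variance-weighted, where they
  disagree the better-matching source counts; in [0, 1].

All three are symmetric in (a, b).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = ["MetricReport", "mutual_information", "q_abf", "q_y", "evaluate"]


@dataclass
class MetricReport:
    mi: float
    q_abf: float
    q_y: float
    #: reserved for metrics defined only in external references
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {"MI": self.mi, "QABF": self.q_abf, "QY": self.q_y}
        out.update(self.extras)
        return out


def _check(*imgs):
    arrs = [np.asarray(i, dtype=float) for i in imgs]
    shape = arrs[0].shape
    for arr in arrs:
        if arr.shape != shape or arr.ndim != 2:
            raise ValueError("metric inputs must be equal-shape 2-D images")
    return arrs


def _mi_pair(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    joint, _, _ = np.histogram2d(x.ravel(), y.ravel(), bins=bins, range=[[0, 1], [0, 1]])
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def mutual_information(a, b, f, bins: int = 256) -> float:
    """MI(A;F) + MI(B;F) on intensities binned over [0, 1]; in bits."""
    a, b, f = _check(a, b, f)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    return _mi_pair(a, f, bins) + _mi_pair(b, f, bins)


def _sobel(img):
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return np.hypot(gx, gy), np.arctan2(gy, gx + (gx == 0) * 1e-30)


# Published sigmoid constants of the gradient-preservation index.
_GAMMA_G, _KAPPA_G, _SIGMA_G = 0.9994, -15.0, 0.5
_GAMMA_A, _KAPPA_A, _SIGMA_A = 0.9879, -22.0, 0.8


def _edge_preservation(gs, angs, gf, angf):
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gs > gf, gf / gs, gs / gf)
    ratio = np.nan_to_num(ratio, nan=0.0)
    both_zero = (gs == 0) & (gf == 0)
    ratio[both_zero] = 1.0  # nothing to lose where neither image has edges
    dang = 1.0 - np.abs(np.arctan(np.tan(angs - angf))) / (np.pi / 2)
    qg = _GAMMA_G / (1.0 + np.exp(_KAPPA_G * (ratio - _SIGMA_G)))
    qa = _GAMMA_A / (1.0 + np.exp(_KAPPA_A * (dang - _SIGMA_A)))
    return qg * qa


def q_abf(a, b, f) -> float:
    """Gradient-based edge-transfer index, weighted by source edge strength.

    Returns 0 for entirely flat sources (no edge information to preserve).
    """
    a, b, f = _check(a, b, f)
    ga, aa = _sobel(a)
    gb, ab_ = _sobel(b)
    gf, af = _sobel(f)
    q_af = _edge_preservation(ga, aa, gf, af)
    q_bf = _edge_preservation(gb, ab_, gf, af)
    wa, wb = ga, gb
    denom = (wa + wb).sum()
    if denom <= 0:
        return 0.0
    return float((q_af * wa + q_bf * wb).sum() / denom)


def q_y(a, b, f, window: int = 7) -> float:
    """Yang's structural fusion metric built on local SSIM maps.

    Where SSIM(A,B) >= 0.75 the local quality is the variance-weighted mean
    of SSIM(A,F) and SSIM(B,F); elsewhere it is their maximum.
    """
    a, b, f = _check(a, b, f)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    kw = dict(win_size=window, data_range=1.0, full=True, gaussian_weights=False)
    _, s_af = structural_similarity(a, f, **kw)
    _, s_bf = structural_similarity(b, f, **kw)
    _, s_ab = structural_similarity(a, b, **kw)
    mean_a = ndimage.uniform_filter(a, window)
    mean_b = ndimage.uniform_filter(b, window)
    var_a = np.clip(ndimage.uniform_filter(a * a, window) - mean_a**2, 0, None)
    var_b = np.clip(ndimage.uniform_filter(b * b, window) - mean_b**2, 0, None)
    denom = var_a + var_b
    lam = np.where(denom > 1e-12, var_a / np.where(denom > 0, denom, 1.0), 0.5)
    weighted = lam * s_af + (1.0 - lam) * s_bf
    switched = np.maximum(s_af, s_bf)
    q = np.where(s_ab >= 0.75, weighted, switched)
    return float(np.clip(q.mean(), 0.0, 1.0))


def evaluate(a, b, f, bins: int = 256, window: int = 7) -> MetricReport:
    """All implemented metrics in one report."""
    return MetricReport(
        mi=mutual_information(a, b, f, bins=bins),
        q_abf=q_abf(a, b, f),
        q_y=q_y(a, b, f, window=window),
    )
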