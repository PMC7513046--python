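"""Nonsubsampled contourlet transform (NSCT).

The transform cascades two nonsubsampled stages, neither of which resamples
the signal, so every band keeps the source image's size and the transform is
exactly shift-invariant under periodic extension:

* a nonsubsampled pyramid (NSPFB): at scale ``j`` the two-channel pyramid
  bank is applied with its kernels a-trous-upsampled by ``2^j I``;
* a nonsubsampled directional filter bank (NSDFB): each band-pass scale is
  split into ``2^d`` directional wedges by a tree of two-channel fan banks
  whose kernels are upsampled by quincunx, dilation and shear matrices chosen
  so that the wedge boundaries subdivide slopes uniformly.

Because every stage satisfies the Bezout identity ``H0 G0 + H1 G1 = 1`` for
*any* upsampling matrix, the full transform is perfectly invertible; all
filtering is implemented multiplicatively on the DFT grid (circular
convolution with zero-phase kernels).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

from .filters import (
    QUINCUNX,
    FilterQuad,
    build_fan_filters,
    build_pyramid_filters,
    kernel_frequency_response,
)

__all__ = ["NsctPyramid", "nsct_decompose", "nsct_reconstruct"]

_SWAP = np.array([[0, 1], [1, 0]], dtype=int)


class NsctConfigError(ValueError):
    """Invalid level/direction configuration."""


@dataclass
class NsctPyramid:
    """NSCT coefficient set: one low-pass band plus directional band-pass bands.

    ``highpass[j]`` holds the directional bands of level ``j`` with
    ``j = 0`` the *coarsest* band-pass scale, matching the order of the
    ``directions`` list; every band has ``shape``.
    """

    lowpass: np.ndarray
    highpass: list[list[np.ndarray]]
    shape: tuple[int, int]
    levels: int
    directions: tuple[int, ...]
    pyramid_filter: str | FilterQuad = "9-7"
    fan_filter: str | FilterQuad = "pkva"

    def iter_bands(self):
        """Yield (level, direction, band) over all band-pass bands."""
        for j, level_bands in enumerate(self.highpass):
            for k, band in enumerate(level_bands):
                yield j, k, band


def _split_matrix(family: str, lo: Fraction, hi: Fraction) -> np.ndarray:
    """M^T for splitting the wedge of slope interval (lo, hi) at its midpoint.

    Boundaries of the upsampled fan pair are the lines where the two
    components of ``M^T omega`` have equal magnitude; the rows are chosen so
    one boundary is the interval midpoint line and the other is a parent edge
    (quincunx and dilation matrices for the first two refinements, integer
    shears after that).
    """
    width = hi - lo
    if width == 2:  # full fan -> quadrants
        return np.array([[1, 1], [-1, 1]], dtype=int)
    if width == 1:  # quadrant -> eighths
        return np.array([[1, 0], [0, 2]], dtype=int)
    mid = (lo + hi) / 2
    p, q = mid.numerator, mid.denominator
    for edge in (lo, hi):
        pe, qe = edge.numerator, edge.denominator
        if pe % 2 != 0:
            break
    else:  # pragma: no cover - one edge numerator is always odd
        raise NsctConfigError("cannot construct shear matrix")
    r1 = ((p + pe) // 2, -(q + qe) // 2)
    r2 = ((p - pe) // 2, -(q - qe) // 2)
    mt = np.array([r1, r2], dtype=int)
    if round(abs(np.linalg.det(mt))) < 1:  # pragma: no cover
        raise NsctConfigError("degenerate shear matrix")
    return mt


def _lower_first(mt: np.ndarray, family: str, lo: Fraction, hi: Fraction) -> bool:
    """True when fan channel 0 covers the lower half of the slope interval."""
    mid = (lo + hi) / 2
    test = float(lo + mid) / 2.0
    w = np.array([1.0, test]) if family == "h" else np.array([test, 1.0])
    v = mt @ w
    return abs(v[0]) > abs(v[1])


def _dfb_responses(
    n_dirs: int, fan: FilterQuad, shape: tuple[int, int]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(analysis, synthesis) frequency responses of the 2^d directional channels."""
    ones = np.ones((shape[0], shape[1] // 2 + 1))
    if n_dirs == 1:
        return [(ones, ones)]
    depth = int(round(np.log2(n_dirs)))
    u = [fan.h0, fan.h1]
    v = [fan.g0, fan.g1]

    # stage 1: base fan pair, no upsampling
    resp_u = [kernel_frequency_response(k, shape) for k in u]
    resp_v = [kernel_frequency_response(k, shape) for k in v]
    full = Fraction(-1), Fraction(1)
    nodes = [
        (resp_u[0], resp_v[0], "h", *full),
        (resp_u[1], resp_v[1], "v", *full),
    ]
    for _ in range(depth - 1):
        new_nodes = []
        for a, s, family, lo, hi in nodes:
            mt = _split_matrix(family, lo, hi)
            if family == "v":
                mt = mt @ _SWAP
            m = mt.T  # kernel_frequency_response upsamples by m => H(m^T w)
            ru = [kernel_frequency_response(k, shape, m) for k in u]
            rv = [kernel_frequency_response(k, shape, m) for k in v]
            mid = (lo + hi) / 2
            lower0 = _lower_first(mt, family, lo, hi)
            order = (0, 1) if lower0 else (1, 0)
            halves = ((lo, mid), (mid, hi))
            for ch, (nlo, nhi) in zip(order, halves):
                new_nodes.append((a * ru[ch], s * rv[ch], family, nlo, nhi))
        nodes = new_nodes
    return [(a, s) for a, s, *_ in nodes]


def _resolve_quads(
    pyramid_filter: str | FilterQuad, fan_filter: str | FilterQuad
) -> tuple[FilterQuad, FilterQuad]:
    pyr = (
        pyramid_filter
        if isinstance(pyramid_filter, FilterQuad)
        else build_pyramid_filters(pyramid_filter)
    )
    fan = (
        fan_filter
        if isinstance(fan_filter, FilterQuad)
        else build_fan_filters(fan_filter)
    )
    return pyr, fan


def _build_plan(
    shape: tuple[int, int],
    levels: int,
    directions: tuple[int, ...],
    pyr: FilterQuad,
    fan: FilterQuad,
):
    """Combined per-band (analysis, synthesis) responses, coarse to fine.

    Returns ``(low_a, low_s, high)`` with ``high[j]`` the list for the level
    matching ``directions[j]`` (level 0 coarsest).
    """
    low_a = np.ones((shape[0], shape[1] // 2 + 1))
    low_s = np.ones_like(low_a)
    high: list[list[tuple[np.ndarray, np.ndarray]]] = []
    # stage i = 0 is the finest scale; directions are listed coarse->fine
    fine_to_coarse: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for i in range(levels):
        m = (2**i) * np.eye(2, dtype=int)
        h0 = kernel_frequency_response(pyr.h0, shape, m)
        h1 = kernel_frequency_response(pyr.h1, shape, m)
        g0 = kernel_frequency_response(pyr.g0, shape, m)
        g1 = kernel_frequency_response(pyr.g1, shape, m)
        band_a, band_s = low_a * h1, low_s * g1
        n_dirs = directions[levels - 1 - i]
        dir_resp = _dfb_responses(n_dirs, fan, shape)
        fine_to_coarse.append([(band_a * da, band_s * ds) for da, ds in dir_resp])
        low_a, low_s = low_a * h0, low_s * g0
    high = fine_to_coarse[::-1]
    return low_a, low_s, high


@lru_cache(maxsize=8)
def _cached_plan(shape, levels, directions, pyr_name, fan_name):
    pyr, fan = _resolve_quads(pyr_name, fan_name)
    return _build_plan(shape, levels, directions, pyr, fan)


def _get_plan(shape, levels, directions, pyramid_filter, fan_filter):
    if isinstance(pyramid_filter, str) and isinstance(fan_filter, str):
        return _cached_plan(shape, levels, directions, pyramid_filter, fan_filter)
    pyr, fan = _resolve_quads(pyramid_filter, fan_filter)
    return _build_plan(shape, levels, directions, pyr, fan)


def _validate_config(levels: int, directions) -> tuple[int, ...]:
    if levels < 1:
        raise NsctConfigError("levels must be >= 1")
    directions = tuple(int(d) for d in directions)
    if len(directions) != levels:
        raise NsctConfigError(
            f"directions has {len(directions)} entries for {levels} levels"
        )
    for d in directions:
        if d < 1 or (d & (d - 1)) != 0:
            raise NsctConfigError(f"direction count {d} is not a power of two")
    return directions


def nsct_decompose(
    img: np.ndarray,
    levels: int = 4,
    directions=(4, 8, 8, 16),
    pyramid_filter: str | FilterQuad = "9-7",
    fan_filter: str | FilterQuad = "pkva",
) -> NsctPyramid:
    """Decompose an image into an NSCT pyramid.

    ``directions`` is ordered coarsest to finest scale.  Extension is
    periodic; callers wanting symmetric extension should pad beforehand
    (the fusion pipeline does).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    directions = _validate_config(levels, directions)
    shape = img.shape
    low_a, _, high = _get_plan(shape, levels, directions, pyramid_filter, fan_filter)
    spec = np.fft.rfft2(img)
    lowpass = np.fft.irfft2(spec * low_a, s=shape)
    highpass = [
        [np.fft.irfft2(spec * a, s=shape) for a, _ in level] for level in high
    ]
    return NsctPyramid(
        lowpass=lowpass,
        highpass=highpass,
        shape=shape,
        levels=levels,
        directions=directions,
        pyramid_filter=pyramid_filter,
        fan_filter=fan_filter,
    )


def nsct_reconstruct(
    pyr: NsctPyramid,
    pyramid_filter: str | FilterQuad | None = None,
    fan_filter: str | FilterQuad | None = None,
) -> np.ndarray:
    """Invert :func:`nsct_decompose`; exact to numerical precision."""
    pyramid_filter = pyramid_filter or pyr.pyramid_filter
    fan_filter = fan_filter or pyr.fan_filter
    shape = tuple(pyr.shape)
    if pyr.lowpass.shape != shape:
        raise ValueError("low-pass band shape mismatch")
    if len(pyr.highpass) != pyr.levels:
        raise ValueError("pyramid level count mismatch")
    _, low_s, high = _get_plan(
        shape, pyr.levels, tuple(pyr.directions), pyramid_filter, fan_filter
    )
    acc = np.fft.rfft2(pyr.lowpass) * low_s
    for level_bands, level_resp in zip(pyr.highpass, high):
        if len(level_bands) != len(level_resp):
            raise ValueError("directional band count mismatch")
        for band, (_, s) in zip(level_bands, level_resp):
            if band.shape != shape:
                raise ValueError("band shape mismatch")
            acc = acc + np.fft.rfft2(band) * s
    return np.fft.irfft2(acc, s=shape)
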