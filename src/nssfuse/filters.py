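"""Two-channel nonsubsampled filter banks.

The transform in :mod:`nssfuse.nsct` is built from two-channel *nonsubsampled*
filter banks: an analysis pair ``(h0, h1)`` and a synthesis pair ``(g0, g1)``
that satisfy the Bezout identity

    H0(z) G0(z) + H1(z) G1(z) = 1,

which is exactly the perfect-reconstruction condition when no down/up-sampling
of the signal takes place.  All kernels here are real, zero-phase (centred on
their middle tap) and centro-symmetric, so their frequency responses are real.

Both filter families are constructed with the McClellan transform: a symmetric
1-D prototype ``H(omega) = sum_m a_m T_m(cos omega)`` is lifted to 2-D by
substituting ``cos omega -> (cos omega_1 + cos omega_2)/2`` (pyramid filters)
which turns a 1-D halfband pair into a 2-D diamond-complementary pair.  Fan
filters are obtained from diamond filters by modulating every other row,
which shifts the passband by pi along the first frequency axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import convolve2d

__all__ = [
    "FilterQuad",
    "QUINCUNX",
    "build_pyramid_filters",
    "build_fan_filters",
    "atrous_upsample",
    "kernel_frequency_response",
    "bezout_residual",
]

#: Quincunx sampling matrix used to upsample fan filters; |det| = 2.
QUINCUNX = np.array([[1, -1], [1, 1]], dtype=int)

# Ladder (lifting) interpolation coefficients of the published PKVA-12 filter;
# they define an approximate 1-D halfband 1/2 + sum_k v_k T_{2k-1}(cos omega).
_PKVA12 = np.array([0.6300, -0.1930, 0.0972, -0.0526, 0.0272, -0.0144])

# Odd Chebyshev coefficients of the 6-point Lagrange (Deslauriers-Dubuc)
# interpolating halfband: taps [3,0,-25,0,150,256,150,0,-25,0,3]/512.
_DMAXFLAT = np.array([300.0, -50.0, 6.0]) / 512.0


class UnsupportedFilterError(ValueError):
    """Raised when a filter family name is not recognised."""


@dataclass(frozen=True)
class FilterQuad:
    """Analysis/synthesis kernels of a two-channel nonsubsampled bank.

    All four kernels are odd-sized 2-D arrays understood as zero-phase
    (centre tap at ``shape // 2``).
    """

    h0: np.ndarray
    h1: np.ndarray
    g0: np.ndarray
    g1: np.ndarray
    name: str = field(default="", compare=False)

    def kernels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return self.h0, self.h1, self.g0, self.g1


def _delta() -> np.ndarray:
    return np.ones((1, 1))


def _chebyshev_coeffs(filt: np.ndarray) -> np.ndarray:
    """Cosine-series coefficients a_m of a symmetric odd-length 1-D filter.

    H(omega) = a_0 + sum_{m>=1} a_m cos(m omega), with a_0 the centre tap and
    a_m twice the m-th off-centre tap.
    """
    filt = np.asarray(filt, dtype=float)
    if filt.ndim != 1 or filt.size % 2 == 0:
        raise ValueError("prototype filter must be 1-D with odd length")
    c = filt.size // 2
    if not np.allclose(filt, filt[::-1], atol=1e-12):
        raise ValueError("prototype filter must be symmetric")
    coeffs = np.empty(c + 1)
    coeffs[0] = filt[c]
    coeffs[1:] = 2.0 * filt[c + 1 :]
    return coeffs


# 3x3 McClellan kernel with frequency response (cos w1 + cos w2)/2.
_DIAMOND_KERNEL = np.array([[0.0, 0.25, 0.0], [0.25, 0.0, 0.25], [0.0, 0.25, 0.0]])


def _pad_to(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    pr = (shape[0] - arr.shape[0]) // 2
    pc = (shape[1] - arr.shape[1]) // 2
    return np.pad(arr, ((pr, pr), (pc, pc)))


def _mcclellan(coeffs: np.ndarray) -> np.ndarray:
    """2-D zero-phase kernel realising sum_m a_m T_m((cos w1 + cos w2)/2).

    Chebyshev recursion carried out on kernels: T_{m+1} = 2 K * T_m - T_{m-1}
    (* = 2-D convolution).
    """
    m = coeffs.size - 1
    size = 2 * m + 1 if m > 0 else 1
    out = np.zeros((size, size))
    t_prev = _delta()  # T_0
    t_cur = _DIAMOND_KERNEL.copy()  # T_1
    out += coeffs[0] * _pad_to(t_prev, out.shape)
    if m >= 1:
        out += coeffs[1] * _pad_to(t_cur, out.shape)
    for k in range(2, m + 1):
        t_next = 2.0 * convolve2d(_DIAMOND_KERNEL, t_cur)
        t_next = t_next - _pad_to(t_prev, t_next.shape)
        t_prev, t_cur = t_cur, t_next
        out += coeffs[k] * _pad_to(t_cur, out.shape)
    return out


def _modulate(kernel: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Shift the frequency response by pi along the given axes (zero-phase)."""
    out = kernel.copy()
    for ax in axes:
        n = kernel.shape[ax]
        sign = (-1.0) ** (np.arange(n) - n // 2)
        shape = [1, 1]
        shape[ax] = n
        out = out * sign.reshape(shape)
    return out


def _trim(kernel: np.ndarray, tol: float = 1e-14) -> np.ndarray:
    """Strip all-zero border rings, keeping the kernel odd and centred."""
    k = kernel
    while k.shape[0] > 1 and k.shape[1] > 1:
        ring = max(
            np.abs(k[0]).max(), np.abs(k[-1]).max(),
            np.abs(k[:, 0]).max(), np.abs(k[:, -1]).max(),
        )
        if ring > tol:
            break
        k = k[1:-1, 1:-1]
    return k


def build_pyramid_filters(name: str) -> FilterQuad:
    """Construct the multi-scale (pyramid) stage filter quad.

    ``"9-7"`` lifts the CDF 9/7 biorthogonal pair to 2-D with the McClellan
    transform; the two high-pass kernels are the (pi, pi)-modulated synthesis/
    analysis low-pass kernels, so the Bezout identity holds to machine
    precision because the 1-D product is an exact halfband.  ``"maxflat"``
    does the same starting from the 5/3 (linear-spline) pair.
    """
    if name == "9-7":
        w = pywt.Wavelet("bior4.4")
        lo_a = np.trim_zeros(np.asarray(w.dec_lo)) / np.sqrt(2.0)
        lo_s = np.trim_zeros(np.asarray(w.rec_lo)) / np.sqrt(2.0)
    elif name == "maxflat":
        lo_a = np.array([1.0, 2.0, 1.0]) / 4.0
        lo_s = np.array([-1.0, 2.0, 6.0, 2.0, -1.0]) / 8.0
    else:
        raise UnsupportedFilterError(f"unknown pyramid filter family: {name!r}")
    h0 = _mcclellan(_chebyshev_coeffs(lo_a))
    g0 = _mcclellan(_chebyshev_coeffs(lo_s))
    # Quadrature (modulation) relation: H1(w) = G0(w + (pi,pi)) etc., hence
    # H0 G0 + H1 G1 = P(t) + P(-t) = 1 with t = (cos w1 + cos w2)/2.
    h1 = _modulate(g0, (0, 1))
    g1 = _modulate(h0, (0, 1))
    return FilterQuad(h0=h0, h1=h1, g0=g0, g1=g1, name=name)


def _fan_from_halfband(odd_coeffs: np.ndarray) -> np.ndarray:
    """Fan filter from odd Chebyshev halfband coefficients.

    The diamond halfband D(t) = 1/2 + sum_k v_k T_{2k-1}(t) satisfies
    D(t) + D(-t) = 1; modulating every other row rotates the diamond into a
    fan whose complement is exactly 1 - F.
    """
    m = 2 * odd_coeffs.size - 1
    coeffs = np.zeros(m + 1)
    coeffs[0] = 0.5
    coeffs[1::2] = odd_coeffs
    diamond = _mcclellan(coeffs)
    return _trim(_modulate(diamond, (0,)))


def build_fan_filters(name: str) -> FilterQuad:
    """Construct the directional (fan) stage filter quad.

    The analysis pair is the complementary fan pair ``(f, delta - f)`` and the
    synthesis pair ``(f, delta + f)``; then H0 G0 + H1 G1 = F^2 + (1 - F^2)
    = 1 identically, for any fan prototype F.  ``"pkva"`` uses the PKVA-12
    ladder coefficients as the halfband prototype, ``"dmaxflat"`` the 6-point
    maximally flat interpolating halfband.
    """
    if name == "pkva":
        f = _fan_from_halfband(_PKVA12)
    elif name == "dmaxflat":
        f = _fan_from_halfband(_DMAXFLAT)
    else:
        raise UnsupportedFilterError(f"unknown fan filter family: {name!r}")
    size = f.shape[0]
    c = size // 2
    delta = np.zeros_like(f)
    delta[c, c] = 1.0
    return FilterQuad(h0=f, h1=delta - f, g0=f.copy(), g1=delta + f, name=name)


def atrous_upsample(kernel: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Upsample a kernel by an integer matrix (zero insertion, a trous style).

    Each tap at offset ``n`` from the kernel centre moves to offset ``m @ n``;
    all other entries are zero.  The frequency response of the result is
    ``H(m^T omega)``.
    """
    kernel = np.asarray(kernel, dtype=float)
    m = np.asarray(m)
    if m.shape != (2, 2) or not np.issubdtype(m.dtype, np.integer):
        if m.shape != (2, 2) or not np.allclose(m, np.round(m)):
            raise ValueError("upsampling matrix must be a 2x2 integer matrix")
        m = np.round(m).astype(int)
    if round(abs(np.linalg.det(m))) < 1:
        raise ValueError("upsampling matrix must be nonsingular")
    cr, cc = (kernel.shape[0] - 1) // 2, (kernel.shape[1] - 1) // 2
    rows, cols = np.nonzero(kernel)
    if rows.size == 0:
        return np.zeros((1, 1))
    offs = np.stack([rows - cr, cols - cc])
    mapped = m @ offs
    if kernel.shape[0] % 2 and kernel.shape[1] % 2:
        # zero-phase kernels stay centred on an odd-sized support
        hi = np.abs(mapped).max(axis=1)
        lo = -hi
    else:
        lo, hi = mapped.min(axis=1), mapped.max(axis=1)
    out = np.zeros((hi[0] - lo[0] + 1, hi[1] - lo[1] + 1))
    out[mapped[0] - lo[0], mapped[1] - lo[1]] = kernel[rows, cols]
    return out


def kernel_frequency_response(
    kernel: np.ndarray,
    shape: tuple[int, int],
    m: np.ndarray | None = None,
) -> np.ndarray:
    """Real DFT-grid frequency response of a zero-phase kernel.

    Computes the response of ``atrous_upsample(kernel, m)`` on the periodic
    ``shape`` grid without materialising the upsampled kernel: taps are folded
    modulo the grid, so kernels larger than the grid are handled exactly.
    Returns the full complex DFT grid reduced to its real part (responses of
    centro-symmetric kernels are real).
    """
    kernel = np.asarray(kernel, dtype=float)
    cr, cc = kernel.shape[0] // 2, kernel.shape[1] // 2
    rows, cols = np.nonzero(kernel)
    vals = kernel[rows, cols]
    offs = np.stack([rows - cr, cols - cc])
    if m is not None:
        offs = np.asarray(np.round(m), dtype=int) @ offs
    folded = np.zeros(shape)
    np.add.at(folded, (offs[0] % shape[0], offs[1] % shape[1]), vals)
    return np.fft.rfft2(folded).real


def bezout_residual(quad: FilterQuad, shape: tuple[int, int] = (64, 64)) -> float:
    """max |H0 G0 + H1 G1 - 1| over a DFT frequency grid."""
    h0 = kernel_frequency_response(quad.h0, shape)
    h1 = kernel_frequency_response(quad.h1, shape)
    g0 = kernel_frequency_response(quad.g0, shape)
    g1 = kernel_frequency_response(quad.g1, shape)
    return float(np.abs(h0 * g0 + h1 * g1 - 1.0).max())
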