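"""Low-pass band fusion by sparse representation.

Each pair of co-located, mean-removed low-pass patches is sparse-coded
*jointly* over the learned dictionary with Simultaneous Orthogonal Matching
Pursuit (SOMP): the two codes share one atom support, chosen greedily by the
summed absolute correlation with both residuals, with per-signal least-squares
coefficients.  The fused code is whichever input code has the larger l1 norm
(Max-L1; ties go to the second source), the fused patch mean follows the
winning code, and the fused band is rebuilt by overlap-add averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FusionConfig
from .dictionary import Dictionary, extract_patches

__all__ = [
    "SparseCode",
    "somp_encode",
    "max_l1_fuse",
    "reconstruct_fused_patch",
    "fuse_lowpass",
    "overlap_counts",
]


def _axis_coverage(length: int, patch_size: int, stride: int) -> np.ndarray:
    diff = np.zeros(length + 1)
    starts = np.arange(0, length - patch_size + 1, stride)
    np.add.at(diff, starts, 1.0)
    np.add.at(diff, starts + patch_size, -1.0)
    return np.cumsum(diff)[:length]


def overlap_counts(shape: tuple[int, int], patch_size: int, stride: int) -> np.ndarray:
    """How many sliding patches cover each pixel (separable product)."""
    return np.outer(
        _axis_coverage(shape[0], patch_size, stride),
        _axis_coverage(shape[1], patch_size, stride),
    )


@dataclass
class SparseCode:
    """Sparse coefficient vector over the dictionary."""

    coefficients: np.ndarray
    support: np.ndarray
    residual_norm: float

    @property
    def l1(self) -> float:
        return float(np.abs(self.coefficients).sum())


def _somp_batch(
    ya: np.ndarray,
    yb: np.ndarray,
    phi: np.ndarray,
    eps: float,
    max_atoms: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised SOMP over a batch of signal pairs.

    ``ya``, ``yb``: (n, B) zero-mean signal columns.  Returns dense
    coefficient arrays (B, n_atoms) for both signals, the residual norms and
    the support-size vector.  Greedy selection maximises
    ``|phi^T r_a| + |phi^T r_b|``; both signals stop together once both
    residuals are within ``eps`` (or ``max_atoms`` is reached).
    """
    n, batch = ya.shape
    n_atoms = phi.shape[1]
    t_max = min(max_atoms, n_atoms, n)
    gram = phi.T @ phi
    ca0 = phi.T @ ya  # (n_atoms, B)
    cb0 = phi.T @ yb
    coef_a = np.zeros((batch, n_atoms))
    coef_b = np.zeros((batch, n_atoms))
    support = np.full((batch, t_max), -1, dtype=int)
    n_sel = np.zeros(batch, dtype=int)
    res_a = np.linalg.norm(ya, axis=0)
    res_b = np.linalg.norm(yb, axis=0)
    alive = (res_a > eps) | (res_b > eps)
    # correlations of the *current residual*: c - G[:, S] @ coef[S]
    ca = ca0.copy()
    cb = cb0.copy()
    for t in range(t_max):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        score = np.abs(ca[:, idx]) + np.abs(cb[:, idx])
        if t > 0:
            sel_prev = support[idx, :t]
            score[sel_prev.T, np.arange(idx.size)] = -np.inf
        pick = np.argmax(score, axis=0)
        support[idx, t] = pick
        n_sel[idx] = t + 1
        # least-squares on the shared support via batched normal equations
        sel = support[idx, : t + 1]  # (b, t+1)
        g_ss = gram[sel[:, :, None], sel[:, None, :]]  # (b, t+1, t+1)
        g_ss = g_ss + 1e-12 * np.eye(t + 1)
        rhs_a = ca0[sel, idx[:, None]]  # (b, t+1)
        rhs_b = cb0[sel, idx[:, None]]
        sol = np.linalg.solve(g_ss, np.stack([rhs_a, rhs_b], axis=-1))
        sa, sb = sol[..., 0], sol[..., 1]
        # explicit residuals (no normal-equation cancellation)
        atoms_sel = phi[:, sel]  # (n, b, t+1)
        ra_vec = ya[:, idx] - np.einsum("nbt,bt->nb", atoms_sel, sa)
        rb_vec = yb[:, idx] - np.einsum("nbt,bt->nb", atoms_sel, sb)
        res_a[idx] = np.linalg.norm(ra_vec, axis=0)
        res_b[idx] = np.linalg.norm(rb_vec, axis=0)
        done = (res_a[idx] <= eps) & (res_b[idx] <= eps)
        coef_a[idx[:, None], sel] = sa
        coef_b[idx[:, None], sel] = sb
        if t + 1 < t_max:
            # residual correlations: c0 - G[:, S] s
            gs = gram[:, sel]  # (n_atoms, b, t+1)
            ca[:, idx] = ca0[:, idx] - np.einsum("abt,bt->ab", gs, sa)
            cb[:, idx] = cb0[:, idx] - np.einsum("abt,bt->ab", gs, sb)
        alive[idx] = ~done
    return coef_a, coef_b, res_a, res_b, support, n_sel


def somp_encode(
    v_a: np.ndarray,
    v_b: np.ndarray,
    phi: Dictionary,
    eps: float = 0.08,
    max_atoms: int = 16,
) -> tuple[SparseCode, SparseCode]:
    """Jointly sparse-code one pair of zero-mean vectors over Phi."""
    atoms = phi.atoms
    v_a = np.asarray(v_a, dtype=float).ravel()
    v_b = np.asarray(v_b, dtype=float).ravel()
    if atoms.size == 0:
        raise ValueError("empty dictionary")
    if v_a.shape[0] != atoms.shape[0] or v_b.shape[0] != atoms.shape[0]:
        raise ValueError("signal length does not match the dictionary row count")
    if eps <= 0:
        raise ValueError("eps must be positive")
    ca, cb, ra, rb, support, n_sel = _somp_batch(
        v_a[:, None], v_b[:, None], atoms, eps, max_atoms
    )
    sup = np.sort(support[0, : n_sel[0]])
    return (
        SparseCode(coefficients=ca[0], support=sup, residual_norm=float(ra[0])),
        SparseCode(coefficients=cb[0], support=sup, residual_norm=float(rb[0])),
    )


def max_l1_fuse(alpha_a: SparseCode, alpha_b: SparseCode) -> tuple[SparseCode, str]:
    """Max-L1 rule: keep the code with the larger l1 norm; ties keep B.

    Returns the fused code and the winner label ("A" or "B"), which decides
    the fused patch mean.
    """
    if alpha_a.coefficients.shape != alpha_b.coefficients.shape:
        raise ValueError("codes are over different dictionaries")
    if alpha_a.l1 > alpha_b.l1:
        return alpha_a, "A"
    return alpha_b, "B"


def reconstruct_fused_patch(
    alpha_f: SparseCode,
    winner: str,
    mean_a: float,
    mean_b: float,
    phi: Dictionary,
) -> np.ndarray:
    """V_F = Phi alpha_F + mean(winner) * 1."""
    if winner not in ("A", "B"):
        raise ValueError("winner must be 'A' or 'B'")
    mean = mean_a if winner == "A" else mean_b
    return phi.atoms @ alpha_f.coefficients + mean


def fuse_lowpass(
    l_a: np.ndarray,
    l_b: np.ndarray,
    phi: Dictionary,
    cfg: FusionConfig | None = None,
    return_winner_map: bool = False,
):
    """Fuse two low-pass bands patch-wise with SOMP + Max-L1.

    Every stride-grid patch pair is jointly coded, merged with the Max-L1
    rule, rebuilt as ``Phi alpha_F`` plus the winning mean, and placed back;
    overlapping contributions are averaged by per-pixel coverage counts.
    With ``return_winner_map`` a second array gives, per pixel, the fraction
    of covering patches won by source A.
    """
    cfg = cfg or FusionConfig()
    l_a = np.asarray(l_a, dtype=float)
    l_b = np.asarray(l_b, dtype=float)
    if l_a.shape != l_b.shape:
        raise ValueError("low-pass bands differ in shape")
    ps, stride = cfg.patch_size, cfg.stride
    if phi.atoms.shape[0] != ps * ps:
        raise ValueError("dictionary row count does not match patch size")
    pa = extract_patches(l_a, ps, stride, "A")
    pb = extract_patches(l_b, ps, stride, "B")
    eps, max_atoms = cfg.resolved_eps, cfg.max_atoms

    n_total = pa.n_patches
    coef_a = np.empty((n_total, phi.n_atoms))
    coef_b = np.empty((n_total, phi.n_atoms))
    chunk = 8192
    for start in range(0, n_total, chunk):
        sl = slice(start, min(start + chunk, n_total))
        ca, cb, *_ = _somp_batch(
            pa.vectors[:, sl], pb.vectors[:, sl], phi.atoms, eps, max_atoms
        )
        coef_a[sl] = ca
        coef_b[sl] = cb

    l1_a = np.abs(coef_a).sum(axis=1)
    l1_b = np.abs(coef_b).sum(axis=1)
    a_wins = l1_a > l1_b  # ties -> B
    coef_f = np.where(a_wins[:, None], coef_a, coef_b)
    means_f = np.where(a_wins, pa.means, pb.means)
    patches_f = phi.atoms @ coef_f.T + means_f  # (n_pix, T)

    fused = np.zeros_like(l_a)
    wins = np.zeros_like(l_a)
    count = overlap_counts(l_a.shape, ps, stride)
    # column-major vectorisation: first ps entries are the first patch column
    patch_imgs = patches_f.T.reshape(n_total, ps, ps).transpose(0, 2, 1)
    rr = pa.positions[:, 0][:, None, None] + np.arange(ps)[None, :, None]
    cc = pa.positions[:, 1][:, None, None] + np.arange(ps)[None, None, :]
    rr = np.broadcast_to(rr, (n_total, ps, ps))
    cc = np.broadcast_to(cc, (n_total, ps, ps))
    np.add.at(fused, (rr, cc), patch_imgs)
    if return_winner_map:
        np.add.at(wins, (rr, cc), np.broadcast_to(a_wins[:, None, None], rr.shape) * 1.0)
    covered = count > 0
    fused[covered] /= count[covered]
    # pixels missed by the stride grid (stride > 1 remainders) fall back to A/B mean
    if not covered.all():
        fused[~covered] = 0.5 * (l_a[~covered] + l_b[~covered])
    if return_winner_map:
        wins[covered] /= count[covered]
        return fused, wins
    return fused
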