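"""PCA dictionary learning from joint patch clusters.

The sparse-coding dictionary is learned per image pair, from the pooled
low-pass patches of both sources: patches are pooled, clustered jointly
(k-means), and each cluster contributes the smallest number ``p`` of leading
principal components whose eigenvalue mass fraction reaches ``delta``.
The per-cluster sub-dictionaries are concatenated into the aggregate
dictionary ``Phi``, which is compact compared to the patch pool while
retaining the informative structure of every cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "PatchSet",
    "SubDictionary",
    "Dictionary",
    "extract_patches",
    "joint_cluster",
    "pca_subdictionary",
    "build_dictionary",
    "learn_dictionary",
    "save_dictionary",
    "load_dictionary",
]


@dataclass
class PatchSet:
    """Vectorised, mean-removed patches of one band.

    ``vectors`` has one length ``patch_size**2`` column per patch (patch
    pixels in column-major order); ``means`` stores the removed means,
    ``positions`` the top-left (row, col) of each patch on the stride grid.
    """

    vectors: np.ndarray
    means: np.ndarray
    positions: np.ndarray
    patch_size: int
    band_shape: tuple[int, int]
    source_label: str = ""

    @property
    def n_patches(self) -> int:
        return self.vectors.shape[1]


@dataclass
class SubDictionary:
    """Orthonormal PCA atoms of one joint patch cluster."""

    atoms: np.ndarray  # (n, p), orthonormal columns
    eigenvalues: np.ndarray  # (p,), descending
    cluster_id: int
    degenerate: bool = False

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]


@dataclass
class Dictionary:
    """Aggregate dictionary Phi: concatenated per-cluster PCA atoms."""

    atoms: np.ndarray  # (n, sum_C p_C), unit-norm columns
    cluster_offsets: np.ndarray  # start column of each sub-dictionary
    patch_size: int = 0

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]


def extract_patches(
    band: np.ndarray, patch_size: int, stride: int = 1, source_label: str = ""
) -> PatchSet:
    """Slide a ``patch_size`` window with the given step, top-left to
    bottom-right, vectorise each patch column-major and remove its mean."""
    band = np.asarray(band, dtype=float)
    rows, cols = band.shape
    if patch_size > min(rows, cols):
        raise ValueError(
            f"patch size {patch_size} exceeds band dimensions {band.shape}"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    view = np.lib.stride_tricks.sliding_window_view(band, (patch_size, patch_size))
    view = view[::stride, ::stride]
    gr, gc = view.shape[:2]
    # row-major enumeration of positions; column-major pixels inside a patch
    vecs = view.reshape(gr * gc, patch_size, patch_size)
    vecs = vecs.transpose(0, 2, 1).reshape(gr * gc, patch_size * patch_size).T
    means = vecs.mean(axis=0)
    vecs = vecs - means
    rr, cc = np.meshgrid(
        np.arange(gr) * stride, np.arange(gc) * stride, indexing="ij"
    )
    positions = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return PatchSet(
        vectors=vecs,
        means=means,
        positions=positions,
        patch_size=patch_size,
        band_shape=(rows, cols),
        source_label=source_label,
    )


def joint_cluster(
    patches_a: PatchSet, patches_b: PatchSet, k: int, seed: int = 0
) -> np.ndarray:
    """Cluster the pooled patches of both sources into ``k`` groups.

    Returns one label per pooled patch (A's patches first, then B's).
    k-means with k-means++ initialisation; deterministic for a fixed seed.
    """
    pooled = np.hstack([patches_a.vectors, patches_b.vectors]).T
    return cluster_vectors(pooled, k, seed)


def cluster_vectors(pooled: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means labels for row vectors; empty clusters are dropped upstream."""
    n = pooled.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the pooled patch count {n}")
    if k == 1:
        return np.zeros(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**32))
    with warnings.catch_warnings():
        # duplicate patches (e.g. flat regions) can collapse clusters
        warnings.simplefilter("ignore")
        return km.fit_predict(pooled)


def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Make each column's first nonzero component positive (determinism)."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


def pca_subdictionary(
    cluster_vectors: np.ndarray, delta: float = 0.95, cluster_id: int = 0
) -> SubDictionary:
    """Leading principal components of one cluster.

    Keeps the smallest ``p`` with cumulative eigenvalue mass fraction
    ``sum_{j<=p} L_j / sum_j L_j >= delta``.  Atoms are orthonormal
    eigenvectors of the cluster covariance (patch means were already
    removed, so no further centering is applied).
    """
    x = np.asarray(cluster_vectors, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("cluster must contain at least one vector")
    n = x.shape[0]
    cov = (x @ x.T) / x.shape[1]
    total = np.trace(cov)
    if total <= 1e-15:
        return SubDictionary(
            atoms=np.empty((n, 0)),
            eigenvalues=np.empty(0),
            cluster_id=cluster_id,
            degenerate=True,
        )
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    frac = np.cumsum(evals) / evals.sum()
    p = int(np.searchsorted(frac, delta - 1e-12) + 1)
    p = min(p, int(np.sum(evals > 1e-12 * evals[0])) or 1)
    return SubDictionary(
        atoms=_sign_fix(evecs[:, :p]),
        eigenvalues=evals[:p],
        cluster_id=cluster_id,
    )


def build_dictionary(subdicts: list[SubDictionary], patch_size: int = 0) -> Dictionary:
    """Concatenate sub-dictionaries, in cluster order, into Phi."""
    nonempty = [d for d in subdicts if d.n_atoms > 0]
    if not nonempty:
        raise ValueError("all sub-dictionaries are empty")
    offsets = np.cumsum([0] + [d.n_atoms for d in nonempty])[:-1]
    atoms = np.hstack([d.atoms for d in nonempty])
    return Dictionary(atoms=atoms, cluster_offsets=offsets, patch_size=patch_size)


def learn_dictionary(
    patches_a: PatchSet,
    patches_b: PatchSet,
    n_clusters: int = 8,
    delta: float = 0.95,
    seed: int = 0,
    max_train_patches: int | None = 20000,
) -> Dictionary:
    """Full dictionary-learning path: pool, cluster, PCA, aggregate.

    Clustering may run on a seeded random subsample of the pool
    (``max_train_patches``); the PCA of each cluster uses all subsampled
    members.  Empty clusters are dropped with a warning.
    """
    pooled = np.hstack([patches_a.vectors, patches_b.vectors])
    n = pooled.shape[1]
    if max_train_patches is not None and n > max_train_patches:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=max_train_patches, replace=False)
        idx.sort()
        pooled = pooled[:, idx]
        n = max_train_patches
    k = min(n_clusters, n)
    labels = cluster_vectors(pooled.T, k, seed)
    subdicts = []
    for c in range(k):
        members = pooled[:, labels == c]
        if members.shape[1] == 0:
            warnings.warn(f"cluster {c} is empty and was dropped", stacklevel=2)
            continue
        subdicts.append(pca_subdictionary(members, delta=delta, cluster_id=c))
    if all(d.degenerate for d in subdicts):
        # entirely flat input: fall back to a single constant-free atom basis
        n_dim = pooled.shape[0]
        eye = np.eye(n_dim)[:, :1]
        subdicts = [SubDictionary(atoms=eye, eigenvalues=np.ones(1), cluster_id=0)]
    return build_dictionary(subdicts, patch_size=patches_a.patch_size)


def save_dictionary(phi: Dictionary, path: str) -> None:
    """Plain-text dictionary file: a small header plus the atom matrix."""
    header = (
        f"nssfuse-dictionary v1\n"
        f"patch_size {phi.patch_size}\n"
        f"n_atoms {phi.n_atoms}\n"
        f"cluster_offsets {' '.join(map(str, phi.cluster_offsets.tolist()))}"
    )
    np.savetxt(path, phi.atoms, header=header)


def load_dictionary(path: str) -> Dictionary:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if len(parts) >= 2 and parts[0] in ("patch_size", "n_atoms"):
                meta[parts[0]] = int(parts[1])
            elif parts and parts[0] == "cluster_offsets":
                meta["cluster_offsets"] = np.array([int(v) for v in parts[1:]])
    atoms = np.loadtxt(path)
    if atoms.ndim == 1:
        atoms = atoms[:, None]
    return Dictionary(
        atoms=atoms,
        cluster_offsets=meta.get("cluster_offsets", np.zeros(1, dtype=int)),
        patch_size=meta.get("patch_size", int(round(np.sqrt(atoms.shape[0])))),
    )
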