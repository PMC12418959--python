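"""Subtype discovery: kNN Gaussian affinity graph + normalized spectral clustering.

Samples are the columns of the consensus embedding.  The similarity graph

    W_ij = exp(-||h_i - h_j||^2 / t)   if h_i in Nei(h_j) or h_j in Nei(h_i)
    W_ij = 0                           otherwise

uses a symmetric-OR k-nearest-neighbour rule with a self-tuned bandwidth
(mean squared distance over retained neighbour pairs).  Clustering follows
the Ng-Jordan-Weiss recipe: eigenvectors of the symmetric normalized
Laplacian, row-normalized, then k-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .errors import ConfigurationError, ValidationError
from .linear import ConsensusRepresentation

__all__ = [
    "SimilarityGraph",
    "SubtypeResult",
    "build_similarity",
    "spectral_embed",
    "cluster_consensus",
    "estimate_num_clusters",
]


@dataclass(frozen=True)
class SimilarityGraph:
    """Symmetric kNN Gaussian affinity matrix with zero diagonal."""

    values: np.ndarray
    neighbor_k: int
    bandwidth: float

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SubtypeResult:
    """Cluster labels plus the spectral embedding they were found in."""

    labels: np.ndarray
    embedding: np.ndarray
    eigenvalues: np.ndarray
    samples: tuple = ()

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def _embedding_points(H) -> np.ndarray:
    """Samples-as-rows coordinate array from a consensus or raw matrix."""
    if isinstance(H, ConsensusRepresentation):
        return H.values.T
    h = np.asarray(H, dtype=float)
    return h.T


def build_similarity(H, neighbor_k: int | None = None, t="auto") -> SimilarityGraph:
    """Build the kNN Gaussian similarity graph over samples.

    ``neighbor_k`` defaults to ``min(15, N - 1)``.  ``t="auto"`` sets the
    bandwidth to the mean squared distance over all retained neighbour
    pairs.  kNN ties are broken by stable index order.
    """
    pts = _embedding_points(H)
    n = pts.shape[0]
    k = min(15, n - 1) if neighbor_k is None else int(neighbor_k)
    if n < k + 1:
        raise ValidationError(f"need at least neighbor_k + 1 = {k + 1} samples, got {n}")
    if k < 1:
        raise ValidationError("neighbor_k must be >= 1")
    d2 = squareform(pdist(pts, metric="sqeuclidean"))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = np.argsort(d2[i], kind="stable")
        neighbors = [j for j in order if j != i][:k]
        mask[i, neighbors] = True
    mask |= mask.T  # symmetric-OR neighbourhood
    np.fill_diagonal(mask, False)
    if t == "auto":
        retained = d2[mask]
        t_val = float(retained.mean()) if retained.size else 1.0
        if t_val <= 0:  # all retained pairs coincide
            t_val = 1.0
    else:
        t_val = float(t)
        if t_val <= 0:
            raise ConfigurationError("bandwidth t must be positive")
    w = np.where(mask, np.exp(-d2 / t_val), 0.0)
    np.fill_diagonal(w, 0.0)
    return SimilarityGraph(values=w, neighbor_k=k, bandwidth=t_val)


def spectral_embed(W: SimilarityGraph, k: int):
    """Embed with the symmetric normalized Laplacian ``L = I - D^-1/2 W D^-1/2``.

    Returns the row-normalized matrix of the ``k`` eigenvectors belonging to
    the smallest eigenvalues, and the full ascending spectrum.
    """
    w = W.values if isinstance(W, SimilarityGraph) else np.asarray(W, dtype=float)
    n = w.shape[0]
    if not 1 <= k < n:
        raise ConfigurationError(f"k={k} must satisfy 1 <= k < N={n}")
    deg = w.sum(axis=1)
    if (deg <= 0).any():
        i = int(np.argmin(deg))
        raise ValidationError(
            f"sample at position {i} is isolated in the graph; "
            "increase neighbor_k"
        )
    dinv = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - dinv[:, None] * w * dinv[None, :]
    lap = (lap + lap.T) / 2.0  # enforce exact symmetry for eigh
    eigvals, eigvecs = scipy.linalg.eigh(lap)
    emb = eigvecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return emb / norms, eigvals


def _relabel_largest_first(labels: np.ndarray) -> np.ndarray:
    """Relabel so cluster 0 is the largest; ties broken by first occurrence."""
    uniq = np.unique(labels)
    first = {u: int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-(labels == u).sum(), first[u]))
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=int)


def cluster_consensus(H, k: int, neighbor_k: int | None = None, t="auto",
                      seed: int = 0, restarts: int = 50) -> SubtypeResult:
    """Spectral clustering of the consensus embedding into ``k`` subtypes."""
    pts = _embedding_points(H)
    n = pts.shape[0]
    if not 2 <= k < n:
        raise ConfigurationError(f"k={k} must satisfy 2 <= k < N={n}")
    graph = build_similarity(H, neighbor_k=neighbor_k, t=t)
    emb, eigvals = spectral_embed(graph, k)
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                random_state=seed)
    labels = _relabel_largest_first(km.fit_predict(emb))
    samples = H.samples if isinstance(H, ConsensusRepresentation) else ()
    return SubtypeResult(labels=labels, embedding=emb,
                         eigenvalues=eigvals[:k + 1], samples=samples)


def estimate_num_clusters(H, k_max: int = 10, neighbor_k: int | None = None,
                          t="auto") -> int:
    """Eigengap heuristic on the normalized Laplacian spectrum.

    Returns the ``k`` in ``2..k_max`` maximizing the gap between the k-th
    and (k+1)-th smallest eigenvalues.  Warns when the winning gap is not
    clearly dominant (< 2x the median gap over the scanned range).
    """
    pts = _embedding_points(H)
    n = pts.shape[0]
    if k_max >= n:
        raise ConfigurationError(f"k_max={k_max} must be < N={n}")
    if k_max < 2:
        raise ConfigurationError("k_max must be >= 2")
    graph = build_similarity(H, neighbor_k=neighbor_k, t=t)
    _, eigvals = spectral_embed(graph, min(k_max + 1, n - 1))
    gaps = np.array([eigvals[k] - eigvals[k - 1] for k in range(2, k_max + 1)])
    best = int(np.argmax(gaps)) + 2
    med = float(np.median(gaps))
    if med > 0 and gaps[best - 2] < 2 * med:
        warnings.warn(
            f"eigengap for k={best} is not dominant (gap {gaps[best - 2]:.3g} "
            f"vs median {med:.3g}); low-confidence estimate",
            stacklevel=2,
        )
    return best
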