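"""Synthetic multi-omics data with planted cluster structure and controlled
missingness, plus clustering agreement metrics.

The generator mirrors the factorization model itself: a shared latent
matrix (one column per sample, clustered around well-separated centroids)
is pushed through per-view linear loadings and Gaussian noise.  Missingness
emulates the partial-data protocol used to stress incomplete multi-omics
methods: whole samples are dropped from a masked view at rates
theta in {0.1, 0.3, 0.5, 0.7} while designated views stay complete, so
every patient remains observed somewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .data import MultiOmicsDataset, OmicsView, align_views
from .errors import ConfigurationError, ValidationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "apply_missingness",
    "adjusted_rand_index",
    "normalized_mutual_information",
]


@dataclass
class SimulationConfig:
    """Study conditions for the planted-partition generator.

    Defaults are the reference conditions used throughout the test battery:
    200 samples, 3 views of 100 features, 4 clusters with centroid
    separation 5 (latent units) against unit within-cluster jitter, and
    observation noise sd 0.5.  ``theta`` gives per-view missing fractions;
    ``complete_views`` are never masked.
    """

    n_samples: int = 200
    n_views: int = 3
    n_clusters: int = 4
    n_features: tuple | int = 100
    separation: float = 5.0
    noise_sd: float = 0.5
    latent_dim: int | None = None
    theta: tuple | float = 0.0
    complete_views: tuple | None = None
    proportions: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.complete_views is None:
            # every view after the first stays complete (the masking
            # protocol masks one modality and keeps the others intact)
            self.complete_views = tuple(range(1, self.n_views))
        if isinstance(self.n_features, int):
            self.n_features = tuple([self.n_features] * self.n_views)
        else:
            self.n_features = tuple(int(d) for d in self.n_features)
        if isinstance(self.theta, (int, float)):
            self.theta = tuple([float(self.theta)] * self.n_views)
        else:
            self.theta = tuple(float(t) for t in self.theta)
        self.complete_views = tuple(int(v) for v in self.complete_views)
        if self.n_views < 1 or self.n_samples < 1:
            raise ConfigurationError("need at least one view and one sample")
        if len(self.n_features) != self.n_views:
            raise ConfigurationError("n_features must give one size per view")
        if len(self.theta) != self.n_views:
            raise ConfigurationError("theta must give one rate per view")
        if any(not 0 <= t < 1 for t in self.theta):
            raise ConfigurationError("theta must lie in [0, 1) per view")
        if self.n_clusters > self.n_samples:
            raise ConfigurationError("more clusters than samples")
        if any(v < 0 or v >= self.n_views for v in self.complete_views):
            raise ConfigurationError("complete_views indices out of range")
        if self.latent_dim is None:
            self.latent_dim = self.n_clusters
        if self.proportions is not None:
            p = tuple(float(x) for x in self.proportions)
            if len(p) != self.n_clusters or abs(sum(p) - 1.0) > 1e-9:
                raise ConfigurationError("proportions must sum to 1, one per cluster")
            self.proportions = p

    @property
    def effective_theta(self):
        """Missing rates with complete views forced to zero."""
        return tuple(0.0 if v in self.complete_views else t
                     for v, t in enumerate(self.theta))


@dataclass(frozen=True)
class GroundTruth:
    """Hidden quantities of a simulated dataset, in intact-sample order."""

    labels: np.ndarray
    latent: np.ndarray
    loadings: tuple


def _centroids(rng, k: int, dim: int, separation: float) -> np.ndarray:
    """Random centroids rescaled so the minimum pairwise distance equals
    ``separation`` (a single centroid sits at the origin)."""
    c = rng.normal(size=(k, dim))
    if k == 1 or separation <= 0:
        return c
    d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    dmin = d.min()
    if dmin <= 0:  # astronomically unlikely with Gaussian draws
        c += rng.normal(scale=1e-3, size=c.shape)
        d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        dmin = d.min()
    return c * (separation / dmin)


def generate_dataset(cfg: SimulationConfig):
    """Draw one multi-omics dataset with planted clusters.

    Latent column of sample i = centroid of its cluster + N(0, I) jitter;
    view v observes ``loadings_v @ latent + N(0, noise_sd^2)``.  Sample IDs
    are zero-padded so lexicographic intact ordering equals draw order.
    Returns ``(dataset, truth)`` with truth aligned to the intact order.
    """
    rng = np.random.default_rng(cfg.seed)
    n, k, d = cfg.n_samples, cfg.n_clusters, cfg.latent_dim
    if cfg.proportions is None:
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
    else:
        sizes = np.floor(np.asarray(cfg.proportions) * n).astype(int)
        while sizes.sum() < n:
            sizes[int(np.argmax(np.asarray(cfg.proportions) * n - sizes))] += 1
    if (sizes == 0).any():
        raise ConfigurationError("a cluster received zero samples")
    labels = rng.permutation(np.repeat(np.arange(k), sizes))
    centroids = _centroids(rng, k, d, cfg.separation)
    latent = centroids[labels].T + rng.normal(size=(d, n))
    width = len(str(n - 1))
    samples = tuple(f"s{i:0{width}d}" for i in range(n))
    views = []
    loadings = []
    for v in range(cfg.n_views):
        dv = cfg.n_features[v]
        load = rng.normal(size=(dv, d)) / np.sqrt(d)
        x = load @ latent + cfg.noise_sd * rng.normal(size=(dv, n))
        feats = tuple(f"v{v}_f{j:04d}" for j in range(dv))
        views.append(OmicsView(name=f"omics{v}", features=feats,
                               samples=samples, values=x))
        loadings.append(load)
    dataset = align_views(views)
    truth = GroundTruth(labels=np.asarray(labels, dtype=int), latent=latent,
                        loadings=tuple(loadings))
    masked = apply_missingness(dataset, cfg.effective_theta,
                               complete_views=cfg.complete_views, seed=cfg.seed)
    return masked, truth


def apply_missingness(dataset: MultiOmicsDataset, theta,
                      complete_views=(), seed: int = 0) -> MultiOmicsDataset:
    """Remove whole sample columns from masked views.

    For each view v not in ``complete_views``, ``floor(theta_v * N_v)``
    samples are removed uniformly without replacement.  The intact sample
    list never changes, and the removal is validated against orphaning any
    sample before any view is touched.
    """
    if isinstance(theta, (int, float)):
        theta = [float(theta)] * dataset.n_views
    theta = [float(t) for t in theta]
    if len(theta) != dataset.n_views:
        raise ConfigurationError("theta must give one rate per view")
    if any(not 0 <= t < 1 for t in theta):
        raise ConfigurationError("theta must lie in [0, 1) per view")
    complete = set(int(v) for v in complete_views)
    rng = np.random.default_rng(seed)
    keep_sets = []
    for v, view in enumerate(dataset.views):
        nv = view.n_samples
        n_remove = 0 if v in complete else int(np.floor(theta[v] * nv))
        removed = set(rng.choice(nv, size=n_remove, replace=False).tolist())
        keep_sets.append([j for j in range(nv) if j not in removed])
    covered = set()
    for view, keep in zip(dataset.views, keep_sets):
        covered |= {view.samples[j] for j in keep}
    orphans = set(dataset.intact_samples) - covered
    if orphans:
        raise ValidationError(
            f"masking would leave samples in zero views: {sorted(orphans)[:5]}"
        )
    new_views = []
    for view, keep in zip(dataset.views, keep_sets):
        if len(keep) == view.n_samples:
            new_views.append(view)
        else:
            new_views.append(OmicsView(
                name=view.name, features=view.features,
                samples=tuple(view.samples[j] for j in keep),
                values=view.values[:, keep]))
    return MultiOmicsDataset(views=tuple(new_views),
                             intact_samples=dataset.intact_samples)


def _check_labels(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValidationError(f"label lengths differ: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 2:
        raise ValidationError("need at least 2 samples to compare labelings")
    return a, b


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index: pair-counting agreement with expected-index
    correction; 1 for identical partitions, ~0 for independent ones."""
    a, b = _check_labels(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def normalized_mutual_information(labels_a, labels_b) -> float:
    """Mutual information normalized by the arithmetic mean of entropies;
    defined as 0 whenever either labeling is constant."""
    a, b = _check_labels(labels_a, labels_b)
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))
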