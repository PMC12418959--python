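"""Containers and I/O for multi-omics feature matrices.

A *view* is one omics modality (mRNA expression, DNA methylation, miRNA,
CNV, ...) stored as a features x samples matrix.  Views may cover different,
overlapping subsets of patients; the *intact* sample set is the union over
views.  Each view carries a binary indicator matrix ``G`` mapping intact
sample positions to the view's observed columns, which is what lets one
objective handle complete and partial data alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParseError, ValidationError

__all__ = [
    "OmicsView",
    "MultiOmicsDataset",
    "IndicatorMatrix",
    "read_omics_csv",
    "zscore_standardize",
    "build_indicator_matrix",
    "align_views",
    "pos_neg_split",
]


@dataclass(frozen=True)
class OmicsView:
    """One omics modality: a ``D_v x N_v`` real matrix with labelled axes.

    Parameters
    ----------
    name : str
        Short identifier of the modality (e.g. ``"mrna"``).
    features : tuple of str
        Row labels, length ``D_v``.
    samples : tuple of str
        Column labels, length ``N_v``; must be unique within the view.
    values : ndarray of shape (D_v, N_v)
        Finite real measurements.
    """

    name: str
    features: tuple
    samples: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "samples", tuple(self.samples))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError(f"view {self.name!r}: values must be 2-D")
        d, n = values.shape
        if d < 1 or n < 1:
            raise ValidationError(f"view {self.name!r}: empty matrix ({d}x{n})")
        if len(self.features) != d or len(self.samples) != n:
            raise ValidationError(
                f"view {self.name!r}: label lengths {len(self.features)}x"
                f"{len(self.samples)} do not match values shape {d}x{n}"
            )
        if len(set(self.samples)) != n:
            seen, dup = set(), None
            for s in self.samples:
                if s in seen:
                    dup = s
                    break
                seen.add(s)
            raise ValidationError(f"view {self.name!r}: duplicate sample ID {dup!r}")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"view {self.name!r}: non-finite value at feature "
                f"{self.features[i]!r}, sample {self.samples[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.features),
                            columns=list(self.samples))


@dataclass(frozen=True)
class IndicatorMatrix:
    """Binary ``N x N_v`` map from intact sample positions to view columns.

    ``G[i, j] = 1`` iff the intact sample at position ``i`` is the ``j``-th
    observed sample of the view.  Each column sums to one, each row to at
    most one, and ``G.T @ G`` is the ``N_v x N_v`` identity.
    """

    values: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", g)
        if g.ndim != 2:
            raise ValidationError("indicator matrix must be 2-D")
        if not np.isin(g, (0.0, 1.0)).all():
            raise ValidationError("indicator entries must be 0 or 1")
        if not np.array_equal(g.sum(axis=0), np.ones(g.shape[1])):
            raise ValidationError("each indicator column must sum to exactly 1")
        if (g.sum(axis=1) > 1).any():
            raise ValidationError("each indicator row may sum to at most 1")

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class MultiOmicsDataset:
    """A collection of views plus the intact (union) sample index."""

    views: tuple
    intact_samples: tuple

    def __post_init__(self):
        object.__setattr__(self, "views", tuple(self.views))
        object.__setattr__(self, "intact_samples", tuple(self.intact_samples))
        if len(self.views) < 1:
            raise ValidationError("dataset needs at least one view")
        intact = set(self.intact_samples)
        if len(intact) != len(self.intact_samples):
            raise ValidationError("duplicate IDs in intact sample list")
        covered = set()
        for v in self.views:
            extra = set(v.samples) - intact
            if extra:
                raise AlignmentError(
                    f"view {v.name!r} has samples outside the intact set: "
                    f"{sorted(extra)[:5]}"
                )
            covered |= set(v.samples)
        orphans = intact - covered
        if orphans:
            raise ValidationError(
                f"intact samples observed in zero views: {sorted(orphans)[:5]}"
            )

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def n_samples(self) -> int:
        return len(self.intact_samples)

    def indicators(self):
        """Indicator matrix for every view, in view order."""
        return [build_indicator_matrix(v, self.intact_samples) for v in self.views]

    def coverage_counts(self) -> np.ndarray:
        """Number of views observing each intact sample."""
        counts = np.zeros(self.n_samples, dtype=int)
        pos = {s: i for i, s in enumerate(self.intact_samples)}
        for v in self.views:
            for s in v.samples:
                counts[pos[s]] += 1
        return counts


def read_omics_csv(path, delimiter: str = ",", name: str | None = None) -> OmicsView:
    """Read one omics view from a delimited text file.

    The first row holds sample IDs, the first column feature IDs, and the
    body must be numeric.  ``"NA"`` and empty cells are treated as parse
    errors, not missing values: missing samples are absent columns, never
    holes in the matrix.
    """
    # check the raw header for duplicate sample IDs (pandas would silently
    # mangle them to "s1.1" etc.)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        dup = next(s for i, s in enumerate(header) if s in header[:i])
        raise ValidationError(f"{path}: duplicate sample ID {dup!r}")
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0, header=0,
                            keep_default_na=False, na_values=[], dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot read table ({exc})") from exc
    if frame.shape[0] < 1 or frame.shape[1] < 1:
        raise ParseError(f"{path}: table has no data body")
    numeric = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{path}: non-numeric cell {frame.iloc[i, j]!r} at feature "
                f"{frame.index[i]!r}, sample {col!r}"
            )
        numeric[:, j] = converted.to_numpy()
    view_name = name if name is not None else str(path)
    return OmicsView(name=view_name, features=tuple(str(f) for f in frame.index),
                     samples=tuple(str(s) for s in frame.columns), values=numeric)


def zscore_standardize(view: OmicsView) -> OmicsView:
    """Z-score each feature row across the view's samples.

    Uses the population (1/N) standard deviation.  Zero-variance rows carry
    no information for clustering and make the score undefined; they are
    dropped with a warning rather than imputed.
    """
    if view.n_samples < 2:
        raise ValidationError(
            f"view {view.name!r}: z-scoring needs at least 2 samples"
        )
    x = view.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population sd (ddof=0)
    keep = sd[:, 0] > 0
    if not keep.any():
        raise ValidationError(f"view {view.name!r}: every feature has zero variance")
    if not keep.all():
        dropped = [view.features[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"view {view.name!r}: dropped {len(dropped)} zero-variance "
            f"feature(s), e.g. {dropped[:3]}",
            stacklevel=2,
        )
    z = (x[keep] - mean[keep]) / sd[keep]
    return replace(view, features=tuple(np.asarray(view.features)[keep]), values=z)


def build_indicator_matrix(view: OmicsView, intact_samples) -> IndicatorMatrix:
    """Construct ``G`` for a view relative to the intact sample ordering."""
    intact_samples = tuple(intact_samples)
    pos = {s: i for i, s in enumerate(intact_samples)}
    g = np.zeros((len(intact_samples), view.n_samples))
    for j, s in enumerate(view.samples):
        if s not in pos:
            raise AlignmentError(
                f"view {view.name!r}: sample {s!r} not in intact sample list"
            )
        g[pos[s], j] = 1.0
    return IndicatorMatrix(g)


def align_views(views) -> MultiOmicsDataset:
    """Union-align views into a dataset.

    The intact ordering is the lexicographic sort of the union of sample
    IDs, which is deterministic across runs and input orderings.
    """
    views = tuple(views)
    if not views:
        raise ValidationError("align_views: empty view list")
    union = sorted(set().union(*(set(v.samples) for v in views)))
    return MultiOmicsDataset(views=views, intact_samples=tuple(union))


def pos_neg_split(m: np.ndarray):
    """Split ``M`` into nonnegative parts ``M± = (|M| ± M) / 2``.

    ``M_plus - M_minus == M`` exactly; both parts are entrywise >= 0.  This
    is the standard device that makes multiplicative updates sign-safe for
    mixed-sign factors.
    """
    m = np.asarray(m, dtype=float)
    a = np.abs(m)
    return (a + m) / 2.0, (a - m) / 2.0
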