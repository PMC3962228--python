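"""Descriptor-matrix handling: normalization, PCA projection, distances,
centrality and structural-disruptor detection.

A dataset is a :class:`DescriptorTable` — compound identifiers plus a dense
real-valued matrix of molecular descriptors (e.g. predicted lipophilicity /
solubility alongside sparse group-count indices). All selection algorithms
operate on a :class:`ChemSpace`, a low-dimensional projection of the table
together with its pairwise Euclidean distance matrix rescaled to [0, 1].

Descriptors are brought to a common [0, 1] range by min-max normalization
rather than standardization: group-count descriptors are zero for most
compounds, so a normality assumption is untenable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DescriptorTable",
    "ChemSpace",
    "DisruptorReport",
    "MinMaxParams",
    "load_table",
    "save_table",
    "normalize_minmax",
    "minmax_params",
    "apply_minmax",
    "denormalize_row",
    "pca_project",
    "distance_matrix",
    "central_index",
    "detect_disruptor",
]


@dataclass
class DescriptorTable:
    """Compound identifiers plus an n_compounds x n_descriptors real matrix."""

    ids: list
    X: np.ndarray
    descriptor_names: list
    normalized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("number of ids does not match number of rows")
        if len(self.descriptor_names) != self.X.shape[1]:
            raise ValueError("number of descriptor names does not match columns")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate compound identifiers")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("descriptor matrix contains missing/non-finite values")

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    def subset(self, rows) -> "DescriptorTable":
        """Row subset preserving descriptor names and normalization state."""
        rows = np.asarray(rows, dtype=int)
        return DescriptorTable(
            ids=[self.ids[i] for i in rows],
            X=self.X[rows],
            descriptor_names=list(self.descriptor_names),
            normalized=self.normalized,
        )


@dataclass
class ChemSpace:
    """A projected search space with its [0,1]-normalized distance matrix."""

    points: np.ndarray
    DM: np.ndarray
    source: str = "selected descriptors"

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]


@dataclass
class DisruptorReport:
    """Outcome of the structural-disruptor test for a candidate compound.

    ``sd_distance`` is measured in central-97% trimmed standard deviations of
    the principal-component scores of the remaining compounds;
    ``loading_shift`` is 1 - |cos| between the component loadings computed
    with and without the candidate.
    """

    is_disruptor: bool
    component: int
    sd_distance: float
    loading_shift: float
    sd_distances: tuple = field(default=())
    loading_shifts: tuple = field(default=())


@dataclass(frozen=True)
class MinMaxParams:
    """Per-column ranges of a fitted min-max normalization."""

    col_min: np.ndarray
    col_max: np.ndarray


def load_table(path, sep: str = ",") -> DescriptorTable:
    """Read a descriptor table from CSV/TSV: first column ``id``, the rest
    numeric descriptors, header required."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("descriptor table needs an id column plus descriptors")
    ids = df.iloc[:, 0].astype(str).tolist()
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(f"missing values in descriptor table {path!r}")
    return DescriptorTable(ids=ids, X=X, descriptor_names=list(df.columns[1:]))


def save_table(table: DescriptorTable, path, sep: str = ",") -> None:
    df = pd.DataFrame(table.X, columns=table.descriptor_names)
    df.insert(0, "id", table.ids)
    df.to_csv(path, sep=sep, index=False)


def minmax_params(table: DescriptorTable) -> MinMaxParams:
    """Fit per-column min/max on a (design) table."""
    return MinMaxParams(col_min=table.X.min(axis=0), col_max=table.X.max(axis=0))


def apply_minmax(
    table: DescriptorTable, params: MinMaxParams, clip: bool = True
) -> DescriptorTable:
    """Apply previously fitted ranges, e.g. to validation compounds.

    Columns that were constant in the fitting set map to zero. With
    ``clip`` the result is truncated to [0, 1] so that out-of-range
    validation compounds cannot extrapolate the scale.
    """
    span = params.col_max - params.col_min
    safe = np.where(span > 0, span, 1.0)
    Xn = (table.X - params.col_min) / safe
    Xn[:, span == 0] = 0.0
    if clip:
        Xn = np.clip(Xn, 0.0, 1.0)
    return replace(table, X=Xn, normalized=True)


def denormalize_row(row: np.ndarray, params: MinMaxParams) -> np.ndarray:
    """Map a row from normalized [0,1] coordinates back to raw units."""
    row = np.asarray(row, dtype=float)
    return row * (params.col_max - params.col_min) + params.col_min


def normalize_minmax(table: DescriptorTable) -> DescriptorTable:
    """Map every column to [0, 1] via (c - min) / (max - min).

    Constant columns become all-zeros instead of being dropped, which keeps
    column indexing stable across design/validation partitions; a constant
    column carries no distance information either way.
    """
    if table.n_compounds < 1 or table.n_descriptors < 1:
        raise ValueError("cannot normalize an empty table")
    return apply_minmax(table, minmax_params(table), clip=False)


def distance_matrix(points: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances divided by the maximum pairwise distance.

    Degenerate input (all points identical) yields the all-zero matrix with
    a warning.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise ValueError("need at least two points for a distance matrix")
    dm = squareform(pdist(points))
    dmax = dm.max()
    if dmax == 0:
        warnings.warn("all points identical: degenerate (all-zero) distance matrix")
        return dm
    return dm / dmax


def _uncentered_pca(X: np.ndarray):
    """SVD-based principal axes of the raw cross-product matrix X'X."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return U * s, s, Vt


def pca_project(
    table: DescriptorTable, k: int, centered: bool = False
) -> ChemSpace:
    """Project onto the top-k principal components and build the distance
    matrix of the scores.

    By default the data are *not* centered before the orthogonal
    transformation — on [0,1]-normalized, mostly-zero descriptors the
    uncentered cross-product decomposition is the conventional protocol
    here. Pass ``centered=True`` for ordinary (covariance) PCA.
    """
    if not table.normalized:
        raise ValueError("pca_project expects a normalized table")
    X = table.X - table.X.mean(axis=0) if centered else table.X
    scores, s, _ = _uncentered_pca(X)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    k_eff = min(k, X.shape[0], X.shape[1])
    if k_eff > rank and rank > 0:
        warnings.warn(
            f"requested {k} components but matrix rank is {rank}; "
            "trailing components are numerically null"
        )
    pts = scores[:, :k_eff]
    return ChemSpace(
        points=pts,
        DM=distance_matrix(pts) if pts.shape[0] >= 2 else np.zeros((1, 1)),
        source="principal components",
    )


def central_index(DM: np.ndarray) -> int:
    """Compound with the minimum sum of distances to all others.

    Ties break to the lowest index, keeping every selector that starts from
    the central point bit-reproducible.
    """
    DM = np.asarray(DM)
    return int(np.argmin(DM.sum(axis=1)))


def _trimmed_stats(scores: np.ndarray, central: float = 0.97):
    """Mean/SD of the central ``central`` fraction of a score vector."""
    tail = (1.0 - central) / 2.0 * 100.0
    lo, hi = np.percentile(scores, [tail, 100.0 - tail])
    kept = scores[(scores >= lo) & (scores <= hi)]
    if kept.size < 2:
        kept = scores
    return float(kept.mean()), float(kept.std(ddof=1))


def detect_disruptor(
    table: DescriptorTable, candidate_row: np.ndarray
) -> DisruptorReport:
    """Test whether appending ``candidate_row`` makes it a structural
    disruptor of the first or second principal component.

    The PCA is recomputed with the candidate appended. For PC1 and PC2 the
    candidate's score is compared with the central 97% of the other
    compounds' scores: ``sd_distance`` is its distance from the trimmed mean
    in trimmed-SD units, and the candidate is flagged when that distance
    reaches five SDs on either component. The loading rotation induced by
    the candidate is reported as ``loading_shift`` (1 - |cosine|) but does
    not enter the boolean, since no principled threshold exists for it.
    """
    if not table.normalized:
        raise ValueError("detect_disruptor expects a normalized table")
    n = table.n_compounds
    if n < 34:
        raise ValueError(
            "need at least 34 compounds: a central-97% trim is meaningless below that"
        )
    cand = np.asarray(candidate_row, dtype=float).ravel()
    if cand.size != table.n_descriptors:
        raise ValueError("candidate row has wrong number of descriptors")

    _, _, Vt_before = _uncentered_pca(table.X)
    X_aug = np.vstack([table.X, cand])
    scores_aug, _, Vt_after = _uncentered_pca(X_aug)

    sd_distances, loading_shifts = [], []
    for pc in range(min(2, Vt_after.shape[0])):
        others = scores_aug[:n, pc]
        mu, sd = _trimmed_stats(others)
        sd = max(sd, 1e-12)
        sd_distances.append(abs(scores_aug[n, pc] - mu) / sd)
        cosine = 0.0
        if pc < Vt_before.shape[0]:
            cosine = abs(float(Vt_before[pc] @ Vt_after[pc]))
            cosine /= max(
                np.linalg.norm(Vt_before[pc]) * np.linalg.norm(Vt_after[pc]), 1e-300
            )
        loading_shifts.append(1.0 - min(cosine, 1.0))

    worst = int(np.argmax(sd_distances))
    return DisruptorReport(
        is_disruptor=bool(max(sd_distances) >= 5.0),
        component=worst + 1,
        sd_distance=float(sd_distances[worst]),
        loading_shift=float(loading_shifts[worst]),
        sd_distances=tuple(sd_distances),
        loading_shifts=tuple(loading_shifts),
    )
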