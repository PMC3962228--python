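"""Static (one-shot) compound-selection algorithms.

Five classic experimental-design strategies, each returning an ordered list
of compound indices of a requested size from a :class:`~adaptsel.chemspace.ChemSpace`:

* Kennard-Stone maximin dissimilarity selection,
* D-Optimal design via Fedorov exchange on the information-matrix determinant,
* space-filling design on a 3-component grid,
* most-descriptive-compound (MDC) similarity selection,
* uniform random selection as a reference.

All ties break to the lowest compound index, so every deterministic
selector is bit-reproducible; the stochastic ones take an explicit
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chemspace import ChemSpace, central_index

__all__ = [
    "SelectionResult",
    "kennard_stone",
    "d_optimal_fedorov",
    "space_filling",
    "mdc",
    "random_select",
]


@dataclass
class SelectionResult:
    indices: list
    method: str
    size: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.indices) != self.size:
            raise ValueError("selection size mismatch")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection contains duplicate indices")


def kennard_stone(space: ChemSpace, n_select: int, start="central") -> SelectionResult:
    """Sequential maximin selection.

    The first compound is the central point of the dataset (minimum distance
    sum) unless an explicit start index is given; each further compound
    maximizes the Euclidean distance to its closest neighbor among those
    already selected.
    """
    n = space.n
    if not 1 <= n_select <= n:
        raise ValueError(f"n_select must be in [1, {n}]")
    DM = space.DM
    first = central_index(DM) if start == "central" else int(start)
    selected = [first]
    # distance of every compound to its nearest selected neighbor
    nearest = DM[:, first].copy()
    for _ in range(n_select - 1):
        nearest[selected] = -np.inf
        nxt = int(np.argmax(nearest))  # argmax takes the lowest index on ties
        selected.append(nxt)
        nearest = np.minimum(nearest, DM[:, nxt])
    return SelectionResult(indices=selected, method="kennard-stone", size=n_select)


def _model_matrix(points: np.ndarray, intercept: bool) -> np.ndarray:
    if intercept:
        return np.hstack([np.ones((points.shape[0], 1)), points])
    return points


def _fedorov_once(F_X: np.ndarray, sel: np.ndarray, free_mask: np.ndarray):
    """One Fedorov exchange descent from an initial set; returns
    (selected indices, determinant trajectory) or None if singular.

    Uses the classical variance-function delta: swapping selected i for
    candidate j multiplies det(X'X) by
    1 + d(j) - d(i) - (d(i) d(j) - d(i,j)^2),
    where d(.) is the prediction variance x' (X'X)^-1 x.
    """
    n = F_X.shape[0]
    sel = list(sel)
    in_sel = np.zeros(n, dtype=bool)
    in_sel[sel] = True
    Xs = F_X[sel]
    F = Xs.T @ Xs
    sign, logdet = np.linalg.slogdet(F)
    if sign <= 0:
        return None
    det = float(np.exp(logdet))
    traj = [det]
    for _ in range(10_000):
        Finv = np.linalg.inv(F)
        free_sel = [i for i in sel if free_mask[i]]
        cand = np.flatnonzero(~in_sel)
        if not free_sel or cand.size == 0:
            break
        A = F_X[free_sel] @ Finv  # |free_sel| x p
        d_i = np.einsum("ij,ij->i", A, F_X[free_sel])
        d_j = np.einsum("ij,ij->i", F_X[cand] @ Finv, F_X[cand])
        cross = A @ F_X[cand].T
        delta = (
            d_j[None, :]
            - d_i[:, None]
            - (d_i[:, None] * d_j[None, :] - cross**2)
        )
        best = np.unravel_index(np.argmax(delta), delta.shape)
        gain = delta[best]
        if gain <= 1e-12:
            break
        i, j = free_sel[best[0]], int(cand[best[1]])
        sel[sel.index(i)] = j
        in_sel[i], in_sel[j] = False, True
        xi, xj = F_X[i], F_X[j]
        F = F + np.outer(xj, xj) - np.outer(xi, xi)
        det *= float(1.0 + gain)
        traj.append(det)
    return sel, traj


def d_optimal_fedorov(
    space: ChemSpace,
    n_select: int,
    fixed=(),
    restarts: int = 10,
    rng: np.random.Generator | None = None,
    intercept: bool = True,
) -> SelectionResult:
    """D-Optimal subset selection with the Fedorov exchange heuristic.

    Maximizes det(X'X) of the selected design points (an intercept column is
    appended by default). Each restart draws a random initial set containing
    the ``fixed`` indices and performs single-point exchanges, accepting
    only determinant increases; the best converged set over all restarts is
    returned, with the (non-decreasing) determinant trajectory in ``meta``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = space.n
    fixed = [int(i) for i in fixed]
    if not 1 <= n_select <= n:
        raise ValueError(f"n_select must be in [1, {n}]")
    if len(fixed) > n_select:
        raise ValueError("more fixed points than n_select")
    F_X = _model_matrix(space.points, intercept)
    free_mask = np.ones(n, dtype=bool)
    free_mask[fixed] = False
    pool = np.flatnonzero(free_mask)
    n_free = n_select - len(fixed)

    if n_free == 0:
        Xs = F_X[fixed]
        det = float(np.linalg.det(Xs.T @ Xs))
        return SelectionResult(
            indices=list(fixed),
            method="d-optimal",
            size=n_select,
            meta={"determinant": det, "det_trajectory": [det]},
        )

    best = None
    for _ in range(max(1, restarts)):
        init = fixed + [int(i) for i in rng.choice(pool, size=n_free, replace=False)]
        out = _fedorov_once(F_X, init, free_mask)
        if out is None:
            continue
        sel, traj = out
        if best is None or traj[-1] > best[1][-1]:
            best = (sel, traj)
    if best is None:
        raise np.linalg.LinAlgError(
            "information matrix singular at every restart: the space is "
            "degenerate or n_select is too small for the model matrix"
        )
    sel, traj = best
    # fixed points first, then the free ones in ascending order for determinism
    free_part = sorted(i for i in sel if i not in fixed)
    return SelectionResult(
        indices=fixed + free_part,
        method="d-optimal",
        size=n_select,
        meta={"determinant": traj[-1], "det_trajectory": traj},
    )


def space_filling(space: ChemSpace, n_select: int) -> SelectionResult:
    """Grid-based space-filling design on exactly three components.

    Each axis is split into b equal bins (b scanned upward from 1) until the
    number of nonempty cells reaches ``n_select``; the representative of a
    cell is the compound closest to the cell center. When more cells than
    needed are nonempty, the most populated cells win (ties by lowest cell
    linear index).
    """
    pts = space.points
    if pts.shape[1] != 3:
        raise ValueError("space_filling is fixed to a 3-component space")
    n = pts.shape[0]
    n_distinct = np.unique(pts, axis=0).shape[0]
    if n_select > n_distinct:
        raise ValueError(
            f"cannot select {n_select} compounds from {n_distinct} distinct points"
        )
    mins, maxs = pts.min(axis=0), pts.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)

    for b in range(1, 10_000):
        # right-closed final bin: every point lands in exactly one cell
        axis_bin = np.minimum((((pts - mins) / span) * b).astype(int), b - 1)
        cell = axis_bin[:, 0] * b * b + axis_bin[:, 1] * b + axis_bin[:, 2]
        cells, counts = np.unique(cell, return_counts=True)
        if cells.size >= n_select:
            break
    else:  # pragma: no cover
        raise RuntimeError("bin scan failed to isolate enough cells")

    if cells.size > n_select:
        # most populated first; ties by lowest linear cell index
        order = np.lexsort((cells, -counts))
        keep = set(cells[order[:n_select]].tolist())
    else:
        keep = set(cells.tolist())

    width = span / b
    selected = []
    for c in sorted(keep):
        members = np.flatnonzero(cell == c)
        i0, i1, i2 = c // (b * b), (c // b) % b, c % b
        center = mins + (np.array([i0, i1, i2]) + 0.5) * width
        dists = np.linalg.norm(pts[members] - center, axis=1)
        selected.append(int(members[np.argmin(dists)]))
    return SelectionResult(
        indices=selected, method="space-filling", size=n_select, meta={"b": b}
    )


def _nn_rank_matrix(DM: np.ndarray) -> np.ndarray:
    """r[i, j] = rank of compound i in compound j's nearest-neighbor ordering
    (1 = nearest, self excluded, ties broken by lower index)."""
    n = DM.shape[0]
    r = np.zeros((n, n))
    for j in range(n):
        order = sorted((DM[i, j], i) for i in range(n) if i != j)
        for rank, (_, i) in enumerate(order, start=1):
            r[i, j] = rank
    np.fill_diagonal(r, np.inf)  # self contributes nothing
    return r


def mdc(space: ChemSpace, n_select: int) -> SelectionResult:
    """Most-descriptive-compound selection.

    Every compound carries a representativeness score: the weighted sum of
    reciprocal nearest-neighbor ranks over all compounds. The top scorer is
    selected, after which each compound's weight is reduced by the
    information the selection already conveys about it
    (w_j <- w_j * (1 - 1/r_cj)); scores are then recomputed. A fixed number
    of compounds is selected rather than a stop criterion.
    """
    n = space.n
    if not 1 <= n_select <= n:
        raise ValueError(f"n_select must be in [1, {n}]")
    r = _nn_rank_matrix(space.DM)
    recip = 1.0 / r  # inf ranks -> 0 contribution
    w = np.ones(n)
    selected: list[int] = []
    score_traj = []
    for _ in range(n_select):
        scores = recip @ w
        scores[selected] = -np.inf
        c = int(np.argmax(scores))
        selected.append(c)
        score_traj.append(float(scores[c]))
        w = w * (1.0 - recip[c, :])
        w[c] = 0.0  # the selected compound's own information is fully deduced
    return SelectionResult(
        indices=selected, method="mdc", size=n_select,
        meta={"score_trajectory": score_traj},
    )


def random_select(
    n: int, n_select: int, rng: np.random.Generator
) -> SelectionResult:
    """Uniform selection without replacement (the reference method)."""
    if not 1 <= n_select <= n:
        raise ValueError(f"n_select must be in [1, {n}]")
    idx = rng.choice(n, size=n_select, replace=False)
    return SelectionResult(
        indices=[int(i) for i in idx], method="random", size=n_select
    )
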