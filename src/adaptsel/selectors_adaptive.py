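"""Stepwise adaptive compound selection: DescRep and PLS-Optimal.

Both methods alternate two phases against an endpoint oracle. First the
representation of the chemical space is refined using the endpoint values
measured so far — DescRep re-selects a small set of endpoint-correlated,
mutually decorrelated descriptors; PLS-Optimal re-fits a PLS model and uses
its latent variables. Then a batch of new compounds is selected in the
refined space, always extending the previously selected seed, until a
prefixed schedule of cumulative sample sizes is exhausted.

DescRep's compound picker is representativeness-based: each candidate x
carries a priority score PS_x = prod_i CF_xi over the selected compounds i,
with the hyperbolic coverage kernel CF_xi = 1 - (1 - DM_xi)^exp. The
exponent adapts each cycle to the local density around the dataset's
central compound so that its n_cover nearest neighbors stay above a
coverage threshold lambda (default 0.75). The batch minimizing the total
remaining priority score is taken.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression

from .chemspace import ChemSpace, DescriptorTable, central_index, distance_matrix, pca_project
from .selectors_static import d_optimal_fedorov

__all__ = [
    "DescriptorScores",
    "AdaptiveRun",
    "score_descriptors",
    "select_descriptors",
    "initial_seed",
    "compute_exponent",
    "priority_scores",
    "select_batch",
    "descrep_run",
    "pls_optimal_extend",
    "pls_optimal_run",
]

DEFAULT_LAMBDA = 0.75
_EPS = 1e-9


@dataclass
class DescriptorScores:
    """Endpoint-correlation scores S plus the descriptor correlation matrix M."""

    S: np.ndarray
    M: np.ndarray
    selected: list = field(default_factory=list)


@dataclass
class CycleRecord:
    cycle: int
    new_indices: list
    descriptor_indices: list | None = None
    exponent: float | None = None


@dataclass
class AdaptiveRun:
    """Record of one adaptive selection: nested selections along a schedule."""

    method: str
    schedule: list
    selected: list
    cycles: list
    y_revealed: dict = field(default_factory=dict)

    def selection_at(self, size: int) -> list:
        """Selection at a given cumulative sample size (a prefix)."""
        if size not in self.schedule:
            raise ValueError(f"size {size} not on the schedule {self.schedule}")
        return self.selected[:size]


def score_descriptors(
    X_measured: np.ndarray, y_measured: np.ndarray, X_design: np.ndarray
) -> DescriptorScores:
    """Score every descriptor by |Pearson r| with the endpoint over the
    measured compounds; build the absolute descriptor-descriptor
    correlation matrix M over the full design set.

    Descriptors constant over the measured compounds score 0; correlations
    involving a design-constant descriptor are 0 off-diagonal (diagonal 1).
    """
    X_measured = np.asarray(X_measured, dtype=float)
    y = np.asarray(y_measured, dtype=float)
    if X_measured.shape[0] < 3:
        raise ValueError("need at least 3 measured compounds for correlations")
    Xc = X_measured - X_measured.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = math.sqrt(float((yc**2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.abs(Xc.T @ yc) / (sx * sy) if sy > 0 else np.zeros(Xc.shape[1])
    S[~np.isfinite(S)] = 0.0
    S[sx == 0] = 0.0

    Xd = np.asarray(X_design, dtype=float)
    Xdc = Xd - Xd.mean(axis=0)
    sd = np.sqrt((Xdc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.abs((Xdc.T @ Xdc) / np.outer(sd, sd))
    M[~np.isfinite(M)] = 0.0
    np.fill_diagonal(M, 1.0)
    M = np.clip(M, 0.0, 1.0)
    return DescriptorScores(S=S, M=M)


def select_descriptors(scores: DescriptorScores, k: int) -> list:
    """Iteratively pick the highest-scoring descriptor and down-weight the
    rest by their correlation to it: S_i <- S_i * (1 - M_ix)^3.

    The cubic factor annihilates perfectly correlated descriptors and barely
    touches orthogonal ones, steering the selection toward complementary
    information. If every remaining score hits zero, the remaining slots are
    filled by lowest index with a warning.
    """
    S = scores.S.astype(float).copy()
    M = scores.M
    if k > S.size:
        raise ValueError("cannot select more descriptors than available")
    picked: list[int] = []
    for _ in range(k):
        S[picked] = -np.inf
        best = int(np.argmax(S))
        if S[best] <= 0.0:
            break
        picked.append(best)
        S = S * (1.0 - M[best, :]) ** 3
    if len(picked) < k:
        warnings.warn(
            "descriptor scores exhausted before k selections; "
            "filling remaining slots by lowest index"
        )
        for i in range(scores.S.size):
            if len(picked) == k:
                break
            if i not in picked:
                picked.append(i)
    scores.selected = picked
    return picked


def initial_seed(
    space: ChemSpace,
    k: int,
    restarts: int = 15,
    rng: np.random.Generator | None = None,
) -> list:
    """Seed selection: k-means partition of the space, restarted with random
    starting compounds; the partition with the lowest total within-cluster
    pairwise distance wins, and each cluster contributes its medoid (lowest
    within-cluster pairwise distance sum)."""
    rng = rng if rng is not None else np.random.default_rng()
    pts = space.points
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == 1:
        return [central_index(space.DM)]

    best_labels, best_obj = None, np.inf
    attempts = 0
    done = 0
    while done < restarts and attempts < restarts * 4:
        attempts += 1
        init_idx = rng.choice(n, size=k, replace=False)
        km = KMeans(n_clusters=k, init=pts[init_idx], n_init=1, max_iter=300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = km.fit_predict(pts)
        if np.unique(labels).size < k:
            continue  # empty cluster: re-draw this restart
        obj = 0.0
        for c in range(k):
            members = pts[labels == c]
            if members.shape[0] > 1:
                obj += float(pdist(members).sum())
        done += 1
        if obj < best_obj:
            best_obj, best_labels = obj, labels
    if best_labels is None:
        raise RuntimeError("k-means produced empty clusters in every restart")

    medoids = []
    for c in range(k):
        members = np.flatnonzero(best_labels == c)
        sub = space.DM[np.ix_(members, members)]
        medoids.append(int(members[np.argmin(sub.sum(axis=1))]))
    return sorted(medoids)


def compute_exponent(
    DM: np.ndarray,
    central: int | None = None,
    n_cover: int = 1,
    lamda: float = DEFAULT_LAMBDA,
) -> float:
    """Adaptive exponent of the coverage kernel.

    Let d_k be the distance from the dataset's central compound to its
    n_cover-th nearest neighbor. The exponent solves
    (1 - d_k)^exp = lambda, i.e. exp = ln(lambda) / ln(1 - d_k), so that
    exactly the n_cover nearest neighbors of the central point are covered
    above the threshold. Dense neighborhoods (small d_k) therefore get a
    sharp kernel, sparse ones a flat kernel.
    """
    DM = np.asarray(DM)
    n = DM.shape[0]
    if n < 2:
        raise ValueError("need at least 2 compounds")
    if not 0.0 < lamda < 1.0:
        raise ValueError("lambda must lie in (0, 1)")
    if not 1 <= n_cover < n:
        raise ValueError(f"n_cover must be in [1, {n - 1}]")
    c = central_index(DM) if central is None else int(central)
    dists = np.sort(np.delete(DM[c], c))
    d_k = float(np.clip(dists[n_cover - 1], _EPS, 1.0 - _EPS))
    return math.log(lamda) / math.log(1.0 - d_k)


def correction_factors(DM_rows: np.ndarray, exp: float) -> np.ndarray:
    """CF = 1 - (1 - DM)^exp, elementwise."""
    return 1.0 - (1.0 - np.asarray(DM_rows)) ** exp


def priority_scores(DM: np.ndarray, selected, exp: float) -> np.ndarray:
    """PS_x = prod over selected i of (1 - (1 - DM_xi)^exp).

    A compound coincident with a selected one gets PS 0 (fully covered); one
    at maximal distance from every selected compound keeps PS 1.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("selected set must be non-empty")
    CF = correction_factors(DM[:, selected], exp)
    return np.prod(CF, axis=1)


def select_batch(
    DM: np.ndarray,
    selected,
    batch: int,
    exp: float,
    max_exhaustive: int = 20_000,
) -> list:
    """Pick the batch of unselected compounds minimizing the total priority
    score over all compounds after their inclusion.

    All candidate combinations are enumerated when their number is at most
    ``max_exhaustive``; beyond that a greedy one-at-a-time minimization is
    used (each addition minimizes the resulting total PS).
    """
    DM = np.asarray(DM)
    n = DM.shape[0]
    selected = list(selected)
    candidates = [i for i in range(n) if i not in selected]
    if batch < 1:
        raise ValueError("batch must be >= 1")
    if batch > len(candidates):
        raise ValueError("batch larger than the number of unselected compounds")

    base = priority_scores(DM, selected, exp)
    CF = correction_factors(DM, exp)  # CF[x, i] covers x by i

    if math.comb(len(candidates), batch) <= max_exhaustive:
        best_combo, best_total = None, np.inf
        for combo in itertools.combinations(candidates, batch):
            ps = base * np.prod(CF[:, combo], axis=1)
            total = float(ps.sum())
            if total < best_total - 1e-15:
                best_total, best_combo = total, combo
        return list(best_combo)

    ps = base.copy()
    chosen: list[int] = []
    cand_mask = np.zeros(n, dtype=bool)
    cand_mask[candidates] = True
    for _ in range(batch):
        totals = ps @ CF  # totals[j] = sum_x ps_x * CF_xj
        totals[~cand_mask] = np.inf
        j = int(np.argmin(totals))
        chosen.append(j)
        cand_mask[j] = False
        ps = ps * CF[:, j]
    return chosen


def _check_schedule(schedule) -> list:
    schedule = [int(s) for s in schedule]
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly increasing")
    return schedule


def descrep_run(
    table: DescriptorTable,
    oracle,
    schedule,
    k_descriptors: int = 5,
    rng: np.random.Generator | None = None,
    lamda: float = DEFAULT_LAMBDA,
    n_components_seed: int = 5,
    max_exhaustive: int = 20_000,
    seed_indices=None,
) -> AdaptiveRun:
    """Run the full DescRep stepwise selection.

    Cycle 0 seeds ``schedule[0]`` compounds via a k-means partition of the
    principal-component space and queries the oracle. Each later cycle
    re-scores the descriptors against the measured endpoint values, selects
    ``k_descriptors`` decorrelated ones, rebuilds the distance matrix in
    that descriptor subspace, recomputes the coverage exponent, and extends
    the selection with the batch minimizing the total priority score.

    ``oracle`` maps a list of compound indices to endpoint values; revealed
    values accumulate in the returned :class:`AdaptiveRun`. A campaign that
    already measured some compounds can warm-start by passing them as
    ``seed_indices`` (length ``schedule[0]``), skipping the k-means seed.
    """
    if not table.normalized:
        raise ValueError("descrep_run expects a normalized table")
    rng = rng if rng is not None else np.random.default_rng()
    schedule = _check_schedule(schedule)

    if seed_indices is not None:
        seed = [int(i) for i in seed_indices]
        if len(seed) != schedule[0]:
            raise ValueError("seed_indices length must equal schedule[0]")
    else:
        pca_space = pca_project(table, k=min(n_components_seed, table.n_compounds,
                                             table.n_descriptors))
        seed = initial_seed(pca_space, schedule[0], rng=rng)
    selected = list(seed)
    run = AdaptiveRun(method="descrep", schedule=schedule, selected=selected,
                      cycles=[CycleRecord(cycle=0, new_indices=list(seed))])
    _reveal(run, oracle, seed)

    for cycle, target in enumerate(schedule[1:], start=1):
        batch = target - len(selected)
        X_measured = table.X[selected]
        y_measured = np.array([run.y_revealed[i] for i in selected])
        scores = score_descriptors(X_measured, y_measured, table.X)
        desc = select_descriptors(scores, k_descriptors)
        DM = distance_matrix(table.X[:, desc])
        n_cover = min(len(selected) + batch, table.n_compounds - 1)
        exp = compute_exponent(DM, n_cover=n_cover, lamda=lamda)
        new = select_batch(DM, selected, batch, exp, max_exhaustive=max_exhaustive)
        selected.extend(new)
        run.cycles.append(CycleRecord(cycle=cycle, new_indices=list(new),
                                      descriptor_indices=list(desc), exponent=exp))
        _reveal(run, oracle, new)
    run.selected = selected
    return run


def _reveal(run: AdaptiveRun, oracle, indices) -> None:
    try:
        values = oracle(list(indices))
    except Exception:
        warnings.warn("oracle failure: adaptive run aborted, partial run preserved")
        raise
    for i, v in zip(indices, np.atleast_1d(np.asarray(values, dtype=float))):
        run.y_revealed[int(i)] = float(v)


def _fit_pls_scores(X, y, n_components):
    """PLS latent-variable projection with automatic rank fallback."""
    n_components = int(n_components)
    while n_components > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls = PLSRegression(n_components=n_components, scale=False)
                pls.fit(X, y)
            return pls
        except Exception:
            warnings.warn("PLS rank deficiency: reducing number of latent variables")
            n_components -= 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=1, scale=False)
        pls.fit(X, y)
    return pls


def pls_optimal_extend(
    table: DescriptorTable,
    y_measured,
    selected,
    batch: int,
    n_latent: int = 5,
    rng: np.random.Generator | None = None,
    restarts: int = 10,
) -> list:
    """One PLS-Optimal cycle: refit PLS on the measured compounds, project
    the whole design set onto its first ``n_latent`` latent variables, and
    extend the selection by ``batch`` compounds with D-Optimal/Fedorov,
    keeping the already-selected compounds fixed."""
    if not table.normalized:
        raise ValueError("pls_optimal_extend expects a normalized table")
    selected = [int(i) for i in selected]
    if batch == 0:
        return list(selected)
    y = np.asarray(y_measured, dtype=float)
    if len(selected) < n_latent + 2:
        n_latent = max(1, len(selected) - 2)
    pls = _fit_pls_scores(table.X[selected], y, n_latent)
    scores = pls.transform(table.X)
    space = ChemSpace(points=scores, DM=distance_matrix(scores),
                      source="pls latent variables")
    result = d_optimal_fedorov(space, n_select=len(selected) + batch,
                               fixed=selected, restarts=restarts, rng=rng)
    return result.indices


def pls_optimal_run(
    table: DescriptorTable,
    oracle,
    schedule,
    n_latent: int = 5,
    rng: np.random.Generator | None = None,
    restarts: int = 10,
    n_components_seed: int = 5,
) -> AdaptiveRun:
    """Full PLS-Optimal stepwise run.

    The seed is a D-Optimal selection on the principal-component space (the
    method's natural endpoint-free starting design); each later cycle calls
    :func:`pls_optimal_extend` on the latent-variable space refit to the
    measured compounds.
    """
    if not table.normalized:
        raise ValueError("pls_optimal_run expects a normalized table")
    rng = rng if rng is not None else np.random.default_rng()
    schedule = _check_schedule(schedule)

    pca_space = pca_project(table, k=min(n_components_seed, table.n_compounds,
                                         table.n_descriptors))
    seed = d_optimal_fedorov(pca_space, schedule[0], restarts=restarts,
                             rng=rng).indices
    selected = list(seed)
    run = AdaptiveRun(method="pls-optimal", schedule=schedule, selected=selected,
                      cycles=[CycleRecord(cycle=0, new_indices=list(seed))])
    _reveal(run, oracle, seed)

    for cycle, target in enumerate(schedule[1:], start=1):
        batch = target - len(selected)
        y_measured = np.array([run.y_revealed[i] for i in selected])
        extended = pls_optimal_extend(table, y_measured, selected, batch,
                                      n_latent=n_latent, rng=rng,
                                      restarts=restarts)
        new = [i for i in extended if i not in selected]
        selected.extend(new)
        run.cycles.append(CycleRecord(cycle=cycle, new_indices=list(new)))
        _reveal(run, oracle, new)
    run.selected = selected
    return run
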