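"""Synthetic descriptor tables with the statistical structure of typical
QSAR descriptor sets, plus controlled structural-disruptor injection.

The generator mimics a dataset described by two families of descriptors: a
few dense continuous ones (predicted lipophilicity and aqueous solubility,
which are strongly anticorrelated in real compound collections) and a long
tail of sparse non-negative group-count descriptors that are exactly zero
for most compounds, as electrotopological group sums are. The endpoint is a
linear (optionally mildly quadratic) combination of a small driver subset
of descriptors plus Gaussian noise, and the generating truth is always
returned so downstream tests can do driver-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemspace import DescriptorTable, detect_disruptor

__all__ = ["SyntheticSpec", "generate", "make_disruptor", "endpoint_for"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults give 2 dense + 200 sparse descriptors with 90% zeros in the
    sparse block. Drivers default to both dense descriptors and the first
    two sparse ones; driver sparse columns are drawn at a reduced zero
    fraction (common chemical groups are the informative ones), capped at
    0.5. ``noise_sd`` is in endpoint units.
    """

    n_compounds: int = 300
    n_dense: int = 2
    n_sparse: int = 200
    sparsity: float = 0.9
    drivers: tuple = None
    weights: tuple = None
    noise_sd: float = 0.3
    nonlinearity: bool = False
    dense_corr: float = -0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        d = self.n_dense + self.n_sparse
        if self.drivers is None:
            default = list(range(min(2, self.n_dense)))
            default += [self.n_dense + j for j in range(min(2, self.n_sparse))]
            self.drivers = tuple(default)
            if self.weights is None:
                self.weights = tuple([1.0, -0.8, 0.6, 0.5][: len(self.drivers)])
        if self.weights is None:
            self.weights = tuple(1.0 for _ in self.drivers)
        if len(self.weights) != len(self.drivers):
            raise ValueError("weights and drivers must have equal length")
        if any(not 0 <= j < d for j in self.drivers):
            raise ValueError("driver index outside the descriptor range")


def _raw_endpoint(X: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    y = np.zeros(X.shape[0])
    for j, w in zip(spec.drivers, spec.weights):
        y += w * X[:, j]
    if spec.nonlinearity and spec.drivers:
        j0 = spec.drivers[0]
        y += 0.3 * X[:, j0] ** 2
    return y


def generate(spec: SyntheticSpec):
    """Draw one synthetic dataset.

    Returns ``(table, y, truth)`` where ``table`` is the raw (unnormalized)
    descriptor table, ``y`` the noisy endpoint, and ``truth`` a record of
    drivers, weights and noise for recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    n, nd, ns = spec.n_compounds, spec.n_dense, spec.n_sparse

    # dense block: correlated Gaussians (lipophilicity/solubility-like)
    cov = np.eye(nd)
    if nd >= 2:
        cov[0, 1] = cov[1, 0] = spec.dense_corr
    dense = rng.multivariate_normal(np.zeros(nd), cov, size=n) if nd else np.empty((n, 0))

    # sparse block: Bernoulli presence mask times half-normal magnitudes
    driver_sparse = {j - nd for j in spec.drivers if j >= nd}
    p_zero = np.full(ns, spec.sparsity)
    for j in driver_sparse:
        p_zero[j] = min(spec.sparsity, 0.5)
    mask = rng.random((n, ns)) >= p_zero
    sparse = mask * np.abs(rng.normal(0.0, 1.0, size=(n, ns)))

    X = np.hstack([dense, sparse])
    y = _raw_endpoint(X, spec) + rng.normal(0.0, spec.noise_sd, size=n)

    names = [f"dense_{j}" for j in range(nd)] + [f"estate_{j}" for j in range(ns)]
    table = DescriptorTable(
        ids=[f"cmpd_{i:04d}" for i in range(n)], X=X, descriptor_names=names
    )
    truth = {
        "drivers": list(spec.drivers),
        "weights": list(spec.weights),
        "noise_sd": spec.noise_sd,
        "nonlinearity": spec.nonlinearity,
        "n_dense": nd,
        "n_sparse": ns,
        "seed": spec.seed,
    }
    return table, y, truth


def endpoint_for(row: np.ndarray, truth: dict,
                 rng: np.random.Generator | None = None) -> float:
    """Endpoint value of an arbitrary descriptor row under a generating truth."""
    spec = SyntheticSpec(
        n_compounds=1,
        n_dense=truth["n_dense"],
        n_sparse=truth["n_sparse"],
        drivers=tuple(truth["drivers"]),
        weights=tuple(truth["weights"]),
        noise_sd=truth["noise_sd"],
        nonlinearity=truth["nonlinearity"],
    )
    y = float(_raw_endpoint(np.atleast_2d(np.asarray(row, dtype=float)), spec)[0])
    if rng is not None:
        y += float(rng.normal(0.0, truth["noise_sd"]))
    return y


def make_disruptor(
    table: DescriptorTable,
    magnitude_sd: float = 5.0,
    rng: np.random.Generator | None = None,
    max_iter: int = 60,
) -> np.ndarray:
    """Construct a structural-disruptor row for a normalized table.

    The row is typical on the high-variance descriptors but extreme along a
    direction dominated by otherwise nearly constant (rarely occupied)
    columns — the signature of a compound carrying a chemical group absent
    from the rest of the set. Its magnitude is scaled up until
    :func:`~adaptsel.chemspace.detect_disruptor` reports at least
    ``magnitude_sd`` trimmed SDs on PC1 or PC2.
    """
    if not table.normalized:
        raise ValueError("make_disruptor expects a normalized table")
    if magnitude_sd < 5.0:
        raise ValueError("a disruptor requires magnitude_sd >= 5")
    rng = rng if rng is not None else np.random.default_rng()

    # signature of a large atypical molecule: at the observed extreme of the
    # common (high-variance) descriptors, and pushed beyond the data range
    # on a handful of otherwise near-constant group columns that it alone
    # occupies
    variances = table.X.var(axis=0)
    order = np.argsort(variances)
    n_rare = max(3, table.n_descriptors // 20)
    rare_cols = order[:n_rare]
    common_cols = order[table.n_descriptors // 2:]

    col_max = table.X.max(axis=0)
    candidate0 = np.median(table.X, axis=0).astype(float)
    # jointly maximal on the common descriptors: no single value is out of
    # range, but their conjunction rotates the leading loadings (the
    # defining trait of a structural disruptor)
    candidate0[common_cols] = col_max[common_cols]
    peaks = np.maximum(col_max[rare_cols], 0.5) * rng.uniform(0.9, 1.1, n_rare)

    scale = 1.0
    for _ in range(max_iter):
        candidate = candidate0.copy()
        candidate[rare_cols] = scale * peaks
        report = detect_disruptor(table, candidate)
        if report.is_disruptor and report.sd_distance >= magnitude_sd:
            return candidate
        scale *= 1.5
    raise RuntimeError(
        "could not construct a disruptor of the requested magnitude; "
        "the descriptor space may be too isotropic"
    )
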