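"""Robustness-evaluation harness: repeated design/validation splits, the
selection-method benchmark grid, summary statistics and the paired sign
(binomial) significance test.

The protocol: the dataset is split many times (default 250) into an 84%
design partition, on which compound selection runs, and a 16% validation
partition on which the PLS model trained on the selected compounds is
scored (RMSE and Pearson r). Static selectors restart from scratch at every
sample size; adaptive selectors run once per trial along the whole
size schedule, so their selections are nested. Optionally a structural
disruptor row is appended to every design partition (before normalization,
so it stretches the descriptor ranges exactly as a real outlier would) to
probe outlier robustness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .chemspace import DescriptorTable, apply_minmax, minmax_params, pca_project
from .modeling import evaluate_model, fit_pls_cv
from .selectors_adaptive import descrep_run, pls_optimal_run
from .selectors_static import (
    d_optimal_fedorov,
    kennard_stone,
    mdc,
    random_select,
    space_filling,
)

__all__ = [
    "SplitSet",
    "BenchmarkGrid",
    "make_splits",
    "run_benchmark",
    "summarize",
    "outlier_delta",
    "sign_binomial_test",
    "STATIC_METHODS",
    "ADAPTIVE_METHODS",
]

STATIC_METHODS = ("kennard-stone", "d-optimal", "space-filling", "mdc", "random")
ADAPTIVE_METHODS = ("descrep", "pls-optimal")


@dataclass
class SplitSet:
    trials: list  # list of (design indices, validation indices)
    design_fraction: float
    master_seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class BenchmarkGrid:
    """Long-format results table: one row per (trial, method, size)."""

    frame: pd.DataFrame
    selected: dict = field(default_factory=dict)  # (trial, method, size) -> id tuple
    dataset_tag: str = "without-disruptor"
    n_failed: int = 0


def make_splits(
    n: int,
    trials: int = 250,
    fraction: float = 0.84,
    rng: np.random.Generator | None = None,
) -> SplitSet:
    """Independent uniform design/validation splits.

    Each trial draws round(fraction * n) design compounds without
    replacement (round-half-up); the remainder form the validation set.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n_design = int(np.floor(fraction * n + 0.5))
    if n_design < 1 or n_design >= n:
        raise ValueError("design fraction leaves an empty partition")
    rng = rng if rng is not None else np.random.default_rng()
    out = []
    for _ in range(trials):
        perm = rng.permutation(n)
        out.append((np.sort(perm[:n_design]), np.sort(perm[n_design:])))
    return SplitSet(trials=out, design_fraction=fraction)


def _select_static(method, space3, space5, size, rng):
    if method == "kennard-stone":
        return kennard_stone(space5, size).indices
    if method == "d-optimal":
        return d_optimal_fedorov(space5, size, rng=rng).indices
    if method == "space-filling":
        return space_filling(space3, size).indices
    if method == "mdc":
        return mdc(space5, size).indices
    if method == "random":
        return random_select(space5.n, size, rng).indices
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    table: DescriptorTable,
    endpoint: np.ndarray,
    methods,
    sizes,
    splits: SplitSet,
    rng: np.random.Generator,
    disruptor: tuple | None = None,
    n_components: int = 5,
    k_descriptors: int = 5,
) -> BenchmarkGrid:
    """Run every selection method at every sample size on every split.

    ``table`` and ``endpoint`` are in raw units and cover all compounds (the
    harness plays the oracle). Per trial, min-max normalization is fitted on
    the design partition only and applied to the validation partition with
    clipping. ``disruptor``, if given, is a ``(row, y)`` pair in raw units
    appended to every design partition before normalization and selection.
    """
    sizes = sorted(int(s) for s in sizes)
    endpoint = np.asarray(endpoint, dtype=float)
    rows, n_failed = [], 0
    selected_map = {}

    for trial, (design, valid) in enumerate(splits.trials):
        trial_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        design_table = table.subset(design)
        y_design = endpoint[design]
        if disruptor is not None:
            d_row, d_y = disruptor
            design_table = DescriptorTable(
                ids=design_table.ids + ["__disruptor__"],
                X=np.vstack([design_table.X, np.asarray(d_row, dtype=float)]),
                descriptor_names=design_table.descriptor_names,
            )
            y_design = np.append(y_design, float(d_y))

        params = minmax_params(design_table)
        norm_design = apply_minmax(design_table, params, clip=False)
        norm_valid = apply_minmax(table.subset(valid), params, clip=True)
        y_valid = endpoint[valid]

        k5 = min(n_components, norm_design.n_compounds, norm_design.n_descriptors)
        space5 = pca_project(norm_design, k=k5)
        space3 = pca_project(norm_design, k=min(3, k5))
        oracle = lambda idx: y_design[np.asarray(idx, dtype=int)]

        for method in methods:
            try:
                per_size = {}
                if method in ADAPTIVE_METHODS:
                    runner = descrep_run if method == "descrep" else pls_optimal_run
                    kwargs = {"k_descriptors": k_descriptors} if method == "descrep" else {}
                    run = runner(norm_design, oracle, sizes,
                                 rng=trial_rng, **kwargs)
                    for size in sizes:
                        per_size[size] = run.selection_at(size)
                else:
                    for size in sizes:
                        per_size[size] = _select_static(
                            method, space3, space5, size, trial_rng
                        )
            except Exception as exc:  # record and continue
                warnings.warn(f"trial {trial}, method {method} failed: {exc}")
                n_failed += 1
                continue

            for size, sel in per_size.items():
                sel = list(sel)
                try:
                    model = fit_pls_cv(
                        norm_design.X[sel], y_design[sel], rng=trial_rng,
                        training_ids=[norm_design.ids[i] for i in sel],
                    )
                    ev = evaluate_model(model, norm_valid.X, y_valid)
                except Exception as exc:
                    warnings.warn(
                        f"trial {trial}, {method}, size {size} model failed: {exc}"
                    )
                    n_failed += 1
                    continue
                rows.append((trial, method, size, ev.rmse, ev.r))
                selected_map[(trial, method, size)] = tuple(
                    design_table.ids[i] for i in sel
                )

    frame = pd.DataFrame(rows, columns=["trial", "method", "size", "rmse", "r"])
    return BenchmarkGrid(
        frame=frame,
        selected=selected_map,
        dataset_tag="with-disruptor" if disruptor is not None else "without-disruptor",
        n_failed=n_failed,
    )


def summarize(grid: BenchmarkGrid) -> pd.DataFrame:
    """Per (method, size): mean RMSE, mean r, SD of RMSE across trials, and
    selection variability (number of distinct compounds selected across
    trials)."""
    g = grid.frame.groupby(["method", "size"])
    out = g.agg(
        mean_rmse=("rmse", "mean"),
        mean_r=("r", "mean"),
        sd_rmse=("rmse", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
        n_trials=("trial", "count"),
    ).reset_index()
    variability = []
    for _, row in out.iterrows():
        ids = set()
        for (trial, method, size), sel in grid.selected.items():
            if method == row["method"] and size == row["size"]:
                ids.update(sel)
        variability.append(len(ids))
    out["variability"] = variability
    return out


def outlier_delta(
    grid_without: BenchmarkGrid, grid_with: BenchmarkGrid
) -> pd.DataFrame:
    """Mean-RMSE difference (without minus with disruptor) per method/size.

    Positive values mean the method produced *better* models when the
    disruptor was present.
    """
    a = summarize(grid_without)[["method", "size", "mean_rmse"]]
    b = summarize(grid_with)[["method", "size", "mean_rmse"]]
    merged = a.merge(b, on=["method", "size"], suffixes=("_without", "_with"),
                     how="inner")
    if len(merged) != len(a) or len(merged) != len(b):
        raise ValueError("paired grids do not cover the same (method, size) cells")
    merged["delta_rmse"] = merged["mean_rmse_without"] - merged["mean_rmse_with"]
    return merged


def sign_binomial_test(rmse_a, rmse_b) -> float:
    """Exact two-sided sign test on paired per-trial RMSEs.

    Counts the trials where method a strictly beats method b, drops ties,
    and evaluates the exact binomial tail probability at p=0.5. All-tie
    input returns p = 1 with a warning.
    """
    a = np.asarray(rmse_a, dtype=float)
    b = np.asarray(rmse_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    wins = int(np.sum(a < b))
    losses = int(np.sum(b < a))
    m = wins + losses
    if m == 0:
        warnings.warn("all trials tied: sign test undefined, returning p=1")
        return 1.0
    return float(binomtest(wins, n=m, p=0.5, alternative="two-sided").pvalue)
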