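"""PLS regression exactly as used to score a compound selection.

A selection is evaluated by fitting a partial-least-squares model on the
selected (measured) compounds using *all* normalized descriptors — not the
low-dimensional search space — and predicting the held-out validation
partition. The number of latent variables is chosen by five-fold
cross-validation on the training compounds, maximizing the
cross-validated coefficient of determination (Q2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

__all__ = ["PlsModel", "fit_pls_cv", "evaluate_model", "Evaluation"]


@dataclass
class PlsModel:
    n_latent: int
    estimator: PLSRegression
    cv_r2_by_components: np.ndarray
    training_ids: list = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float))).ravel()

    def summary(self) -> dict:
        """JSON-serializable model summary (no binary model format)."""
        return {
            "n_latent": int(self.n_latent),
            "cv_r2_by_components": [float(v) for v in self.cv_r2_by_components],
            "coefficients": [float(c) for c in np.ravel(self.estimator.coef_)],
            "training_ids": list(self.training_ids),
        }


@dataclass
class Evaluation:
    rmse: float
    r: float
    r_defined: bool = True

    def __iter__(self):  # allows `rmse, r = evaluate_model(...)`
        return iter((self.rmse, self.r))


def _fit_pls(X, y, c):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=c, scale=False)
        pls.fit(X, y)
    return pls


def fit_pls_cv(
    X_train,
    y_train,
    max_components: int | None = None,
    folds: int = 5,
    rng: np.random.Generator | None = None,
    training_ids=None,
) -> PlsModel:
    """Fit a PLS model with the latent-variable count chosen by k-fold CV.

    For each candidate component count the cross-validated R2 is computed
    with seeded shuffled folds, each fold scored against its own observed
    values with the training-fold mean as baseline (Q2 convention); the
    count with the maximal CV R2 wins (ties to the smaller count) and the
    model is refit on all training rows.

    With fewer training rows than folds the CV degrades to leave-one-out
    with a warning. The component cap keeps the tiny-n regime sane:
    at most ``n_train - ceil(n_train/folds) - 1`` components ever enter CV.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n, d = X.shape
    if np.ptp(y) == 0:
        raise ValueError("zero-variance endpoint: nothing to model")
    if n < folds:
        warnings.warn(f"n_train={n} < folds={folds}: using leave-one-out CV")
        folds = n
    if folds < 2:
        raise ValueError("need at least 2 training compounds")
    rng = rng if rng is not None else np.random.default_rng()

    cap = max(1, min(n - math.ceil(n / folds) - 1, d))
    if max_components is None:
        max_components = min(10, max(1, n - 2), d)
    max_components = max(1, min(max_components, cap))

    kf = KFold(n_splits=folds, shuffle=True,
               random_state=int(rng.integers(0, 2**31 - 1)))
    splits = list(kf.split(X))

    cv_r2 = np.full(max_components, -np.inf)
    for c in range(1, max_components + 1):
        press, tss = 0.0, 0.0
        ok = True
        for tr, te in splits:
            try:
                pls = _fit_pls(X[tr], y[tr], c)
            except Exception:
                ok = False
                break
            pred = np.asarray(pls.predict(X[te])).ravel()
            press += float(np.sum((pred - y[te]) ** 2))
            tss += float(np.sum((y[te] - y[tr].mean()) ** 2))
        if ok and tss > 0:
            cv_r2[c - 1] = 1.0 - press / tss
    best_c = int(np.argmax(cv_r2)) + 1  # argmax ties -> smaller count
    model = _fit_pls(X, y, best_c)
    return PlsModel(
        n_latent=best_c,
        estimator=model,
        cv_r2_by_components=cv_r2,
        training_ids=list(training_ids) if training_ids is not None else [],
    )


def evaluate_model(model: PlsModel, X_val, y_val) -> Evaluation:
    """RMSE and Pearson correlation of predictions on a validation set.

    Constant predictions leave the correlation undefined; it is recorded as
    0 with ``r_defined=False``.
    """
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float).ravel()
    if X_val.shape[0] == 0:
        raise ValueError("empty validation set")
    pred = model.predict(X_val)
    rmse = float(np.sqrt(np.mean((pred - y_val) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(y_val) == 0 or len(y_val) < 2:
        return Evaluation(rmse=rmse, r=0.0, r_defined=False)
    r, _ = pearsonr(pred, y_val)
    return Evaluation(rmse=rmse, r=float(r))
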