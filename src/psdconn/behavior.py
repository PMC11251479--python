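"""Brain-behavior association and depression-severity prediction.

Associations between connectivity summaries and depression scales use
Spearman rank correlation with Bonferroni correction over the three
scales (significance at p < 0.05/3). Prediction uses ridge regression
whose penalty is chosen by leave-one-out cross-validation; features are
standardised inside each training fold and the intercept is never
penalised. Performance is the Spearman correlation between the observed
scores and the out-of-fold predictions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge

__all__ = [
    "SpearmanResult",
    "PredictionResult",
    "spearman_bonferroni",
    "ridge_loocv_predict",
    "default_lambda_grid",
]


def default_lambda_grid() -> np.ndarray:
    """17 penalties log-spaced between 1e-3 and 1e3."""
    return np.logspace(-3, 3, 17)


@dataclass
class SpearmanResult:
    rho: float
    p: float
    significant: bool
    n: int
    alpha_corrected: float
    flagged: str | None = None  # e.g. constant-input warning


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for small n (all n! permutations)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / np.sqrt(((rx - rx.mean()) ** 2).sum())
    ryc = ry - ry.mean()
    den = np.sqrt((ryc ** 2).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        r = float(rx @ ryc[list(perm)]) / den
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_bonferroni(values, scores, n_tests: int = 3,
                        alpha: float = 0.05) -> SpearmanResult:
    """Spearman rank correlation with Bonferroni-corrected significance.

    Ties receive average ranks. The two-sided p uses the t approximation
    for n >= 10 and exact permutation for smaller samples. ``significant``
    is True iff p < alpha / n_tests.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and scores must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    alpha_c = alpha / n_tests
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=np.nan, p=np.nan, significant=False, n=n,
                              alpha_corrected=alpha_c,
                              flagged="constant input: rho undefined")
    rho, p_t = stats.spearmanr(x, y)
    p = float(p_t) if n >= 10 else _exact_spearman_p(x, y, rho)
    return SpearmanResult(rho=float(rho), p=float(p), significant=bool(p < alpha_c),
                          n=n, alpha_corrected=alpha_c)


@dataclass
class PredictionResult:
    chosen_lambda: float
    predicted: np.ndarray  # LOOCV predictions, one per subject
    performance: SpearmanResult
    n_features: int
    loocv_mse: dict = field(default_factory=dict)  # lambda -> mean sq. error
    mode: str = "single_loop"
    flagged: str | None = None


def _fold_standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _loocv_predictions(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        Xtr, Xte = _fold_standardize(X[tr], X[[i]])
        model = Ridge(alpha=lam, fit_intercept=True)
        model.fit(Xtr, y[tr])
        preds[i] = model.predict(Xte)[0]
    return preds


def ridge_loocv_predict(features: np.ndarray, targets, lambda_grid=None,
                        n_tests: int = 3, alpha: float = 0.05,
                        nested: bool = False) -> PredictionResult:
    """Ridge prediction of behavioural scores with LOOCV penalty selection.

    For every lambda in the grid, each subject is predicted by a ridge
    model fitted on the remaining subjects (features standardised with
    training-fold statistics, intercept unpenalised). The reported
    predictions are the out-of-fold predictions at the MSE-minimising
    lambda (ties go to the smaller penalty). With ``nested=True`` the
    penalty is re-chosen inside each outer training fold instead, which
    removes the optimism of reusing the same folds for selection and
    reporting; the result's ``mode`` records which variant ran.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_subjects, n_features) aligned with targets")
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 subjects for LOOCV prediction")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("missing or non-finite entries in features/targets")
    grid = np.asarray(default_lambda_grid() if lambda_grid is None else lambda_grid,
                      dtype=float)
    if np.any(grid <= 0):
        raise ValueError("all lambda values must be positive")
    grid = np.sort(grid)

    flagged = None
    if np.ptp(y) == 0:
        flagged = "constant target: performance undefined"

    if nested:
        preds = np.empty(n)
        for i in range(n):
            tr = np.arange(n) != i
            mses = [np.mean((_loocv_predictions(X[tr], y[tr], lam) - y[tr]) ** 2)
                    for lam in grid]
            lam_i = float(grid[int(np.argmin(mses))])
            Xtr, Xte = _fold_standardize(X[tr], X[[i]])
            model = Ridge(alpha=lam_i, fit_intercept=True).fit(Xtr, y[tr])
            preds[i] = model.predict(Xte)[0]
        # report the penalty chosen on the full LOOCV for provenance
        mse = {float(l): float(np.mean((_loocv_predictions(X, y, l) - y) ** 2))
               for l in grid}
        chosen = min(mse, key=lambda l: (mse[l], l))
        mode = "nested"
    else:
        all_preds = {float(l): _loocv_predictions(X, y, float(l)) for l in grid}
        mse = {l: float(np.mean((p - y) ** 2)) for l, p in all_preds.items()}
        chosen = min(mse, key=lambda l: (mse[l], l))
        preds = all_preds[chosen]
        mode = "single_loop"

    if flagged is None:
        perf = spearman_bonferroni(y, preds, n_tests=n_tests, alpha=alpha)
    else:
        perf = SpearmanResult(rho=np.nan, p=np.nan, significant=False, n=n,
                              alpha_corrected=alpha / n_tests, flagged=flagged)
    return PredictionResult(chosen_lambda=float(chosen), predicted=preds,
                            performance=perf, n_features=X.shape[1],
                            loocv_mse=mse, mode=mode, flagged=flagged)
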