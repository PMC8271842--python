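"""L1-penalized binary logistic regression for wavelength-band selection.

The classifier models the log-odds that a seed belongs to the target variety
as a linear function of its (pretreated) spectrum,

    log[ p_i / (1 - p_i) ] = eta_i = b0 + sum_j b_j x_ij,

and estimates the coefficients by minimizing the penalized cost

    S_lam(b) = -l(b) + lam * sum_j |b_j|,        l(b) = sum_i [y_i eta_i - log(1 + e^{eta_i})],

with the intercept excluded from the penalty.  The solver works on the
per-sample average of this cost (so the penalty weight ``lam`` is expressed
per observation, the convention under which the default search range
1e-4..0.2 produces meaningful compression regardless of sample size) and
uses cyclic coordinate descent with soft-thresholding inside an iteratively
reweighted quadratic approximation, warm-started along a descending lambda
grid.  The L1 geometry zeroes coefficients exactly; the surviving
wavelengths are the selected feature bands.

Lambda is chosen by seeded, stratified 10-fold cross-validation.  Two rules
are offered: ``min_error`` picks the lambda minimizing the mean squared
difference between predicted probability and the 0/1 label, while the
default ``max_accuracy_sparsest`` picks, among lambdas tied at the maximum
CV classification accuracy, the largest one — the model needing the fewest
bands for the same predictive performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import _solver
from .exceptions import DomainError

__all__ = [
    "ModelCoefficients",
    "CVResult",
    "BandSelection",
    "default_lambda_grid",
    "lambda_max",
    "log_likelihood",
    "penalized_objective",
    "fit_lasso_logistic",
    "regularization_path",
    "cross_validate",
    "select_lambda",
    "selected_bands",
    "predict_proba",
    "predict",
    "kkt_residual",
]


@dataclass
class ModelCoefficients:
    """Fitted penalized logistic model, coefficients on the original scale."""

    intercept: float
    betas: np.ndarray
    lam: float
    centers: np.ndarray
    scales: np.ndarray
    converged: bool = True
    n_sweeps: int = 0

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=np.float64)
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.scales = np.asarray(self.scales, dtype=np.float64)
        if self.lam < 0:
            raise DomainError("lambda must be non-negative")
        if not np.isfinite(self.betas).all() or not np.isfinite(self.intercept):
            raise DomainError("non-finite coefficients")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.betas))

    @property
    def betas_standardized(self) -> np.ndarray:
        return self.betas * self.scales


@dataclass
class CVResult:
    """Cross-validation summary over a descending lambda grid."""

    lambda_grid: np.ndarray
    cv_error: np.ndarray
    cv_error_sd: np.ndarray
    n_nonzero: np.ndarray
    cv_accuracy: np.ndarray
    fold_assignment: np.ndarray
    seed: int
    models: list[ModelCoefficients] = field(default_factory=list, repr=False)


@dataclass
class BandSelection:
    """Nonzero-coefficient bands: 1-based indices, wavelengths, coefficients."""

    indices: np.ndarray
    wavelengths_nm: np.ndarray
    coefficients: np.ndarray


def default_lambda_grid(num: int = 100, lo: float = 1e-4, hi: float = 0.2) -> np.ndarray:
    """Descending log-spaced lambda grid over the default search range."""
    if not 0 < lo < hi:
        raise DomainError("need 0 < lo < hi")
    return np.geomspace(hi, lo, num)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise DomainError("X must be 2-D")
    if y.shape != (X.shape[0],):
        raise DomainError("y must align with rows of X")
    if not np.isin(y, (0, 1)).all():
        raise DomainError("y must be binary 0/1")
    return X, y.astype(np.float64)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centers = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)
    Z = (X - centers) / scales
    return np.ascontiguousarray(Z), centers, scales


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest per-sample penalty at which the solution is the null model:
    max_j |(1/n) sum_i z_ij (y_i - ybar)| on standardized columns."""
    X, y = _validate_xy(X, y)
    Z, _, _ = _standardize(X)
    resid = y - y.mean()
    return float(np.abs(Z.T @ resid).max() / len(y))


def log_likelihood(model: ModelCoefficients, X: np.ndarray, y: np.ndarray) -> float:
    """Binomial log-likelihood l(b) = sum_i [y_i eta_i - log(1 + e^{eta_i})]."""
    X, y = _validate_xy(X, y)
    eta = model.intercept + X @ model.betas
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def penalized_objective(model: ModelCoefficients, X: np.ndarray, y: np.ndarray) -> float:
    """Penalized cost S_lam(b) = -l(b) + lam * sum_j |b_j| (total-likelihood form)."""
    return -log_likelihood(model, X, y) + model.lam * float(np.abs(model.betas).sum())


def fit_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    init: ModelCoefficients | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> ModelCoefficients:
    """Fit one penalized logistic model by coordinate descent.

    Columns are standardized internally; returned coefficients are
    back-transformed to the original scale.  A model that hits ``max_iter``
    coordinate sweeps carries ``converged=False`` and a warning is issued.
    """
    X, y = _validate_xy(X, y)
    if X.shape[0] < 2:
        raise DomainError("need at least 2 samples")
    if np.unique(y).size < 2:
        raise DomainError("both classes must be present")
    if lam < 0:
        raise DomainError("lambda must be non-negative")
    Z, centers, scales = _standardize(X)
    if init is not None:
        beta_std = init.betas * scales
        beta_std[X.std(axis=0) == 0] = 0.0  # constant columns stay out
        beta0_std = init.intercept + float(init.betas @ centers)
    else:
        ybar = y.mean()
        beta0_std = float(np.log(ybar / (1.0 - ybar)))
        beta_std = np.zeros(X.shape[1])
    beta0_std, beta_std, sweeps, converged = _solver.fit_one_standardized(
        Z, y, float(lam), beta0_std, np.ascontiguousarray(beta_std), tol, max_iter
    )
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge within {max_iter} sweeps "
            f"(lambda={lam:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    betas = beta_std / scales
    intercept = float(beta0_std - betas @ centers)
    return ModelCoefficients(
        intercept=intercept,
        betas=betas,
        lam=float(lam),
        centers=centers,
        scales=scales,
        converged=bool(converged),
        n_sweeps=int(sweeps),
    )


def regularization_path(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> list[ModelCoefficients]:
    """Warm-started fits from the largest to the smallest grid lambda."""
    X, y = _validate_xy(X, y)
    if np.unique(y).size < 2:
        raise DomainError("both classes must be present")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size == 0 or np.any(np.diff(grid) >= 0):
        raise DomainError("lambda grid must be non-empty and strictly descending")
    Z, centers, scales = _standardize(X)
    B0, B, sweeps, conv = _solver.fit_path_standardized(
        Z, y, np.ascontiguousarray(grid), tol, max_iter
    )
    models = []
    for li, lam in enumerate(grid):
        betas = B[li] / scales
        models.append(
            ModelCoefficients(
                intercept=float(B0[li] - betas @ centers),
                betas=betas,
                lam=float(lam),
                centers=centers.copy(),
                scales=scales.copy(),
                converged=bool(conv[li]),
                n_sweeps=int(sweeps[li]),
            )
        )
    return models


def _stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    assignment = np.full(y.size, -1, dtype=np.int64)
    start = int(rng.integers(folds))
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = (np.arange(idx.size) + start + offset) % folds
        offset += idx.size
    return assignment


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> CVResult:
    """Seeded, label-stratified K-fold cross-validation over a lambda grid.

    For every fold and lambda the model is fitted on the other K-1 folds and
    evaluated on the held-out fold.  ``cv_error`` is the across-fold mean of
    the per-fold mean squared difference between predicted probability and
    the 0/1 label; ``cv_accuracy`` the mean fold accuracy at threshold 0.5.
    ``n_nonzero`` counts selected bands along the path fitted on all samples
    (also returned in ``models``).
    """
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    if n < folds:
        raise DomainError(f"need at least {folds} samples for {folds}-fold CV")
    if np.unique(y).size < 2:
        raise DomainError("both classes must be present")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    assignment = None
    for attempt in range(10):
        rng = np.random.default_rng(seed + attempt)
        cand = _stratified_folds(y, folds, rng)
        ok = all(
            np.unique(y[cand != f]).size == 2 for f in range(folds)
        )
        if ok:
            assignment = cand
            break
    if assignment is None:
        raise DomainError(
            "could not build folds whose training parts contain both classes"
        )
    fold_err = np.empty((folds, grid.size))
    fold_acc = np.empty((folds, grid.size))
    for f in range(folds):
        tr = assignment != f
        va = ~tr
        path = regularization_path(X[tr], y[tr], grid, tol=tol, max_iter=max_iter)
        B = np.stack([m.betas for m in path])          # L x P
        b0 = np.array([m.intercept for m in path])
        probs = expit(X[va] @ B.T + b0)                 # n_val x L
        yv = y[va][:, None]
        fold_err[f] = np.mean((probs - yv) ** 2, axis=0)
        fold_acc[f] = np.mean((probs > 0.5).astype(float) == yv, axis=0)
    full_path = regularization_path(X, y, grid, tol=tol, max_iter=max_iter)
    return CVResult(
        lambda_grid=grid,
        cv_error=fold_err.mean(axis=0),
        cv_error_sd=fold_err.std(axis=0, ddof=1),
        n_nonzero=np.array([m.n_nonzero for m in full_path]),
        cv_accuracy=fold_acc.mean(axis=0),
        fold_assignment=assignment,
        seed=seed,
        models=full_path,
    )


def select_lambda(cv: CVResult, rule: str = "max_accuracy_sparsest") -> float:
    """Pick lambda from a CV summary.

    ``min_error``: argmin of ``cv_error``.  ``max_accuracy_sparsest``
    (default): among lambdas whose ``cv_accuracy`` equals the maximum, the
    largest (fewest bands).  The grid is descending, so ties resolve to the
    first matching index in both rules.
    """
    if cv.lambda_grid.size == 0:
        raise DomainError("empty CV result")
    if rule == "min_error":
        return float(cv.lambda_grid[int(np.argmin(cv.cv_error))])
    if rule == "max_accuracy_sparsest":
        best = cv.cv_accuracy.max()
        return float(cv.lambda_grid[int(np.argmax(cv.cv_accuracy == best))])
    raise DomainError(f"unknown selection rule {rule!r}")


def selected_bands(
    model: ModelCoefficients, wavelengths_nm: np.ndarray
) -> BandSelection:
    """Bands with exactly nonzero coefficients, reported 1-based."""
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=np.float64)
    if wavelengths_nm.size != model.betas.size:
        raise DomainError("wavelength axis does not match coefficient vector")
    nz = np.flatnonzero(model.betas != 0.0)
    return BandSelection(
        indices=nz + 1,
        wavelengths_nm=wavelengths_nm[nz],
        coefficients=model.betas[nz],
    )


def predict_proba(model: ModelCoefficients, X: np.ndarray) -> np.ndarray:
    """Probability of the target class, 1/(1 + exp(-eta))."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.betas.size:
        raise DomainError(
            f"X with {X.shape[1] if X.ndim == 2 else '?'} columns does not match "
            f"{model.betas.size} coefficients"
        )
    return expit(model.intercept + X @ model.betas)


def predict(model: ModelCoefficients, X: np.ndarray) -> np.ndarray:
    """Classify as target iff p > 0.5 (a tie at exactly 0.5 is non-target)."""
    return (predict_proba(model, X) > 0.5).astype(np.int64)


def kkt_residual(model: ModelCoefficients, X: np.ndarray, y: np.ndarray) -> float:
    """Maximum violation of the stationarity conditions on standardized columns.

    For the per-sample objective, optimality requires
    |g_j| <= lam for zero coefficients and g_j = -lam * sign(b_j) otherwise,
    where g_j = (1/n) sum_i z_ij (p_i - y_i).
    """
    X, y = _validate_xy(X, y)
    Z = (X - model.centers) / model.scales
    p = predict_proba(model, X)
    grad = Z.T @ (p - y) / len(y)
    b = model.betas_standardized
    res = np.where(
        b == 0.0,
        np.maximum(np.abs(grad) - model.lam, 0.0),
        np.abs(grad + model.lam * np.sign(b)),
    )
    return float(res.max()) if res.size else 0.0
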