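"""Nodewise l1-regularized regressions: the estimation engine shared by the
cross-sectional mixed graphical model and the lag-1 mixed VAR.

Each node is regressed on all other nodes.  Gaussian targets use the lasso;
categorical targets use l1-penalized multinomial logistic regression in the
over-parameterized coding (one coefficient row per category, no reference
level — the l1 penalty identifies this model).  The penalty weight is chosen
by K-fold cross-validation over a glmnet-style log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LogisticRegression, lasso_path
from sklearn.model_selection import KFold, StratifiedKFold

from .data import CATEGORICAL, GAUSSIAN, MixedDataset

import warnings

N_LAMBDA_DEFAULT = 50
LAMBDA_MIN_RATIO = 1e-4


@dataclass
class NodewiseModel:
    """One node's fitted regularized regression.

    ``coef_blocks`` maps every other node index j to its coefficient block on
    the original predictor scale: shape (L_j,) for a gaussian target and
    (K, L_j) for a categorical target with K levels, where L_j is 1 for a
    gaussian predictor and the predictor's level count otherwise.  A zero
    block means j is outside the target's neighborhood.
    """

    target: int
    family: str
    n_levels: int | None
    intercepts: np.ndarray          # shape () gaussian, (K,) categorical
    coef_blocks: dict[int, np.ndarray]
    lambda_selected: float
    lambda_path: np.ndarray
    cv_error_path: np.ndarray
    residual_scale: float | None = None   # sigma of Eq.-style gaussian conditional
    predictor_levels: dict[int, int] = field(default_factory=dict)

    def block_strength(self, j: int) -> float:
        """Aggregate a predictor's block to a scalar nonnegative strength:
        the mean absolute coefficient over the block."""
        return float(np.mean(np.abs(self.coef_blocks[j])))

    def neighborhood(self) -> list[int]:
        return [j for j, b in self.coef_blocks.items() if np.any(b != 0)]


class ConstantColumnError(ValueError):
    pass


def encode_predictors(
    d: MixedDataset, target: int, standardize: bool = False
):
    """Build the design matrix for the regression of ``target`` on all other
    columns.

    Gaussian predictors contribute one column each (divided by their sample
    standard deviation when ``standardize``); a categorical predictor with L
    levels contributes L indicator columns, left unscaled.  Returns
    ``(X, block_map, scales)`` where ``block_map`` is a list of
    ``(node_index, column_slice)`` pairs and ``scales`` holds the per-column
    divisors (1 for indicators).
    """
    if not 0 <= target < d.p:
        raise ValueError(f"target index {target} outside 0..{d.p - 1}")
    n = d.n
    mats: list[np.ndarray] = []
    block_map: list[tuple[int, slice]] = []
    scales: list[float] = []
    start = 0
    for j, spec in enumerate(d.specs):
        if j == target:
            continue
        x = d.values[:, j]
        if len(np.unique(x)) < 2:
            raise ConstantColumnError(
                f"column {spec.name!r} is constant (zero variance)"
            )
        if spec.is_categorical:
            K = spec.n_levels
            M = np.zeros((n, K))
            M[np.arange(n), x.astype(int) - 1] = 1.0
            scales.extend([1.0] * K)
        else:
            s = float(np.std(x))
            M = (x / s)[:, None] if standardize else x[:, None]
            scales.append(s if standardize else 1.0)
        mats.append(M)
        width = M.shape[1]
        block_map.append((j, slice(start, start + width)))
        start += width
    X = np.hstack(mats)
    return X, block_map, np.asarray(scales)


def _lambda_max_gaussian(X: np.ndarray, y: np.ndarray) -> float:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(Xc.T @ yc)) / len(y))


def _lambda_max_categorical(X: np.ndarray, y: np.ndarray, K: int) -> float:
    # gradient of the mean multinomial NLL at the intercept-only model
    n = len(y)
    Xc = X - X.mean(axis=0)
    g_max = 0.0
    for k in range(1, K + 1):
        ind = (y == k).astype(float)
        p_k = ind.mean()
        g = np.abs(Xc.T @ (ind - p_k)) / n
        g_max = max(g_max, float(g.max()))
    return g_max


def default_lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    n_levels: int | None = None,
    n_lambda: int = N_LAMBDA_DEFAULT,
) -> np.ndarray:
    """Decreasing log-spaced grid from the smallest all-zero penalty lambda_max
    down to ``LAMBDA_MIN_RATIO * lambda_max``."""
    if family == GAUSSIAN:
        lmax = _lambda_max_gaussian(X, y)
    else:
        lmax = _lambda_max_categorical(X, y, int(n_levels))
    if lmax <= 0:
        return np.array([0.0])
    return np.logspace(np.log10(lmax), np.log10(lmax * LAMBDA_MIN_RATIO), n_lambda)


def _fit_gaussian_at(X, y, lam: float) -> tuple[float, np.ndarray]:
    """Coefficients at a single penalty value; exact least squares at lam=0."""
    if lam <= 0:
        Xa = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
        return float(beta[0]), beta[1:]
    m = Lasso(alpha=lam, fit_intercept=True, max_iter=50_000, tol=1e-10)
    m.fit(X, y)
    return float(m.intercept_), m.coef_.copy()


def _logreg(lam: float, n: int, warm=None, tight: bool = False) -> LogisticRegression:
    if lam <= 0:
        return LogisticRegression(
            C=np.inf, solver="lbfgs", max_iter=20_000, tol=1e-10
        )
    C = 1.0 / (n * lam)
    kw = dict(l1_ratio=1.0, solver="saga", C=C, fit_intercept=True)
    if tight:
        kw.update(max_iter=20_000, tol=1e-8)
    else:
        kw.update(max_iter=3_000, tol=1e-5)
    return LogisticRegression(**kw)


def _categorical_coefs(clf: LogisticRegression, K: int, D: int):
    """Full (K, D) coefficient matrix and (K,) intercepts in the symmetric
    over-parameterized representation, regardless of how the solver
    parameterized the fit (binary fits return a single contrast row)."""
    classes = clf.classes_.astype(int)
    if len(classes) == 2 and clf.coef_.shape[0] == 1:
        delta = clf.coef_[0]
        b = float(clf.intercept_[0])
        coefs = np.zeros((K, D))
        icpt = np.zeros(K)
        lo, hi = classes[0] - 1, classes[1] - 1
        coefs[hi] = delta / 2.0
        coefs[lo] = -delta / 2.0
        icpt[hi] = b / 2.0
        icpt[lo] = -b / 2.0
        return icpt, coefs
    coefs = np.zeros((K, D))
    icpt = np.zeros(K)
    for row, cls in enumerate(classes):
        coefs[cls - 1] = clf.coef_[row]
        icpt[cls - 1] = clf.intercept_[row]
    return icpt, coefs


def _multinomial_deviance(probs: np.ndarray, y: np.ndarray) -> float:
    p_true = probs[np.arange(len(y)), y.astype(int) - 1]
    return float(-2.0 * np.mean(np.log(np.clip(p_true, 1e-12, None))))


def _cv_gaussian(X, y, lambda_path, cv_folds, seed):
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    losses = np.zeros((cv_folds, len(lambda_path)))
    for f, (tr, te) in enumerate(kf.split(X)):
        Xtr, ytr = X[tr], y[tr]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        _, coefs, _ = lasso_path(
            Xtr - xm, ytr - ym, alphas=lambda_path, max_iter=50_000, tol=1e-8
        )
        pred = (X[te] - xm) @ coefs + ym          # (n_te, n_lambda)
        losses[f] = np.mean((pred - y[te][:, None]) ** 2, axis=0)
    return losses


def _cv_categorical(X, y, K, lambda_path, cv_folds, seed):
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    losses = np.zeros((cv_folds, len(lambda_path)))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, ytr = X[tr], y[tr]
        clf = None
        for li, lam in enumerate(lambda_path):
            clf = _logreg(lam, len(tr))
            if li > 0 and lam > 0:
                clf.warm_start = False  # cheap fits; fresh solve is robust
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(Xtr, ytr)
            probs = _class_probs(clf, X[te], K)
            losses[f, li] = _multinomial_deviance(probs, y[te])
    return losses


def _class_probs(clf, X, K):
    raw = clf.predict_proba(X)
    probs = np.zeros((X.shape[0], K))
    for col, cls in enumerate(clf.classes_.astype(int)):
        probs[:, cls - 1] = raw[:, col]
    return probs


def select_lambda(lambda_path, losses, rule: str = "min") -> float:
    """Pick the penalty from per-fold CV losses: ``min`` takes the grid value
    with smallest mean loss; ``1se`` the most regularized value whose mean
    loss is within one standard error of that minimum."""
    mean = losses.mean(axis=0)
    i_min = int(np.argmin(mean))
    if rule == "min":
        return float(lambda_path[i_min])
    if rule == "1se":
        se = losses.std(axis=0, ddof=1) / np.sqrt(losses.shape[0])
        thresh = mean[i_min] + se[i_min]
        ok = np.flatnonzero(mean <= thresh)
        return float(lambda_path.max() if ok.size == 0 else lambda_path[ok.min()])
    raise ValueError(f"unknown selection rule {rule!r}")


def _threshold_value(rule: str, lam: float, sigma_hat: float,
                     n_cols: int, n: int) -> float:
    """Post-fit coefficient cut.  ``auto`` is the universal threshold
    sigma * sqrt(2 log D / n) floored at the selected penalty; an explicitly
    unpenalized fit (lam == 0) is never cut."""
    if rule == "none" or lam <= 0:
        return 0.0
    if rule == "lambda":
        return lam
    return max(lam, sigma_hat * np.sqrt(2.0 * np.log(n_cols) / n))


def fit_node(
    d: MixedDataset,
    target: int,
    lambda_path: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    selection: str = "min",
    threshold: str = "auto",
) -> NodewiseModel:
    """Fit one node's regularized neighborhood regression on a centered
    dataset, selecting the penalty by ``cv_folds``-fold cross-validation
    (squared error for gaussian targets, multinomial deviance otherwise) and
    refitting on the full data at the selected value.

    Cross-validated minimum-loss selection keeps many tiny spurious
    coefficients, so solver-scale coefficients below a threshold are zeroed
    afterwards: ``"auto"`` (default) cuts at the universal bound
    sigma_hat * sqrt(2 log D / n) (D design columns; sigma_hat = 1 for
    categorical targets) or at the selected penalty, whichever is larger;
    ``"lambda"`` cuts at the selected penalty only; ``"none"`` disables the
    cut.  An explicit all-zero ``lambda_path`` is an unpenalized request and
    is never thresholded.  Coefficients are reported on the original
    predictor scale (continuous predictors are standardized inside the
    solver only).
    """
    if threshold not in ("auto", "lambda", "none"):
        raise ValueError(f"unknown threshold rule {threshold!r}")
    if cv_folds < 2:
        raise ValueError("cv_folds >= 2 required")
    if cv_folds > d.n:
        raise ValueError(f"cv_folds={cv_folds} exceeds n={d.n}")
    spec = d.specs[target]
    y = d.values[:, target]
    X, block_map, scales = encode_predictors(d, target, standardize=True)

    if lambda_path is None:
        lambda_path = default_lambda_path(
            X, y, spec.family, spec.n_levels
        )
    lambda_path = np.asarray(lambda_path, dtype=float)
    if np.any(np.diff(lambda_path) > 0):
        raise ValueError("lambda_path must be non-increasing")

    if spec.is_categorical:
        K = spec.n_levels
        observed = np.unique(y.astype(int))
        if len(observed) < K:
            raise ValueError(
                f"target {spec.name!r}: only {len(observed)} of {K} levels "
                f"observed; cannot fit all category parameters"
            )
        if len(lambda_path) > 1:
            losses = _cv_categorical(X, y, K, lambda_path, cv_folds, seed)
        else:
            losses = np.zeros((cv_folds, 1))
        lam = select_lambda(lambda_path, losses, selection)
        clf = _logreg(lam, d.n, tight=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X, y)
        icpt, coefs = _categorical_coefs(clf, K, X.shape[1])
        tau = _threshold_value(threshold, lam, 1.0, X.shape[1], d.n)
        if tau > 0:
            # cut on the solver's own contrast scale, before the symmetric
            # halving, so binary targets are treated like the K>2 case
            raw = clf.coef_
            keep = np.zeros(X.shape[1], dtype=bool)
            for row in raw:
                keep |= np.abs(row) >= tau
            coefs[:, ~keep] = 0.0
        coefs = coefs / scales[None, :]
        intercepts = icpt
        residual_scale = None
    else:
        if len(lambda_path) > 1:
            losses = _cv_gaussian(X, y, lambda_path, cv_folds, seed)
        else:
            losses = np.zeros((cv_folds, 1))
        lam = select_lambda(lambda_path, losses, selection)
        b0, coef = _fit_gaussian_at(X, y, lam)
        sigma_hat = float(np.std(y - (b0 + X @ coef)))
        tau = _threshold_value(threshold, lam, sigma_hat, X.shape[1], d.n)
        if tau > 0:
            coef = np.where(np.abs(coef) < tau, 0.0, coef)
        coef = coef / scales
        intercepts = np.asarray(b0)
        resid = y - (b0 + (X * scales) @ (coef))
        residual_scale = float(np.std(resid))
        coefs = coef

    if not np.all(np.isfinite(losses)):
        raise ValueError("non-finite cross-validation loss")

    blocks: dict[int, np.ndarray] = {}
    levels: dict[int, int] = {}
    for j, sl in block_map:
        if spec.is_categorical:
            blocks[j] = coefs[:, sl].copy()
        else:
            blocks[j] = coefs[sl].copy()
        levels[j] = sl.stop - sl.start

    return NodewiseModel(
        target=target,
        family=spec.family,
        n_levels=spec.n_levels,
        intercepts=intercepts,
        coef_blocks=blocks,
        lambda_selected=float(lam),
        lambda_path=lambda_path,
        cv_error_path=losses.mean(axis=0),
        residual_scale=residual_scale,
        predictor_levels=levels,
    )
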