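"""Per-miRNA univariate diagnostics.

Each miRNA is scored as a single predictor of case/control status through a
univariate logistic regression on log2(CPM + 1).  Reported per miRNA:

* AUROC of the in-sample model probabilities (Mann-Whitney form, ties 1/2),
* a 95% confidence interval by DeLong's placement-value method,
* leave-one-out cross-validated prediction errors: the average squared
  error between outcome and predicted probability (``loo_cost``, the
  headline error rate) and the 0/1 misclassification rate at threshold 0.5
  (``loo_misclass``).

Logistic fits use iteratively reweighted least squares with an iteration
cap; quasi-separated fits are flagged rather than penalized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

IRLS_MAX_ITER = 25
IRLS_DEVIANCE_TOL = 1e-8


class LogisticFit(NamedTuple):
    intercept: float
    slope: float
    converged: bool
    separated: bool
    n_iter: int


@dataclass
class UnivariateRecord:
    mirna_id: str
    auroc: float
    ci_low: float
    ci_high: float
    loo_cost: float
    loo_misclass: float
    coef_intercept: float
    coef_slope: float
    separated: bool = False


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise ValidationError("labels must be 0/1")
    if len(uniq) < 2:
        raise ValidationError("both classes must be present")
    return y.astype(float)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_logistic_univariate(x: Sequence[float], y: Sequence[float]) -> LogisticFit:
    """Maximum-likelihood univariate logistic fit by IRLS.

    A constant predictor collapses to the intercept-only model
    (slope 0, intercept logit of the base rate).  Non-convergence at the
    iteration cap sets the ``separated`` flag.
    """
    x = np.asarray(x, dtype=float)
    y = _check_binary(np.asarray(y))
    if x.size != y.size:
        raise ValidationError("x and y must have the same length")
    ybar = y.mean()
    if np.ptp(x) == 0:
        return LogisticFit(float(np.log(ybar / (1 - ybar))), 0.0, True, False, 0)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    dev = _deviance(y, np.full_like(y, 0.5))
    converged = False
    it = 0
    for it in range(1, IRLS_MAX_ITER + 1):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        new_dev = _deviance(y, _sigmoid(X @ beta))
        if abs(dev - new_dev) < IRLS_DEVIANCE_TOL:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    # separation: iteration cap reached, or the deviance collapsed to ~0
    # (every sample fitted almost perfectly, coefficients diverging)
    separated = (not converged) or dev < 1e-6
    if separated:
        logger.debug("flagging (quasi-)separation: converged=%s dev=%.3g", converged, dev)
    return LogisticFit(float(beta[0]), float(beta[1]), converged, separated, it)


def predict_proba(fit: LogisticFit, x: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return _sigmoid(fit.intercept + fit.slope * x)


# ---------------------------------------------------------------------------
# ROC / AUROC
# ---------------------------------------------------------------------------

def auroc(scores: Sequence[float], y: Sequence[float]) -> float:
    """Mann-Whitney AUROC: P(score_case > score_control) + P(equal)/2."""
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(np.asarray(y))
    m = int(y.sum())
    n = y.size - m
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - m * (m + 1) / 2) / (m * n))


def roc_curve(scores: Sequence[float], y: Sequence[float]) -> RocCurve:
    """Empirical ROC points, from (0,0) to (1,1), thresholds descending."""
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(np.asarray(y))
    order = np.argsort(-scores, kind="mergesort")
    ys = y[order]
    uniq = np.r_[True, np.diff(scores[order]) != 0]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    keep = np.r_[uniq[1:], True]  # last point of each tie block
    tpr = np.r_[0.0, tp[keep] / y.sum()]
    fpr = np.r_[0.0, fp[keep] / (y.size - y.sum())]
    thresholds = np.r_[np.inf, scores[order][keep]]
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr)


def delong_ci(
    scores: Sequence[float], y: Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """DeLong placement-value 95% (by default) CI for the AUROC, clipped to
    [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(np.asarray(y))
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("DeLong CI needs >= 2 samples in each class")
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    a = psi.mean()
    v_pos = psi.mean(axis=1)
    v_neg = psi.mean(axis=0)
    se2 = v_pos.var(ddof=1) / pos.size + v_neg.var(ddof=1) / neg.size
    z = stats.norm.ppf((1 + level) / 2)
    half = z * math.sqrt(max(se2, 0.0))
    return float(np.clip(a - half, 0, 1)), float(np.clip(a + half, 0, 1))


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

def loo_cv(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Leave-one-out CV of the univariate logistic model.

    Returns ``(loo_cost, loo_misclass)``: the average squared prediction
    error and the 0/1 error at threshold 0.5.  A fold whose training labels
    collapse to a single class predicts from the intercept-only model.
    """
    x = np.asarray(x, dtype=float)
    y = _check_binary(np.asarray(y))
    n = y.size
    if n < 4:
        raise ValidationError("LOO-CV needs at least 4 samples")
    sq_err = np.empty(n)
    mis = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        yt = y[mask]
        if yt.min() == yt.max():
            p_hat = float(np.clip(yt.mean(), 1e-12, 1 - 1e-12))
            logger.debug("fold %d has a single training class; intercept-only", i)
        else:
            fit = fit_logistic_univariate(x[mask], yt)
            p_hat = float(predict_proba(fit, x[i : i + 1])[0])
        sq_err[i] = (y[i] - p_hat) ** 2
        mis[i] = float((p_hat > 0.5) != bool(y[i]))
    return float(sq_err.mean()), float(mis.mean())


# ---------------------------------------------------------------------------
# panel driver
# ---------------------------------------------------------------------------

def univariate_panel(
    expr: ExpressionMatrix,
    meta: Sequence,
    mirnas: Sequence[str],
    spec,
) -> list[UnivariateRecord]:
    """Univariate diagnostics for each requested miRNA, in input order.

    The predictor is log2(CPM + 1); the ROC score is the in-sample model
    probability (monotone in the predictor, so AUROC = max(A, 1 - A) of the
    raw predictor).
    """
    group_of = {r.sample_id: r.group for r in meta}
    labels = np.asarray([group_of.get(s) for s in expr.sample_ids])
    keep = np.isin(labels, [spec.case_label, spec.control_label])
    y = (labels[keep] == spec.case_label).astype(float)
    log2cpm = expr.log2_cpm()[:, keep]
    index = {mid: i for i, mid in enumerate(expr.mirna_ids)}
    records: list[UnivariateRecord] = []
    for mid in mirnas:
        if mid not in index:
            raise ValidationError(f"unknown miRNA id {mid!r}")
        xv = log2cpm[index[mid]]
        fit = fit_logistic_univariate(xv, y)
        scores = predict_proba(fit, xv)
        a = auroc(scores, y)
        lo, hi = delong_ci(scores, y)
        cost, mis = loo_cv(xv, y)
        records.append(
            UnivariateRecord(
                mirna_id=mid,
                auroc=a,
                ci_low=lo,
                ci_high=hi,
                loo_cost=cost,
                loo_misclass=mis,
                coef_intercept=fit.intercept,
                coef_slope=fit.slope,
                separated=fit.separated,
            )
        )
    return records
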