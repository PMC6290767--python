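"""Random-forest panel modeling with out-of-bag diagnostics.

The forest itself is a bagged ensemble of Gini decision trees
(sklearn's RandomForestClassifier); everything out-of-bag is computed here
from the per-tree bootstrap membership:

* ``oob_proba``: per training sample, the fraction of trees *not* trained
  on it that vote for the case class;
* ``oob_error``: misclassification rate of the OOB majority vote (vote
  fraction > 0.5 predicts the case class, exact ties fall to control with a
  warning); 1 - oob_error is the panel's "predictive power";
* ``importance``: unscaled mean decrease accuracy — for each tree, the drop
  in its OOB accuracy after permuting one feature's OOB values, averaged
  over trees.

Exhaustive subset evaluation retrains a forest for every non-empty subset
of the stable feature list (2^k - 1 evaluations) and scores each by the
AUROC of its OOB probabilities with a DeLong confidence interval.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import ValidationError
from .preprocess import ExpressionMatrix
from .univariate import auroc, delong_ci

logger = logging.getLogger(__name__)

MAX_EXHAUSTIVE_FEATURES = 20


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    mtry: int | None = None  # None -> floor(sqrt(p))
    min_node: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValidationError("mtry must be >= 1")
        if self.min_node < 1:
            raise ValidationError("min_node must be >= 1")

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, int(np.floor(np.sqrt(p))))
        return min(m, p)


@dataclass
class ForestModel:
    """A trained forest plus its OOB diagnostics."""

    estimator: RandomForestClassifier
    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]
    config: ForestConfig
    oob_proba: np.ndarray = field(init=False)
    oob_pred: np.ndarray = field(init=False)
    oob_error: float = field(init=False)

    def __post_init__(self) -> None:
        n = self.y.size
        votes1 = np.zeros(n)
        n_oob = np.zeros(n)
        for tree, sampled in zip(
            self.estimator.estimators_, self.estimator.estimators_samples_
        ):
            oob = np.ones(n, dtype=bool)
            oob[sampled] = False
            if not oob.any():
                continue
            pred = tree.predict(self.X[oob])
            votes1[oob] += pred
            n_oob[oob] += 1
        covered = n_oob > 0
        if not covered.all():
            logger.warning(
                "%d training samples have no OOB tree; excluded from OOB error",
                int((~covered).sum()),
            )
        proba = np.full(n, np.nan)
        proba[covered] = votes1[covered] / n_oob[covered]
        self.oob_proba = proba
        pred = np.zeros(n)
        pred[covered] = (proba[covered] > 0.5).astype(float)
        if np.any(proba[covered] == 0.5):
            warnings.warn("tied OOB vote (exactly 0.5); assigned to control class")
        self.oob_pred = pred
        self.oob_error = float(np.mean(pred[covered] != self.y[covered]))

    @property
    def predictive_power(self) -> float:
        return 1.0 - self.oob_error

    @cached_property
    def importance(self) -> dict[str, float]:
        """Unscaled mean decrease accuracy over OOB samples, per feature."""
        n, p = self.X.shape
        rng = np.random.default_rng([self.config.seed, 1])
        drops = np.zeros((len(self.estimator.estimators_), p))
        for t, (tree, sampled) in enumerate(
            zip(self.estimator.estimators_, self.estimator.estimators_samples_)
        ):
            oob = np.ones(n, dtype=bool)
            oob[sampled] = False
            if not oob.any():
                continue
            X_oob = self.X[oob]
            y_oob = self.y[oob]
            acc = np.mean(tree.predict(X_oob) == y_oob)
            for f in range(p):
                X_perm = X_oob.copy()
                X_perm[:, f] = rng.permutation(X_perm[:, f])
                acc_perm = np.mean(tree.predict(X_perm) == y_oob)
                drops[t, f] = acc - acc_perm
        mda = drops.mean(axis=0)
        return {fid: float(v) for fid, v in zip(self.feature_ids, mda)}

    def vote_fractions(self, X_new: np.ndarray) -> np.ndarray:
        """Full-ensemble (non-OOB) case-class vote fraction per row."""
        votes = np.zeros(X_new.shape[0])
        for tree in self.estimator.estimators_:
            votes += tree.predict(X_new)
        return votes / len(self.estimator.estimators_)


@dataclass
class SubsetEvaluation:
    subset: tuple[str, ...]
    auroc: float
    ci_low: float
    ci_high: float
    oob_accuracy: float
    perfect: bool


def train_forest(
    X: np.ndarray,
    y: Sequence[int],
    cfg: ForestConfig,
    feature_ids: Sequence[str] | None = None,
) -> ForestModel:
    """Train a bagged-tree ensemble; deterministic given ``cfg.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValidationError("feature matrix must be 2-D with >= 1 feature")
    if not set(np.unique(y).tolist()) == {0, 1}:
        raise ValidationError("labels must contain both classes, coded 0/1")
    if feature_ids is None:
        feature_ids = [f"feature_{j}" for j in range(X.shape[1])]
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.resolved_mtry(X.shape[1]),
        min_samples_leaf=cfg.min_node,
        bootstrap=True,
        random_state=int(cfg.seed) % (2**32),
        n_jobs=1,
    )
    est.fit(X, y.astype(int))
    return ForestModel(est, X, y.astype(float), list(feature_ids), cfg)


def panel_summary(model: ForestModel) -> tuple[float, list[tuple[str, float]]]:
    """OOB error plus the importance ranking (descending mean decrease
    accuracy, ties broken by feature id)."""
    ranking = sorted(model.importance.items(), key=lambda kv: (-kv[1], kv[0]))
    return model.oob_error, ranking


def evaluate_subsets(
    X: np.ndarray,
    y: Sequence[int],
    features: Sequence[str],
    cfg: ForestConfig,
) -> list[SubsetEvaluation]:
    """Train and score a forest for every non-empty feature subset.

    Each subset's forest seed derives from (cfg.seed, subset index), so the
    enumeration is reproducible subset by subset.
    """
    features = list(features)
    if not 1 <= len(features) <= MAX_EXHAUSTIVE_FEATURES:
        raise ValidationError(
            f"exhaustive enumeration supports 1..{MAX_EXHAUSTIVE_FEATURES} features "
            f"(got {len(features)}); sample subsets instead"
        )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    col = {f: j for j, f in enumerate(features)}
    evals: list[SubsetEvaluation] = []
    idx = 0
    for size in range(1, len(features) + 1):
        for subset in itertools.combinations(features, size):
            sub_seed = int(np.random.default_rng([cfg.seed, 2, idx]).integers(2**31))
            sub_cfg = ForestConfig(
                n_trees=cfg.n_trees, mtry=cfg.mtry, min_node=cfg.min_node, seed=sub_seed
            )
            cols = [col[f] for f in subset]
            model = train_forest(X[:, cols], y, sub_cfg, feature_ids=list(subset))
            ok = ~np.isnan(model.oob_proba)
            a = auroc(model.oob_proba[ok], model.y[ok])
            lo, hi = delong_ci(model.oob_proba[ok], model.y[ok])
            acc = 1.0 - model.oob_error
            evals.append(
                SubsetEvaluation(
                    subset=subset,
                    auroc=a,
                    ci_low=lo,
                    ci_high=hi,
                    oob_accuracy=acc,
                    perfect=bool(acc == 1.0),
                )
            )
            idx += 1
    return evals


def perfect_signatures(evals: Sequence[SubsetEvaluation]) -> list[tuple[str, ...]]:
    """Subsets classifying every sample correctly out-of-bag, smallest
    first (ties lexicographic)."""
    if not evals:
        raise ValidationError("no subset evaluations given")
    hits = [e.subset for e in evals if e.perfect]
    return sorted(hits, key=lambda s: (len(s), tuple(sorted(s))))


def classify_samples(
    model: ForestModel,
    expr: ExpressionMatrix,
    feature_ids: Sequence[str],
) -> list[tuple[str, str, float]]:
    """Classify new samples from their CPM profiles.

    Returns ``(sample_id, label, vote_fraction)`` per sample, where label is
    "case"/"control" by majority vote (> 0.5 -> case).  Every panel miRNA
    must be present; there is no imputation.
    """
    missing = [f for f in feature_ids if f not in expr.mirna_ids]
    if missing:
        raise ValidationError(f"panel miRNAs missing from expression data: {missing}")
    if list(feature_ids) != model.feature_ids:
        raise ValidationError("feature_ids do not match the trained model's panel")
    rows = [expr.mirna_ids.index(f) for f in feature_ids]
    X_new = np.log2(expr.cpm[rows, :].T + 1.0)
    fracs = model.vote_fractions(X_new)
    out = []
    for sid, v in zip(expr.sample_ids, fracs):
        if v == 0.5:
            warnings.warn(f"tied vote for sample {sid}; assigned control")
        out.append((sid, "case" if v > 0.5 else "control", float(v)))
    return out
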