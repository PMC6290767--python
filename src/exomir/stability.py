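"""Stability selection by repeated stratified 70/30 partitioning.

Each repeat splits the cohort into a discovery (70%) and validation (30%)
set, stratified by class; the three-test consensus DE rule is applied to
the discovery set only, and every miRNA passing it is tallied.  When the
repeat yields at least one consensus miRNA, a random forest is trained on
the discovery samples (log2(CPM+1) features) and its accuracy on the held
out validation samples is recorded.  After ``n_repeats`` repeats (100 by
default), miRNAs selected in strictly more than ``stable_threshold`` (75%)
of repeats form the *stable* classifier set.

Per-repeat randomness derives from ``(scheme.seed, repeat_index)``, so the
loop is bit-reproducible and any single repeat can be replayed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diffexp import ContrastSpec, run_contrast
from .errors import ValidationError
from .io import CountMatrix
from .panel import ForestConfig, train_forest
from .preprocess import cpm_normalize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartitionScheme:
    train_fraction: float = 0.70
    n_repeats: int = 100
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if not self.stratified:
            raise ValidationError("only stratified partitioning is supported")


@dataclass
class StabilityResult:
    selection_count: dict[str, int]
    n_repeats: int
    per_repeat_test_accuracy: list[float]
    stable_threshold: float = 0.75


def stratified_partition(
    labels: Sequence[str],
    train_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split: round(train_fraction * n_class) samples
    (round-half-to-even) to train, the rest to test; disjoint, exhaustive."""
    labels = np.asarray(labels)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        n_train = int(round(train_fraction * idx.size))
        if n_train == 0 or n_train == idx.size:
            raise ValidationError(
                f"class {g!r}: train fraction {train_fraction} leaves an empty split"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def run_stability(
    m: CountMatrix,
    meta: Sequence,
    spec: ContrastSpec,
    scheme: PartitionScheme,
    forest_cfg: ForestConfig | None = None,
    stable_threshold: float = 0.75,
) -> StabilityResult:
    """The full resampling loop on a preprocessed (QC'd, abundance-filtered)
    matrix.  The abundance filter is *not* recomputed inside repeats."""
    if forest_cfg is None:
        forest_cfg = ForestConfig()
    group_of = {r.sample_id: r.group for r in meta}
    wanted = [
        s for s in m.sample_ids
        if group_of.get(s) in (spec.case_label, spec.control_label)
    ]
    sub = m.subset_samples(wanted)
    meta_sub = [r for r in meta if r.sample_id in set(wanted)]
    labels = np.asarray([group_of[s] for s in sub.sample_ids])
    log2cpm = cpm_normalize(sub).log2_cpm()
    y_all = (labels == spec.case_label).astype(int)

    counts: dict[str, int] = {mid: 0 for mid in sub.mirna_ids}
    accuracies: list[float] = []
    for r in range(scheme.n_repeats):
        rng = np.random.default_rng([scheme.seed, r, 0])
        tr, te = stratified_partition(labels, scheme.train_fraction, rng)
        disc = sub.subset_samples([sub.sample_ids[i] for i in tr])
        records = run_contrast(disc, meta_sub, spec)
        selected = [rec.mirna_id for rec in records if rec.consensus]
        for mid in selected:
            counts[mid] += 1
        if selected:
            rows = [sub.mirna_ids.index(mid) for mid in selected]
            X_tr = log2cpm[np.ix_(rows, tr)].T
            X_te = log2cpm[np.ix_(rows, te)].T
            fseed = int(np.random.default_rng([scheme.seed, r, 1]).integers(2**31))
            cfg = ForestConfig(
                n_trees=forest_cfg.n_trees,
                mtry=forest_cfg.mtry,
                min_node=forest_cfg.min_node,
                seed=fseed,
            )
            model = train_forest(X_tr, y_all[tr], cfg, feature_ids=selected)
            pred = (model.vote_fractions(X_te) > 0.5).astype(int)
            accuracies.append(float(np.mean(pred == y_all[te])))
        else:
            accuracies.append(math.nan)
        if (r + 1) % 10 == 0:
            logger.info("stability repeat %d/%d", r + 1, scheme.n_repeats)
    return StabilityResult(
        selection_count=counts,
        n_repeats=scheme.n_repeats,
        per_repeat_test_accuracy=accuracies,
        stable_threshold=stable_threshold,
    )


def stable_features(res: StabilityResult) -> list[str]:
    """miRNAs selected in strictly more than ``stable_threshold`` of
    repeats, by descending count then id."""
    cut = res.stable_threshold * res.n_repeats
    hits = [(mid, c) for mid, c in res.selection_count.items() if c > cut]
    if not hits:
        logger.warning("no stable features at threshold %.2f", res.stable_threshold)
    return [mid for mid, _ in sorted(hits, key=lambda kv: (-kv[1], kv[0]))]
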