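"""Three-test consensus differential expression with signed fold change.

For every miRNA surviving preprocessing, three two-sided tests are run per
two-group contrast:

* Wilcoxon rank-sum on CPM values (exact null distribution when there are
  no ties and the pooled sample size is at most 30, otherwise the normal
  approximation with tie and continuity corrections),
* Student's pooled-variance t test on log2(CPM + 1) (configurable to raw
  CPM),
* an exact test for negative-binomially distributed counts with a common
  method-of-moments dispersion, conditioning the case group-sum on the
  total after linear equalization of library sizes.

A miRNA is a *consensus* call when its CPM ratio passes the fold-change
threshold in either direction and all three unadjusted p values pass the p
threshold.  Benjamini-Hochberg q values are reported per test column.

NB parameterization throughout: variance = mu + phi * mu**2.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import ValidationError
from .io import CountMatrix
from .preprocess import cpm_normalize

logger = logging.getLogger(__name__)

#: pseudo-offset (CPM) added to both group means when one of them is zero,
#: for fold-change display only; p values are unaffected
ZERO_MEAN_CPM_OFFSET = 0.5

#: pooled sample size up to which the Wilcoxon null is enumerated exactly
EXACT_WILCOXON_MAX_N = 30

#: group-sum total up to which the NB conditional law is enumerated exactly;
#: above it the beta-binomial is replaced by its Beta mixing limit
EXACT_NB_MAX_TOTAL = 20_000


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison with its consensus thresholds."""

    case_label: str
    control_label: str
    fc_threshold: float = 2.0
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.case_label == self.control_label:
            raise ValidationError("case and control labels must differ")
        if self.fc_threshold < 1:
            raise ValidationError("fc_threshold must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must be in (0, 1)")


@dataclass
class DiffExprRecord:
    """Per-miRNA differential-expression summary (one output row)."""

    mirna_id: str
    cpm_case_mean: float
    cpm_control_mean: float
    ratio: float
    fc_display: float
    p_exact: float
    p_t: float
    p_wilcoxon: float
    q_exact: float = math.nan
    q_t: float = math.nan
    q_wilcoxon: float = math.nan
    consensus: bool = False


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    n_mirna_used: int

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValidationError("dispersion must be >= 0")


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (2.95 -> 3.0, -2.45 -> -2.5)."""
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def signed_fold_change(mean_case: float, mean_control: float) -> tuple[float, float]:
    """Case/control CPM ratio plus its signed one-decimal display value.

    Ratios >= 1 display as the rounded ratio; ratios < 1 display as the
    negated reciprocal of the *rounded* ratio, matching the convention of
    the published summary tables (e.g. 0.296 -> rounded 0.3 -> -3.3).
    """
    if mean_case <= 0 or mean_control <= 0:
        raise ValidationError(
            "zero group mean; add the pseudo-offset "
            f"(ZERO_MEAN_CPM_OFFSET={ZERO_MEAN_CPM_OFFSET}) to both means for FC"
        )
    ratio = mean_case / mean_control
    if ratio >= 1:
        display = round_half_away(ratio, 1)
    else:
        rounded = round_half_away(ratio, 1)
        # ratios under 0.05 round to 0.0; use the unrounded reciprocal there
        display = -round_half_away(1.0 / (rounded if rounded > 0 else ratio), 1)
    return ratio, display


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p value.

    Exact by enumeration when there are no ties and the pooled n is <= 30;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and pooled.size <= EXACT_WILCOXON_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def student_t_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided pooled-variance two-sample t test (df = n_x + n_y - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 values")
    mean_diff = x.mean() - y.mean()
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        if mean_diff == 0:
            return 1.0
        warnings.warn("zero pooled variance with unequal means; p = 0")
        return 0.0
    t = mean_diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(2 * stats.t.sf(abs(t), df=n1 + n2 - 2))


def estimate_common_dispersion(
    m: CountMatrix, groups: Sequence[str]
) -> DispersionEstimate:
    """Method-of-moments common NB dispersion.

    Counts are linearly scaled to the geometric-mean library size; for each
    miRNA the within-group pooled variance s2 and pooled mean mbar give
    phi_i = max(0, (s2 - mbar) / mbar**2); the estimate is the median over
    miRNAs with positive mean, clipped to [0, 10].
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
    gm = math.exp(np.mean(np.log(m.library_sizes)))
    scaled = m.counts * (gm / m.library_sizes)[None, :]
    ss = np.zeros(m.n_mirna)
    df = 0
    means = np.zeros(m.n_mirna)
    n_total = 0
    for g in labels:
        sub = scaled[:, groups == g]
        n_g = sub.shape[1]
        ss += (n_g - 1) * sub.var(axis=1, ddof=1)
        df += n_g - 1
        means += n_g * sub.mean(axis=1)
        n_total += n_g
    s2 = ss / df
    mbar = means / n_total
    ok = mbar > 0
    if not ok.any():
        return DispersionEstimate(phi=0.0, n_mirna_used=0)
    phi_i = np.maximum(0.0, (s2[ok] - mbar[ok]) / mbar[ok] ** 2)
    phi = float(np.clip(np.median(phi_i), 0.0, 10.0))
    return DispersionEstimate(phi=phi, n_mirna_used=int(ok.sum()))


def _beta_tail_pvalue(x_obs: float, r1: float, r2: float) -> float:
    """Double-tail p value of a Beta(r1, r2) via density matching.

    Used as the large-total limit of the conditional beta-binomial law.
    Requires r1 > 1 and r2 > 1 (unimodal density).
    """
    def logpdf(x: float) -> float:
        return (r1 - 1) * math.log(x) + (r2 - 1) * math.log1p(-x)

    mode = (r1 - 1) / (r1 + r2 - 2)
    x_obs = min(max(x_obs, 1e-12), 1 - 1e-12)
    if abs(x_obs - mode) < 1e-12:
        return 1.0
    target = logpdf(x_obs)
    if x_obs < mode:
        # matching point on the right of the mode
        lo, hi = mode, 1 - 1e-15
        if logpdf(hi) > target:
            other = 1.0
        else:
            other = optimize.brentq(lambda x: logpdf(x) - target, lo, hi, xtol=1e-13)
        p = stats.beta.cdf(x_obs, r1, r2) + stats.beta.sf(other, r1, r2)
    else:
        lo, hi = 1e-15, mode
        if logpdf(lo) > target:
            other = 0.0
        else:
            other = optimize.brentq(lambda x: logpdf(x) - target, lo, hi, xtol=1e-13)
        p = stats.beta.sf(x_obs, r1, r2) + stats.beta.cdf(other, r1, r2)
    return float(min(p, 1.0))


def _betabinom_doubletail(s1: int, s_total: int, r1: float, r2: float) -> float:
    """Exact double-tail p of BetaBinomial(s_total, r1, r2) at s1: the sum of
    probabilities of all outcomes no more likely than the observed one."""
    a = np.arange(s_total + 1)
    logpmf = stats.betabinom.logpmf(a, s_total, r1, r2)
    lobs = logpmf[s1]
    tol = 1e-8 * max(1.0, abs(lobs))
    mask = logpmf <= lobs + tol
    return float(min(np.exp(special.logsumexp(logpmf[mask])), 1.0))


def nb_exact_test(
    case_counts: Sequence[float],
    control_counts: Sequence[float],
    lib_sizes: Sequence[float],
    phi: float,
) -> float:
    """Exact test for a difference between two groups of NB counts.

    Counts are linearly scaled to the geometric-mean library size and
    rounded to integer pseudo-counts.  Group sums S1, S2 are then compared
    under a common-mean NB model with per-group-sum dispersion ``phi/n_g``:
    conditional on the total, the case sum follows
    BetaBinomial(S1+S2, n_case/phi, n_control/phi), which in the Poisson
    limit (phi = 0) is Binomial(S1+S2, n_case/(n_case+n_control)).  The p
    value is the total probability of outcomes no more likely than the one
    observed.
    """
    if phi < 0:
        raise ValidationError("dispersion must be >= 0")
    case = np.asarray(case_counts, dtype=float)
    ctrl = np.asarray(control_counts, dtype=float)
    libs = np.asarray(lib_sizes, dtype=float)
    allc = np.concatenate([case, ctrl])
    if np.any(allc != np.round(allc)):
        raise ValidationError("exact test requires integer counts")
    if libs.size != allc.size or np.any(libs <= 0):
        raise ValidationError("need one positive library size per sample")
    n1, n2 = case.size, ctrl.size
    gm = math.exp(np.mean(np.log(libs)))
    scaled = np.round(allc * gm / libs).astype(np.int64)
    s1 = int(scaled[:n1].sum())
    s2 = int(scaled[n1:].sum())
    s_total = s1 + s2
    if s_total == 0:
        return 1.0
    if phi == 0:
        return float(stats.binomtest(s1, s_total, n1 / (n1 + n2)).pvalue)
    r1, r2 = n1 / phi, n2 / phi
    if s_total <= EXACT_NB_MAX_TOTAL or r1 <= 1 or r2 <= 1:
        if s_total > EXACT_NB_MAX_TOTAL:
            # U-shaped/monotone mixing density: keep the exact enumeration
            logger.debug("nb_exact_test: large-total exact fallback (r <= 1)")
        return _betabinom_doubletail(s1, s_total, r1, r2)
    return _beta_tail_pvalue(s1 / s_total, r1, r2)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# contrast driver
# ---------------------------------------------------------------------------

def run_contrast(
    m: CountMatrix,
    meta: Sequence,
    spec: ContrastSpec,
    t_scale: str = "log2cpm",
    phi: float | None = None,
) -> list[DiffExprRecord]:
    """Run the three-test consensus DE analysis on a preprocessed matrix.

    ``meta`` is a sequence of SampleRecord (or any objects with
    ``sample_id``/``group``).  Samples not labeled with the case or control
    label are ignored.  ``phi`` overrides the method-of-moments common
    dispersion (used by the synthetic null-calibration tests).
    """
    if t_scale not in ("log2cpm", "cpm"):
        raise ValidationError(f"unknown t_scale {t_scale!r}")
    group_of = {r.sample_id: r.group for r in meta}
    wanted = [
        s for s in m.sample_ids
        if group_of.get(s) in (spec.case_label, spec.control_label)
    ]
    sub = m.subset_samples(wanted)
    labels = np.asarray([group_of[s] for s in sub.sample_ids])
    case_mask = labels == spec.case_label
    ctrl_mask = labels == spec.control_label
    if case_mask.sum() < 2 or ctrl_mask.sum() < 2:
        raise ValidationError(
            f"need >= 2 samples per group; got {int(case_mask.sum())} "
            f"{spec.case_label} vs {int(ctrl_mask.sum())} {spec.control_label}"
        )

    expr = cpm_normalize(sub)
    cpm = expr.cpm
    log2cpm = expr.log2_cpm()
    t_values = log2cpm if t_scale == "log2cpm" else cpm

    if sub.is_raw:
        if phi is None:
            phi = estimate_common_dispersion(sub, labels).phi
    else:
        logger.warning(
            "matrix is not raw counts; NB exact test disabled (p_exact = NA), "
            "consensus uses the remaining two tests"
        )

    records: list[DiffExprRecord] = []
    for i, mid in enumerate(sub.mirna_ids):
        mean_case = float(cpm[i, case_mask].mean())
        mean_ctrl = float(cpm[i, ctrl_mask].mean())
        mc, mk = mean_case, mean_ctrl
        if mc <= 0 or mk <= 0:
            mc += ZERO_MEAN_CPM_OFFSET
            mk += ZERO_MEAN_CPM_OFFSET
        ratio, display = signed_fold_change(mc, mk)
        p_w = wilcoxon_rank_sum(cpm[i, case_mask], cpm[i, ctrl_mask])
        p_t = student_t_test(t_values[i, case_mask], t_values[i, ctrl_mask])
        if sub.is_raw:
            p_e = nb_exact_test(
                sub.counts[i, case_mask],
                sub.counts[i, ctrl_mask],
                np.concatenate([sub.library_sizes[case_mask], sub.library_sizes[ctrl_mask]]),
                phi,
            )
        else:
            p_e = math.nan
        records.append(
            DiffExprRecord(
                mirna_id=mid,
                cpm_case_mean=mean_case,
                cpm_control_mean=mean_ctrl,
                ratio=ratio,
                fc_display=display,
                p_exact=p_e,
                p_t=p_t,
                p_wilcoxon=p_w,
            )
        )

    for attr_p, attr_q in (("p_exact", "q_exact"), ("p_t", "q_t"), ("p_wilcoxon", "q_wilcoxon")):
        ps = np.array([getattr(r, attr_p) for r in records])
        if np.all(np.isnan(ps)):
            continue
        qs = bh_adjust(ps)
        for r, q in zip(records, qs):
            setattr(r, attr_q, float(q))

    for r in records:
        fc_pass = r.ratio >= spec.fc_threshold or r.ratio <= 1.0 / spec.fc_threshold
        ps = [r.p_t, r.p_wilcoxon] + ([] if math.isnan(r.p_exact) else [r.p_exact])
        r.consensus = bool(fc_pass and all(p <= spec.p_threshold for p in ps))
    return records
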