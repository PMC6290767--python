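"""Sample QC, CPM normalization and low-abundance filtering.

The order of operations mirrors the sequencing workflow: per-sample library
totals gate sample QC (strictly more than ``min_total`` reads required);
counts-per-million use the *pre-filter* library totals as denominator; the
abundance filter then drops miRNAs with fewer than ``min_count`` raw reads
in strictly more than ``max_frac_below`` of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyCohortError, ValidationError
from .io import CountMatrix

logger = logging.getLogger(__name__)

MIN_LIBRARY_READS = 45_000
MIN_ABUNDANCE_COUNT = 50
MAX_FRAC_BELOW = 0.20


@dataclass
class ExpressionMatrix:
    """Counts-per-million view of a count matrix."""

    mirna_ids: list[str]
    sample_ids: list[str]
    cpm: np.ndarray
    source_library_sizes: np.ndarray

    @property
    def n_mirna(self) -> int:
        return self.cpm.shape[0]

    def row(self, mirna_id: str) -> np.ndarray:
        try:
            i = self.mirna_ids.index(mirna_id)
        except ValueError:
            raise ValidationError(f"unknown miRNA id {mirna_id!r}") from None
        return self.cpm[i]

    def log2_cpm(self) -> np.ndarray:
        """log2(CPM + 1), the predictor scale used by the modeling stages."""
        return np.log2(self.cpm + 1.0)


def qc_filter_samples(m: CountMatrix, min_total: float = MIN_LIBRARY_READS) -> CountMatrix:
    """Drop samples whose library size is <= ``min_total`` reads."""
    keep = m.library_sizes > min_total
    dropped = [s for s, k in zip(m.sample_ids, keep) if not k]
    if dropped:
        logger.info("qc_filter_samples: dropping %s (library <= %g)", dropped, min_total)
    if not keep.any():
        raise EmptyCohortError(f"all {m.n_sample} samples below library floor {min_total}")
    if keep.all():
        return m
    return m.subset_samples([s for s, k in zip(m.sample_ids, keep) if k])


def cpm_normalize(m: CountMatrix) -> ExpressionMatrix:
    """counts * 1e6 / library_size, per sample.

    The denominator is the sample's total over all tabulated miRNAs, so CPM
    columns are unchanged by any later row filtering.
    """
    if np.any(m.library_sizes <= 0):
        raise ValidationError("zero library size; cannot CPM-normalize")
    cpm = m.counts * 1e6 / m.library_sizes[None, :]
    return ExpressionMatrix(
        list(m.mirna_ids), list(m.sample_ids), cpm, m.library_sizes.copy()
    )


def filter_low_abundance(
    m: CountMatrix,
    min_count: float = MIN_ABUNDANCE_COUNT,
    max_frac_below: float = MAX_FRAC_BELOW,
) -> CountMatrix:
    """Remove miRNA i iff #{j: counts[i,j] < min_count} / n > max_frac_below.

    Operates on raw counts; survivor order is preserved; library sizes are
    carried over from the input so CPM stays referenced to all reads.
    """
    frac_below = (m.counts < min_count).mean(axis=1)
    keep = frac_below <= max_frac_below
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_low_abundance: removing %d of %d miRNAs", n_drop, m.n_mirna)
    if not keep.any():
        logger.warning("filter_low_abundance: no miRNA survived the filter")
    if keep.all():
        return m
    return m.subset_mirnas(keep)
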