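"""Synthetic serum-exosome miRNA cohorts with planted group effects.

The generator draws negative-binomially distributed read counts for two
diagnostic groups (case vs control), with

* a per-miRNA baseline abundance profile whose log10 CPM is uniform over a
  configurable range,
* log-normal per-sample library sizes clamped at a 45,000-read floor (the
  QC floor applied to the real sequencing cohorts),
* a planted set of differentially abundant miRNAs with signed fold changes,
  applied to the case group's expected proportions and renormalized, so the
  compositional spillover of real CPM data is reproduced.

The NB parameterization is variance = mu + phi * mu**2 (dispersion phi),
shared with the differential-expression module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .io import CountMatrix, SampleRecord

__all__ = [
    "SyntheticDesign",
    "PlantedTruth",
    "draw_baseline_profile",
    "generate_counts",
    "default_discovery_design",
]

# seed-stream offsets: all randomness derives from default_rng([seed, offset])
_STREAM_BASELINE = 0
_STREAM_LIBRARY = 1
_STREAM_COUNTS = 2


@dataclass(frozen=True)
class SyntheticDesign:
    """Full description of a synthetic two-group cohort."""

    n_case: int = 12
    n_control: int = 12
    n_mirna: int = 300
    baseline_log10cpm_range: tuple[float, float] = (1.7, 4.5)
    planted_log10cpm_range: tuple[float, float] = (2.3, 4.5)
    dispersion: float = 0.15
    library_size_logmean: float = math.log(2e6)
    library_size_logsd: float = 0.4
    min_library: int = 45_000
    planted_effects: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError("need at least 2 samples per group")
        if self.n_mirna < 1:
            raise ValidationError("n_mirna must be positive")
        for rng_name in ("baseline_log10cpm_range", "planted_log10cpm_range"):
            lo, hi = getattr(self, rng_name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or not lo < hi:
                raise ValidationError(f"{rng_name} must be finite with low < high")
        phi = np.asarray(self.dispersion, dtype=float)
        if np.any(phi < 0) or not np.all(np.isfinite(phi)):
            raise ValidationError("dispersion must be finite and >= 0")
        idx = [i for i, _ in self.planted_effects]
        if len(set(idx)) != len(idx):
            raise ValidationError("planted miRNA indices must be unique")
        for i, fc in self.planted_effects:
            if not 0 <= i < self.n_mirna:
                raise ValidationError(f"planted index {i} out of range")
            if abs(fc) < 1:
                raise ValidationError(
                    f"signed fold change {fc} invalid: magnitude must be >= 1"
                )

    def phi_per_mirna(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.dispersion, dtype=float), (self.n_mirna,)
        ).copy()


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a generated cohort: which miRNAs carry which effect."""

    de_index_set: frozenset[int]
    signed_fc: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.de_index_set != frozenset(self.signed_fc):
            raise ValidationError("de_index_set must equal the keys of signed_fc")


def draw_baseline_profile(design: SyntheticDesign, rng: np.random.Generator) -> np.ndarray:
    """Baseline miRNA proportions: log10 CPM uniform on the design range,
    then normalized to sum to 1."""
    lo, hi = design.baseline_log10cpm_range
    log10cpm = rng.uniform(lo, hi, size=design.n_mirna)
    cpm = np.power(10.0, log10cpm)
    return cpm / cpm.sum()


def _effect_ratio(signed_fc: float) -> float:
    """Multiplier applied to the case-group proportion."""
    return signed_fc if signed_fc > 0 else 1.0 / abs(signed_fc)


def generate_counts(
    design: SyntheticDesign,
    case_label: str = "GBM",
    control_label: str = "HC",
) -> tuple[CountMatrix, list[SampleRecord], PlantedTruth]:
    """Draw a synthetic cohort: counts, metadata and the planted truth.

    Counts are NB(mean = pi_ig * L_j, dispersion = phi_i); dispersion 0
    degenerates to Poisson sampling.  Identical seeds give bit-identical
    output.
    """
    rng_base = np.random.default_rng([design.seed, _STREAM_BASELINE])
    rng_lib = np.random.default_rng([design.seed, _STREAM_LIBRARY])
    rng_cnt = np.random.default_rng([design.seed, _STREAM_COUNTS])

    lo, hi = design.baseline_log10cpm_range
    log10cpm = rng_base.uniform(lo, hi, size=design.n_mirna)
    if design.planted_effects:
        # effect carriers sit in the abundance range where dysregulated
        # serum-exosome miRNAs are observed (all pass the 50-read filter)
        plo, phi_hi = design.planted_log10cpm_range
        idx = np.array([i for i, _ in design.planted_effects])
        log10cpm[idx] = rng_base.uniform(plo, phi_hi, size=idx.size)
    cpm = np.power(10.0, log10cpm)
    pi_control = cpm / cpm.sum()
    mult = np.ones(design.n_mirna)
    for i, fc in design.planted_effects:
        mult[i] = _effect_ratio(fc)
    pi_case = pi_control * mult
    pi_case /= pi_case.sum()

    n_total = design.n_case + design.n_control
    libs = rng_lib.lognormal(
        design.library_size_logmean, design.library_size_logsd, size=n_total
    )
    libs = np.maximum(np.round(libs), design.min_library).astype(np.int64)

    pi = np.concatenate(
        [np.tile(pi_case[:, None], (1, design.n_case)),
         np.tile(pi_control[:, None], (1, design.n_control))],
        axis=1,
    )
    mu = pi * libs[None, :]
    phi = design.phi_per_mirna()[:, None]
    def _draw_columns(cols: np.ndarray) -> np.ndarray:
        sub_mu = mu[:, cols]
        out = np.empty_like(sub_mu)
        poisson_rows = phi[:, 0] == 0
        if poisson_rows.any():
            out[poisson_rows] = rng_cnt.poisson(sub_mu[poisson_rows])
        nb_rows = ~poisson_rows
        if nb_rows.any():
            r = 1.0 / phi[nb_rows]
            p = r / (r + sub_mu[nb_rows])
            out[nb_rows] = rng_cnt.negative_binomial(r, p)
        return out

    counts = _draw_columns(np.arange(n_total))
    # the emulated cohorts are post-QC: every sample *achieved* the read
    # floor, so columns whose realized total falls below it are redrawn
    # (NB law conditioned on total >= min_library; deterministic given seed)
    for _ in range(100):
        low = np.flatnonzero(counts.sum(axis=0) < design.min_library)
        if low.size == 0:
            break
        counts[:, low] = _draw_columns(low)
    else:
        raise ValidationError(
            "library floor unattainable: expected depth far below min_library"
        )

    case_ids = [f"{case_label}_{k + 1:02d}" for k in range(design.n_case)]
    ctrl_ids = [f"{control_label}_{k + 1:02d}" for k in range(design.n_control)]
    sample_ids = case_ids + ctrl_ids
    mirna_ids = [f"mir_{i:04d}" for i in range(design.n_mirna)]
    matrix = CountMatrix.from_counts(mirna_ids, sample_ids, counts.astype(np.int64))
    meta = [
        SampleRecord(sample_id=s, group=case_label, cohort="discovery") for s in case_ids
    ] + [
        SampleRecord(sample_id=s, group=control_label, cohort="discovery") for s in ctrl_ids
    ]
    truth = PlantedTruth(
        de_index_set=frozenset(i for i, _ in design.planted_effects),
        signed_fc={i: fc for i, fc in design.planted_effects},
    )
    return matrix, meta, truth


#: signed fold changes of the 26 dysregulated miRNAs of the reference
#: case/control comparison (11 up-regulated, 15 down-regulated; magnitudes
#: span 2.0-3.3)
REFERENCE_SIGNED_FCS: tuple[float, ...] = (
    3.0, 2.5, 2.4, 2.4, 2.4, 2.3, 2.2, 2.2, 2.2, 2.0, 2.0,
    -2.0, -2.0, -2.0, -2.0, -2.0,
    -2.4,
    -2.5, -2.5, -2.5, -2.5, -2.5, -2.5,
    -3.3, -3.3, -3.3,
)


def default_discovery_design(seed: int = 42) -> SyntheticDesign:
    """The frozen default cohort: 12 case vs 12 control samples, 300 miRNAs,
    common dispersion 0.15, and 26 planted effects whose signed fold changes
    replicate the published effect-size spectrum."""
    planted = tuple((i, fc) for i, fc in enumerate(REFERENCE_SIGNED_FCS))
    return SyntheticDesign(
        n_case=12,
        n_control=12,
        n_mirna=300,
        dispersion=0.15,
        planted_effects=planted,
        seed=seed,
    )


def null_design(seed: int = 7, n_mirna: int = 300, **overrides) -> SyntheticDesign:
    """A cohort with no planted effects (null calibration runs)."""
    return replace(
        SyntheticDesign(planted_effects=(), seed=seed, n_mirna=n_mirna), **overrides
    )
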