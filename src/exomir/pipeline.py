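"""End-to-end discovery workflow: preprocess -> diffexp -> univariate ->
stability -> panel, with one TSV per stage and a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .diffexp import ContrastSpec, run_contrast
from .errors import StageError, ValidationError
from .io import (
    CountMatrix,
    SampleRecord,
    read_count_matrix,
    read_metadata,
    write_count_matrix,
    write_records,
    read_records,
)
from .panel import ForestConfig, evaluate_subsets, panel_summary, perfect_signatures, train_forest
from .preprocess import cpm_normalize, filter_low_abundance, qc_filter_samples
from .stability import PartitionScheme, run_stability, stable_features
from .univariate import univariate_panel

logger = logging.getLogger(__name__)

STAGE_FILES = (
    "preprocess.tsv",
    "diffexp.tsv",
    "univariate.tsv",
    "stability.tsv",
    "panel.tsv",
)


@dataclass
class PipelineConfig:
    counts_path: str
    metadata_path: str
    output_dir: str
    contrast: ContrastSpec = field(default_factory=lambda: ContrastSpec("GBM", "HC"))
    scheme: PartitionScheme = field(default_factory=PartitionScheme)
    forest: ForestConfig = field(default_factory=ForestConfig)
    min_total: float = 45_000
    min_count: float = 50
    max_frac_below: float = 0.20
    dialect: str = "raw_tsv"
    stable_threshold: float = 0.75
    subset_max_features: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        # nested configs validate themselves on construction
        if self.subset_max_features < 1:
            raise ValidationError("subset_max_features must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "contrast" in d and isinstance(d["contrast"], dict):
            d["contrast"] = ContrastSpec(**d["contrast"])
        if "scheme" in d and isinstance(d["scheme"], dict):
            d["scheme"] = PartitionScheme(**d["scheme"])
        if "forest" in d and isinstance(d["forest"], dict):
            d["forest"] = ForestConfig(**d["forest"])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class _StabilityRow:
    mirna_id: str
    selection_count: int
    frequency: float
    stable: bool


@dataclass
class _ImportanceRow:
    mirna_id: str
    importance: float
    rank: int


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the whole workflow; returns the manifest dict.

    Stage outputs land in ``cfg.output_dir``: the five stage TSVs of
    :data:`STAGE_FILES` plus ``panel_subsets.tsv``, ``panel_perfect.tsv``,
    ``cpm.tsv``, ``stability_accuracy.tsv`` and ``manifest.json``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "exomir_version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stages": {},
    }

    def _stage(name):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    # preprocess -----------------------------------------------------------
    t0 = _stage("preprocess")
    try:
        m = read_count_matrix(cfg.counts_path, dialect=cfg.dialect)
        meta = read_metadata(cfg.metadata_path)
        m = qc_filter_samples(m, cfg.min_total)
        m = filter_low_abundance(m, cfg.min_count, cfg.max_frac_below)
        write_count_matrix(m, out / "preprocess.tsv")
        expr = cpm_normalize(m)
        cpm_df = m.to_frame()
        cpm_df.loc[:, :] = expr.cpm
        cpm_df.index.name = "mirna_id"
        cpm_df.to_csv(out / "cpm.tsv", sep="\t", float_format="%.6g")
    except Exception as e:  # noqa: BLE001 - stage context wrapper
        raise StageError("preprocess", str(e)) from e
    manifest["stages"]["preprocess"] = {
        "n_mirna": m.n_mirna, "n_sample": m.n_sample, "seconds": round(time.perf_counter() - t0, 2),
    }

    # diffexp --------------------------------------------------------------
    t0 = _stage("diffexp")
    try:
        de = run_contrast(m, meta, cfg.contrast)
        write_records(de, out / "diffexp.tsv")
    except Exception as e:
        raise StageError("diffexp", str(e)) from e
    consensus_ids = [r.mirna_id for r in de if r.consensus]
    manifest["stages"]["diffexp"] = {
        "n_records": len(de), "n_consensus": len(consensus_ids),
        "seconds": round(time.perf_counter() - t0, 2),
    }

    # univariate -----------------------------------------------------------
    t0 = _stage("univariate")
    try:
        uni = univariate_panel(expr, meta, consensus_ids, cfg.contrast)
        write_records(uni, out / "univariate.tsv", columns=[
            "mirna_id", "auroc", "ci_low", "ci_high",
            "loo_cost", "loo_misclass", "coef_intercept", "coef_slope", "separated",
        ])
    except Exception as e:
        raise StageError("univariate", str(e)) from e
    manifest["stages"]["univariate"] = {
        "n_records": len(uni), "seconds": round(time.perf_counter() - t0, 2),
    }

    # stability ------------------------------------------------------------
    t0 = _stage("stability")
    try:
        res = run_stability(
            m, meta, cfg.contrast, cfg.scheme, cfg.forest,
            stable_threshold=cfg.stable_threshold,
        )
        stable = stable_features(res)
        rows = [
            _StabilityRow(mid, c, c / res.n_repeats, mid in stable)
            for mid, c in sorted(
                res.selection_count.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        write_records(rows, out / "stability.tsv")
        acc_rows = [
            {"repeat": i, "test_accuracy": a}
            for i, a in enumerate(res.per_repeat_test_accuracy)
        ]
        write_records(acc_rows, out / "stability_accuracy.tsv", columns=["repeat", "test_accuracy"])
    except Exception as e:
        raise StageError("stability", str(e)) from e
    manifest["stages"]["stability"] = {
        "n_repeats": res.n_repeats, "n_stable": len(stable),
        "mean_test_accuracy": float(np.nanmean(res.per_repeat_test_accuracy))
        if res.per_repeat_test_accuracy else None,
        "seconds": round(time.perf_counter() - t0, 2),
    }

    # panel ----------------------------------------------------------------
    t0 = _stage("panel")
    try:
        group_of = {r.sample_id: r.group for r in meta}
        labels = np.asarray([group_of[s] for s in m.sample_ids])
        y = (labels == cfg.contrast.case_label).astype(int)
        if stable:
            rows_idx = [m.mirna_ids.index(mid) for mid in stable]
            X = np.log2(expr.cpm[rows_idx, :].T + 1.0)
            model = train_forest(X, y, cfg.forest, feature_ids=stable)
            oob_err, ranking = panel_summary(model)
            imp_rows = [
                _ImportanceRow(mid, v, k + 1) for k, (mid, v) in enumerate(ranking)
            ]
            write_records(imp_rows, out / "panel.tsv")
            subset_feats = stable[: cfg.subset_max_features]
            evals = evaluate_subsets(X[:, [stable.index(f) for f in subset_feats]],
                                     y, subset_feats, cfg.forest)
            write_records(evals, out / "panel_subsets.tsv")
            perfect = perfect_signatures(evals)
            perf_rows = [
                {"size": len(s), "subset": ",".join(s)} for s in perfect
            ]
            write_records(perf_rows, out / "panel_perfect.tsv", columns=["size", "subset"])
            panel_stats = {
                "n_stable": len(stable),
                "oob_error": oob_err,
                "predictive_power": model.predictive_power,
                "n_subsets": len(evals),
                "n_perfect": len(perfect),
            }
        else:
            write_records([], out / "panel.tsv", columns=["mirna_id", "importance", "rank"])
            write_records([], out / "panel_subsets.tsv", columns=[
                "subset", "auroc", "ci_low", "ci_high", "oob_accuracy", "perfect"])
            write_records([], out / "panel_perfect.tsv", columns=["size", "subset"])
            panel_stats = {"n_stable": 0}
    except Exception as e:
        raise StageError("panel", str(e)) from e
    panel_stats["seconds"] = round(time.perf_counter() - t0, 2)
    manifest["stages"]["panel"] = panel_stats

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def make_report(output_dir: str | Path) -> str:
    """Human-readable run summary, regenerable from the stage files alone."""
    out = Path(output_dir)
    for name in STAGE_FILES + ("manifest.json",):
        if not (out / name).exists():
            raise StageError("report", f"missing stage file {name}")
    manifest = json.loads((out / "manifest.json").read_text())
    de = read_records(out / "diffexp.tsv")
    stab = read_records(out / "stability.tsv")
    lines = [
        f"exomir {manifest['exomir_version']} run report",
        f"seed: {manifest['seed']}",
        "",
        f"consensus differentially expressed miRNAs: {int(de['consensus'].sum())} "
        f"of {len(de)} tested",
    ]
    stable = stab[stab["stable"]] if len(stab) else stab
    if len(stable):
        lines.append(f"stable classifier miRNAs (> {manifest['config']['stable_threshold']:.0%} of "
                     f"{manifest['config']['scheme']['n_repeats']} partitions):")
        for _, row in stable.iterrows():
            lines.append(f"  {row['mirna_id']} ({int(row['selection_count'])})")
        panel = manifest["stages"]["panel"]
        if "oob_error" in panel:
            lines.append(
                f"panel OOB error: {panel['oob_error']:.4f} "
                f"(predictive power {100 * panel['predictive_power']:.1f}%)"
            )
            lines.append(
                f"subset evaluations: {panel['n_subsets']}; "
                f"perfect signatures: {panel['n_perfect']}"
            )
            perf = read_records(out / "panel_perfect.tsv")
            for _, row in perf.iterrows():
                lines.append(f"  perfect: [{row['subset']}]")
    else:
        lines.append("no stable features")
    return "\n".join(lines) + "\n"
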