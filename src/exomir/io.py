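"""Tabular input/output: count matrices, sample metadata and stage results.

On-disk dialects
----------------
Count matrix (``raw_tsv``)
    UTF-8 TSV, no quoting; first column ``mirna_id``, one numeric column per
    sample.  Values must be non-negative integers.
Count matrix (``geo_series_matrix``)
    Same table shape but tolerant of GEO series-matrix decoration: comment
    lines starting with ``!`` or ``#`` are skipped, and float values
    (normalized data) are accepted.  Matrices read through this dialect are
    flagged ``is_raw=False`` so that downstream count-based tests (the NB
    exact test) know they cannot be applied.
Metadata
    TSV with header ``sample_id  group  cohort [age  gender]``.
Results
    One TSV per pipeline stage.  Float formatting is documented in
    :func:`write_records`: p/q values in scientific notation with two
    significant digits (``1.6E-07``), display fold changes with one decimal,
    all other floats with six significant digits.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import JoinError, ParseError, ValidationError

logger = logging.getLogger(__name__)

DIALECTS = ("raw_tsv", "geo_series_matrix")


@dataclass
class SampleRecord:
    """One row of the sample metadata table."""

    sample_id: str
    group: str
    cohort: str = "discovery"
    age: float | None = None
    gender: str | None = None


@dataclass
class CountMatrix:
    """miRNA-major raw read-count matrix with per-sample library sizes.

    ``library_sizes`` are the totals of the matrix the samples were *read*
    with; row filtering (abundance filter) deliberately preserves them so
    that CPM denominators keep referring to all tabulated miRNA reads.
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_mirna, n_sample)
    library_sizes: np.ndarray  # (n_sample,)
    is_raw: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        n_mirna, n_sample = self.counts.shape
        if len(self.mirna_ids) != n_mirna or len(self.sample_ids) != n_sample:
            raise ValidationError("id lists do not match count matrix shape")
        if len(set(self.mirna_ids)) != n_mirna:
            dupes = _duplicates(self.mirna_ids)
            raise ValidationError(f"duplicate miRNA ids: {sorted(dupes)}")
        if len(set(self.sample_ids)) != n_sample:
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)}")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.is_raw and np.any(self.counts != np.round(self.counts)):
            raise ValidationError("raw counts must be integral")
        colsums = self.counts.sum(axis=0)
        if np.any(self.library_sizes + 1e-9 < colsums):
            raise ValidationError("library_sizes smaller than column sums")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_counts(
        cls,
        mirna_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray,
        is_raw: bool = True,
    ) -> "CountMatrix":
        counts = np.asarray(counts, dtype=float)
        return cls(
            list(mirna_ids),
            list(sample_ids),
            counts,
            counts.sum(axis=0),
            is_raw=is_raw,
        )

    # -- views -----------------------------------------------------------
    @property
    def n_mirna(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sample(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        """Column subset preserving per-sample library sizes."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(
            self.mirna_ids,
            list(sample_ids),
            self.counts[:, idx],
            self.library_sizes[idx],
            is_raw=self.is_raw,
        )

    def subset_mirnas(self, keep: np.ndarray) -> "CountMatrix":
        """Row subset by boolean mask or index array; library sizes kept."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            [self.mirna_ids[i] for i in keep],
            self.sample_ids,
            self.counts[keep, :],
            self.library_sizes,
            is_raw=self.is_raw,
        )

    def to_frame(self) -> pd.DataFrame:
        # copy so frame edits can never alias the count matrix
        return pd.DataFrame(
            self.counts.copy(), index=list(self.mirna_ids), columns=list(self.sample_ids)
        )


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, dialect: str = "raw_tsv") -> CountMatrix:
    """Read a miRNA x sample count matrix TSV.

    Row order of the file is preserved.  Library sizes are the column sums.
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if dialect == "geo_series_matrix":
        numbered = [
            (i + 1, ln)
            for i, ln in enumerate(lines)
            if ln.strip() and not ln.startswith(("!", "#"))
        ]
    else:
        numbered = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not numbered:
        raise ParseError(f"{path}: empty file")
    header_no, header = numbered[0]
    cols = header.rstrip("\n").split("\t")
    if len(cols) < 2:
        raise ParseError(f"{path}:{header_no}: header has no sample columns")
    sample_ids = cols[1:]
    n_fields = len(cols)
    mirna_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in numbered[1:]:
        fields = line.rstrip("\n").split("\t")
        if len(fields) != n_fields:
            raise ParseError(
                f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
            )
        mirna_ids.append(fields[0])
        row = []
        for k, tok in enumerate(fields[1:], start=2):
            try:
                v = float(tok)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric count {tok!r} in field {k}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{path}:{lineno}: negative or non-finite count {tok!r}")
            row.append(v)
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    counts = np.asarray(rows, dtype=float)
    is_raw = dialect == "raw_tsv"
    if is_raw and np.any(counts != np.round(counts)):
        bad = int(np.argwhere(counts != np.round(counts))[0][0])
        raise ValidationError(
            f"{path}: non-integer value in raw count matrix (row {mirna_ids[bad]!r})"
        )
    return CountMatrix.from_counts(mirna_ids, sample_ids, counts, is_raw=is_raw)


METADATA_COLUMNS = ("sample_id", "group", "cohort", "age", "gender")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV; reports the inferred group label set."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty metadata file") from None
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: metadata must contain columns {sorted(required)}")
    ids = df["sample_id"].tolist()
    dup = _duplicates(ids)
    if dup:
        raise ValidationError(f"{path}: duplicate sample_id values: {sorted(dup)}")
    records: list[SampleRecord] = []
    for i, row in df.iterrows():
        group = row.get("group")
        if group is None or pd.isna(group) or not str(group).strip():
            raise ValidationError(f"{path}: row {i + 2}: missing group label")
        age = row.get("age")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                group=str(group),
                cohort=str(row["cohort"]) if "cohort" in df.columns and pd.notna(row.get("cohort")) else "discovery",
                age=float(age) if age is not None and pd.notna(age) and str(age).strip() else None,
                gender=str(row["gender"]) if "gender" in df.columns and pd.notna(row.get("gender")) else None,
            )
        )
    labels = sorted({r.group for r in records})
    logger.info("read %d sample records; group labels %s", len(records), labels)
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, sep="\t", index=False)


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    df = m.to_frame()
    if m.is_raw:
        df = df.astype(int)
    df.index.name = "mirna_id"
    df.to_csv(path, sep="\t")


def join_metadata(m: CountMatrix, records: Sequence[SampleRecord]) -> dict[str, str]:
    """Map sample_id -> group label, erroring on orphans on either side."""
    meta_ids = {r.sample_id for r in records}
    matrix_ids = set(m.sample_ids)
    orphans_meta = sorted(meta_ids - matrix_ids)
    orphans_matrix = sorted(matrix_ids - meta_ids)
    if orphans_meta or orphans_matrix:
        raise JoinError(
            f"metadata-only samples: {orphans_meta}; matrix-only samples: {orphans_matrix}"
        )
    return {r.sample_id: r.group for r in records}


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

#: column-name driven float formats (first match wins)
_FLOAT_FORMATS: tuple[tuple[tuple[str, ...], str], ...] = (
    (("p_", "q_"), "{:.1E}"),   # 2 significant digits, scientific
    (("fc_display",), "{:.1f}"),  # one decimal, Table-style display
)


def _format_value(name: str, value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return str(bool(value))
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "NA"
        for prefixes, fmt in _FLOAT_FORMATS:
            if any(name.startswith(p) or name == p for p in prefixes):
                return fmt.format(float(value))
        return "{:.6g}".format(float(value))
    if isinstance(value, (frozenset, set, tuple, list)):
        return ",".join(str(v) for v in sorted(value))
    return str(value)


def write_records(records: Sequence, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a homogeneous list of dataclass records as a TSV.

    Column order follows the dataclass field order (stable).  An empty list
    with explicit ``columns`` yields a header-only file.
    """
    if columns is None:
        if not records:
            raise ValidationError("empty record list requires explicit columns")
        columns = [f.name for f in dataclasses.fields(records[0])]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            d = dataclasses.asdict(rec) if dataclasses.is_dataclass(rec) else dict(rec)
            fh.write("\t".join(_format_value(c, d.get(c)) for c in columns) + "\n")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read back a stage TSV written by :func:`write_records`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
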