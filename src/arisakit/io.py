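"""Tabular I/O and shared containers.

The package exchanges four plain-text table formats:

* **peak table** — size-called fragment-analyzer peaks, one row per peak,
  with columns ``sample_id``, ``replicate_id``, ``size_bp``,
  ``intensity_rfu`` (TAB or comma separated; vendor exports with other
  column names are mapped through a *dialect* dict).
* **OTU table** — samples x OTUs abundance matrix as TSV, samples in rows,
  first column ``sample_id``.
* **metadata** — two-column TSV mapping ``sample_id`` to a group label.
* **distance matrix** — labeled square symmetric TSV.

All readers either return every data row or raise an explicit error naming
the offending line; nothing is silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    JoinError,
    ParseError,
    SchemaError,
    ValidationError,
)

# canonical peak-table column names; a dialect maps canonical -> file header
PEAK_COLUMNS = ("sample_id", "replicate_id", "size_bp", "intensity_rfu")

READ_COUNT = "read_count"
RELATIVE_INTENSITY = "relative_intensity"


@dataclass(frozen=True)
class PeakRecord:
    """One size-called electropherogram peak."""

    sample_id: str
    replicate_id: str
    size_bp: float
    intensity_rfu: float

    def __post_init__(self) -> None:
        if not self.sample_id or not self.replicate_id:
            raise ValidationError("sample_id and replicate_id must be non-empty")
        if not self.size_bp > 0:
            raise ValidationError(f"size_bp must be positive, got {self.size_bp}")
        if self.intensity_rfu < 0:
            raise ValidationError(
                f"intensity_rfu must be non-negative, got {self.intensity_rfu}"
            )


@dataclass
class PeakTable:
    """Ordered collection of :class:`PeakRecord` with a provenance tag."""

    records: list[PeakRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.replicate_id, r.size_bp, r.intensity_rfu) for r in self.records],
            columns=list(PEAK_COLUMNS),
        )


@dataclass
class OTUTable:
    """Samples x OTUs abundance matrix.

    ``abundance_kind`` is ``"read_count"`` for sequencing tables and
    ``"relative_intensity"`` for processed fingerprint tables (rows of the
    latter sum to 1, or to 0 for flagged empty samples).
    """

    data: pd.DataFrame  # index = sample ids, columns = OTU ids
    abundance_kind: str = READ_COUNT

    def __post_init__(self) -> None:
        if self.abundance_kind not in (READ_COUNT, RELATIVE_INTENSITY):
            raise ValidationError(f"unknown abundance_kind {self.abundance_kind!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate OTU id {dup!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("abundance matrix contains negative entries")
        if self.abundance_kind == RELATIVE_INTENSITY and len(self.data.columns):
            sums = self.data.sum(axis=1).to_numpy()
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0))
            if bad.any():
                sid = self.data.index[np.nonzero(bad)[0][0]]
                raise ValidationError(
                    f"relative-intensity row {sid!r} sums to {sums[bad][0]!r}, not 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def to_proportions(self) -> "OTUTable":
        """Row-normalize to per-sample proportions (all-zero rows stay zero)."""
        totals = self.data.sum(axis=1)
        safe = totals.replace(0.0, 1.0)
        return OTUTable(self.data.div(safe, axis=0), RELATIVE_INTENSITY)


@dataclass
class SampleMetadata:
    """Mapping sample id -> group label."""

    groups: dict[str, str]

    def __len__(self) -> int:
        return len(self.groups)

    def group_of(self, sample_id: str) -> str:
        try:
            return self.groups[sample_id]
        except KeyError:
            raise JoinError(f"sample {sample_id!r} has no group in the metadata") from None

    def labels_for(self, sample_ids: Sequence[str]) -> list[str]:
        return [self.group_of(s) for s in sample_ids]

    def by_group(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, g in self.groups.items():
            out.setdefault(g, []).append(sid)
        return out


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise dissimilarities in [0, 1]."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = "braycurtis"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValidationError("distance-matrix labels are not unique")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (self.values < 0).any():
            raise ValidationError("distance matrix contains negative values")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major (scipy ``squareform``) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.metric_name)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_lines(path: str | Path) -> list[str]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return [ln for ln in text.splitlines() if ln.strip() != ""]


def read_peak_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> PeakTable:
    """Read a size-called peak table (TSV or CSV, auto-detected).

    Parameters
    ----------
    path:
        File with a header line naming at least the four canonical columns.
    dialect:
        Optional mapping ``canonical name -> column name in the file`` for
        vendor exports whose headers differ from the canonical schema.

    Raises
    ------
    EmptyInputError, SchemaError, ParseError, ValidationError
    """
    lines = _read_lines(path)
    if not lines:
        raise EmptyInputError(f"{path}: file is empty")
    delim = _sniff_delimiter(lines[0])
    header = [h.strip() for h in lines[0].split(delim)]
    dialect = dict(dialect or {})
    col_idx: dict[str, int] = {}
    for canon in PEAK_COLUMNS:
        name = dialect.get(canon, canon)
        if name not in header:
            raise SchemaError(f"{path}: missing required column {name!r}")
        col_idx[canon] = header.index(name)

    if len(lines) == 1:
        raise EmptyInputError(f"{path}: header only, no data rows")

    records: list[PeakRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) < len(header):
            raise ParseError(f"{path}: line {lineno}: expected {len(header)} fields")
        raw = {c: fields[i] for c, i in col_idx.items()}
        try:
            size = float(raw["size_bp"])
            inten = float(raw["intensity_rfu"])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
        if not math.isfinite(size) or not math.isfinite(inten):
            raise ParseError(f"{path}: line {lineno}: non-finite value")
        try:
            records.append(
                PeakRecord(raw["sample_id"], raw["replicate_id"], size, inten)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return PeakTable(records, provenance=str(path))


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_otu_table(path: str | Path, abundance_kind: str = READ_COUNT) -> OTUTable:
    """Read a samples-in-rows OTU table from TSV."""
    lines = _read_lines(path)
    if len(lines) < 2:
        raise EmptyInputError(f"{path}: no data rows")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not np.issubdtype(df.to_numpy().dtype, np.number):
        raise ParseError(f"{path}: non-numeric abundance values")
    return OTUTable(df, abundance_kind)


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a two-column (sample_id, group) TSV."""
    lines = _read_lines(path)
    if not lines:
        raise EmptyInputError(f"{path}: file is empty")
    start = 0
    first = [f.strip() for f in lines[0].split("\t")]
    if first and first[0].lower() in ("sample_id", "sample", "#sampleid"):
        start = 1
    if start >= len(lines):
        raise EmptyInputError(f"{path}: header only, no data rows")
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        sid, group = fields[0], fields[1]
        if sid in mapping:
            raise ValidationError(f"{path}: line {lineno}: duplicate sample {sid!r}")
        mapping[sid] = group
    return SampleMetadata(mapping)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, g in meta.groups.items():
            fh.write(f"{sid}\t{g}\n")


def read_distance_matrix(path: str | Path, metric_name: str = "braycurtis") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(l) for l in df.index]
    if labels != [str(c) for c in df.columns]:
        raise ValidationError(f"{path}: row and column labels differ")
    return DistanceMatrix(labels, df.to_numpy(dtype=float), metric_name)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# OTU-table utilities shared by both method arms
# ---------------------------------------------------------------------------

def remove_rare_otus(table: OTUTable, min_count: int = 3) -> OTUTable:
    """Drop OTUs whose total read count across all samples is below ``min_count``.

    With the default ``min_count=3`` this removes singleton and doubleton
    clusters, the standard low-abundance filter applied to amplicon OTU
    tables before diversity analysis. The rule is applied to study-wide
    totals, not per-sample counts.
    """
    if table.abundance_kind != READ_COUNT:
        raise ValidationError("rare-OTU removal applies to read-count tables only")
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    totals = table.data.sum(axis=0)
    keep = totals[totals >= min_count].index
    return OTUTable(table.data[keep], READ_COUNT)


def check_metadata_covers(table: OTUTable, meta: SampleMetadata) -> None:
    """Raise :class:`JoinError` naming the first sample missing a group."""
    for sid in table.sample_ids:
        if sid not in meta.groups:
            raise JoinError(f"sample {sid!r} present in OTU table but absent from metadata")
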