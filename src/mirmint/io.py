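"""Tab-separated readers and writers for count matrices, metadata, target maps
and results tables.

All artifacts are UTF-8 TSV with Unix newlines.  Writers are deterministic:
the same in-memory object always produces identical bytes, and reals are
serialized at 6 significant digits.  Readers never silently drop rows — a
malformed row raises :class:`~mirmint.errors.FormatError` naming the line.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateKeyError, FormatError

log = logging.getLogger(__name__)

_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Integer feature x sample count matrix.

    ``counts`` is a pandas DataFrame indexed by feature id with one column per
    sample.  Identifiers are case-sensitive and must be unique; counts must be
    non-negative integers (missing values are not permitted).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise DuplicateKeyError(f"duplicate feature id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise DuplicateKeyError(f"duplicate sample id {dup!r}")
        if df.isna().any().any():
            raise ValueError("count matrix contains missing values")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            object.__setattr__(self, "counts", df.astype(np.int64))
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class SampleMetadata:
    """Ordered sample -> group assignment for a two-group (or k-group) design."""

    samples: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.groups):
            raise ValueError("samples and groups must have equal length")
        if len(set(self.samples)) != len(self.samples):
            raise DuplicateKeyError("duplicate sample id in metadata")
        if len(self.samples) < 1:
            raise FormatError("metadata holds no samples")

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in zip(self.samples, self.groups) if g == group]

    def as_mapping(self) -> dict[str, str]:
        return dict(zip(self.samples, self.groups))


@dataclass(frozen=True)
class TargetMap:
    """Unique (miRNA, target gene) pairs, optionally scored.

    Pairs keep first-seen order; duplicates collapse to one entry.
    """

    pairs: tuple[tuple[str, str], ...]
    scores: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, g in self.pairs:
            if not m or not g:
                raise FormatError("target-map identifiers must be non-empty")
        if len(set(self.pairs)) != len(self.pairs):
            dedup = tuple(dict.fromkeys(self.pairs))
            object.__setattr__(self, "pairs", dedup)

    def __len__(self) -> int:
        return len(self.pairs)

    def targets_of(self, mirna: str) -> list[str]:
        return [g for m, g in self.pairs if m == mirna]

    def as_dict(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for m, g in self.pairs:
            out.setdefault(m, []).append(g)
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_rows(path: str | Path) -> list[list[str]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return [row for row in csv.reader(fh, delimiter="\t")]


def read_count_matrix(path: str | Path, dialect: str = "named-first-column") -> CountMatrix:
    """Read a count matrix TSV.

    ``named-first-column`` expects a header ``<name><TAB>sample...``;
    ``plain`` expects the header to contain only the sample ids, with each
    data row carrying ``feature<TAB>counts...``.
    """
    if dialect not in ("plain", "named-first-column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    samples = header[1:] if dialect == "named-first-column" else header
    if not samples:
        raise FormatError(f"{path}: header names no samples")
    features: list[str] = []
    data: list[list[int]] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(samples) + 1:
            raise FormatError(
                f"{path}: line {lineno}: expected {len(samples) + 1} fields, got {len(row)}"
            )
        fid = row[0]
        if fid in seen:
            raise DuplicateKeyError(f"{path}: line {lineno}: duplicate feature id {fid!r}")
        seen.add(fid)
        vals: list[int] = []
        for s, cell in zip(samples, row[1:]):
            try:
                v = int(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer count {cell!r} for sample {s!r}"
                ) from None
            if v < 0:
                raise ValueError(f"{path}: line {lineno}: negative count for sample {s!r}")
            vals.append(v)
        features.append(fid)
        data.append(vals)
    df = pd.DataFrame(data, index=features, columns=samples, dtype=np.int64)
    return CountMatrix(df)


def write_count_matrix(
    matrix: CountMatrix, path: str | Path, dialect: str = "named-first-column",
    feature_column: str = "feature",
) -> None:
    lines: list[str] = []
    if dialect == "named-first-column":
        lines.append("\t".join([feature_column, *matrix.sample_ids]))
    elif dialect == "plain":
        lines.append("\t".join(matrix.sample_ids))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    arr = matrix.counts.to_numpy()
    for fid, row in zip(matrix.feature_ids, arr):
        lines.append("\t".join([fid, *(str(int(v)) for v in row)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_metadata(path: str | Path) -> SampleMetadata:
    rows = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file")
    if [c.strip() for c in rows[0][:2]] != ["sample", "group"]:
        raise FormatError(f"{path}: expected header 'sample<TAB>group'")
    samples: list[str] = []
    groups: list[str] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 fields")
        if row[0] in samples:
            raise DuplicateKeyError(f"{path}: line {lineno}: duplicate sample {row[0]!r}")
        samples.append(row[0])
        groups.append(row[1])
    if not samples:
        raise FormatError(f"{path}: no samples listed")
    return SampleMetadata(tuple(samples), tuple(groups))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    lines = ["sample\tgroup"]
    lines += [f"{s}\t{g}" for s, g in zip(meta.samples, meta.groups)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_target_map(
    path: str | Path,
    dialect: str = "two-column",
    mirna_column: str = "miRNA",
    gene_column: str = "Gene Symbol",
    strip_species_prefix: bool = False,
) -> TargetMap:
    """Read a miRNA -> target-gene map.

    ``two-column`` is the canonical dialect (header ``mirna<TAB>gene``).
    ``targetscan-export`` tolerates a TargetScan-style download: any column
    layout, with the miRNA and gene-symbol columns named by ``mirna_column``
    and ``gene_column``; all other columns are ignored.

    ``strip_species_prefix`` removes a leading species token such as ``mmu-``
    from miRNA names before matching (off by default: identifiers are matched
    exactly).
    """
    rows = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if dialect == "two-column":
        if [c.strip() for c in header[:2]] != ["mirna", "gene"]:
            raise FormatError(f"{path}: expected header 'mirna<TAB>gene'")
        mi_idx, ge_idx = 0, 1
    elif dialect == "targetscan-export":
        for col in (mirna_column, gene_column):
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        mi_idx = header.index(mirna_column)
        ge_idx = header.index(gene_column)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    pairs: list[tuple[str, str]] = []
    n_rows = 0
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) <= max(mi_idx, ge_idx):
            raise FormatError(f"{path}: line {lineno}: too few fields")
        m, g = row[mi_idx], row[ge_idx]
        if strip_species_prefix:
            m = _SPECIES_PREFIX.sub("", m)
        pairs.append((m, g))
        n_rows += 1
    tm = TargetMap(tuple(dict.fromkeys(pairs)))
    log.info("read %d rows -> %d unique miRNA-gene pairs from %s", n_rows, len(tm), path)
    return tm


def write_target_map(tm: TargetMap, path: str | Path) -> None:
    lines = ["mirna\tgene"]
    lines += [f"{m}\t{g}" for m, g in tm.pairs]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def format_number(v: object) -> str:
    """Serialize one cell: reals at 6 significant digits, ints exactly."""
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return "NA"
        return f"{float(v):.6g}"
    return str(v)


def write_results_table(
    table: pd.DataFrame, path: str | Path, columns: Sequence[str] | None = None
) -> None:
    """Write a results DataFrame deterministically (same table -> same bytes)."""
    cols = list(columns) if columns is not None else list(table.columns)
    lines = ["\t".join(cols)]
    for _, row in table[cols].iterrows():
        lines.append("\t".join(format_number(row[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
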