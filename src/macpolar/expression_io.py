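"""Reading, writing and normalizing expression matrices and sample annotations.

The in-memory container is :class:`ExpressionMatrix`: a log2-scale gene-by-sample
table in which rows are probes *or* genes (several probe rows may map to one gene
symbol and are never collapsed — all probe instances feed downstream score
calculations) and missing entries are ``NaN``, never 0.  Two on-disk dialects are
supported: plain TSV (first column row id, header row of sample ids) and the GEO
series-matrix text format (only the fenced table plus ``!Sample_`` metadata lines
are consumed).

RNA-seq counts are normalized as log2(CPM + 1) (or log2(RPKM + 1) when gene
lengths are given); Affymetrix/RMA data are assumed normalized upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("macpolar")

SCALE_TAGS = ("log2cpm", "log2rpkm", "rma", "unknown")

#: condition labels treated as the baseline (negative) class
NEGATIVE_CONDITIONS = frozenset({"pre", "sedentary", "untrained", "control", "baseline"})
#: condition labels treated as the exercised (positive) class
POSITIVE_CONDITIONS = frozenset({"post", "trained", "exercised", "exercise"})


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, rows × samples.

    Parameters
    ----------
    values
        DataFrame indexed by row id (probe or gene), columns are sample ids.
        ``NaN`` marks a missing measurement.
    gene_of_row
        Gene symbol per row; may repeat across rows (multi-probe genes).
        Defaults to the row ids themselves.
    scale_tag
        One of ``log2cpm``, ``log2rpkm``, ``rma``, ``unknown``.
    metadata
        Free-form annotation source (e.g. ``!Sample_`` lines of a GEO
        series-matrix file).
    """

    values: pd.DataFrame
    gene_of_row: pd.Series | None = None
    scale_tag: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gene_of_row is None:
            self.gene_of_row = pd.Series(self.values.index, index=self.values.index)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate row id(s): {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample id(s): {dups}")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite where present")
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"scale_tag must be one of {SCALE_TAGS}, got {self.scale_tag!r}")
        if self.scale_tag in ("log2cpm", "log2rpkm") and np.nanmin(arr, initial=0.0) < 0:
            raise ValueError(f"{self.scale_tag} values must be >= 0")
        if not self.gene_of_row.index.equals(self.values.index):
            raise ValueError("gene_of_row index must equal the matrix row index")

    # -- accessors ----------------------------------------------------------
    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def rows_for_gene(self, gene: str) -> pd.Index:
        """All probe rows mapping to *gene* (possibly empty)."""
        return self.values.index[self.gene_of_row.to_numpy() == gene]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.gene_of_row.copy(),
                                self.scale_tag, dict(self.metadata))

    def drop_rows(self, row_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(row_ids)
        return ExpressionMatrix(self.values.drop(index=ids),
                                self.gene_of_row.drop(index=ids),
                                self.scale_tag, dict(self.metadata))


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------


def _table_from_rows(header: list[str], rows: list[tuple[int, list[str]]],
                     path: str) -> pd.DataFrame:
    sample_ids = header[1:]
    if len(sample_ids) == 0:
        raise ParseError(f"{path}: malformed header (no sample columns) at line 1")
    seen: dict[str, int] = {}
    for s in sample_ids:
        seen[s] = seen.get(s, 0) + 1
    dup = [s for s, c in seen.items() if c > 1]
    if dup:
        raise ParseError(f"{path}: repeated sample column(s) {dup} in header line")
    index, data = [], []
    row_seen: set[str] = set()
    for lineno, parts in rows:
        if len(parts) != len(header):
            raise ParseError(
                f"{path}: line {lineno} has {len(parts)} fields, expected {len(header)}")
        if parts[0] in row_seen:
            raise ParseError(f"{path}: duplicate row id {parts[0]!r} at line {lineno}")
        row_seen.add(parts[0])
        index.append(parts[0])
        data.append(parts[1:])
    frame = pd.DataFrame(data, index=index, columns=sample_ids)
    # unparseable cells (including empty strings) become missing
    return frame.apply(pd.to_numeric, errors="coerce")


def read_matrix(path: str | Path, format: str = "tsv",
                scale_tag: str = "unknown") -> ExpressionMatrix:
    """Read an expression matrix from *path* in the named dialect.

    ``format="tsv"``: first column row id, header row of sample ids.
    ``format="series_matrix"``: GEO series-matrix text; only the table between
    ``!series_matrix_table_begin``/``_end`` fences is parsed, and ``!Sample_``
    metadata lines are retained in :attr:`ExpressionMatrix.metadata`.
    """
    path = Path(path)
    if format == "tsv":
        header: list[str] | None = None
        rows: list[tuple[int, list[str]]] = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if header is None:
                    header = parts
                else:
                    rows.append((lineno, parts))
        if header is None:
            raise ParseError(f"{path}: empty file")
        return ExpressionMatrix(_table_from_rows(header, rows, str(path)),
                                scale_tag=scale_tag)
    if format == "series_matrix":
        return _read_series_matrix(path, scale_tag)
    raise ValueError(f"unknown format {format!r}")


def _strip_quotes(token: str) -> str:
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        return token[1:-1]
    return token


def _read_series_matrix(path: Path, scale_tag: str) -> ExpressionMatrix:
    metadata: dict[str, list[list[str]]] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    in_table = False
    saw_fence = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped:
                continue
            if stripped.startswith("!series_matrix_table_begin"):
                in_table, saw_fence = True, True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                parts = [_strip_quotes(p) for p in stripped.split("\t")]
                if header is None:
                    header = parts
                else:
                    rows.append((lineno, parts))
            elif stripped.startswith("!Sample_"):
                key = stripped.split("\t", 1)[0].lstrip("!")
                vals = [_strip_quotes(p) for p in stripped.split("\t")[1:]]
                metadata.setdefault(key, []).append(vals)
            # all other metadata lines are ignored (minimal faithful GEO support)
    if not saw_fence or header is None:
        raise ParseError(f"{path}: no series_matrix table fences found")
    matrix = ExpressionMatrix(_table_from_rows(header, rows, str(path)),
                              scale_tag=scale_tag)
    matrix.metadata.update(metadata)
    return matrix


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV; missing entries become empty cells."""
    matrix.values.to_csv(path, sep="\t", na_rep="", index_label="id")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_counts(counts: pd.DataFrame, method: str = "cpm",
                     gene_lengths: pd.Series | None = None) -> ExpressionMatrix:
    """log2(CPM + 1) / log2(RPKM + 1) normalization of a nonnegative count matrix.

    Parameters
    ----------
    counts
        Raw counts, rows × samples.
    method
        ``"cpm"`` or ``"rpkm"``.
    gene_lengths
        Gene length in kilobases per row; required for RPKM.
    """
    arr = counts.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("counts must be nonnegative")
    libsize = np.nansum(arr, axis=0)
    if (libsize <= 0).any():
        bad = counts.columns[libsize <= 0].tolist()
        raise ValueError(f"zero library size for sample(s) {bad}")
    per_million = arr / libsize[None, :] * 1e6
    if method == "cpm":
        values = np.log2(per_million + 1.0)
        tag = "log2cpm"
    elif method == "rpkm":
        if gene_lengths is None:
            raise ValueError("rpkm normalization requires gene_lengths (kb per row)")
        lengths = gene_lengths.reindex(counts.index).to_numpy(dtype=float)
        if np.isnan(lengths).any() or (lengths <= 0).any():
            raise ValueError("gene_lengths must cover all rows with positive kb values")
        values = np.log2(per_million / lengths[:, None] + 1.0)
        tag = "log2rpkm"
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return ExpressionMatrix(
        pd.DataFrame(values, index=counts.index, columns=counts.columns),
        scale_tag=tag)


def looks_log_scaled(matrix: ExpressionMatrix, max_log: float = 30.0) -> bool:
    """Heuristic: log2 expression rarely exceeds ~30; raw intensities/counts do.

    Overridable — pass a different *max_log* or skip :func:`ensure_log2`
    entirely when the scale is known.
    """
    arr = matrix.values.to_numpy(dtype=float)
    if np.all(np.isnan(arr)):
        return True
    return float(np.nanmax(arr)) <= max_log


def ensure_log2(matrix: ExpressionMatrix, max_log: float = 30.0,
                force: bool | None = None) -> ExpressionMatrix:
    """Apply log2(x + 1) when the matrix does not look log-scaled.

    ``force=True`` transforms unconditionally; ``force=False`` never does.
    """
    do = force if force is not None else not looks_log_scaled(matrix, max_log)
    if not do:
        return matrix
    arr = matrix.values.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("cannot log2-transform a matrix with negative values")
    values = pd.DataFrame(np.log2(arr + 1.0), index=matrix.row_ids,
                          columns=matrix.sample_ids)
    log.info("applied log2(x+1) transform (max value %.1f exceeded %.1f)",
             np.nanmax(arr), max_log)
    return ExpressionMatrix(values, matrix.gene_of_row.copy(), "unknown",
                            dict(matrix.metadata))


# ---------------------------------------------------------------------------
# Probe → gene mapping
# ---------------------------------------------------------------------------


def attach_gene_map(matrix: ExpressionMatrix,
                    probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Fill gene symbols from a probe → gene mapping.

    Unmapped rows keep their row id as the gene symbol.  Rows are *not*
    collapsed: every probe instance is retained for downstream score
    calculations.  Mapping keys that match no row are ignored with a warning.
    """
    unknown = [p for p in probe_to_gene if p not in matrix.values.index]
    if unknown:
        log.warning("attach_gene_map: %d mapping key(s) match no row (e.g. %r)",
                    len(unknown), unknown[0])
    gene_of_row = pd.Series(
        [probe_to_gene.get(rid, gene) for rid, gene in
         zip(matrix.row_ids, matrix.gene_of_row)],
        index=matrix.row_ids)
    return ExpressionMatrix(matrix.values.copy(), gene_of_row,
                            matrix.scale_tag, dict(matrix.metadata))


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------


@dataclass
class SampleAnnotation:
    """Per-sample condition labels and optional subgroup fields.

    ``table`` is indexed by sample id and must contain a ``condition`` column
    with exactly two levels per dataset (pre/post or sedentary/trained).  A
    ``timepoint_class`` column (immediate / long_term) and arbitrary subgroup
    columns (gender, age_group, intensity, tissue, species, exercise_type)
    may follow.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "condition" not in self.table.columns:
            raise ValueError("annotation table requires a 'condition' column")
        if self.table.index.duplicated().any():
            raise ParseError("duplicate sample id(s) in annotation")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def validate_with_matrix(self, matrix: ExpressionMatrix) -> None:
        missing = self.table.index.difference(matrix.sample_ids)
        if len(missing):
            raise ValueError(f"annotated sample(s) absent from matrix: {list(missing)}")
        levels = self.condition_levels()
        if len(levels) != 2:
            raise ValueError(f"condition must have exactly two levels, got {levels}")

    def condition_levels(self) -> list[str]:
        return sorted(self.table["condition"].dropna().unique().tolist())

    def condition_split(self, positive_label: str | None = None
                        ) -> tuple[list[str], list[str], str, str]:
        """Split sample ids into (negative, positive) condition groups.

        The positive class is post/trained; override with *positive_label*
        for other two-level designs.
        """
        levels = self.condition_levels()
        if len(levels) != 2:
            raise ValueError(f"condition must have exactly two levels, got {levels}")
        if positive_label is not None:
            if positive_label not in levels:
                raise ValueError(f"positive label {positive_label!r} not in {levels}")
            pos = positive_label
        else:
            pos_hits = [lv for lv in levels if lv.lower() in POSITIVE_CONDITIONS]
            neg_hits = [lv for lv in levels if lv.lower() in NEGATIVE_CONDITIONS]
            if len(pos_hits) == 1:
                pos = pos_hits[0]
            elif len(neg_hits) == 1:
                pos = next(lv for lv in levels if lv != neg_hits[0])
            else:
                raise ValueError(
                    f"cannot infer positive class from levels {levels}; "
                    "pass positive_label explicitly")
        neg = next(lv for lv in levels if lv != pos)
        cond = self.table["condition"]
        return (cond.index[cond == neg].tolist(),
                cond.index[cond == pos].tolist(), neg, pos)

    def subset(self, sample_ids: Iterable[str]) -> "SampleAnnotation":
        return SampleAnnotation(self.table.loc[list(sample_ids)].copy())


def read_annotation(path: str | Path) -> SampleAnnotation:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleAnnotation(table)


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="sample_id")
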