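"""Readers and writers for the external formats the pipeline touches.

All readers validate strictly: malformed input raises :class:`FormatError`
naming the offending line/cell rather than being silently coerced.  BED
coordinates are 0-based half-open throughout; 1-based coordinates appear
only in log messages, labelled as such.

Supported formats
-----------------
- expression matrix: TSV (genes x cell lines) or GCT
- response table: CSV/TSV of per-cell-line log10 IC50 (log10 molar)
- BED6 promoter/interval files
- JASPAR-style PFM count matrices (bare 4-row and letter-prefixed dialects)
- GMT gene-set collections
- FASTA (via Biopython SeqIO)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("comparekit")

#: token that marks a missing expression value (configurable per call)
DEFAULT_MISSING_TOKEN = "NA"

NUCLEOTIDES = ("A", "C", "G", "T")


class FormatError(ValueError):
    """A file violated its format contract; the message names the location."""


class ValidationError(ValueError):
    """An in-memory object violated a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """log2-scale expression values, genes x cell lines.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``cellline_ids[j]``; missing values are NaN.  Every column must carry at
    least 3 non-missing values so that downstream pairwise-complete
    correlations are defined.
    """

    gene_ids: list[str]
    cellline_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in ExpressionMatrix")
        if len(set(self.cellline_ids)) != len(self.cellline_ids):
            raise ValidationError("duplicate cell-line ids in ExpressionMatrix")
        if self.values.shape != (len(self.gene_ids), len(self.cellline_ids)):
            raise ValidationError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cellline_ids)} lines"
            )
        n_ok = np.sum(~np.isnan(self.values), axis=0)
        bad = [self.cellline_ids[j] for j in np.nonzero(n_ok < 3)[0]]
        if bad:
            raise ValidationError(
                f"columns with fewer than 3 non-missing values: {bad}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.cellline_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            cellline_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class ResponseVector:
    """Per-cell-line log10 IC50 (log10 molar) — the COMPARE target profile."""

    cellline_ids: list[str]
    log10_ic50: np.ndarray

    def __post_init__(self) -> None:
        self.log10_ic50 = np.asarray(self.log10_ic50, dtype=float)
        if len(set(self.cellline_ids)) != len(self.cellline_ids):
            raise ValidationError("duplicate cell-line ids in ResponseVector")
        if self.log10_ic50.shape != (len(self.cellline_ids),):
            raise ValidationError("response length does not match id list")
        if not np.all(np.isfinite(self.log10_ic50)):
            raise ValidationError("non-finite log10 IC50 values")

    def __len__(self) -> int:
        return len(self.cellline_ids)

    def to_series(self) -> pd.Series:
        return pd.Series(self.log10_ic50, index=self.cellline_ids)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} for {self.name}")
        if self.start >= self.end:
            raise ValidationError(
                f"start {self.start} >= end {self.end} for {self.name}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PWM:
    """Position probability matrix in A,C,G,T row order.

    ``matrix[b, i]`` is the probability of base ``NUCLEOTIDES[b]`` at motif
    position ``i``; every column sums to 1.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValidationError(
                f"{self.motif_id}: matrix must be 4 x L, got {self.matrix.shape}"
            )
        if self.matrix.shape[1] < 2:
            raise ValidationError(f"{self.motif_id}: motif shorter than 2 columns")
        if self.pseudocount <= 0:
            raise ValidationError(f"{self.motif_id}: pseudocount must be positive")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValidationError(
                f"{self.motif_id}: column probabilities do not sum to 1"
            )
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValidationError(f"{self.motif_id}: background does not sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(NUCLEOTIDES[b] for b in np.argmax(self.matrix, axis=0))

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: np.ndarray | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (
            counts.sum(axis=0) + 4.0 * pseudocount
        )
        kwargs = {} if background is None else {"background": background}
        return cls(motif_id=motif_id, matrix=probs, pseudocount=pseudocount, **kwargs)


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, member ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv",
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> ExpressionMatrix:
    """Read a genes x cell-lines expression table.

    ``dialect='tsv'``: header row of cell-line ids, first column gene ids.
    ``dialect='gct'``: the GCT envelope (version line, dimension line, then a
    TSV with Name/Description columns).

    Duplicate gene-id rows are collapsed by their mean with a logged warning.
    Any cell that is neither numeric nor the missing token raises
    :class:`FormatError` naming the gene row and cell-line column.
    """
    path = Path(path)
    if dialect not in ("tsv", "gct"):
        raise ValueError(f"unknown dialect {dialect!r}")
    skiprows = 2 if dialect == "gct" else 0
    try:
        raw = pd.read_csv(
            path, sep="\t", dtype=str, skiprows=skiprows,
            keep_default_na=False, header=0,
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty expression file") from None
    if raw.empty or raw.shape[1] < 2:
        raise FormatError(f"{path}: empty or column-less expression file")
    if dialect == "gct":
        raw = raw.drop(columns=[raw.columns[1]])  # Description column
    gene_col = raw.columns[0]
    gene_ids = raw[gene_col].astype(str)
    cellline_ids = [str(c) for c in raw.columns[1:]]

    cells = raw.iloc[:, 1:].to_numpy(dtype=str)
    values = np.empty(cells.shape, dtype=float)
    for i in range(cells.shape[0]):
        for j in range(cells.shape[1]):
            token = cells[i, j].strip()
            if token == missing_token or token == "":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(token)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {token!r} at "
                    f"row {gene_ids.iloc[i]}, column {cellline_ids[j]}"
                ) from None

    frame = pd.DataFrame(values, index=gene_ids.to_numpy(), columns=cellline_ids)
    if gene_ids.duplicated().any():
        dupes = sorted(gene_ids[gene_ids.duplicated()].unique())
        log.warning(
            "collapsing %d duplicated gene id(s) by mean: %s",
            len(dupes), ", ".join(dupes),
        )
        frame = frame.groupby(level=0, sort=False).mean()
    return ExpressionMatrix.from_frame(frame)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> Path:
    path = Path(path)
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", na_rep=missing_token)
    return path


# ---------------------------------------------------------------------------
# Response table I/O
# ---------------------------------------------------------------------------

def read_response(path: str | Path, sep: str = ",") -> ResponseVector:
    """Read a two-column (cell line, log10 IC50) table; extra columns ignored."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty response file") from None
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: response table needs >= 2 columns")
    ids = [str(x) for x in frame.iloc[:, 0]]
    vals = pd.to_numeric(frame.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        bad = [ids[i] for i in np.nonzero(vals.isna().to_numpy())[0]]
        raise FormatError(f"{path}: non-numeric log10 IC50 for {bad}")
    return ResponseVector(cellline_ids=ids, log10_ic50=vals.to_numpy())


def write_response(resp: ResponseVector, path: str | Path, sep: str = ",") -> Path:
    path = Path(path)
    pd.DataFrame(
        {"cellline": resp.cellline_ids, "log10_ic50": resp.log10_ic50}
    ).to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (>=3 columns); coordinates stay 0-based half-open."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "+"
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, strand=strand)
                )
            except ValidationError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )
    return path


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

def parse_jaspar(
    path: str | Path,
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
) -> list[PWM]:
    """Parse JASPAR-style count matrices into probability PWMs.

    Accepts both the bare dialect (">id" then four rows of counts in A,C,G,T
    order) and the letter-prefixed dialect ("A [ 10 0 ]").  Counts plus the
    pseudocount are normalised per column.
    """
    path = Path(path)
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: list[tuple[str | None, list[float], int]] = []

    def finish() -> None:
        nonlocal rows, motif_id
        if motif_id is None:
            return
        if len(rows) != 4:
            raise FormatError(
                f"{path}: motif {motif_id}: expected 4 nucleotide rows, "
                f"got {len(rows)}"
            )
        letters = [r[0] for r in rows]
        if all(l is not None for l in letters):
            if sorted(letters) != sorted(NUCLEOTIDES):
                missing = set(NUCLEOTIDES) - set(letters)  # type: ignore[arg-type]
                raise FormatError(
                    f"{path}: motif {motif_id}: missing nucleotide row(s) "
                    f"{sorted(missing)}"
                )
            order = {l: r for l, r, _ in rows}
            counts_rows = [order[n] for n in NUCLEOTIDES]
        else:
            counts_rows = [r[1] for r in rows]
        lengths = {len(r) for r in counts_rows}
        if len(lengths) != 1:
            raise FormatError(
                f"{path}: motif {motif_id}: unequal row lengths {sorted(lengths)}"
            )
        counts = np.array(counts_rows, dtype=float)
        if np.any(counts < 0):
            raise FormatError(f"{path}: motif {motif_id}: negative counts")
        pwms.append(
            PWM.from_counts(motif_id, counts, pseudocount=pseudocount,
                            background=background)
        )
        rows, motif_id = [], None

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                finish()
                motif_id = line[1:].split()[0] if line[1:].split() else line[1:]
                continue
            if motif_id is None:
                raise FormatError(
                    f"{path}: line {lineno}: counts before any '>' header"
                )
            letter: str | None = None
            body = line
            first = line.split(None, 1)[0]
            if first.upper() in NUCLEOTIDES:
                letter = first.upper()
                body = line.split(None, 1)[1] if len(line.split(None, 1)) > 1 else ""
            body = body.replace("[", " ").replace("]", " ")
            try:
                values = [float(tok) for tok in body.split()]
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric count"
                ) from None
            rows.append((letter, values, lineno))
    finish()
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then member gene ids, tab-separated."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 fields "
                    f"(name, description, members...), got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} empty")
            if name in sets:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate set name {name!r}"
                )
            sets[name] = (description, members)
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        for name, (description, members) in collection.sets.items():
            handle.write("\t".join([name, description, *sorted(members)]) + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase-sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Mapping[str, str] | Sequence[tuple[str, str]],
                path: str | Path) -> Path:
    path = Path(path)
    items = records.items() if isinstance(records, Mapping) else records
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    SeqIO.write(seq_records, str(path), "fasta")
    return path
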