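"""Readers and writers for the standard formats the pipeline touches.

Expression matrices (GCT / TSV), gene-set collections (GMT), genomic
intervals (BED), position frequency matrices (JASPAR text), sequences
(FASTA) and qPCR Ct tables (TSV) all pass through this module.  All
genomic coordinates are 0-based half-open (BED convention) everywhere
inside the package; 1-based positions appear only at the CLI boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("atranet")

UNDIFF = "undifferentiated"
DIFF = "differentiated"

BASES = ("A", "C", "G", "T")


class FormatError(ValueError):
    """A file violates its declared format contract."""


class ConfigurationError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probe x sample log2-intensity matrix for one cell line.

    ``data`` is indexed by probe id with sample ids as columns;
    ``condition`` maps every sample id to ``undifferentiated`` or
    ``differentiated``.
    """

    data: pd.DataFrame
    condition: pd.Series
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise FormatError("duplicate probe or sample identifiers")
        self.condition = pd.Series(self.condition)
        missing = set(self.data.columns) - set(self.condition.index)
        if missing:
            raise ConfigurationError(
                f"samples without a condition label: {sorted(missing)}"
            )
        self.condition = self.condition.loc[self.data.columns]
        bad = set(self.condition.unique()) - {UNDIFF, DIFF}
        if bad:
            raise ConfigurationError(f"unknown condition labels: {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def samples_in(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative start in {self}")
        if self.end <= self.start:
            raise FormatError(f"empty or inverted interval {self}")
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneSetCollection:
    """Term id -> (term name, member gene symbols)."""

    sets: dict[str, tuple[str, list[str]]]

    def members(self, term: str) -> list[str]:
        return self.sets[term][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass
class PWM:
    """Position frequency matrix, rows A, C, G, T."""

    counts: np.ndarray
    matrix_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise FormatError("PWM counts must be a 4 x L matrix")
        if self.counts.shape[1] < 1:
            raise FormatError("PWM must have at least one column")
        if (self.counts < 0).any():
            raise FormatError("PWM counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise FormatError("every PWM column needs a positive total")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass
class CtTable:
    """Long-format qPCR table: sample_group, gene, replicate, ct."""

    rows: pd.DataFrame

    REQUIRED = ("sample_group", "gene", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise FormatError(f"Ct table lacks columns {sorted(missing)}")
        ct = self.rows["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all():
            raise FormatError("non-finite Ct value")

    def groups(self) -> list[str]:
        return sorted(self.rows["sample_group"].unique())

    def genes(self) -> list[str]:
        return sorted(self.rows["gene"].unique())


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    condition_map: Mapping[str, str] | None = None,
    cell_line: str = "",
) -> ExpressionMatrix:
    """Read a probe x sample log2-intensity matrix.

    ``format`` is ``"gct"`` (versioned two-line header, declared
    dimensions honoured) or ``"tsv"`` (probe ids in the first column).
    ``condition_map`` must label every sample id.
    """
    path = Path(path)
    if format == "gct":
        data = _read_gct(path)
    elif format == "tsv":
        data = pd.read_csv(path, sep="\t", index_col=0)
        data.index = data.index.astype(str)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if condition_map is None:
        raise ConfigurationError("condition_map is required")
    missing = set(data.columns) - set(condition_map)
    if missing:
        raise ConfigurationError(f"condition_map misses samples {sorted(missing)}")
    cond = pd.Series({s: condition_map[s] for s in data.columns})
    return ExpressionMatrix(data=data.astype(float), condition=cond, cell_line=cell_line)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"unsupported GCT version line {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError("GCT dimension line must hold rows and columns")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    if body.shape[0] != n_rows or body.shape[1] - 2 != n_cols:
        raise FormatError(
            f"GCT declares {n_rows} x {n_cols} but holds "
            f"{body.shape[0]} x {body.shape[1] - 2}"
        )
    body = body.set_index(body.columns[0])
    body.index = body.index.astype(str)
    return body.drop(columns=[body.columns[0]])


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        matrix.data.to_csv(path, sep="\t", index_label="probe")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.data.shape[0]}\t{matrix.data.shape[1]}\n")
            out = matrix.data.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def write_condition_map(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.condition.rename("condition").to_csv(path, sep="\t", index_label="sample")


def read_condition_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].to_dict()


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term, description, tab-separated members."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            term, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(
                    f"duplicate members in term {term!r} deduplicated",
                    stacklevel=2,
                )
            if not deduped:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no members")
            sets[term] = (desc, deduped)
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (>=3 columns); output sorted by (chrom, start)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=name,
                    strand=strand,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# JASPAR PFMs
# ---------------------------------------------------------------------------


def read_jaspar_pfm(path: str | Path) -> list[PWM]:
    """Read one or more JASPAR-format PFMs; rows normalised to A,C,G,T."""
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            pwms = []
            for m in records:
                counts = np.array([m.counts[b] for b in BASES], dtype=float)
                pwms.append(PWM(counts=counts, matrix_id=m.matrix_id or m.name or ""))
        # biopython raises on ragged rows; surface it as a format error
        except Exception as exc:  # noqa: BLE001 - normalise parser errors
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"bad JASPAR file {path}: {exc}") from exc
    if not pwms:
        raise FormatError(f"no matrices found in {path}")
    for p in pwms:
        if len({len(row) for row in p.counts}) != 1:
            raise FormatError("PWM rows of unequal length")
    return pwms


def write_jaspar_pfm(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.matrix_id} {p.matrix_id}\n")
            for base, row in zip(BASES, p.counts):
                row_s = " ".join(f"{v:.0f}" if v == int(v) else f"{v}" for v in row)
                fh.write(f"{base} [ {row_s} ]\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name -> sequence mapping (upper-case)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


def read_ct_table(path: str | Path) -> CtTable:
    df = pd.read_csv(path, sep="\t")
    return CtTable(rows=df)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
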