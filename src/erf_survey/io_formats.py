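"""Readers, writers and coordinate utilities.

All public coordinates are 1-based inclusive, matching GFF3.  The module
wraps Biopython/gffutils for the standard formats and adds the strict
validation the downstream survey stages rely on (non-empty sequences,
restricted alphabets, exon intervals inside gene spans).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import SimpleFastaParser

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"protein record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise FormatError(
                f"protein record {self.id!r} contains non-amino-acid codes {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CdsRecord:
    id: str
    sequence: str
    frame_checked: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"CDS record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - NT_ALPHABET
        if bad:
            raise FormatError(
                f"CDS record {self.id!r} contains non-nucleotide codes {sorted(bad)}"
            )
        if self.frame_checked and len(self.sequence) % 3 != 0:
            raise FormatError(
                f"CDS record {self.id!r} length {len(self.sequence)} is not a multiple of 3"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene with its exon structure, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        self.exon_intervals = sorted((int(a), int(b)) for a, b in self.exon_intervals)
        prev_end = None
        for a, b in self.exon_intervals:
            if a > b:
                raise ValueError(f"gene {self.gene_id}: exon interval ({a},{b}) inverted")
            if a < self.start or b > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon ({a},{b}) outside gene span "
                    f"({self.start},{self.end})"
                )
            if prev_end is not None and a <= prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exon intervals")
            prev_end = b


@dataclass
class DomainTableRow:
    """One per-domain hit from a profile-HMM search table."""

    protein_id: str
    domain_name: str
    evalue: float
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}: negative E-value {self.evalue}")
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"{self.protein_id}: bad envelope ({self.env_start},{self.env_end})"
            )


# ---------------------------------------------------------------------------
# FASTA

def _iter_fasta(path: str | Path):
    path = Path(path)
    with open(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
        if not first.startswith(">"):
            raise FormatError(
                f"{path}: not FASTA — first non-blank line does not start with '>'"
            )
    with open(path) as handle:
        for n, (header, seq) in enumerate(SimpleFastaParser(handle), 1):
            if not header.strip():
                raise FormatError(f"{path}: record {n} has an empty header")
            if not seq:
                raise FormatError(
                    f"{path}: record {n} ({header.split()[0]!r}) has an empty sequence"
                )
            yield header, seq.upper()


def read_fasta(path: str | Path, kind: str = "protein") -> list:
    """Read a FASTA file into Protein- or CdsRecords (order preserved).

    ``kind`` is ``"protein"``, ``"cds"`` or ``"nucleotide"`` (genome contigs:
    returned as CdsRecords without frame checking).
    """
    records = []
    seen = set()
    for header, seq in _iter_fasta(path):
        parts = header.split(None, 1)
        rid, desc = parts[0], parts[1] if len(parts) > 1 else ""
        if rid in seen:
            raise FormatError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        if kind == "protein":
            records.append(ProteinRecord(rid, seq, desc))
        elif kind in ("cds", "nucleotide"):
            records.append(CdsRecord(rid, seq, frame_checked=False, description=desc))
        else:
            raise ValueError(f"unknown kind {kind!r}")
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            desc = f" {rec.description}" if getattr(rec, "description", "") else ""
            out.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def read_genome(path: str | Path) -> dict[str, str]:
    """Genome FASTA as a chromosome → sequence mapping."""
    return {rec.id: rec.sequence for rec in read_fasta(path, kind="nucleotide")}


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Assemble GeneModels from a GFF3 file.

    Exon intervals come from ``exon`` children; when a gene has none,
    ``CDS`` children are used instead (documented fallback for CDS-only
    annotations).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
        if not exons:
            exons = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exon_intervals=exons,
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path, source: str = "erf_survey") -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for m in models:
            out.write(
                f"{m.chromosome}\t{source}\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            for k, (a, b) in enumerate(m.exon_intervals, 1):
                out.write(
                    f"{m.chromosome}\t{source}\texon\t{a}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{k};Parent={m.gene_id}\n"
                )


def count_exons(model: GeneModel) -> int:
    if not model.exon_intervals:
        raise ValueError(f"gene {model.gene_id}: annotation has no exon intervals")
    return len(model.exon_intervals)


# ---------------------------------------------------------------------------
# Promoters

def extract_promoter(
    genome: Mapping[str, str], model: GeneModel, length: int = 2000
) -> str:
    """Upstream genomic sequence of a gene, in promoter orientation.

    Plus strand: bases ``[start-length, start-1]``.  Minus strand: reverse
    complement of ``[end+1, end+length]``.  Truncated with a warning at
    contig boundaries; a gene with no upstream bases yields an empty string.
    """
    if length <= 0:
        raise ValueError("promoter length must be positive")
    if model.chromosome not in genome:
        raise KeyError(f"chromosome {model.chromosome!r} absent from genome")
    chrom = genome[model.chromosome]
    if model.strand == "+":
        lo = max(1, model.start - length)
        hi = model.start - 1
        seq = chrom[lo - 1 : hi] if hi >= lo else ""
    else:
        lo = model.end + 1
        hi = min(len(chrom), model.end + length)
        seq = str(Seq(chrom[lo - 1 : hi]).reverse_complement()) if hi >= lo else ""
    if len(seq) < length:
        warnings.warn(
            f"gene {model.gene_id}: promoter truncated to {len(seq)} bp at contig edge",
            stacklevel=2,
        )
    return seq


# ---------------------------------------------------------------------------
# Domain tables

#: default column order of the whitespace-delimited per-domain table
DOMTBL_COLUMNS = ("protein_id", "domain_name", "evalue", "env_start", "env_end")


def read_domain_table(
    path: str | Path,
    evalue_max: float = 1e-5,
    columns: Sequence[str] = DOMTBL_COLUMNS,
) -> list[DomainTableRow]:
    """Read a per-domain hit table, keeping rows with E-value strictly below
    ``evalue_max``.

    ``columns`` maps file columns onto the five consumed fields, tolerating
    dialect variation; lines starting with ``#`` are comments.
    """
    idx = {name: columns.index(name) for name in DOMTBL_COLUMNS}
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < len(columns):
                raise FormatError(f"{path}:{lineno}: expected {len(columns)} columns")
            try:
                evalue = float(fields[idx["evalue"]])
                start = int(fields[idx["env_start"]])
                end = int(fields[idx["env_end"]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if evalue >= evalue_max:
                continue
            rows.append(
                DomainTableRow(
                    protein_id=fields[idx["protein_id"]],
                    domain_name=fields[idx["domain_name"]],
                    evalue=evalue,
                    env_start=start,
                    env_end=end,
                )
            )
    return rows


def write_domain_table(rows: Iterable[DomainTableRow], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("#protein_id\tdomain_name\tevalue\tenv_start\tenv_end\n")
        for r in rows:
            out.write(
                f"{r.protein_id}\t{r.domain_name}\t{r.evalue:.3g}\t{r.env_start}\t{r.env_end}\n"
            )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
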