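"""Sequence and annotation I/O: validated RNA/DNA records, FASTA reading and
writing, BED6/GFF3 gene annotations, and strand-aware extraction of 5'-flanking
promoter regions (600 bp upstream of the TSS by default).

Coordinates are 0-based half-open throughout. BED input is native; GFF3 start
coordinates are converted by subtracting 1. The TSS is the first transcribed
base and is excluded from the upstream window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mirfunc")

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGTN")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside its alphabet."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated single-stranded RNA (e.g. a 20-22 nt mature microRNA).

    The sequence is normalized on construction: upper-cased with T folded to U.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        norm = self.seq.upper().replace("T", "U")
        object.__setattr__(self, "seq", norm)
        if len(norm) < 1:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        for off, ch in enumerate(norm):
            if ch not in RNA_ALPHABET:
                raise SequenceValidationError(
                    f"record {self.id!r}: illegal RNA character {ch!r} at offset {off}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DnaSequence:
    """A validated DNA sequence; N is tolerated but flagged via ``has_n``."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        norm = self.seq.upper()
        object.__setattr__(self, "seq", norm)
        if len(norm) < 1:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        for off, ch in enumerate(norm):
            if ch not in DNA_ALPHABET:
                raise SequenceValidationError(
                    f"record {self.id!r}: illegal DNA character {ch!r} at offset {off}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def has_n(self) -> bool:
        return "N" in self.seq


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene-level anchor for promoter extraction.

    ``tss`` is the 0-based position of the first transcribed base on ``strand``.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


def read_fasta(path: str | Path, alphabet: Literal["DNA", "RNA"]) -> list:
    """Read a FASTA file into validated records, order preserved.

    Sequences are upper-cased; T is folded to U when ``alphabet`` is RNA.
    Raises on an empty file or on illegal characters (naming the record).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no records")
    cls = RnaSequence if alphabet == "RNA" else DnaSequence
    return [cls(id=r.id, seq=str(r.seq)) for r in records]


def write_fasta(records: Iterable[RnaSequence | DnaSequence], path: str | Path) -> None:
    """Write records to FASTA (byte-exact round trip with :func:`read_fasta`)."""
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def reverse_complement(seq: DnaSequence) -> DnaSequence:
    """Reverse complement of a DNA sequence (an involution)."""
    return DnaSequence(id=seq.id, seq=seq.seq.translate(_DNA_COMPLEMENT)[::-1])


def extract_promoter(
    genome: Mapping[str, DnaSequence],
    ann: GeneAnnotation,
    upstream_bp: int = 600,
) -> DnaSequence:
    """Extract the 5'-flanking sequence immediately upstream of a gene's TSS.

    Plus strand: ``genome[chrom][tss - upstream_bp, tss)`` reported 5'->3'.
    Minus strand: reverse complement of ``genome[chrom][tss + 1, tss + 1 + upstream_bp)``.
    A window truncated at a contig edge is returned shorter with a logged
    warning; a window that lies entirely off-contig is an error.
    """
    if upstream_bp < 1:
        raise ValueError(f"upstream_bp must be >= 1, got {upstream_bp}")
    if ann.chrom not in genome:
        raise KeyError(f"{ann.gene_id}: chromosome {ann.chrom!r} not in genome")
    contig = genome[ann.chrom]
    n = contig.length
    if not (0 <= ann.tss < n):
        raise ValueError(
            f"{ann.gene_id}: tss {ann.tss} outside contig {ann.chrom} (length {n})"
        )
    pid = f"{ann.gene_id}_promoter"
    if ann.strand == "+":
        start = ann.tss - upstream_bp
        if start < 0:
            if ann.tss == 0:
                raise ValueError(f"{ann.gene_id}: upstream window fully off contig")
            logger.warning(
                "%s: promoter truncated at contig start (%d of %d bp)",
                ann.gene_id, ann.tss, upstream_bp,
            )
            start = 0
        return DnaSequence(id=pid, seq=contig.seq[start:ann.tss])
    # minus strand: upstream lies 3' of the tss on the plus strand
    start = ann.tss + 1
    end = start + upstream_bp
    if start >= n:
        raise ValueError(f"{ann.gene_id}: upstream window fully off contig")
    if end > n:
        logger.warning(
            "%s: promoter truncated at contig end (%d of %d bp)",
            ann.gene_id, n - start, upstream_bp,
        )
        end = n
    window = DnaSequence(id=pid, seq=contig.seq[start:end])
    return reverse_complement(window)


def read_annotations(path: str | Path, fmt: Literal["BED", "GFF3"] | None = None) -> list[GeneAnnotation]:
    """Read gene annotations from BED6 or GFF3.

    The TSS is derived from the feature span: the start base for '+' genes and
    the end base for '-' genes. Format is inferred from the suffix when ``fmt``
    is None (.bed -> BED, .gff/.gff3 -> GFF3).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "BED" if suffix == ".bed" else "GFF3"
    out: list[GeneAnnotation] = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if fmt == "BED":
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        else:
            chrom, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name") or f[8]
        tss = start if strand == "+" else end - 1
        out.append(GeneAnnotation(gene_id=name, chrom=chrom, tss=tss, strand=strand))
    return out


def write_promoter_manifest(
    rows: list[tuple[str, str, int, int, str, int]], path: str | Path
) -> None:
    """Write a TSV manifest (gene_id, chrom, start, end, strand, length)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tlength\n")
        for gene_id, chrom, start, end, strand, length in rows:
            fh.write(f"{gene_id}\t{chrom}\t{start}\t{end}\t{strand}\t{length}\n")
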