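"""Readers/writers for the external formats the pipeline touches.

Conventions used throughout the package:

* Coordinates are 0-based, half-open internally; files on disk follow BED.
* The ``start`` of a locus is the genomic coordinate of the mature 5'
  nucleotide, regardless of strand (for a minus-strand locus this is the
  BED interval's ``end - 1``).  This makes 5'-extension arithmetic
  strand-uniform.
* Genomes may contain N, but any locus overlapping an N is rejected with a
  warning: exact-match semantics are undefined over N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOME_ALPHABET = set("ACGTN")
GENOTYPES = ("wild_type", "prg1", "prde1", "other")
PROTOCOLS = ("untreated", "TAP", "capRNA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeSequence:
    """One chromosome: an identifier plus an uppercase nucleotide string."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("chromosome identifier must be non-empty")
        if not self.seq:
            raise FormatError(f"chromosome {self.name!r} has an empty sequence")
        self.seq = self.seq.upper()
        for i, ch in enumerate(self.seq):
            if ch not in GENOME_ALPHABET:
                raise FormatError(
                    f"chromosome {self.name!r}: illegal character {ch!r} "
                    f"at position {i}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PiRNALocus:
    """A mature 21U-RNA locus.

    ``start`` is the genomic position of the mature 5' nucleotide on the
    sense strand (strand-aware anchor, see module docstring).
    """

    locus_id: str
    chrom: str
    start: int
    strand: str
    mature_length: int = 21
    mature_seq: str = ""
    motif_score: float | None = None
    class_label: str = "unscored"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.locus_id}: strand must be + or -")
        if self.mature_length < 1:
            raise ValueError(f"locus {self.locus_id}: mature_length must be >= 1")

    @property
    def bed_interval(self) -> tuple[int, int]:
        """0-based half-open genomic interval of the mature sequence."""
        if self.strand == "+":
            return self.start, self.start + self.mature_length
        return self.start - self.mature_length + 1, self.start + 1


@dataclass
class Library:
    """A collapsed small-RNA sample: unique sequences with counts."""

    sample_id: str
    genotype: str
    protocol: str
    reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        for seq, count in self.reads.items():
            if count <= 0:
                raise ValueError(f"read {seq!r}: count must be positive")
            if not (15 <= len(seq) <= 100):
                raise ValueError(
                    f"read {seq!r}: length {len(seq)} outside [15, 100]"
                )

    @property
    def total_count(self) -> int:
        return sum(self.reads.values())

    @property
    def n_unique(self) -> int:
        return len(self.reads)


@dataclass
class GeneInterval:
    """A strand-annotated gene body (BED6 record)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: annotation must be stranded")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: bad interval")


@dataclass
class ExpressionMatrix:
    """log2 expression values, genes x samples, with sample metadata."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    samples: pd.DataFrame  # columns: sample_id, genotype, replicate

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("sample metadata does not match matrix columns")

    def genotype_columns(self, genotype: str) -> list[str]:
        mask = self.samples["genotype"] == genotype
        return list(self.samples.loc[mask, "sample_id"])

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.samples["genotype"]))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, GenomeSequence]:
    """Read a genome FASTA into an ordered map of chromosome -> sequence.

    Sequences are uppercased; N is allowed.  Duplicate headers and
    characters outside {A,C,G,T,N} raise :class:`FormatError`.
    """
    genome: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FormatError(f"duplicate FASTA header {record.id!r}")
        genome[record.id] = GenomeSequence(record.id, str(record.seq))
    if not genome:
        raise FormatError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: dict[str, GenomeSequence], path) -> None:
    records = [
        SeqRecord(Seq(g.seq), id=name, description="") for name, g in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Loci (BED6, optionally + score/class columns)
# ---------------------------------------------------------------------------

def locus_from_interval(
    locus_id: str,
    chrom: str,
    bed_start: int,
    bed_end: int,
    strand: str,
    genome: dict[str, GenomeSequence],
) -> PiRNALocus:
    """Build a locus from a BED interval, extracting its strand-aware sequence."""
    if chrom not in genome:
        raise FormatError(f"locus {locus_id}: unknown chromosome {chrom!r}")
    chrom_seq = genome[chrom].seq
    if not (0 <= bed_start < bed_end <= len(chrom_seq)):
        raise FormatError(
            f"locus {locus_id}: interval [{bed_start},{bed_end}) exceeds "
            f"chromosome {chrom} (length {len(chrom_seq)})"
        )
    length = bed_end - bed_start
    raw = chrom_seq[bed_start:bed_end]
    if "N" in raw:
        raise FormatError(f"locus {locus_id}: interval overlaps N bases")
    mature_seq = raw if strand == "+" else revcomp(raw)
    anchor = bed_start if strand == "+" else bed_end - 1
    if length != 21:
        warnings.warn(
            f"locus {locus_id}: non-canonical mature length {length}",
            stacklevel=2,
        )
    if mature_seq[0] != "T":
        warnings.warn(
            f"locus {locus_id}: mature sequence does not start with T (5'U)",
            stacklevel=2,
        )
    return PiRNALocus(
        locus_id=locus_id,
        chrom=chrom,
        start=anchor,
        strand=strand,
        mature_length=length,
        mature_seq=mature_seq,
    )


def read_loci(path, genome: dict[str, GenomeSequence]) -> list[PiRNALocus]:
    """Read piRNA loci from a BED6(+2) file against a loaded genome.

    Columns 7 and 8, if present, are interpreted as motif score and class
    label (as written by :func:`write_loci` after scoring).
    """
    loci: list[PiRNALocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{line_no}: expected >= 6 BED columns")
            chrom, s, e, name, _score, strand = fields[:6]
            if name in seen:
                raise FormatError(f"{path}:{line_no}: duplicate locus id {name!r}")
            seen.add(name)
            locus = locus_from_interval(name, chrom, int(s), int(e), strand, genome)
            if len(fields) >= 8:
                if fields[6] not in (".", ""):
                    locus.motif_score = float(fields[6])
                if fields[7]:
                    locus.class_label = fields[7]
            loci.append(locus)
    return loci


def write_loci(loci: list[PiRNALocus], path, scored: bool = False) -> None:
    """Write loci as BED6; with ``scored=True`` append score and class columns."""
    with open(path, "w") as fh:
        for loc in loci:
            s, e = loc.bed_interval
            row = [loc.chrom, str(s), str(e), loc.locus_id, "0", loc.strand]
            if scored:
                score = "." if loc.motif_score is None else f"{loc.motif_score:.4f}"
                row += [score, loc.class_label]
            fh.write("\t".join(row) + "\n")


def read_genes(path) -> list[GeneInterval]:
    """Read strand-annotated gene bodies from a BED6 file."""
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{line_no}: expected >= 6 BED columns")
            chrom, s, e, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{line_no}: gene {name!r} lacks a strand annotation"
                )
            genes.append(GeneInterval(name, chrom, int(s), int(e), strand))
    return genes


def write_genes(genes: list[GeneInterval], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Small-RNA libraries (TSV: sequence<TAB>count)
# ---------------------------------------------------------------------------

def read_library(path, sample_id: str, genotype: str, protocol: str) -> Library:
    """Read a collapsed library TSV; duplicate sequences are merged by summing."""
    reads: dict[str, int] = {}
    n_rows = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{line_no}: expected 2 columns")
            seq, count_str = fields
            try:
                count = int(count_str)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{line_no}: count {count_str!r} is not an integer"
                ) from exc
            if count <= 0:
                raise FormatError(f"{path}:{line_no}: count must be positive")
            reads[seq.upper()] = reads.get(seq.upper(), 0) + count
            n_rows += 1
    if n_rows == 0:
        raise FormatError(f"empty library: {path}")
    return Library(sample_id=sample_id, genotype=genotype, protocol=protocol,
                   reads=reads)


def write_library(library: Library, path) -> None:
    with open(path, "w") as fh:
        for seq in sorted(library.reads):
            fh.write(f"{seq}\t{library.reads[seq]}\n")


# ---------------------------------------------------------------------------
# Expression matrix (TSV with a two-line header: sample ids, genotypes)
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        genotype_line = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene" or genotype_line[0] != "genotype":
            raise FormatError(
                f"{path}: expected two header lines starting 'gene' and 'genotype'"
            )
        sample_ids = header[1:]
        genotypes = genotype_line[1:]
        if len(sample_ids) != len(genotypes):
            raise FormatError(f"{path}: header lines have different widths")
        values = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    values.columns = sample_ids
    values.index.name = "gene"
    reps: dict[str, int] = {}
    replicate = []
    for g in genotypes:
        reps[g] = reps.get(g, 0) + 1
        replicate.append(reps[g])
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "genotype": genotypes, "replicate": replicate}
    )
    return ExpressionMatrix(values=values.astype(float), samples=samples)


def write_expression(expr: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(expr.samples["sample_id"]) + "\n")
        fh.write("genotype\t" + "\t".join(expr.samples["genotype"]) + "\n")
        expr.values.to_csv(fh, sep="\t", header=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Validation entry point (CLI `validate`)
# ---------------------------------------------------------------------------

def validate_file(path) -> str:
    """Best-effort validation of one input file; returns the detected kind.

    The kind is guessed from the extension (.fa/.fasta, .bed, .tsv); a
    matrix TSV is recognized by its two-line header.
    """
    name = str(path)
    if name.endswith((".fa", ".fasta")):
        read_fasta(path)
        return "fasta"
    if name.endswith(".bed"):
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise FormatError(f"{name}: expected >= 6 BED columns")
                int(fields[1]), int(fields[2])
                if fields[5] not in ("+", "-"):
                    raise FormatError(f"{name}: strand column must be + or -")
        return "bed"
    if name.endswith(".tsv"):
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("gene\t"):
            read_expression(path)
            return "expression"
        read_library(path, "validation", "other", "untreated")
        return "library"
    raise FormatError(f"cannot determine format of {name}")
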