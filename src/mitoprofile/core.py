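"""Core domain types for annotated circular mitogenomes.

Coordinates follow the convention of published mitogenome gene tables:
1-based, inclusive, on the heavy (H) strand.  A feature whose ``stop`` is
smaller than its ``start`` wraps across the origin of a circular genome.
Light (L) strand features are stored with H-strand coordinates and
reverse-complemented on extraction.

The genetic code used throughout is NCBI translation table 2 (vertebrate
mitochondrial): ATA encodes Met, TGA encodes Trp, and AGA/AGG are stop
codons.  Start codons default to {ATG, GTG}, the two initiators observed
in teleost mitochondrial protein-coding genes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement as _bio_revcomp

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")

# IUPAC code -> set of unambiguous bases it stands for
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return _bio_revcomp(seq)


class GeneKind(enum.Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CR = "CR"


class Strand(enum.Enum):
    H = "+"
    L = "-"


@dataclass(frozen=True)
class NucSequence:
    """An uppercased IUPAC nucleotide sequence, optionally circular."""

    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper().replace("U", "T"))
        if not self.residues:
            raise ValueError("empty nucleotide sequence")
        bad = set(self.residues) - IUPAC_NUCLEOTIDES
        if bad:
            raise ValueError(f"non-IUPAC nucleotide symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(reverse_complement(self.residues), circular=self.circular)


@dataclass(frozen=True)
class GeneRecord:
    """One row of a mitogenome gene table (1-based inclusive coordinates)."""

    name: str
    kind: GeneKind
    start: int
    stop: int
    strand: Strand = Strand.H
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.stop < 1:
            raise ValueError(f"{self.name}: coordinates must be >= 1")
        if self.anticodon is not None and len(self.anticodon) != 3:
            raise ValueError(f"{self.name}: anticodon must be a triplet")

    def size(self, genome_length: Optional[int] = None) -> int:
        """Feature length in bp; wrap-around features need ``genome_length``."""
        if self.stop >= self.start:
            return self.stop - self.start + 1
        if genome_length is None:
            raise ValueError(f"{self.name}: wrap-around feature needs genome length")
        return (genome_length - self.start + 1) + self.stop

    @property
    def wraps(self) -> bool:
        return self.stop < self.start


@dataclass
class AnnotatedMitogenome:
    """A circular mitogenome: sequence (optional) plus an ordered gene table.

    Table-only mode (``sequence=None``) supports layout arithmetic on
    published annotation tables without the underlying sequence; the genome
    length is then inferred from the largest stop coordinate unless given.
    """

    sequence: Optional[NucSequence] = None
    genes: list[GeneRecord] = field(default_factory=list)
    taxon: str = ""
    accession: str = ""
    genome_length: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene names in table: {dupes}")
        if sum(g.kind is GeneKind.CR for g in self.genes) > 1:
            raise ValueError("at most one control-region record permitted")
        if any(self.genes[i].start > self.genes[i + 1].start for i in range(len(self.genes) - 1)):
            warnings.warn("gene table not sorted by start; sorting", stacklevel=2)
            self.genes = sorted(self.genes, key=lambda g: g.start)
        if self.sequence is not None:
            if self.genome_length is not None and self.genome_length != len(self.sequence):
                raise ValueError("genome_length disagrees with sequence length")
            self.genome_length = len(self.sequence)
        elif self.genome_length is None:
            self.genome_length = max((g.stop for g in self.genes), default=0) or None
        if self.genome_length is not None:
            for g in self.genes:
                if g.start > self.genome_length or g.stop > self.genome_length:
                    raise ValueError(
                        f"{g.name}: coordinates {g.start}..{g.stop} exceed "
                        f"genome length {self.genome_length}"
                    )
                if g.wraps and not self.circular:
                    raise ValueError(f"{g.name}: wrap-around feature on a linear genome")

    @property
    def circular(self) -> bool:
        return self.sequence.circular if self.sequence is not None else True

    def genes_of_kind(self, kind: GeneKind) -> list[GeneRecord]:
        return [g for g in self.genes if g.kind is kind]

    def gene(self, name: str) -> GeneRecord:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with explicit start/stop codon sets."""

    code_id: int
    codon_to_aa: dict  # 64 entries; stops map to '*'
    start_codons: frozenset
    stop_codons: frozenset

    @classmethod
    def from_ncbi(cls, code_id: int = 2,
                  start_codons: Iterable[str] = ("ATG", "GTG")) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[code_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        assert len(mapping) == 64
        return cls(
            code_id=code_id,
            codon_to_aa=mapping,
            start_codons=frozenset(start_codons),
            stop_codons=frozenset(table.stop_codons),
        )

    def aa(self, codon: str) -> str:
        """Amino acid for a codon; 'X' for any ambiguous/gapped codon."""
        return self.codon_to_aa.get(codon, "X")

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


#: NCBI table 2 with the teleost-mitogenome initiators ATG/GTG.
VERTEBRATE_MITO = GeneticCode.from_ncbi(2)


def extract_gene_sequence(genome: AnnotatedMitogenome, gene: GeneRecord) -> NucSequence:
    """Coding-strand sequence of ``gene`` (revcomp for L-strand features).

    Wrap-around features (stop < start) are only legal on circular genomes.
    """
    if genome.sequence is None:
        raise ValueError("genome is table-only: no sequence to extract from")
    residues = genome.sequence.residues
    n = len(residues)
    if gene.start > n or gene.stop > n:
        raise ValueError(f"{gene.name}: coordinates outside genome of length {n}")
    if gene.wraps:
        if not genome.sequence.circular:
            raise ValueError(f"{gene.name}: wrap-around feature on a linear genome")
        sub = residues[gene.start - 1:] + residues[:gene.stop]
    else:
        sub = residues[gene.start - 1:gene.stop]
    if gene.strand is Strand.L:
        sub = reverse_complement(sub)
    return NucSequence(sub, circular=False)


def translate(cds, code: GeneticCode = VERTEBRATE_MITO) -> str:
    """Translate an in-frame CDS; stops render as '*', ambiguity as 'X'.

    Trailing 1-2 nt (an incomplete terminal codon) are ignored with a
    warning, matching how polyadenylation-completed mitochondrial stop
    codons appear in genomic sequence.
    """
    seq = str(cds)
    if not seq:
        raise ValueError("empty CDS")
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(seq) % 3:
        warnings.warn(f"CDS length {len(seq)} not a multiple of 3; "
                      f"trailing {len(seq) % 3} nt ignored", stacklevel=2)
    protein = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        aa = code.aa(codon)
        if aa == "X":
            warnings.warn(f"ambiguous codon {codon} at position {i + 1}", stacklevel=2)
        protein.append(aa)
    return "".join(protein)


@dataclass(frozen=True)
class OrfReport:
    """Open-reading-frame diagnostics for one protein-coding gene."""

    gene_name: str
    start_codon: str
    start_ok: bool
    internal_stops: tuple  # 1-based codon indices, terminal codon excluded
    length_mod3: int
    terminal_codon: Optional[str]  # None when length is not a codon multiple

    @property
    def ok(self) -> bool:
        return self.start_ok and not self.internal_stops


def validate_orf(genome: AnnotatedMitogenome, gene: GeneRecord,
                 code: GeneticCode = VERTEBRATE_MITO) -> OrfReport:
    """Check start-codon membership and internal in-frame stops of a PCG."""
    if gene.kind is not GeneKind.PCG:
        raise ValueError(f"{gene.name}: validate_orf applies to PCGs only")
    seq = str(extract_gene_sequence(genome, gene))
    mod3 = len(seq) % 3
    n_codons = len(seq) // 3
    start_codon = seq[:3]
    internal = []
    # the terminal codon (complete or not) is exempt: incomplete stops are
    # completed by polyadenylation and a final stop is expected
    last_internal = n_codons - 1 if mod3 == 0 else n_codons
    for ci in range(1, last_internal):
        if code.is_stop(seq[3 * ci:3 * ci + 3]):
            internal.append(ci + 1)
    terminal = seq[3 * (n_codons - 1):3 * n_codons] if mod3 == 0 else None
    return OrfReport(
        gene_name=gene.name,
        start_codon=start_codon,
        start_ok=start_codon in code.start_codons,
        internal_stops=tuple(internal),
        length_mod3=mod3,
        terminal_codon=terminal,
    )
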