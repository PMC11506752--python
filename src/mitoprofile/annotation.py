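"""Partitioned composition/skew profiling and gene-layout arithmetic.

Composition follows the conventions of published mitogenome tables:
percentages of A/T/G/C over the partition length (two decimals in
reports), AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C) on raw
counts (three decimals in reports).  Ambiguity codes count toward length
but never toward a skew or percentage numerator.

Layout arithmetic: the intergenic-nucleotide (IN) count attributed to a
feature is ``start(next) - stop(this) - 1`` in table order (negative
values are overlaps with the next feature); the last feature closes the
circle back to the first.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .core import (AnnotatedMitogenome, GeneKind, GeneRecord, GeneticCode,
                   NucSequence, VERTEBRATE_MITO, extract_gene_sequence)


def base_composition(seq) -> dict:
    """Counts and percentages of A, C, G, T (and any ambiguity symbols)."""
    residues = str(seq)
    if not residues:
        raise ValueError("empty sequence")
    counts = Counter(residues)
    n = len(residues)
    out = {"length": n, "counts": dict(counts)}
    for base in "ACGT":
        out[f"percent_{base}"] = 100.0 * counts.get(base, 0) / n
    out["percent_AT"] = 100.0 * (counts.get("A", 0) + counts.get("T", 0)) / n
    return out


def at_gc_skew(seq) -> tuple:
    """(AT-skew, GC-skew) on raw counts; None marks a zero denominator."""
    counts = Counter(str(seq))
    a, t = counts.get("A", 0), counts.get("T", 0)
    g, c = counts.get("G", 0), counts.get("C", 0)
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    return at_skew, gc_skew


@dataclass(frozen=True)
class CompositionProfile:
    """Composition of one named partition of a mitogenome."""

    partition: str
    length: int
    percent_a: float
    percent_t: float
    percent_g: float
    percent_c: float
    percent_at: float
    at_skew: Optional[float]
    gc_skew: Optional[float]
    percent_of_genome: Optional[float] = None

    @classmethod
    def from_sequence(cls, partition: str, seq,
                      genome_length: Optional[int] = None) -> "CompositionProfile":
        comp = base_composition(seq)
        at, gc = at_gc_skew(seq)
        return cls(
            partition=partition,
            length=comp["length"],
            percent_a=comp["percent_A"], percent_t=comp["percent_T"],
            percent_g=comp["percent_G"], percent_c=comp["percent_C"],
            percent_at=comp["percent_AT"], at_skew=at, gc_skew=gc,
            percent_of_genome=(100.0 * comp["length"] / genome_length
                               if genome_length else None),
        )

    def rounded(self) -> dict:
        """Report-style rounding: percentages 2 dp, skews 3 dp."""
        return {
            "partition": self.partition, "length": self.length,
            "A%": round(self.percent_a, 2), "T%": round(self.percent_t, 2),
            "G%": round(self.percent_g, 2), "C%": round(self.percent_c, 2),
            "A+T%": round(self.percent_at, 2),
            "AT-skew": None if self.at_skew is None else round(self.at_skew, 3),
            "GC-skew": None if self.gc_skew is None else round(self.gc_skew, 3),
            "% of genome": (None if self.percent_of_genome is None
                            else round(self.percent_of_genome, 2)),
        }


DEFAULT_PARTITIONS = ("complete", "PCGs", "tRNAs", "rRNAs", "CR")

_KIND_BY_PARTITION = {"PCGs": GeneKind.PCG, "tRNAs": GeneKind.TRNA,
                      "rRNAs": GeneKind.RRNA, "CR": GeneKind.CR}


def partition_members(genome: AnnotatedMitogenome, partition: str) -> list:
    if partition == "complete":
        return list(genome.genes)
    return genome.genes_of_kind(_KIND_BY_PARTITION[partition])


def partition_lengths(genome: AnnotatedMitogenome,
                      partitions=DEFAULT_PARTITIONS) -> dict:
    """Table-only partition totals: {name: (length bp, % of genome)}."""
    n = genome.genome_length
    out = {}
    for name in partitions:
        if name == "complete":
            length = n
        else:
            length = sum(g.size(n) for g in partition_members(genome, name))
        out[name] = (length, 100.0 * length / n)
    return out


def partition_profile(genome: AnnotatedMitogenome,
                      partitions=DEFAULT_PARTITIONS,
                      coding_strand: bool = True) -> list:
    """Composition profiles for named partitions (requires sequence).

    A partition's sequence is the concatenation of its member genes in
    table order, each on its coding strand (L-strand genes
    reverse-complemented); ``coding_strand=False`` keeps every member on
    the heavy-strand reference instead.
    """
    if genome.sequence is None:
        raise ValueError("partition_profile requires a sequence")
    profiles = []
    for name in partitions:
        if name == "complete":
            profiles.append(CompositionProfile.from_sequence(
                name, genome.sequence, genome.genome_length))
            continue
        members = partition_members(genome, name)
        if not members:
            warnings.warn(f"partition {name!r} is empty; skipped", stacklevel=2)
            continue
        parts = []
        for g in members:
            if coding_strand:
                parts.append(str(extract_gene_sequence(genome, g)))
            else:
                ref = g if g.strand.value == "+" else GeneRecord(
                    g.name, g.kind, g.start, g.stop)
                parts.append(str(extract_gene_sequence(genome, ref)))
        profiles.append(CompositionProfile.from_sequence(
            name, "".join(parts), genome.genome_length))
    return profiles


# ---------------------------------------------------------------------------
# layout arithmetic


@dataclass(frozen=True)
class LayoutRecord:
    """Per-feature layout row: IN to the next feature plus codon endpoints."""

    gene_name: str
    intergenic_nucleotides: int
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None  # triplet, "TA-", "T--" or None


@dataclass(frozen=True)
class OverlapSummary:
    overlap_count: int
    overlap_total_bp: int
    longest_overlap_bp: int
    longest_overlap_pair: tuple
    longest_spacer_bp: int
    longest_spacer_gene: str


def intergenic_layout(genome: AnnotatedMitogenome):
    """(per-feature LayoutRecords, OverlapSummary) from coordinates alone."""
    genes = sorted(genome.genes, key=lambda g: g.start)
    if len(genes) < 2:
        raise ValueError("layout arithmetic needs at least two features")
    if genes != genome.genes:
        warnings.warn("gene table was not sorted by start; sorted", stacklevel=2)
    n = genome.genome_length
    records = []
    for i, g in enumerate(genes):
        if i + 1 < len(genes):
            inter = genes[i + 1].start - g.stop - 1
        else:  # close the circle back to the first feature
            inter = (n - g.stop) + genes[0].start - 1
        records.append(LayoutRecord(g.name, inter))
    overlaps = [(-r.intergenic_nucleotides, r.gene_name, genes[i + 1].name
                 if i + 1 < len(genes) else genes[0].name)
                for i, r in enumerate(records) if r.intergenic_nucleotides < 0]
    spacers = [(r.intergenic_nucleotides, r.gene_name) for r in records
               if r.intergenic_nucleotides > 0]
    longest_overlap = max(overlaps, default=(0, "", ""))
    longest_spacer = max(spacers, default=(0, ""))
    summary = OverlapSummary(
        overlap_count=len(overlaps),
        overlap_total_bp=sum(o[0] for o in overlaps),
        longest_overlap_bp=longest_overlap[0],
        longest_overlap_pair=(longest_overlap[1], longest_overlap[2]),
        longest_spacer_bp=longest_spacer[0],
        longest_spacer_gene=longest_spacer[1],
    )
    return records, summary


def classify_stop(cds: str, code: GeneticCode = VERTEBRATE_MITO) -> tuple:
    """Stop-codon class of a coding-strand CDS.

    Returns (label, anomalous): a complete terminal triplet must be a stop
    codon; a 2-nt tail must be "TA" (reported "TA-"); a 1-nt tail must be
    "T" (reported "T--"); anything else is flagged anomalous.  Incomplete
    stops are completed to TAA by polyadenylation of the mature mRNA.
    """
    mod3 = len(cds) % 3
    if mod3 == 0:
        terminal = cds[-3:]
        return terminal, not code.is_stop(terminal)
    if mod3 == 2:
        return ("TA-", cds[-2:] != "TA")
    return ("T--", cds[-1] != "T")


def codon_endpoints(genome: AnnotatedMitogenome,
                    code: GeneticCode = VERTEBRATE_MITO) -> list:
    """Start codon and stop-codon class for every PCG (requires sequence)."""
    if genome.sequence is None:
        raise ValueError("codon_endpoints requires a sequence")
    out = []
    for g in genome.genes_of_kind(GeneKind.PCG):
        cds = str(extract_gene_sequence(genome, g))
        if len(cds) < 6:
            raise ValueError(f"{g.name}: PCG shorter than 6 nt")
        stop_label, anomalous = classify_stop(cds, code)
        out.append({
            "gene": g.name,
            "start_codon": cds[:3],
            "start_ok": cds[:3] in code.start_codons,
            "stop_codon": stop_label,
            "stop_anomalous": anomalous,
        })
    return out


def incomplete_stop_genes(genome: AnnotatedMitogenome) -> list:
    """PCGs whose printed size is not a codon multiple (incomplete stops)."""
    n = genome.genome_length
    return [g.name for g in genome.genes_of_kind(GeneKind.PCG) if g.size(n) % 3]
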