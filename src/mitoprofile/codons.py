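"""Codon counting, amino-acid frequencies, and relative synonymous codon
usage (RSCU) under the vertebrate mitochondrial code.

RSCU(c) = k * n_c / sum(n_c' over the codon family of c's amino acid),
where k is the family size.  Families follow the amino acid, not the codon
block: under code 2 both Leu (TTR + CTN) and Ser (TCN + AGY) are six-codon
families.  A uniformly used family therefore averages RSCU 1, and the
family RSCU values always sum to k.

By default terminal stop codons and incomplete trailing codons are
excluded from the totals; pass ``include_stops=True`` to count complete
stop codons as their own '*' family.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .core import GeneticCode, VERTEBRATE_MITO


@dataclass
class CodonUsageTable:
    per_codon: dict  # codon -> count (sense codons; '*' codons only if included)
    code: GeneticCode = field(default=VERTEBRATE_MITO, repr=False)
    include_stops: bool = False

    @property
    def per_amino_acid(self) -> dict:
        totals = defaultdict(int)
        for codon, n in self.per_codon.items():
            totals[self.code.aa(codon)] += n
        return dict(totals)

    @property
    def total_codons(self) -> int:
        """Total sense codons counted (stops never inflate the total)."""
        return sum(n for codon, n in self.per_codon.items()
                   if not self.code.is_stop(codon))

    def families(self) -> dict:
        """aa -> list of codons, for every amino acid of the code."""
        fams = defaultdict(list)
        for codon, aa in sorted(self.code.codon_to_aa.items()):
            fams[aa].append(codon)
        return dict(fams)


def codon_counts(cds_list, code: GeneticCode = VERTEBRATE_MITO,
                 include_stops: bool = False) -> CodonUsageTable:
    """Count in-frame codons over a list of coding-strand CDS sequences.

    Each CDS is read in frame from its first position.  Incomplete
    trailing codons are dropped; a complete terminal stop codon is dropped
    unless ``include_stops``.
    """
    if not cds_list:
        raise ValueError("codon_counts needs at least one CDS")
    counts = Counter()
    for cds in cds_list:
        seq = str(cds)
        codons = [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
        if codons and code.is_stop(codons[-1]) and not include_stops:
            codons = codons[:-1]
        counts.update(c for c in codons if set(c) <= set("ACGT"))
    return CodonUsageTable(dict(counts), code=code, include_stops=include_stops)


def rscu(table: CodonUsageTable) -> dict:
    """Per-codon RSCU; families with zero usage map to None (undefined)."""
    values = {}
    for aa, codons in table.families().items():
        if aa == "*" and not table.include_stops:
            continue
        family_total = sum(table.per_codon.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            values[c] = (k * table.per_codon.get(c, 0) / family_total
                         if family_total else None)
    return values


def aa_frequencies(table: CodonUsageTable) -> dict:
    """Relative amino-acid usage: family total / total sense codons."""
    total = table.total_codons
    if total == 0:
        raise ValueError("empty codon usage table")
    return {aa: n / total for aa, n in sorted(table.per_amino_acid.items())
            if aa != "*"}


def aa_ranking(table: CodonUsageTable) -> list:
    """Amino acids sorted by decreasing usage (ties broken alphabetically)."""
    freqs = aa_frequencies(table)
    return sorted(freqs, key=lambda aa: (-freqs[aa], aa))
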