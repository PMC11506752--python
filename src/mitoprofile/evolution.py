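"""Selection and diversity statistics: Nei-Gojobori (1986) Ka/Ks with
Jukes-Cantor correction, nucleotide diversity with sliding windows, and
transition/transversion saturation against the Kimura two-parameter
distance.

NG86 conventions used here (documented because DnaSP and MEGA differ in
the details):

* synonymous/nonsynonymous *sites* are counted per codon position as the
  fraction of single-nucleotide changes that are synonymous among the
  changes that do not create a stop codon (variant "exclude-stops"); with
  variant "include-stops" all three changes enter the denominator and a
  change to a stop counts as nonsynonymous;
* *differences* between codons differing at several positions are averaged
  over all mutational pathways that avoid stop-codon intermediates; if
  every pathway is blocked the codon falls back to all pathways and the
  result is flagged;
* codon pairs containing a gap, ambiguity, or stop codon are dropped
  pairwise;
* proportions are Jukes-Cantor corrected, d = -(3/4) ln(1 - (4/3) p);
  p >= 3/4 yields an infinite (saturated) distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Optional

from .core import GeneticCode, VERTEBRATE_MITO

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
BASES = "ACGT"


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def jukes_cantor(p: float) -> float:
    """JC69 distance; infinite once the proportion saturates at 3/4."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1 - (4.0 / 3.0) * p)


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986


def ng86_sites(codon: str, code: GeneticCode = VERTEBRATE_MITO,
               variant: str = "exclude-stops") -> tuple:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    With the stop-excluded denominator the two counts sum to at most 3.
    """
    codon = codon.upper()
    if set(codon) - set(BASES) or len(codon) != 3:
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = code.aa(codon)
    s = n = 0.0
    for pos in range(3):
        syn = nonsyn = 0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if code.is_stop(mutant):
                if variant == "include-stops":
                    nonsyn += 1
                continue
            if code.aa(mutant) == aa:
                syn += 1
            else:
                nonsyn += 1
        total = syn + nonsyn
        if total:
            s += syn / total
            n += nonsyn / total
    return s, n


def _codon_path_counts(c1: str, c2: str, code: GeneticCode,
                       variant: str) -> tuple:
    """Pathway-averaged (syn, nonsyn) differences between two sense codons.

    Returns (sd, nd, fallback_flag).
    """
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0, False

    def walk(order, allow_stops):
        sd = nd = 0
        current = c1
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if code.is_stop(nxt) and not allow_stops:
                return None
            step_syn = (code.aa(current) == code.aa(nxt)
                        and not code.is_stop(nxt) and not code.is_stop(current))
            if step_syn:
                sd += 1
            else:
                nd += 1
            current = nxt
        return sd, nd

    allow = variant == "include-stops"
    results = [r for order in permutations(diff_positions)
               if (r := walk(order, allow)) is not None]
    fallback = False
    if not results:  # every pathway runs through a stop: fall back, flagged
        fallback = True
        results = [walk(order, True) for order in permutations(diff_positions)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd, fallback


@dataclass(frozen=True)
class PairwiseSelection:
    """NG86 Ka/Ks estimate for one aligned in-frame CDS pair."""

    gene_name: str
    codons_compared: int
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float
    ka: float
    pathway_fallback: bool = False

    @property
    def ratio(self) -> Optional[float]:
        """Ka/Ks; None (undefined) when Ks = 0 or either rate is saturated."""
        if self.ks == 0 or math.isinf(self.ks) or math.isinf(self.ka):
            return None
        return self.ka / self.ks

    @property
    def saturated(self) -> bool:
        return math.isinf(self.ks) or math.isinf(self.ka)


def ng86_pair(cds1, cds2, code: GeneticCode = VERTEBRATE_MITO,
              gene_name: str = "", variant: str = "exclude-stops") -> PairwiseSelection:
    """Nei-Gojobori Ka/Ks between two aligned, in-frame CDS sequences.

    Sites are averaged over the two sequences; multi-hit codons are
    averaged over stop-avoiding mutational pathways.  Symmetric in its
    arguments.
    """
    s1, s2 = str(cds1).upper(), str(cds2).upper()
    if len(s1) != len(s2):
        raise ValueError(f"unaligned CDS pair: lengths {len(s1)} != {len(s2)}")
    if len(s1) % 3:
        raise ValueError(f"alignment length {len(s1)} is not a codon multiple")
    S = N = sd = nd = 0.0
    compared = 0
    fallback = False
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i:i + 3], s2[i:i + 3]
        if set(c1 + c2) - set(BASES):
            continue  # pairwise deletion of gapped/ambiguous codons
        if code.is_stop(c1) or code.is_stop(c2):
            continue
        compared += 1
        sa, na = ng86_sites(c1, code, variant)
        sb, nb = ng86_sites(c2, code, variant)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        dsd, dnd, fb = _codon_path_counts(c1, c2, code, variant)
        sd += dsd
        nd += dnd
        fallback = fallback or fb
    if compared == 0:
        raise ValueError("no comparable codon pairs")
    ps = sd / S if S else 0.0
    pn = nd / N if N else 0.0
    return PairwiseSelection(
        gene_name=gene_name, codons_compared=compared,
        s_sites=S, n_sites=N, sd=sd, nd=nd, ps=ps, pn=pn,
        ks=jukes_cantor(ps), ka=jukes_cantor(pn),
        pathway_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# nucleotide diversity


def _usable_columns(alignment, deletion: str):
    length = len(alignment[0])
    if any(len(s) != length for s in alignment):
        raise ValueError("ragged alignment")
    if deletion == "complete":
        return [j for j in range(length)
                if all(s[j] in BASES for s in alignment)]
    return list(range(length))


def nucleotide_diversity(alignment, deletion: str = "complete") -> float:
    """Mean pairwise per-site difference proportion (pi).

    ``deletion="complete"`` drops every column containing a gap or
    ambiguity before comparing (DnaSP-style); ``"pairwise"`` drops unusable
    sites per pair.
    """
    seqs = [str(s).upper() for s in alignment]
    if len(seqs) < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    cols = _usable_columns(seqs, deletion)
    total = 0.0
    n_pairs = 0
    for a, b in combinations(seqs, 2):
        if deletion == "complete":
            usable = cols
        else:
            usable = [j for j in cols if a[j] in BASES and b[j] in BASES]
        if not usable:
            continue
        diffs = sum(a[j] != b[j] for j in usable)
        total += diffs / len(usable)
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no comparable sites in any pair")
    return total / n_pairs


@dataclass(frozen=True)
class DiversityResult:
    pi: float
    windows: tuple  # (start, end, pi) with 1-based inclusive coordinates
    window_size: int
    step_size: int
    truncated: bool = False


def sliding_window_pi(alignment, window: int = 200, step: int = 25,
                      deletion: str = "complete") -> DiversityResult:
    """Sliding-window nucleotide diversity (defaults 200 bp / 25 bp).

    Windows start at 1, 1+step, ... while they fit inside the alignment;
    a window longer than the alignment yields one truncated window,
    flagged.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    seqs = [str(s).upper() for s in alignment]
    length = len(seqs[0])
    truncated = window > length
    spans = ([(1, length)] if truncated else
             [(s, s + window - 1) for s in range(1, length - window + 2, step)])
    windows = tuple((start, end,
                     nucleotide_diversity([s[start - 1:end] for s in seqs], deletion))
                    for start, end in spans)
    return DiversityResult(
        pi=nucleotide_diversity(seqs, deletion),
        windows=windows, window_size=window, step_size=step, truncated=truncated,
    )


# ---------------------------------------------------------------------------
# saturation / K2P


def kimura_2p(p: float, q: float) -> float:
    """Kimura (1980) two-parameter distance from transition (p) and
    transversion (q) proportions; infinite outside the log domain."""
    w1 = 1 - 2 * p - q
    w2 = 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return math.inf
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass(frozen=True)
class SaturationRecord:
    taxon_pair: tuple
    p: float  # transition proportion
    q: float  # transversion proportion
    k2p: float


def k2p_saturation(alignment, names=None) -> list:
    """Per-pair transition/transversion proportions and K2P distances.

    Sites where either sequence is gapped/ambiguous are ignored pairwise.
    """
    seqs = [str(s).upper() for s in alignment]
    if len(seqs) < 2:
        raise ValueError("saturation analysis needs at least two sequences")
    if names is None:
        names = [f"seq{i + 1}" for i in range(len(seqs))]
    records = []
    for (i, a), (j, b) in combinations(enumerate(seqs), 2):
        ts = tv = n = 0
        for x, y in zip(a, b):
            if x not in BASES or y not in BASES:
                continue
            n += 1
            if x == y:
                continue
            if _is_transition(x, y):
                ts += 1
            else:
                tv += 1
        if n == 0:
            raise ValueError(f"no comparable sites between {names[i]} and {names[j]}")
        p, q = ts / n, tv / n
        records.append(SaturationRecord((names[i], names[j]), p, q, kimura_2p(p, q)))
    return records
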