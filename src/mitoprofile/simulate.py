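"""Deterministic synthetic mitogenome and alignment generator.

The generator emulates the study system: a 16.5-kb circular teleost
mitogenome laid out exactly like the packaged S. dorsalis annotation
(13 PCGs, 22 tRNAs, two rRNAs, one control region, heavy/light strand
assignment, gene overlaps, incomplete stop codons), with dialable base
composition and strand skews.  Defaults reproduce the study's composition
targets (AT fraction 0.5313, AT-skew 0.034, GC-skew -0.288).

Composition targets are met in expectation (per-position sampling), not
exactly; protein-coding constraints (legal start codon, size-appropriate
terminal codon, no internal in-frame stops) are then enforced on the
coding strand wherever the position is not owned by an earlier template
feature — in overlap zones the earlier gene wins and the conflict is
logged in the genome's metadata.

All randomness flows through one numpy Generator seeded from the spec, in
a fixed consumption order, so a given spec is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .core import (AnnotatedMitogenome, GeneKind, GeneRecord, GeneticCode,
                   NucSequence, Strand, VERTEBRATE_MITO, reverse_complement,
                   translate)
from .noncoding import PAIRED

BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationSpec:
    """Conditions for one synthetic mitogenome.

    Defaults are the study conditions: the packaged 16,541-bp layout and
    the whole-mitogenome composition row (AT 53.13%, AT-skew 0.034,
    GC-skew -0.288).
    """

    layout_template: Optional[AnnotatedMitogenome] = None  # default: packaged table
    target_at_fraction: float = 0.5313
    target_at_skew: float = 0.034
    target_gc_skew: float = -0.288
    codon_bias: Optional[dict] = None  # aa -> {codon: weight}
    plant_csb: bool = False
    fold_trnas: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_at_fraction < 1:
            raise ValueError("AT fraction must be in (0, 1)")
        for skew in (self.target_at_skew, self.target_gc_skew):
            if not -1 <= skew <= 1:
                raise ValueError("skews must lie in [-1, 1]")

    def base_probabilities(self) -> np.ndarray:
        """P(A), P(C), P(G), P(T) implied by the AT fraction and skews."""
        at, gc = self.target_at_fraction, 1 - self.target_at_fraction
        return np.array([
            at * (1 + self.target_at_skew) / 2,
            gc * (1 - self.target_gc_skew) / 2,
            gc * (1 + self.target_gc_skew) / 2,
            at * (1 - self.target_at_skew) / 2,
        ])


def _load_template() -> AnnotatedMitogenome:
    from .genome_io import load_table1
    return load_table1()


def _coding_positions(gene: GeneRecord, n: int) -> np.ndarray:
    """Genome indices (0-based) of the gene read 5'->3' on its coding strand."""
    if gene.wraps:
        span = np.concatenate([np.arange(gene.start - 1, n), np.arange(0, gene.stop)])
    else:
        span = np.arange(gene.start - 1, gene.stop)
    return span[::-1] if gene.strand is Strand.L else span


def _write_coding(seq: np.ndarray, positions: np.ndarray, owned: np.ndarray,
                  offset: int, fragment: str, strand: Strand, log: list,
                  gene: str) -> None:
    """Write a coding-strand fragment at codon offset, skipping owned sites."""
    for k, base in enumerate(fragment):
        p = positions[offset + k]
        value = _COMPLEMENT[base] if strand is Strand.L else base
        if owned[p]:
            if seq[p] != value:
                log.append(f"{gene}: position {p + 1} owned by an earlier "
                           f"feature; constraint skipped")
        else:
            seq[p] = value


_NONSTOP_PERMS = {}  # stop codon -> non-stop permutations of its own bases


def _nonstop_permutations(codon: str, code: GeneticCode) -> tuple:
    """Distinct reorderings of the codon's bases that are not stop codons.

    Used to resolve sampled in-frame stops without changing base counts,
    so constrained genomes keep the spec's composition in expectation.
    Every code-2 stop has at least one (e.g. TAA -> ATA).
    """
    from itertools import permutations as _perms
    key = (codon, code.code_id)
    if key not in _NONSTOP_PERMS:
        _NONSTOP_PERMS[key] = tuple(sorted(
            {"".join(p) for p in _perms(codon)} - set(code.stop_codons)))
    return _NONSTOP_PERMS[key]


def generate_mitogenome(spec: SimulationSpec,
                        code: GeneticCode = VERTEBRATE_MITO) -> AnnotatedMitogenome:
    """Sample an annotated circular mitogenome satisfying the spec.

    PCGs receive a legal start codon (ATG; GTG for COI), a terminal codon
    matching their size mod 3 (TAA / TA / T), and internal in-frame stops
    are resolved by rewriting third positions.  The control region can
    carry planted CSB motifs; tRNA spans can be filled with perfect
    cloverleaves carrying the annotated anticodon.
    """
    template = spec.layout_template or _load_template()
    n = template.genome_length
    rng = np.random.default_rng(spec.seed)
    seq = rng.choice(BASES, size=n, p=spec.base_probabilities())
    owned = np.zeros(n, dtype=bool)
    log: list = []

    for gene in template.genes:
        pos = _coding_positions(gene, n)
        if gene.kind is GeneKind.PCG:
            _constrain_pcg(seq, pos, owned, gene, code, rng, log)
        elif gene.kind is GeneKind.TRNA and spec.fold_trnas:
            leaf = make_cloverleaf(len(pos), anticodon=gene.anticodon, rng=rng)
            _write_coding(seq, pos, owned, 0, leaf, gene.strand, log, gene.name)
        elif gene.kind is GeneKind.CR and spec.plant_csb:
            _plant_csb_motifs(seq, pos, owned, gene, rng, log)
        if gene.wraps:
            owned[pos] = True
        else:
            owned[gene.start - 1:gene.stop] = True

    genome = AnnotatedMitogenome(
        sequence=NucSequence("".join(seq), circular=True),
        genes=[GeneRecord(g.name, g.kind, g.start, g.stop, g.strand, g.anticodon)
               for g in template.genes],
        taxon="synthetic mitogenome",
        accession=f"SIM{spec.seed}",
        metadata={"simulation_conflicts": log, "seed": spec.seed},
    )
    return genome


def _constrain_pcg(seq, pos, owned, gene, code, rng, log) -> None:
    size = len(pos)
    start_codon = "GTG" if gene.name == "COI" else "ATG"
    _write_coding(seq, pos, owned, 0, start_codon, gene.strand, log, gene.name)
    mod3 = size % 3
    terminal = {0: "TAA", 2: "TA", 1: "T"}[mod3]
    _write_coding(seq, pos, owned, size - len(terminal), terminal,
                  gene.strand, log, gene.name)
    # resolve internal in-frame stops by permuting the codon's own bases
    # (composition-preserving by construction)
    n_codons = size // 3
    last_internal = n_codons - 1 if mod3 == 0 else n_codons
    for ci in range(last_internal):
        idx = pos[3 * ci:3 * ci + 3]
        codon = "".join(_COMPLEMENT[seq[p]] if gene.strand is Strand.L else seq[p]
                        for p in idx)
        if code.is_stop(codon):
            options = _nonstop_permutations(codon, code)
            replacement = options[int(rng.integers(len(options)))]
            _write_coding(seq, pos, owned, 3 * ci, replacement,
                          gene.strand, log, gene.name)


def _plant_csb_motifs(seq, pos, owned, gene, rng, log) -> None:
    from .noncoding import load_default_csb_motifs
    from .core import IUPAC_SETS

    config = load_default_csb_motifs()
    order = config.get("order", sorted(config["motifs"]))
    size = len(pos)
    gap = size // (len(order) + 1)
    for slot, name in enumerate(order):
        pattern = config["motifs"][name]
        concrete = "".join(sorted(IUPAC_SETS[c])[int(rng.integers(len(IUPAC_SETS[c])))]
                           for c in pattern)
        offset = gap * (slot + 1) - len(pattern) // 2
        if offset + len(pattern) > size:
            log.append(f"{gene.name}: CSB {name} does not fit; skipped")
            continue
        _write_coding(seq, pos, owned, offset, concrete, gene.strand, log, gene.name)


# ---------------------------------------------------------------------------
# cloverleaf construction


def _random_stem(rng, length: int) -> tuple:
    """A perfectly Watson-Crick-paired stem and its antiparallel partner."""
    five = "".join(str(rng.choice(list("ACGT"))) for _ in range(length))
    three = "".join(_COMPLEMENT[b] for b in reversed(five))
    return five, three


def _random_loop(rng, length: int) -> str:
    # loops avoid internal complementarity concerns by construction: any bases
    return "".join(str(rng.choice(list("ACGT"))) for _ in range(length))


def make_cloverleaf(length: int, anticodon: Optional[str] = None,
                    rng=None, seed: int = 0) -> str:
    """A perfect synthetic cloverleaf tRNA gene of 67-78 nt.

    Layout: acceptor(7) + 2 + [DHU 4+loop+4] + 1 + [AC 5+7+5] + variable
    + [T 5+7+5] + acceptor'(7) + discriminator(1); DHU loop (4-9 nt) and
    variable loop (3-9 nt) absorb the length difference.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    extra = length - 60
    if not 7 <= extra <= 18:
        raise ValueError(f"cloverleaf length {length} outside 67-78 nt")
    dl = min(9, max(4, extra - 3))
    v = extra - dl
    if v < 3:
        dl, v = extra - 3, 3
    acc5, acc3 = _random_stem(rng, 7)
    d5, d3 = _random_stem(rng, 4)
    ac5, ac3 = _random_stem(rng, 5)
    t5, t3 = _random_stem(rng, 5)
    ac_loop = _random_loop(rng, 7)
    if anticodon:
        ac_loop = ac_loop[:2] + anticodon.upper().replace("U", "T") + ac_loop[5:]
    parts = [acc5, _random_loop(rng, 2), d5, _random_loop(rng, dl), d3,
             _random_loop(rng, 1), ac5, ac_loop, ac3, _random_loop(rng, v),
             t5, _random_loop(rng, 7), t3, acc3, _random_loop(rng, 1)]
    leaf = "".join(parts)
    assert len(leaf) == length
    return leaf


# ---------------------------------------------------------------------------
# CDS mutagenesis


def _classify_changes(codon: str, code: GeneticCode) -> dict:
    """{'syn': [(pos, alt)], 'nonsyn': [(pos, alt)]} avoiding stop creation."""
    aa = code.aa(codon)
    out = {"syn": [], "nonsyn": []}
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if code.is_stop(mutant):
                continue
            out["syn" if code.aa(mutant) == aa else "nonsyn"].append((pos, alt))
    return out


def mutate_cds(cds, n_syn: int, n_nonsyn: int,
               code: GeneticCode = VERTEBRATE_MITO, seed: int = 0) -> str:
    """Apply exactly ``n_syn`` synonymous and ``n_nonsyn`` nonsynonymous
    single-nucleotide substitutions, at distinct codons, never creating a
    stop codon.  Deterministic per seed.

    Because every mutated codon differs at exactly one position, pathway
    counting is exact: an NG86 comparison of original vs mutant recovers
    Sd = n_syn and Nd = n_nonsyn.
    """
    seq = str(cds).upper()
    if len(seq) % 3:
        raise ValueError("CDS length must be a codon multiple")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if any(code.is_stop(c) for c in codons):
        raise ValueError("CDS must be stop-free")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(codons))
    chosen: dict = {}
    for kind, need in (("syn", n_syn), ("nonsyn", n_nonsyn)):
        placed = 0
        for ci in order:
            if placed == need:
                break
            if ci in chosen or set(codons[ci]) - set("ACGT"):
                continue
            options = _classify_changes(codons[ci], code)[kind]
            if not options:
                continue
            pos, alt = options[int(rng.integers(len(options)))]
            chosen[ci] = (pos, alt)
            placed += 1
        if placed < need:
            raise ValueError(f"cannot place {need} {kind} changes in this CDS")
    mutated = list(codons)
    for ci, (pos, alt) in chosen.items():
        mutated[ci] = mutated[ci][:pos] + alt + mutated[ci][pos + 1:]
    return "".join(mutated)


def random_cds(n_codons: int, code: GeneticCode = VERTEBRATE_MITO,
               seed: int = 0) -> str:
    """A random stop-free in-frame CDS starting with ATG."""
    rng = np.random.default_rng(seed)
    sense = sorted(c for c in code.codon_to_aa if not code.is_stop(c))
    codons = ["ATG"] + [sense[int(rng.integers(len(sense)))]
                        for _ in range(n_codons - 1)]
    return "".join(codons)


# ---------------------------------------------------------------------------
# alignment simulation (two-rate transition/transversion process)


def _k2p_p_q(alpha: float, beta: float, t: float) -> tuple:
    """Expected transition/transversion difference proportions at time t."""
    p = 0.25 + 0.25 * math.exp(-4 * beta * t) - 0.5 * math.exp(-2 * (alpha + beta) * t)
    q = 0.5 - 0.5 * math.exp(-4 * beta * t)
    return p, q


def _transition_matrix(alpha: float, beta: float, t: float) -> np.ndarray:
    """K2P transition probability matrix over ACGT at time t."""
    p, q = _k2p_p_q(alpha, beta, t)
    ts_partner = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T
    P = np.full((4, 4), q / 2)
    for i in range(4):
        P[i, i] = 1 - p - q
        P[i, ts_partner[i]] = p
    return P


def _solve_time(alpha: float, beta: float, divergence: float) -> float:
    if divergence == 0:
        return 0.0
    f = lambda t: sum(_k2p_p_q(alpha, beta, t)) - divergence
    hi = 1.0
    while f(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise ValueError("divergence too close to saturation")
    return brentq(f, 0.0, hi)


def generate_alignment(n_taxa: int, length: int, mean_divergence: float,
                       ti_tv_ratio: float = 2.0, seed: int = 0,
                       clades: int = 1,
                       between_divergence: Optional[float] = None) -> dict:
    """Simulate an ungapped alignment under a K2P substitution process.

    A uniform-random root evolves along a star tree whose branch times are
    solved so the *expected* pairwise p-distance equals
    ``mean_divergence`` exactly (the process is reversible with a uniform
    stationary distribution, so two branches of time t/2 compose to t).
    ``ti_tv_ratio`` is the expected transition/transversion count ratio.

    With ``clades=2`` the taxa split into two groups whose ancestors are
    separated by ``between_divergence`` (default 4x the within-clade
    divergence), for clade-separation tests.
    """
    if n_taxa < 1 or length < 1:
        raise ValueError("n_taxa and length must be positive")
    if not 0 <= mean_divergence < 0.75:
        raise ValueError("mean divergence must be in [0, 0.75)")
    if clades not in (1, 2):
        raise ValueError("clades must be 1 or 2")
    rng = np.random.default_rng(seed)
    beta = 1.0
    alpha = 2.0 * ti_tv_ratio * beta
    root = rng.integers(4, size=length)

    def evolve(state: np.ndarray, t: float) -> np.ndarray:
        if t == 0:
            return state.copy()
        P = _transition_matrix(alpha, beta, t)
        out = np.empty_like(state)
        for b in range(4):
            mask = state == b
            out[mask] = rng.choice(4, size=int(mask.sum()), p=P[b])
        return out

    names = [f"taxon{i + 1}" for i in range(n_taxa)]
    t_within = _solve_time(alpha, beta, mean_divergence)
    if clades == 1:
        states = [evolve(root, t_within / 2) for _ in range(n_taxa)]
    else:
        bdiv = between_divergence or min(0.74, 4 * mean_divergence)
        t_between = _solve_time(alpha, beta, bdiv)
        ancestors = [evolve(root, t_between / 2), evolve(root, t_between / 2)]
        half = (n_taxa + 1) // 2
        states, names = [], []
        for i in range(n_taxa):
            clade = 0 if i < half else 1
            states.append(evolve(ancestors[clade], t_within / 2))
            names.append(f"clade{clade + 1}_taxon{i + 1}")
    idx_to_base = np.array(list("ACGT"))
    return {name: "".join(idx_to_base[s]) for name, s in zip(names, states)}
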