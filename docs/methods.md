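# Methods and design notes

## Scope and model of the data

The package operates on *annotated* mitogenomes: a circular DNA sequence
(optional) plus an ordered gene table with 1-based inclusive heavy-strand
coordinates, a strand flag, and a feature kind (PCG / tRNA / rRNA / control
region). Annotation itself (assembly, gene calling) is out of scope;
tables from annotation servers or publications are consumed as input, with
a light validator (`validate_orf`) for protein-coding genes. A gene with
`stop < start` wraps across the replication origin and is legal only on a
circular genome; the packaged *S. dorsalis* reference layout contains none,
but parser and generator support them.

All protein-coding arithmetic uses NCBI translation table 2 (vertebrate
mitochondrial): ATA = Met, TGA = Trp, AGA/AGG = stop. Start codons default
to {ATG, GTG}, the initiators observed in teleost mitogenomes; the set is a
`GeneticCode` field, not a constant, so other conventions are one object
away.

## Composition and skew

Percentages are counts over partition length; ambiguity codes count toward
length but never toward a numerator, so A+C+G+T percentages sum to < 100
only when ambiguity is present (the MEGA-style reading). AT-skew and
GC-skew are computed on raw counts; a zero denominator yields an undefined
marker (`None`), not an exception. Report rounding follows the published
table convention — percentages to 2 decimals, skews to 3 — while raw
values are retained on the profile objects.

Partition sequences concatenate member genes in table order, each on its
**coding** strand (light-strand genes reverse-complemented). Published
composition tables do not state their strand handling; coding-strand is
this package's documented choice, and `coding_strand=False` (CLI
`--reference-strand`) profiles the heavy strand instead.

The PCG partition of the packaged table spans 11,427 bp = 69.08 % of
16,541 bp. The published description of this mitogenome prints 69.10 %
for the same quantity; the raw quotient is reported and tests allow 0.05
percentage points for the unknown upstream rounding path.

## Layout arithmetic

IN(i) = start(i+1) − stop(i) − 1 in table order, attributed to the
*earlier* feature; the final feature closes the circle with
(L − stop) + start(first) − 1. With overlaps counted negative, ΣIN =
L − Σsizes exactly (tested). Stop-codon classes are decided by size mod 3:
0 → the terminal triplet (flagged anomalous if not a stop codon), 2 → `TA-`
(flagged unless the tail is TA), 1 → `T--` (flagged unless the tail is T);
incomplete stops are completed to TAA by polyadenylation of the mature
transcript. On the packaged table this arithmetic alone identifies
{ND2, ND3, ND4, COII, COIII, ATP6, CYTB} as the incomplete-stop set. The
printed table lists complete TAA stops for COIII and CYTB while their
printed sizes (785, 1141) are not codon multiples; the package follows the
arithmetic (and the accompanying text), not those two table cells.

## Codon usage

Counting reads each CDS in frame from position 1; incomplete trailing
codons are dropped, and a complete *terminal* stop codon is dropped unless
`include_stops=True`. Stops never enter the sense-codon total. RSCU
families follow the amino acid (Leu = TTR + CTN, Ser = TCN + AGY, both
6-fold under code 2), so ΣRSCU over a family equals the family size — an
exact invariant under test. Published per-species "codon transcription"
totals produced by legacy software are not reproducible from stated inputs
and are not asserted anywhere; the package's convention is the explicit
one above.

## Nei–Gojobori Ka/Ks

Site counts per codon position are the fraction of single-nucleotide
changes that are synonymous *among changes that do not create a stop
codon* (so sites sum to ≤ 3); the `include-stops` variant divides by all
three changes and counts stop-creating changes as nonsynonymous.
Differences for codons differing at d positions are averaged over the d!
mutational pathways that avoid stop intermediates; if all pathways are
blocked the codon falls back to all pathways and the result carries a
flag. Codon pairs containing gaps, ambiguity, or a stop codon in either
sequence are dropped pairwise. Proportions pS = Sd/S and pN = Nd/N are
Jukes–Cantor corrected; p ≥ 3/4 yields an infinite (saturated) distance,
and Ka/Ks is reported as undefined (`None`) rather than 0 or ∞ when
Ks = 0. The implementation is checked against an independent
pathway-enumeration oracle (Biopython translation, itertools enumeration)
on random codon pairs.

## Diversity and saturation

π is the mean pairwise per-site difference proportion. Columns containing
any gap/ambiguity are excluded alignment-wide before comparison (complete
deletion, the DnaSP-style default); `deletion="pairwise"` switches to
per-pair exclusion. The sliding window starts at 1 and advances by the
step while the window fits (defaults 200/25 bp); an oversized window
degrades to a single truncated, flagged window. K2P distances use the
closed form from transition/transversion proportions over pairwise-ungapped
sites, with an infinite-distance marker outside the log domain.

## CSB motifs and cloverleaf heuristic

The CSB scan is IUPAC-aware Hamming matching (motif symbol set must
contain the query base), best hit = fewest mismatches then leftmost, absent
motifs reported as `None`. The published CSB consensus sequences for this
genus are only available graphically, so the packaged motif set
(`csb_motifs_synthetic.yaml`) contains synthetic placeholders with the
reported domain lengths (CSB-D 18, CSB-1 22, CSB-2 17, CSB-3 19 bp); real
analyses must supply real consensus patterns via the same YAML layout.

The cloverleaf check is a transparent pairing heuristic (Watson–Crick +
GU wobble), not a covariance model: acceptor stem = best 7-mer pairing of
the 5′ end against the 3′ end (0–2 discriminator offsets, present at
≥ 5/7 pairs), anticodon arm = best 5-bp stem with 7-nt loop in the middle
third (ties resolved toward mid-sequence, where the anticodon loop sits),
DHU arm = perfect ≥ 3-bp stem between acceptor and anticodon arm, T-arm =
perfect ≥ 4-bp stem between anticodon arm and the 3′ acceptor strand. A
3′-terminal CCA is trimmed first, making the report invariant to its
presence. On randomized backgrounds a spurious competing stem occasionally
outscores the true anticodon arm (a few percent of random constructions);
the heuristic is intended for screening and for generator-constructed
sequences, and is validated only on such constructions.

## Supermatrix and NJ tree

Genes concatenate in canonical vertebrate mitochondrial order (ND1, ND2,
COI, COII, ATP8, ATP6, COIII, ND3, ND4L, ND4, ND5, ND6, CYTB); published
concatenated-PCG datasets rarely state their gene order, so the canonical
order is adopted and documented. Charsets tile the matrix
without overlap; missing taxa are gap-filled per gene and their missing
fraction reported. Exports (relaxed PHYLIP, NEXUS + charsets, RAxML
partition lines) are byte-stable for identical input; per-gene
codon-position sub-partitioning is deliberately not emitted by default.
The NJ tree (scikit-bio's implementation behind `nj_tree`) is a smoke
check for the distance pipeline, with taxa sorted for deterministic
tie-breaks and negative branch lengths clamped to zero; Bayesian/ML
inference belongs to external tools.

## Synthetic data generator

`SimulationSpec` defaults are the study conditions: the packaged 16,541-bp
layout and the published whole-mitogenome composition row (AT fraction
0.5313, AT-skew 0.034, GC-skew −0.288). Per-position sampling uses the
base distribution implied by (AT fraction, skews), so composition targets
hold in expectation with binomial noise (σ ≈ 0.011 for a skew at 16.5 kb;
tests use the ±0.02 band this implies). Constraints are then written on
each PCG's coding strand in template order: start codon ATG (GTG for COI),
terminal TAA/TA/T by size mod 3, and internal in-frame stops resolved by
replacing the stop with a random non-stop *permutation of its own bases* —
a composition-preserving resolution (every code-2 stop has one, e.g.
TAA → ATA). Positions owned by an earlier template feature are never
overwritten; conflicts are logged in `genome.metadata`. In the packaged
layout the overlap-compromised PCGs are ATP6 (start codon inside ATP8),
ND4 (start codon inside ND4L), and ND6 (terminal codon inside ND5); the
other ten PCGs always pass `validate_orf`. Optional switches plant CSB
motifs in the control region and fill tRNA spans with perfect cloverleaves
carrying the annotated anticodons.

`mutate_cds` applies exact counts of synonymous/nonsynonymous
single-nucleotide changes at distinct codons, never creating stops; since
each mutated codon differs at one position, NG86 recovers Sd and Nd
exactly. `generate_alignment` evolves a uniform root along a star (or
two-clade) tree under an exact K2P Markov chain whose branch time is
solved numerically so the *expected* pairwise p-distance equals the
requested divergence; the transition/transversion ratio is the expected
instantaneous count ratio. All randomness flows through a single seeded
numpy generator in fixed order, so outputs are byte-reproducible per seed.

What the generator does *not* emulate: indels, among-site rate variation,
codon-usage selection, replication-origin mutation gradients, and real
tRNA/rRNA secondary structure (unless planted). Passing parameter-recovery
tests therefore demonstrates correctness of the estimators under the
stated generating process, not robustness to real-data complications.

## Problem sizes

Default test and acceptance runs use the 16.5-kb packaged layout, 10-kb
simulated alignments for distance recovery, 100-codon CDS mutagenesis, and
a few hundred random 30-codon pairs for the NG86 oracle equivalence —
sizes chosen so the whole suite completes in seconds while keeping
binomial tolerances tight.
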