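"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: translation goes
through Biopython's table-2 translator, pathway counting through plain
itertools enumeration, and motif matching through a naive
position-by-position scan with a locally defined IUPAC table.
"""

from itertools import combinations, permutations

from Bio.Seq import Seq

MITO_STOPS = {"TAA", "TAG", "AGA", "AGG"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
    "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def aa2(codon: str) -> str:
    """Amino acid under the vertebrate mitochondrial code via Biopython."""
    if codon in MITO_STOPS:
        return "*"
    return str(Seq(codon).translate(table=2))


def site_counts(codon: str):
    """Stop-excluded NG86 site decomposition by direct enumeration."""
    s = n = 0.0
    for pos in range(3):
        outcomes = []
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if mut in MITO_STOPS:
                continue
            outcomes.append(aa2(mut) == aa2(codon))
        if outcomes:
            s += sum(outcomes) / len(outcomes)
            n += (len(outcomes) - sum(outcomes)) / len(outcomes)
    return s, n


def pair_differences(c1: str, c2: str):
    """Pathway-averaged (syn, nonsyn) differences, stop paths excluded."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in permutations(positions):
        cur, steps, blocked = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in MITO_STOPS:
                blocked = True
                break
            steps.append(aa2(cur) == aa2(nxt))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:
        for order in permutations(positions):
            cur, steps = c1, []
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                steps.append(aa2(cur) == aa2(nxt) and nxt not in MITO_STOPS
                             and cur not in MITO_STOPS)
                cur = nxt
            paths.append(steps)
    sd = sum(sum(p) for p in paths) / len(paths)
    nd = sum(len(p) - sum(p) for p in paths) / len(paths)
    return sd, nd


def ng86(seq1: str, seq2: str):
    """Full NG86 (S, N, Sd, Nd) for an aligned in-frame pair."""
    S = N = sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if set(c1 + c2) - set("ACGT") or c1 in MITO_STOPS or c2 in MITO_STOPS:
            continue
        s1, n1 = site_counts(c1)
        s2, n2 = site_counts(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        d_s, d_n = pair_differences(c1, c2)
        sd += d_s
        nd += d_n
    return S, N, sd, nd


def mean_pairwise_p_distance(seqs):
    """pi as the plain mean of pairwise difference proportions over
    columns that are unambiguous in every sequence."""
    cols = [j for j in range(len(seqs[0]))
            if all(s[j] in "ACGT" for s in seqs)]
    props = []
    for a, b in combinations(seqs, 2):
        props.append(sum(a[j] != b[j] for j in cols) / len(cols))
    return sum(props) / len(props)


def naive_motif_scan(text: str, motif: str, max_mismatch: int):
    """All (start, mismatches) hits, 1-based, by direct comparison."""
    hits = []
    for i in range(len(text) - len(motif) + 1):
        mism = sum(text[i + j] not in IUPAC[motif[j]]
                   for j in range(len(motif)))
        if mism <= max_mismatch:
            hits.append((i + 1, mism))
    return hits
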