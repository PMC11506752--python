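"""Control-region conserved-sequence-block (CSB) detection and a
transparent tRNA cloverleaf arm heuristic.

The CSB scan is an IUPAC-aware Hamming search: a motif symbol matches a
query base when the base belongs to the symbol's IUPAC set.  The packaged
motif set (``data/csb_motifs_synthetic.yaml``) contains SYNTHETIC
placeholder patterns with the reported teleost domain lengths (CSB-D 18,
CSB-1 22, CSB-2 17, CSB-3 19 bp); supply real consensus motifs for
analyses of real control regions.

The cloverleaf check is a pairing heuristic (Watson-Crick plus GU
wobble), not a covariance model: it looks for the acceptor stem (5' 7-mer
against the 3' end), an anticodon arm (5-bp stem + 7-nt loop) in the
middle third, a DHU arm (>= 3-bp stem) between acceptor and anticodon
arms, and a T-arm (>= 4-bp stem) between the anticodon arm and the 3'
acceptor side.  Mitochondrial tRNA-Ser(AGY) genes, which lack the DHU
arm, report that arm absent.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional

import yaml

from .core import IUPAC_SETS

PAIRED = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # 1-based inclusive in the query
    end: int
    mismatches: int
    matched: str


def motif_search(seq, motif: str, max_mismatch: int = 0,
                 motif_name: str = "") -> list:
    """All positions where the IUPAC motif matches with <= max_mismatch.

    Overlapping hits are allowed; hits are returned left to right.
    """
    text = str(seq).upper()
    pattern = motif.upper()
    bad = [c for c in pattern if c not in IUPAC_SETS]
    if bad:
        raise ValueError(f"invalid IUPAC symbols in motif: {bad}")
    m = len(pattern)
    if m > len(text):
        raise ValueError("motif longer than the searched sequence")
    sets = [IUPAC_SETS[c] for c in pattern]
    hits = []
    for i in range(len(text) - m + 1):
        mism = 0
        for j, allowed in enumerate(sets):
            if text[i + j] not in allowed:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(MotifHit(motif_name or pattern, i + 1, i + m, mism,
                                 text[i:i + m]))
    return hits


def load_default_csb_motifs() -> dict:
    """The packaged synthetic CSB motif configuration."""
    path = importlib.resources.files("mitoprofile.data") / "csb_motifs_synthetic.yaml"
    with path.open() as fh:
        return yaml.safe_load(fh)


def load_csb_motifs(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if "motifs" not in config:
        raise ValueError("motif config must contain a 'motifs' mapping")
    return config


@dataclass(frozen=True)
class CsbAnnotation:
    hits: dict  # motif name -> MotifHit or None (absent within tolerance)
    order: tuple  # expected 5'->3' domain order
    order_ok: bool

    def found(self) -> list:
        return [name for name in self.order if self.hits.get(name) is not None]


def find_csb(cr_seq, motif_config: Optional[dict] = None) -> CsbAnnotation:
    """Best hit per CSB motif in a control-region sequence.

    Best = fewest mismatches, then leftmost.  A motif not found within its
    mismatch tolerance is reported absent (None), never raised.  The
    annotation also reports whether the found domains appear in the
    expected 5'->3' order (CSB-D, CSB-1, CSB-2, CSB-3 by default).
    """
    config = motif_config or load_default_csb_motifs()
    motifs = config["motifs"]
    tolerances = config.get("max_mismatch", {})
    order = tuple(config.get("order", sorted(motifs)))
    hits = {}
    for name, pattern in motifs.items():
        tol = tolerances.get(name, 0)
        found = motif_search(cr_seq, pattern, tol, motif_name=name)
        hits[name] = min(found, key=lambda h: (h.mismatches, h.start)) if found else None
    starts = [hits[name].start for name in order if hits.get(name) is not None]
    return CsbAnnotation(hits=hits, order=order,
                         order_ok=starts == sorted(starts))


# ---------------------------------------------------------------------------
# tRNA cloverleaf heuristic


def _paired_count(seq: str, i: int, j_last: int, length: int) -> int:
    """Pairs formed by seq[i:i+length] against seq[j_last-length+1:j_last+1]
    read antiparallel."""
    return sum((seq[i + k], seq[j_last - k]) in PAIRED for k in range(length))


@dataclass(frozen=True)
class ArmReport:
    present: bool
    stem_length: int
    paired_fraction: float


@dataclass(frozen=True)
class CloverleafReport:
    acceptor: ArmReport
    dhu: ArmReport
    anticodon_arm: ArmReport
    tpc: ArmReport
    anticodon: Optional[str]
    anticodon_matches: Optional[bool] = None  # vs an expected triplet, if given

    @property
    def is_cloverleaf(self) -> bool:
        return (self.acceptor.present and self.anticodon_arm.present
                and self.dhu.present and self.tpc.present)


def _best_stem(seq: str, lo: int, hi: int, stem_lengths, loop_range) -> ArmReport:
    """Best perfect antiparallel stem-loop inside seq[lo:hi].

    Reports the longest stem length for which every position pairs; if
    none, the best paired fraction found at the longest stem length.
    """
    best = ArmReport(False, 0, 0.0)
    for m in sorted(stem_lengths, reverse=True):
        for i in range(lo, hi - 2 * m - min(loop_range) + 1):
            for loop in loop_range:
                end = i + 2 * m + loop  # exclusive
                if end > hi:
                    continue
                paired = _paired_count(seq, i, end - 1, m)
                frac = paired / m
                if paired == m:
                    return ArmReport(True, m, 1.0)
                if frac > best.paired_fraction:
                    best = ArmReport(False, m, frac)
    return best


def fold_trna(seq, expected_anticodon: Optional[str] = None) -> CloverleafReport:
    """Heuristic cloverleaf arm assignment for a mitochondrial tRNA gene.

    Accepts 55-95 nt; a 3'-terminal CCA (added post-transcriptionally, and
    occasionally encoded) is trimmed first, so the report is invariant to
    its presence.
    """
    s = str(seq).upper().replace("U", "T")
    if s.endswith("CCA"):
        s = s[:-3]
    n = len(s)
    if not 55 <= n <= 95:
        raise ValueError(f"tRNA length {n} outside the 55-95 nt range")

    # acceptor stem: 5' 7-mer vs the 3' end, allowing 0-2 trailing
    # (discriminator) nucleotides after the 3' strand of the stem
    best_acc, acc_off = ArmReport(False, 7, 0.0), 0
    for off in range(0, 3):
        paired = _paired_count(s, 0, n - 1 - off, 7)
        frac = paired / 7
        if frac > best_acc.paired_fraction:
            best_acc, acc_off = ArmReport(paired >= 5, 7, frac), off
    acc3_start = n - 7 - acc_off  # first index of the 3' acceptor strand

    # anticodon arm: 5-bp stem + 7-nt loop + 5-bp stem, middle third; ties
    # in pairing resolve toward mid-sequence, where the anticodon loop sits
    ac_best, ac_start, ac_score = ArmReport(False, 5, 0.0), None, None
    for i in range(max(8, n // 3 - 4), min(n - 24, 2 * n // 3) + 1):
        paired = _paired_count(s, i, i + 16, 5)
        score = (paired, -abs(i + 8 - n / 2))
        if ac_score is None or score > ac_score:
            ac_best, ac_start, ac_score = ArmReport(paired >= 4, 5, paired / 5), i, score
    anticodon = s[ac_start + 7:ac_start + 10] if ac_start is not None else None
    matches = None
    if expected_anticodon is not None:
        matches = anticodon == expected_anticodon.upper().replace("U", "T")

    if ac_start is None:
        dhu = tpc = ArmReport(False, 0, 0.0)
    else:
        dhu = _best_stem(s, 7, ac_start, stem_lengths=(3, 4),
                         loop_range=range(3, 11))
        tpc = _best_stem(s, ac_start + 17, acc3_start, stem_lengths=(4, 5),
                         loop_range=range(3, 10))
    return CloverleafReport(acceptor=best_acc, dhu=dhu, anticodon_arm=ac_best,
                            tpc=tpc, anticodon=anticodon,
                            anticodon_matches=matches)
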