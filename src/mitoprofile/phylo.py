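"""Concatenated protein-coding-gene supermatrix construction, partition
export (relaxed PHYLIP, NEXUS charsets, RAxML partition lines), and a
distance-based neighbor-joining smoke tree.

Tree *inference* proper (Bayesian/ML) is delegated to external tools;
this module guarantees bit-stable, partition-annotated inputs for them.
Genes are concatenated in canonical vertebrate mitochondrial gene order.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

#: canonical vertebrate mitochondrial protein-coding gene order
CANONICAL_PCG_ORDER = ("ND1", "ND2", "COI", "COII", "ATP8", "ATP6", "COIII",
                       "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB")


@dataclass
class Supermatrix:
    taxa: list
    rows: dict  # taxon -> concatenated aligned sequence
    charsets: dict  # gene -> (start, end), 1-based inclusive, tiling 1..length
    gene_order: list
    missing_fraction: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def build_supermatrix(per_gene_alignments: dict,
                      gene_order=None) -> Supermatrix:
    """Concatenate per-gene alignments ({gene: {taxon: seq}}) into one matrix.

    Genes appear in canonical mitochondrial order (extras appended
    alphabetically); taxa are matched by exact name across genes, and a
    taxon missing from a gene is gap-filled over that charset and counted
    in its missing fraction.  Empty genes are dropped with a warning.
    """
    import warnings

    cleaned = {}
    for gene, aln in per_gene_alignments.items():
        if not aln:
            warnings.warn(f"gene {gene!r} has no taxa; dropped", stacklevel=2)
            continue
        if not isinstance(aln, dict):
            names = [t for t, _ in aln]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate taxon in gene {gene!r}")
            aln = dict(aln)
        lengths = {len(str(s)) for s in aln.values()}
        if len(lengths) > 1:
            raise ValueError(f"gene {gene!r}: unequal aligned lengths {sorted(lengths)}")
        cleaned[gene] = {t: str(s).upper() for t, s in aln.items()}
    if not cleaned:
        raise ValueError("no non-empty gene alignments")
    if gene_order is None:
        gene_order = ([g for g in CANONICAL_PCG_ORDER if g in cleaned]
                      + sorted(set(cleaned) - set(CANONICAL_PCG_ORDER)))
    taxa = sorted({t for aln in cleaned.values() for t in aln})
    rows = {t: [] for t in taxa}
    charsets = {}
    pos = 1
    missing_bp = {t: 0 for t in taxa}
    for gene in gene_order:
        aln = cleaned[gene]
        glen = len(next(iter(aln.values())))
        charsets[gene] = (pos, pos + glen - 1)
        for t in taxa:
            if t in aln:
                rows[t].append(aln[t])
            else:
                rows[t].append("-" * glen)
                missing_bp[t] += glen
        pos += glen
    total = pos - 1
    return Supermatrix(
        taxa=taxa,
        rows={t: "".join(parts) for t, parts in rows.items()},
        charsets=charsets,
        gene_order=list(gene_order),
        missing_fraction={t: missing_bp[t] / total for t in taxa},
    )


def sanitize_taxon_names(sm: Supermatrix) -> tuple:
    """Whitespace-free taxon labels; returns (renamed matrix, mapping)."""
    mapping = {t: re.sub(r"\s+", "_", t) for t in sm.taxa}
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("taxon name sanitization created a collision")
    return Supermatrix(
        taxa=[mapping[t] for t in sm.taxa],
        rows={mapping[t]: s for t, s in sm.rows.items()},
        charsets=dict(sm.charsets), gene_order=list(sm.gene_order),
        missing_fraction={mapping[t]: f for t, f in sm.missing_fraction.items()},
    ), mapping


def to_phylip(sm: Supermatrix) -> str:
    sm, _ = sanitize_taxon_names(sm)
    width = max(len(t) for t in sm.taxa) + 2
    lines = [f" {len(sm.taxa)} {sm.length}"]
    lines += [f"{t:<{width}}{sm.rows[t]}" for t in sm.taxa]
    return "\n".join(lines) + "\n"


def to_nexus(sm: Supermatrix) -> str:
    sm, _ = sanitize_taxon_names(sm)
    width = max(len(t) for t in sm.taxa) + 2
    out = ["#NEXUS", "", "BEGIN DATA;",
           f"  DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.length};",
           "  FORMAT DATATYPE=DNA MISSING=? GAP=-;", "  MATRIX"]
    out += [f"    {t:<{width}}{sm.rows[t]}" for t in sm.taxa]
    out += ["  ;", "END;", "", "BEGIN SETS;"]
    out += [f"  CHARSET {gene} = {a}-{b};" for gene, (a, b) in sm.charsets.items()]
    out += ["END;", ""]
    return "\n".join(out)


def to_raxml_partitions(sm: Supermatrix) -> str:
    return "".join(f"DNA, {gene} = {a}-{b}\n"
                   for gene, (a, b) in sm.charsets.items())


def export_supermatrix(sm: Supermatrix, prefix) -> dict:
    """Write PHYLIP, NEXUS, and RAxML partition files next to ``prefix``.

    Output is byte-stable for identical input.
    """
    paths = {"phylip": f"{prefix}.phy", "nexus": f"{prefix}.nex",
             "partitions": f"{prefix}.partitions.txt"}
    contents = {"phylip": to_phylip(sm), "nexus": to_nexus(sm),
                "partitions": to_raxml_partitions(sm)}
    for key, path in paths.items():
        with open(path, "w") as fh:
            fh.write(contents[key])
    return paths


def nj_tree(distances, labels=None) -> str:
    """Neighbor-joining newick string from a symmetric distance matrix.

    Labels are ordered lexicographically before agglomeration so ties
    break deterministically; negative branch lengths are clamped to zero.
    Fewer than three taxa yield a trivial tree.
    """
    arr = np.asarray(distances, dtype=float)
    if labels is None:
        labels = [f"t{i + 1}" for i in range(arr.shape[0])]
    labels = [str(l) for l in labels]
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(arr < 0) or np.any(np.diag(arr) != 0):
        raise ValueError("distances must be nonnegative with a zero diagonal")
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    arr = arr[np.ix_(order, order)]
    labels = [labels[i] for i in order]
    if len(labels) == 1:
        return f"{labels[0]};"
    if len(labels) == 2:
        d = arr[0, 1] / 2
        return f"({labels[0]}:{d:g},{labels[1]}:{d:g});"
    tree = _skbio_nj(DistanceMatrix(arr, labels))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
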