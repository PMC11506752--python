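"""Readers and writers: GenBank flat files, FASTA (plain and alignment
mode), and the documented gene-table TSV dialect.

The TSV dialect mirrors published mitogenome annotation tables: header row
``gene  kind  start  stop  strand  anticodon``, 1-based inclusive integer
coordinates without thousands separators, strand symbols ``+``/``-``, and
``.`` for empty anticodons.  A packaged table, ``selene_dorsalis_table1.tsv``,
carries the S. dorsalis (GenBank PP857611) annotation used throughout the
test-suite and the acceptance script.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .core import AnnotatedMitogenome, GeneKind, GeneRecord, NucSequence, Strand

GENE_TABLE_COLUMNS = ("gene", "kind", "start", "stop", "strand", "anticodon")

_KIND_BY_FEATURE = {"CDS": GeneKind.PCG, "tRNA": GeneKind.TRNA, "rRNA": GeneKind.RRNA}
_CR_NAMES = {"D-LOOP", "CONTROL REGION", "CR", "D_LOOP", "PUTATIVE CONTROL REGION"}


def _data_path(name: str):
    return importlib.resources.files("mitoprofile.data").joinpath(name)


def packaged_table1_path():
    """Path to the packaged S. dorsalis annotation table."""
    return _data_path("selene_dorsalis_table1.tsv")


def load_synonym_map() -> dict:
    """Canonical gene-symbol map shipped as package data.

    GenBank mitochondrial gene naming is inconsistent across submitters
    (COX1 vs COI, cob vs CYTB, ...); unknown names pass through unchanged.
    """
    df = pd.read_csv(_data_path("gene_synonyms.tsv"), sep="\t", dtype=str)
    return {a.upper(): c for a, c in zip(df["alias"], df["canonical"])}


_SYNONYMS: Optional[dict] = None


def canonical_gene_name(name: str) -> str:
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = load_synonym_map()
    return _SYNONYMS.get(name.strip().upper(), name.strip())


# ---------------------------------------------------------------------------
# gene-table TSV


def read_gene_table(path, genome_length: Optional[int] = None,
                    sequence: Optional[NucSequence] = None,
                    taxon: str = "", accession: str = "") -> AnnotatedMitogenome:
    """Read a gene-table TSV into a (by default table-only) mitogenome."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns and c != "anticodon"]
    if missing:
        raise ValueError(f"gene table missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in GENE_TABLE_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown gene-table columns: {unknown}", stacklevel=2)
    genes = []
    for _, row in df.iterrows():
        try:
            start, stop = int(row["start"]), int(row["stop"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{row['gene']}: non-integer coordinates "
                f"({row['start']!r}, {row['stop']!r})") from exc
        anticodon = row.get("anticodon")
        if anticodon in (None, ".", "", "nan") or pd.isna(anticodon):
            anticodon = None
        strand = row["strand"].replace("−", "-")  # tolerate minus sign
        genes.append(GeneRecord(
            name=str(row["gene"]),
            kind=GeneKind(row["kind"]),
            start=start,
            stop=stop,
            strand=Strand(strand),
            anticodon=anticodon,
        ))
    return AnnotatedMitogenome(sequence=sequence, genes=genes,
                               genome_length=genome_length,
                               taxon=taxon, accession=accession)


def write_gene_table(genome: AnnotatedMitogenome, path) -> None:
    rows = [{
        "gene": g.name,
        "kind": g.kind.value,
        "start": g.start,
        "stop": g.stop,
        "strand": g.strand.value,
        "anticodon": g.anticodon if g.anticodon else ".",
    } for g in genome.genes]
    pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)


def load_table1(sequence: Optional[NucSequence] = None) -> AnnotatedMitogenome:
    """The packaged S. dorsalis annotation (38 features, 16,541 bp)."""
    return read_gene_table(packaged_table1_path(), sequence=sequence,
                           taxon="Selene dorsalis", accession="PP857611")


# ---------------------------------------------------------------------------
# GenBank


def _feature_name(feature) -> str:
    for key in ("gene", "product", "note"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return feature.type


def read_genbank(path) -> AnnotatedMitogenome:
    """Read one GenBank flat-file record into an AnnotatedMitogenome.

    CDS features become PCGs, tRNA/rRNA keep their kind, D-loop (or a
    misc_feature naming the control region) becomes the CR.  Locations on
    the complement strand map to the light strand; ``join`` locations that
    span the origin of a circular record become wrap-around coordinates.
    """
    record = SeqIO.read(str(path), "genbank")
    if len(record.seq) == 0:
        raise ValueError("GenBank record has no ORIGIN sequence")
    circular = record.annotations.get("topology", "linear") == "circular"
    seq = NucSequence(str(record.seq), circular=circular)
    n = len(seq)
    genes, seen = [], set()
    for feature in record.features:
        if feature.type in _KIND_BY_FEATURE:
            kind = _KIND_BY_FEATURE[feature.type]
            name = canonical_gene_name(_feature_name(feature))
        elif feature.type in ("D-loop", "misc_feature") and \
                _feature_name(feature).strip().upper() in _CR_NAMES:
            kind, name = GeneKind.CR, "CR"
        else:
            continue
        loc = feature.location
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            # origin-spanning join on a circular genome: ends at n, restarts at 1
            if len(parts) == 2 and int(parts[1].end) == n and int(parts[0].start) == 0:
                start, stop = int(parts[1].start) + 1, int(parts[0].end)
            else:
                start, stop = int(parts[0].start) + 1, int(parts[-1].end)
        else:
            start, stop = int(loc.start) + 1, int(loc.end)
        if stop > n or start > n:
            raise ValueError(f"{name}: feature beyond sequence length {n}")
        if stop < start and not circular:
            raise ValueError(f"{name}: reversed coordinates on a linear record")
        if name in seen:  # gene + CDS pairs describe the same locus once
            continue
        seen.add(name)
        strand = Strand.L if loc.strand == -1 else Strand.H
        anticodon = None
        if "anticodon" in feature.qualifiers:
            ac = feature.qualifiers["anticodon"][0]
            anticodon = ac[-4:-1].upper().replace("U", "T") if "seq:" in ac else None
        genes.append(GeneRecord(name, kind, start, stop, strand, anticodon))
    return AnnotatedMitogenome(
        sequence=seq, genes=sorted(genes, key=lambda g: g.start),
        taxon=record.annotations.get("organism", ""), accession=record.id)


def write_genbank(genome: AnnotatedMitogenome, path) -> None:
    """Write a mitogenome (sequence required) as a GenBank flat file."""
    if genome.sequence is None:
        raise ValueError("cannot write GenBank without a sequence")
    record = SeqRecord(
        Seq(genome.sequence.residues),
        id=genome.accession or "SIMULATED",
        name=(genome.accession or "SIMULATED")[:16],
        description=genome.taxon or "simulated mitogenome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.sequence.circular else "linear",
        },
    )
    type_by_kind = {GeneKind.PCG: "CDS", GeneKind.TRNA: "tRNA",
                    GeneKind.RRNA: "rRNA", GeneKind.CR: "D-loop"}
    n = genome.genome_length
    for g in genome.genes:
        strand = -1 if g.strand is Strand.L else 1
        if g.wraps:
            loc = CompoundLocation([FeatureLocation(g.start - 1, n, strand),
                                    FeatureLocation(0, g.stop, strand)])
        else:
            loc = FeatureLocation(g.start - 1, g.stop, strand)
        qualifiers = {"gene": [g.name]}
        if g.kind is GeneKind.CR:
            qualifiers = {"note": ["control region"]}
        record.features.append(SeqFeature(loc, type=type_by_kind[g.kind],
                                          qualifiers=qualifiers))
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alignment: bool = False) -> dict:
    """Read FASTA into an ordered ``{name: residues}`` mapping.

    In alignment mode all records must have equal length.
    """
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if alignment:
        lengths = {len(s) for s in records.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    return records


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    """Write ``{name: residues}`` as FASTA with fixed-width line wrapping."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            seq = str(seq)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
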