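"""Readers/writers and the coordinate conventions used throughout the package.

All in-memory coordinates are 0-based half-open. Conversion to and from
1-based inclusive happens exactly once, at the GFF3/SAM file boundary
(PAF is already 0-based half-open). Sequence strands are ``+``/``-``.

Domain containers:

* :class:`GenomeSequence` - one chromosome/contig of one species.
* :class:`GeneModel` - a single-isoform gene model (exons + CDS span).
* :class:`ReadAlignment` - one read-to-genome alignment segment, in either
  PAF or SAM provenance, with the target resolved to (species, chromosome)
  through a configurable name-prefix map (the two parental references are
  typically concatenated for joint mapping, e.g. ``cbr|chrIV``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("hybrec")

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


@dataclass
class GenomeSequence:
    """An uppercase DNA sequence over {A,C,G,T,N} belonging to one species."""

    species_label: str
    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.chrom_id}: empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"{self.chrom_id}: invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A single-isoform gene model with 0-based half-open intervals."""

    gene_id: str
    chrom_id: str
    strand: str
    exon_intervals: tuple[tuple[int, int], ...]
    cds_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exon_intervals)
        if not exons:
            raise ValueError(f"{self.gene_id}: no exons")
        for s, e in exons:
            if not 0 <= s < e:
                raise ValueError(f"{self.gene_id}: bad exon interval ({s},{e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
        self.exon_intervals = exons
        cs, ce = self.cds_span
        if not (exons[0][0] <= cs < ce <= exons[-1][1]):
            raise ValueError(f"{self.gene_id}: CDS span outside exon hull")
        self.cds_span = (cs, ce)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exon_intervals[0][0], self.exon_intervals[-1][1])


@dataclass
class ReadAlignment:
    """One aligned segment of a read against a (species, chromosome) target.

    ``read_start``/``read_end`` are on the original read (soft/hard clips
    recoverable as the flanks outside this interval); ``identity`` is
    matches over aligned block length.
    """

    read_id: str
    read_len: int
    read_start: int
    read_end: int
    target_species: str
    chrom_id: str
    target_start: int
    target_end: int
    strand: str
    matches: int
    block_len: int
    score: int = 0
    is_secondary: bool = False
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.read_start < self.read_end <= self.read_len):
            raise ValueError(f"{self.read_id}: bad read interval")
        if self.matches > self.block_len:
            raise ValueError(f"{self.read_id}: matches exceed block length")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len if self.block_len else 0.0


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, species_label: str = "") -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records (order preserved)."""
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(species_label, rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[GenomeSequence], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.chrom_id, description="") for r in records),
        str(path),
        "fasta",
    )


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    """Write (read_id, sequence, quality-string) tuples as FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read FASTQ as (read_id, sequence) pairs; qualities are not used."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path, chrom_lengths: dict[str, int] | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive -> 0-based half-open).

    One GeneModel per gene; when several mRNAs exist, the isoform with the
    longest total CDS is kept. Genes without CDS features are skipped with a
    warning. If ``chrom_lengths`` is given, exons outside chromosome bounds
    raise an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        best: tuple[int, list, list, object] | None = None
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
            exons = list(db.children(mrna, featuretype="exon", order_by="start"))
            if not cds:
                continue
            if not exons:
                exons = cds
            total_cds = sum(c.end - c.start + 1 for c in cds)
            if best is None or total_cds > best[0]:
                best = (total_cds, exons, cds, mrna)
        if best is None:
            log.warning("gene %s has no CDS; skipped", gene.id)
            continue
        _, exons, cds, _ = best
        exon_iv = tuple(sorted((e.start - 1, e.end) for e in exons))
        cds_span = (min(c.start - 1 for c in cds), max(c.end for c in cds))
        if chrom_lengths is not None:
            limit = chrom_lengths.get(gene.seqid)
            if limit is not None and exon_iv[-1][1] > limit:
                raise ValueError(f"gene {gene.id}: exon exceeds chromosome bounds")
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, exon_iv, cds_span))
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS; internal -> 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            common = f"{g.chrom_id}\thybrec\t"
            fh.write(f"{common}gene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{common}mRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={mid};Parent={g.gene_id}\n")
            for i, (xs, xe) in enumerate(g.exon_intervals, 1):
                fh.write(
                    f"{common}exon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={mid}.e{i};Parent={mid}\n"
                )
            cs, ce = g.cds_span
            for xs, xe in g.exon_intervals:
                a, b = max(xs, cs), min(xe, ce)
                if a < b:
                    fh.write(
                        f"{common}CDS\t{a + 1}\t{b}\t.\t{g.strand}\t0\tParent={mid}\n"
                    )


# ---------------------------------------------------------------------------
# Alignments (PAF / SAM)
# ---------------------------------------------------------------------------

def resolve_target(name: str, prefix_map: dict[str, str], sep: str = "|") -> tuple[str, str]:
    """Resolve a target sequence name like ``cbr|chrIV`` to (species, chrom)."""
    if sep in name:
        prefix, chrom = name.split(sep, 1)
        if prefix in prefix_map:
            return prefix_map[prefix], chrom
    raise ValueError(f"cannot resolve target name {name!r} with prefix map {prefix_map}")


def _read_paf(path, prefix_map: dict[str, str], sep: str) -> list[ReadAlignment]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            species, chrom = resolve_target(f[5], prefix_map, sep)
            tags = dict(
                (t.split(":", 2)[0], t.split(":", 2)[2]) for t in f[12:] if t.count(":") >= 2
            )
            out.append(
                ReadAlignment(
                    read_id=f[0],
                    read_len=int(f[1]),
                    read_start=int(f[2]),
                    read_end=int(f[3]),
                    target_species=species,
                    chrom_id=chrom,
                    target_start=int(f[7]),
                    target_end=int(f[8]),
                    strand=f[4],
                    matches=int(f[9]),
                    block_len=int(f[10]),
                    is_secondary=tags.get("tp") == "S",
                    is_supplementary=False,
                )
            )
    return out


def _read_sam(path, prefix_map: dict[str, str], sep: str) -> list[ReadAlignment]:
    import pysam

    out = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                skipped += 1
                continue
            species, chrom = resolve_target(rec.reference_name, prefix_map, sep)
            cig = rec.cigartuples or []
            # leading/trailing clips (soft=4, hard=5) define the read interval
            lead = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            tail = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
            m = sum(l for op, l in cig if op in (0, 7, 8))
            ins = sum(l for op, l in cig if op == 1)
            dele = sum(l for op, l in cig if op == 2)
            read_len = lead + m + ins + tail
            block = m + ins + dele
            nm = rec.get_tag("NM") if rec.has_tag("NM") else None
            matches = m - max(nm - ins - dele, 0) if nm is not None else m
            if rec.is_reverse:
                read_start, read_end = tail, tail + m + ins
            else:
                read_start, read_end = lead, lead + m + ins
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    read_len=read_len,
                    read_start=read_start,
                    read_end=read_end,
                    target_species=species,
                    chrom_id=chrom,
                    target_start=rec.reference_start,
                    target_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    matches=matches,
                    block_len=block,
                    is_secondary=rec.is_secondary,
                    is_supplementary=rec.is_supplementary,
                )
            )
    if skipped:
        log.info("skipped %d unmapped SAM records", skipped)
    return out


def read_alignments(
    path, fmt: str, prefix_map: dict[str, str], sep: str = "|"
) -> list[ReadAlignment]:
    """Read PAF or SAM alignments; target names resolved via ``prefix_map``."""
    fmt = fmt.upper()
    if fmt == "PAF":
        return _read_paf(path, prefix_map, sep)
    if fmt == "SAM":
        return _read_sam(path, prefix_map, sep)
    raise ValueError(f"unknown alignment format {fmt!r}")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def read_ortholog_map(path) -> list[tuple[str, str]]:
    """Read a one-to-one ortholog table (columns gene_a, gene_b)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_a, gene_b")
    return list(zip(df["gene_a"].astype(str), df["gene_b"].astype(str)))


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
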