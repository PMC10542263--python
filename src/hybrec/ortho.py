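"""Alignment-length-weighted similarity of one-to-one ortholog pairs.

Each ortholog gene pair is partitioned into three region classes:

* **CDS** - the spliced coding sequence, strand-corrected so it begins with
  the start codon;
* **intron** - the gaps between consecutive exons, in transcription order;
* **intergenic** - the upstream and downstream flanks, where the upstream
  flank runs from the start codon of the gene to the start or stop codon of
  the immediately 5' neighboring gene (whichever faces the gene), and the
  downstream flank likewise from the stop codon to the facing codon of the
  3' neighbor.

Orthologous sequences of each class are locally aligned; the percent
identity of the best alignment is weighted by the ratio of the alignable
length to the length of the larger input, so that a short perfect island in
a long diverged region yields a low similarity. A pair with no alignment
reaching the score floor is classified unalignable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import AlignmentResult, Scoring, gotoh_local, revcomp
from .io import GeneModel, GenomeSequence

log = logging.getLogger("hybrec")


@dataclass
class SequencePartition:
    """CDS / intron / intergenic sequences of one gene, strand-corrected."""

    gene_id: str
    cds_seq: str
    intron_seqs: list[str]
    upstream_seq: str
    downstream_seq: str
    truncated_upstream: bool = False
    truncated_downstream: bool = False

    @property
    def intergenic_seqs(self) -> list[str]:
        return [s for s in (self.upstream_seq, self.downstream_seq) if s]


@dataclass
class SimilarityRecord:
    """Weighted similarity of one region-class comparison of an ortholog pair."""

    pair_id: str
    region_class: str  # CDS | intron | intergenic
    len_a: int
    len_b: int
    alignable: bool
    pid: float | None = None
    aln_len: int | None = None
    weighted_similarity: float | None = None


def _facing_edge(neighbor: GeneModel) -> tuple[int, int]:
    """The neighbor's CDS boundary coordinates (start, end)."""
    return neighbor.cds_span


def partition_gene(
    gene: GeneModel,
    genome: GenomeSequence,
    upstream_neighbor: GeneModel | None = None,
    downstream_neighbor: GeneModel | None = None,
) -> SequencePartition:
    """Extract CDS, introns and intergenic flanks for one gene.

    ``upstream_neighbor``/``downstream_neighbor`` are the genes immediately
    5' and 3' of ``gene`` in its own reading orientation. The flank interval
    runs to the neighbor's nearest CDS boundary (its start codon if the
    neighbor points toward the gene, its stop codon if it points away).
    Missing neighbors truncate the flank at the chromosome end and set a
    flag; a neighbor overlapping the gene is an error.
    """
    seq = genome.sequence
    cs, ce = gene.cds_span
    minus = gene.strand == "-"

    def cut(s: int, e: int) -> str:
        return seq[s:e]

    # coding sequence: exon portions inside the CDS span, spliced
    cds_parts = [cut(max(xs, cs), min(xe, ce)) for xs, xe in gene.exon_intervals if min(xe, ce) > max(xs, cs)]
    cds = "".join(cds_parts)
    introns = [
        cut(e1, s2) for (_, e1), (s2, _) in zip(gene.exon_intervals, gene.exon_intervals[1:])
    ]
    gs, ge = gene.span

    # genomic-left / genomic-right neighbors in gene orientation
    left = upstream_neighbor if not minus else downstream_neighbor
    right = downstream_neighbor if not minus else upstream_neighbor
    trunc_left = trunc_right = False
    if left is not None:
        edge = max(_facing_edge(left))
        if edge > gs:
            raise ValueError(f"{gene.gene_id}: left neighbor {left.gene_id} overlaps the gene")
        left_iv = (edge, cs)
    else:
        left_iv = (0, cs)
        trunc_left = True
    if right is not None:
        edge = min(_facing_edge(right))
        if edge < ge:
            raise ValueError(f"{gene.gene_id}: right neighbor {right.gene_id} overlaps the gene")
        right_iv = (ce, edge)
    else:
        right_iv = (ce, len(seq))
        trunc_right = True

    left_seq = cut(*left_iv)
    right_seq = cut(*right_iv)
    if minus:
        cds = revcomp(cds)
        introns = [revcomp(s) for s in introns[::-1]]
        upstream, downstream = revcomp(right_seq), revcomp(left_seq)
        trunc_up, trunc_down = trunc_right, trunc_left
    else:
        upstream, downstream = left_seq, right_seq
        trunc_up, trunc_down = trunc_left, trunc_right
    return SequencePartition(
        gene.gene_id, cds, introns, upstream, downstream, trunc_up, trunc_down
    )


def align_local(a: str, b: str, scoring: Scoring = Scoring()) -> AlignmentResult | None:
    """Best local alignment, or None when the best score is below the floor.

    The floor (``scoring.min_score``, default 40 = 20 exact matches) is the
    deterministic analogue of "no output" from a word-seeded aligner.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    res = gotoh_local(a, b, scoring)
    if res.score < scoring.min_score:
        return None
    return res


def weighted_similarity(
    a: str, b: str, scoring: Scoring = Scoring(), pair_id: str = "", region_class: str = ""
) -> SimilarityRecord:
    """Percent identity weighted by alignable length over the larger input.

    ``weighted = pid * aln_len / max(len_a, len_b)`` (ratio capped at 1 so
    gap-inflated alignment lengths cannot push the value above pid).
    """
    res = align_local(a, b, scoring)
    if res is None:
        return SimilarityRecord(pair_id, region_class, len(a), len(b), False)
    ratio = min(res.aln_len / max(len(a), len(b)), 1.0)
    return SimilarityRecord(
        pair_id,
        region_class,
        len(a),
        len(b),
        True,
        pid=res.pid,
        aln_len=res.aln_len,
        weighted_similarity=res.pid * ratio,
    )


def _neighbors(genes: list[GeneModel]) -> dict[str, tuple[GeneModel | None, GeneModel | None]]:
    """Map gene_id -> (5' neighbor, 3' neighbor) per chromosome."""
    out: dict[str, tuple[GeneModel | None, GeneModel | None]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom_id, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.span)
        for i, g in enumerate(chrom_genes):
            left = chrom_genes[i - 1] if i > 0 else None
            right = chrom_genes[i + 1] if i + 1 < len(chrom_genes) else None
            if g.strand == "+":
                out[g.gene_id] = (left, right)
            else:
                out[g.gene_id] = (right, left)
    return out


def compare_ortholog_pairs(
    genomes_a: list[GenomeSequence],
    genomes_b: list[GenomeSequence],
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    ortholog_map: list[tuple[str, str]],
    scoring: Scoring = Scoring(),
) -> pd.DataFrame:
    """Per-pair, per-region-class weighted similarities for all orthologs.

    Emits one record for the CDS, one per intron (paired by transcription
    order up to the shorter intron count), and one each for the upstream and
    downstream intergenic flank.
    """
    chrom_a = {g.chrom_id: g for g in genomes_a}
    chrom_b = {g.chrom_id: g for g in genomes_b}
    idx_a = {g.gene_id: g for g in genes_a}
    idx_b = {g.gene_id: g for g in genes_b}
    nb_a = _neighbors(genes_a)
    nb_b = _neighbors(genes_b)
    records: list[SimilarityRecord] = []
    for ga_id, gb_id in ortholog_map:
        ga, gb = idx_a[ga_id], idx_b[gb_id]
        pa = partition_gene(ga, chrom_a[ga.chrom_id], *nb_a[ga_id])
        pb = partition_gene(gb, chrom_b[gb.chrom_id], *nb_b[gb_id])
        pair_id = f"{ga_id}~{gb_id}"
        records.append(weighted_similarity(pa.cds_seq, pb.cds_seq, scoring, pair_id, "CDS"))
        n_int = min(len(pa.intron_seqs), len(pb.intron_seqs))
        if len(pa.intron_seqs) != len(pb.intron_seqs):
            log.warning("%s: intron counts differ (%d vs %d)", pair_id, len(pa.intron_seqs), len(pb.intron_seqs))
        for i in range(n_int):
            if pa.intron_seqs[i] and pb.intron_seqs[i]:
                records.append(
                    weighted_similarity(pa.intron_seqs[i], pb.intron_seqs[i], scoring, pair_id, "intron")
                )
        for sa, sb in ((pa.upstream_seq, pb.upstream_seq), (pa.downstream_seq, pb.downstream_seq)):
            if sa and sb:
                records.append(weighted_similarity(sa, sb, scoring, pair_id, "intergenic"))
    return pd.DataFrame([r.__dict__ for r in records])


def summarize_similarity(records: pd.DataFrame) -> dict:
    """Per-class alignable fractions, similarity stats and pairwise tests.

    Pairwise class comparisons of weighted similarity (alignable records
    only) use the Wilcoxon rank-sum test with Benjamini-Hochberg adjustment;
    classes with no alignable records are skipped with a warning.
    """
    from .stats import adjust_fdr, wilcoxon_ranksum

    summary: dict = {"classes": {}, "comparisons": []}
    classes = sorted(records["region_class"].unique())
    values: dict[str, np.ndarray] = {}
    for cls in classes:
        sub = records[records["region_class"] == cls]
        vals = sub.loc[sub["alignable"], "weighted_similarity"].to_numpy(dtype=float)
        values[cls] = vals
        summary["classes"][cls] = {
            "n": int(len(sub)),
            "alignable_fraction": float(sub["alignable"].mean()),
            "mean_weighted_similarity": float(np.mean(vals)) if vals.size else None,
            "median_weighted_similarity": float(np.median(vals)) if vals.size else None,
        }
    pairs = []
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1:]:
            if values[c1].size == 0 or values[c2].size == 0:
                log.warning("comparison %s vs %s skipped: empty class", c1, c2)
                continue
            pairs.append((c1, c2, wilcoxon_ranksum(values[c1], values[c2])))
    if pairs:
        adj = adjust_fdr([r.p_value for _, _, r in pairs])
        for (c1, c2, res), p_adj in zip(pairs, adj):
            summary["comparisons"].append(
                {
                    "class_a": c1,
                    "class_b": c2,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "p_adjusted": p_adj,
                }
            )
    return summary
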