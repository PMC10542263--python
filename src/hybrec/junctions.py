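"""Recombination-junction calling from long reads aligned to both parents.

A boundary-spanning read is one whose prefix aligns to one parental genome
and whose suffix aligns to the other - the read-level evidence for a
targeted-recombination junction. This module identifies such reads from
PAF/SAM alignments (or maps reads itself with a seed-and-extend wrapper
around the internal local aligner, so toy-scale analyses need no external
mapper), clusters them into junction calls, computes the microhomology
shared by the joined parental flanks, and reports per-parent deletion
ranges relative to the predicted Cas9 cut sites.

Because a microhomology of length h makes the exact junction placement
ambiguous over an h-base window, breakpoints are reported at the leftmost
placement and deletions as ranges of width exactly h (the "8-9 nt" /
"4-5 nt" reporting style); the microhomology itself is computed from the
parental genome sequences, not from the error-bearing reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median_low

from ._align import Scoring, gotoh_local, revcomp
from .guides import CutSite
from .io import GenomeSequence, ReadAlignment

log = logging.getLogger("hybrec")


# ---------------------------------------------------------------------------
# internal read mapping (seed-and-extend over the affine local aligner)
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _seed_clusters(hits: list[tuple[int, int]], diag_gap: int = 120) -> list[list[tuple[int, int]]]:
    """Group (read_pos, genome_pos) seed hits by alignment diagonal."""
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h[1] - h[0], h[0]))
    groups: list[list[tuple[int, int]]] = [[hits[0]]]
    for h in hits[1:]:
        prev = groups[-1][-1]
        if (h[1] - h[0]) - (prev[1] - prev[0]) <= diag_gap:
            groups[-1].append(h)
        else:
            groups.append([h])
    return groups


def map_reads(
    reads: list[tuple[str, str]],
    genomes: list[GenomeSequence],
    k: int = 15,
    min_seeds: int = 3,
    pad: int = 150,
    min_score: int = 60,
    max_kmer_hits: int = 50,
    scoring: Scoring | None = None,
) -> list[ReadAlignment]:
    """Map reads against one or more chromosomes by seed-and-extend.

    Exact k-mer seeds are grouped by diagonal; each seed group is extended
    by the affine-gap local aligner on a padded window. Intended for
    toy-scale genomes; real data should be mapped externally (PAF/SAM input
    to :func:`find_boundary_reads`).
    """
    scoring = scoring or Scoring()
    indexes = [(g, _kmer_index(g.sequence, k)) for g in genomes]
    out: list[ReadAlignment] = []
    for rid, seq in reads:
        L = len(seq)
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            for genome, idx in indexes:
                hits = []
                for p in range(0, len(q) - k + 1):
                    pos = idx.get(q[p : p + k])
                    if pos and len(pos) <= max_kmer_hits:
                        for g in pos:
                            hits.append((p, g))
                for group in _seed_clusters(hits):
                    if len(group) < min_seeds:
                        continue
                    rs = max(min(p for p, _ in group) - pad, 0)
                    re_ = min(max(p for p, _ in group) + k + pad, len(q))
                    gs = max(min(g for _, g in group) - pad, 0)
                    ge = min(max(g for _, g in group) + k + pad, len(genome))
                    res = gotoh_local(q[rs:re_], genome.sequence[gs:ge], scoring)
                    if res.score < min_score:
                        continue
                    qa, qe = rs + res.a_start, rs + res.a_end
                    if strand == "-":
                        read_start, read_end = L - qe, L - qa
                    else:
                        read_start, read_end = qa, qe
                    out.append(
                        ReadAlignment(
                            read_id=rid,
                            read_len=L,
                            read_start=read_start,
                            read_end=read_end,
                            target_species=genome.species_label,
                            chrom_id=genome.chrom_id,
                            target_start=gs + res.b_start,
                            target_end=gs + res.b_end,
                            strand=strand,
                            matches=res.identities,
                            block_len=res.aln_len,
                            score=res.score,
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# boundary reads
# ---------------------------------------------------------------------------

@dataclass
class BoundaryRead:
    """A read split between the two parental genomes across a junction."""

    read_id: str
    segment_a: ReadAlignment
    segment_b: ReadAlignment
    read_gap: int  # unaligned read bases between segments (negative = overlap)
    orientation: str  # collinear | inverted


def find_boundary_reads(
    alignments: list[ReadAlignment],
    species_a: str,
    species_b: str,
    min_clip: int = 100,
    min_identity: float = 0.80,
    min_seg_len: int = 100,
    max_read_gap: int = 50,
) -> list[BoundaryRead]:
    """Select reads with one qualifying segment to each parental genome.

    A read qualifies when its best species-A and species-B segments are
    complementary on read coordinates (each flank left unaligned by one
    segment, at least ``min_clip`` bases, is covered by the other), both
    pass the identity and length floors, and the unaligned gap (or overlap)
    between them is at most ``max_read_gap``. Orientation is collinear when
    the two segments map to the same strand.
    """
    by_read: dict[str, list[ReadAlignment]] = {}
    for aln in alignments:
        if not aln.is_secondary:
            by_read.setdefault(aln.read_id, []).append(aln)
    out: list[BoundaryRead] = []
    for rid, alns in by_read.items():
        best: dict[str, ReadAlignment] = {}
        for aln in alns:
            cur = best.get(aln.target_species)
            if cur is None or aln.score > cur.score or (
                aln.score == cur.score and aln.matches > cur.matches
            ):
                best[aln.target_species] = aln
        if species_a not in best or species_b not in best:
            continue
        sa, sb = best[species_a], best[species_b]
        if min(sa.read_end - sa.read_start, sb.read_end - sb.read_start) < min_seg_len:
            continue
        if sa.identity < min_identity or sb.identity < min_identity:
            continue
        left, right = (sa, sb) if sa.read_start <= sb.read_start else (sb, sa)
        # non-nested, complementary coverage
        if right.read_end <= left.read_end:
            continue
        if left.read_len - left.read_end < min_clip or right.read_start < min_clip:
            continue
        gap = right.read_start - left.read_end
        if abs(gap) > max_read_gap:
            continue
        orientation = "collinear" if sa.strand == sb.strand else "inverted"
        out.append(BoundaryRead(rid, sa, sb, gap, orientation))
    return out


# ---------------------------------------------------------------------------
# junction calls
# ---------------------------------------------------------------------------

@dataclass
class JunctionCall:
    """A consensus recombination junction with per-parent deletion ranges."""

    breakpoint_a: int
    breakpoint_b: int
    orientation: str
    a_is_left: bool
    microhomology_len: int
    n_support: int
    del_a_range: tuple[int, int] | None = None
    del_b_range: tuple[int, int] | None = None
    distal: bool = False
    consensus_junction_seq: str = ""


def _junction_coord(seg: ReadAlignment, is_left: bool) -> int:
    """Genome coordinate of the segment end that faces the junction."""
    if is_left:
        return seg.target_end if seg.strand == "+" else seg.target_start
    return seg.target_start if seg.strand == "+" else seg.target_end


def _shared_window(
    left_seq: str, left_coord: int, left_strand: str,
    right_seq: str, right_coord: int, right_strand: str,
    cap: int = 30,
) -> int:
    """Microhomology: the longest window over which the junction can slide.

    The left flank's maximal extension already includes the shared bases, so
    the window is the largest h for which the h bases ending at the left
    flank's maximal end equal the first h bases of the right flank.
    """
    if left_strand == "+":
        lseq = lambda h: left_seq[left_coord - h : left_coord]
    else:
        lseq = lambda h: revcomp(left_seq[left_coord : left_coord + h])
    if right_strand == "+":
        rseq = lambda h: right_seq[right_coord : right_coord + h]
    else:
        rseq = lambda h: revcomp(right_seq[right_coord - h : right_coord])
    for h in range(cap, 0, -1):
        l = lseq(h)
        if len(l) == h and l == rseq(h):
            return h
    return 0


def call_junction(
    boundary_reads: list[BoundaryRead],
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    cut_a: CutSite | None = None,
    cut_b: CutSite | None = None,
    min_support: int = 3,
    cluster_radius: int = 50,
    far_threshold: int = 10_000,
) -> list[JunctionCall]:
    """Cluster boundary reads and call consensus junctions.

    Reads are clustered by junction-adjacent coordinates on both parents
    (within ``cluster_radius``) and orientation; per cluster the consensus
    maximal segment ends are medians. The microhomology is then computed
    from the parental genomes and the breakpoints reported at the leftmost
    placement, with deletions as [min,max] ranges of width equal to the
    microhomology, counted from each cut site toward the junction. Clusters
    with fewer than ``min_support`` reads are suppressed (logged); calls
    farther than ``far_threshold`` from either cut site are flagged distal.
    """
    if not boundary_reads:
        return []
    feats = []
    for br in boundary_reads:
        actual_a_left = br.segment_a.read_start <= br.segment_b.read_start
        # junction-adjacent genome coordinates (invariant to read orientation)
        ja = _junction_coord(br.segment_a, actual_a_left)
        jb = _junction_coord(br.segment_b, not actual_a_left)
        # canonical frame: species-A segment on the forward strand
        a_left = actual_a_left if br.segment_a.strand == "+" else not actual_a_left
        feats.append((br, a_left, ja, jb))

    # greedy clustering on (orientation, side, ja, jb)
    feats.sort(key=lambda f: (f[0].orientation, f[1], f[2], f[3]))
    clusters: list[list[tuple]] = []
    for f in feats:
        placed = False
        for cl in clusters:
            anchor = cl[0]
            if (
                f[0].orientation == anchor[0].orientation
                and f[1] == anchor[1]
                and abs(f[2] - anchor[2]) <= cluster_radius
                and abs(f[3] - anchor[3]) <= cluster_radius
            ):
                cl.append(f)
                placed = True
                break
        if not placed:
            clusters.append([f])

    calls: list[JunctionCall] = []
    for cl in clusters:
        n = len(cl)
        orientation = cl[0][0].orientation
        a_left = cl[0][1]
        if n < min_support:
            log.info("junction cluster with %d read(s) below min_support; suppressed", n)
            continue
        ja = median_low(sorted(f[2] for f in cl))
        jb = median_low(sorted(f[3] for f in cl))
        # canonical strands: species A forward; B forward iff collinear
        strand_b = "+" if orientation == "collinear" else "-"
        if a_left:
            mh = _shared_window(genome_a.sequence, ja, "+", genome_b.sequence, jb, strand_b)
            bp_a = ja - mh  # left flank pulled back to the leftmost placement
            bp_b = jb
            bp_a_alt, bp_b_alt = ja, jb + mh if strand_b == "+" else jb - mh
        else:
            mh = _shared_window(genome_b.sequence, jb, strand_b, genome_a.sequence, ja, "+")
            bp_b = jb - mh if strand_b == "+" else jb + mh
            bp_a = ja
            bp_a_alt, bp_b_alt = ja + mh, jb
        call = JunctionCall(
            breakpoint_a=bp_a,
            breakpoint_b=bp_b,
            orientation=orientation,
            a_is_left=a_left,
            microhomology_len=mh,
            n_support=n,
        )
        if cut_a is not None:
            d0, d1 = abs(cut_a.position - bp_a), abs(cut_a.position - bp_a_alt)
            call.del_a_range = (min(d0, d1), max(d0, d1))
        if cut_b is not None:
            d0, d1 = abs(cut_b.position - bp_b), abs(cut_b.position - bp_b_alt)
            call.del_b_range = (min(d0, d1), max(d0, d1))
        far_a = cut_a is not None and abs(cut_a.position - bp_a) > far_threshold
        far_b = cut_b is not None and abs(cut_b.position - bp_b) > far_threshold
        call.distal = far_a or far_b
        tmpl = build_junction_template(genome_a, genome_b, bp_a, bp_b, orientation, flank=25)
        call.consensus_junction_seq = tmpl.sequence
        calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# junction templates & support validation
# ---------------------------------------------------------------------------

@dataclass
class JunctionTemplate:
    """A spliced reference across a junction, for read-support validation."""

    sequence: str
    junction_offset: int
    provenance: list[tuple[str, str, tuple[int, int], str]] = field(default_factory=list)
    truncated: bool = False


def build_junction_template(
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    breakpoint_a: int,
    breakpoint_b: int,
    orientation: str = "collinear",
    flank: int = 2000,
) -> JunctionTemplate:
    """Concatenate ``flank`` bases of each parent across the junction.

    Template = A[bp_a-flank : bp_a] + B[bp_b : bp_b+flank] (the species-B
    part reverse-complemented, taken left of bp_b, for inverted
    orientation). Flanks are truncated at chromosome ends with a flag.
    """
    a_lo = max(breakpoint_a - flank, 0)
    left = genome_a.sequence[a_lo:breakpoint_a]
    if orientation == "collinear":
        b_hi = min(breakpoint_b + flank, len(genome_b))
        right = genome_b.sequence[breakpoint_b:b_hi]
        prov_b = (genome_b.species_label, genome_b.chrom_id, (breakpoint_b, b_hi), "+")
        truncated = a_lo > breakpoint_a - flank or (breakpoint_b + flank) > len(genome_b)
    elif orientation == "inverted":
        b_lo = max(breakpoint_b - flank, 0)
        right = revcomp(genome_b.sequence[b_lo:breakpoint_b])
        prov_b = (genome_b.species_label, genome_b.chrom_id, (b_lo, breakpoint_b), "-")
        truncated = (breakpoint_a - flank) < 0 or (breakpoint_b - flank) < 0
    else:
        raise ValueError(f"bad orientation {orientation!r}")
    truncated = truncated or (breakpoint_a - flank) < 0
    return JunctionTemplate(
        sequence=left + right,
        junction_offset=len(left),
        provenance=[
            (genome_a.species_label, genome_a.chrom_id, (a_lo, breakpoint_a), "+"),
            prov_b,
        ],
        truncated=truncated,
    )


def validate_support(
    reads: list[tuple[str, str]],
    template: JunctionTemplate,
    min_span: int = 200,
    scoring: Scoring | None = None,
):
    """Count reads whose alignment spans the junction with margin.

    A read supports the junction when a single local alignment to the
    template covers at least ``min_span/2`` bases on each side of the
    junction offset. Returns (n_support, per-read DataFrame).
    """
    import pandas as pd

    tmpl_genome = GenomeSequence("template", "junction", template.sequence)
    alns = map_reads(reads, [tmpl_genome], scoring=scoring or Scoring())
    half = min_span // 2
    rows = []
    supported = set()
    for aln in alns:
        span_left = template.junction_offset - aln.target_start
        span_right = aln.target_end - template.junction_offset
        if span_left >= half and span_right >= half:
            supported.add(aln.read_id)
            rows.append(
                {
                    "read_id": aln.read_id,
                    "span_left": span_left,
                    "span_right": span_right,
                    "identity": round(aln.identity, 4),
                }
            )
    return len(supported), pd.DataFrame(rows)


def calls_to_dataframe(calls: list[JunctionCall]):
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "breakpoint_a": c.breakpoint_a,
                "breakpoint_b": c.breakpoint_b,
                "orientation": c.orientation,
                "a_is_left": c.a_is_left,
                "microhomology": c.microhomology_len,
                "del_a_min": None if c.del_a_range is None else c.del_a_range[0],
                "del_a_max": None if c.del_a_range is None else c.del_a_range[1],
                "del_b_min": None if c.del_b_range is None else c.del_b_range[0],
                "del_b_max": None if c.del_b_range is None else c.del_b_range[1],
                "n_support": c.n_support,
                "distal": c.distal,
            }
        )
    return pd.DataFrame(rows)
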