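"""Enumeration and species-specificity classification of SpCas9 target sites.

A Cas9 target is a 20-nt protospacer followed by an NGG PAM; the enzyme
makes a blunt double-strand break 3 bp 5' of the PAM (between protospacer
positions 17 and 18). A guide is species-specific when its homologous
counterpart in the other parental genome cannot be cut: either the
counterpart PAM is no longer NGG (PAM polymorphism, the criterion used for
interspecies allele discrimination), or - optionally - the PAM-proximal
seed carries enough mismatches to abolish targeting.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._align import Scoring, revcomp
from .io import GenomeSequence
from .ortho import align_local


@dataclass
class CutSite:
    """A predicted blunt-cut position (between-base coordinate)."""

    species_label: str
    chrom_id: str
    position: int


@dataclass
class GuideCandidate:
    """A 20-nt protospacer + NGG PAM with its predicted cut site.

    ``protospacer_interval`` is 0-based half-open on the forward strand of
    the chromosome; ``counterpart_status`` is filled by
    :func:`classify_specificity`.
    """

    species_label: str
    chrom_id: str
    protospacer: str
    pam: str
    strand: str
    protospacer_interval: tuple[int, int]
    cut_site: CutSite
    counterpart_status: str | None = None
    seed_mismatches: int | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be exactly 20 nt")
        if self.pam[1:3] != "GG":
            raise ValueError(f"PAM {self.pam!r} is not NGG")


def enumerate_targets(
    region: str,
    species_label: str = "",
    chrom_id: str = "",
    offset: int = 0,
) -> list[GuideCandidate]:
    """All SpCas9 target sites (both strands) in a sequence window.

    ``offset`` is the chromosome coordinate of ``region[0]``, so emitted
    intervals and cut positions are chromosome coordinates. Windows shorter
    than 23 nt yield an empty list. Candidates are sorted by protospacer
    start, plus strand first on ties.
    """
    region = region.upper()
    out: list[GuideCandidate] = []
    n = len(region)
    for i in range(n - 22):
        window = region[i : i + 23]
        # plus strand: protospacer then NGG
        if window[21:23] == "GG":
            out.append(
                GuideCandidate(
                    species_label,
                    chrom_id,
                    protospacer=window[:20],
                    pam=window[20:23],
                    strand="+",
                    protospacer_interval=(offset + i, offset + i + 20),
                    cut_site=CutSite(species_label, chrom_id, offset + i + 17),
                )
            )
        # minus strand: CCN at the window start reads NGG on the reverse strand
        if window[0:2] == "CC":
            out.append(
                GuideCandidate(
                    species_label,
                    chrom_id,
                    protospacer=revcomp(window[3:23]),
                    pam=revcomp(window[0:3]),
                    strand="-",
                    protospacer_interval=(offset + i + 3, offset + i + 23),
                    cut_site=CutSite(species_label, chrom_id, offset + i + 6),
                )
            )
    out.sort(key=lambda c: (c.protospacer_interval[0], c.strand))
    return out


def _site_forward_window(candidate: GuideCandidate) -> tuple[int, int]:
    """Chromosome interval of the full 23-nt site (protospacer + PAM)."""
    s, e = candidate.protospacer_interval
    return (s, e + 3) if candidate.strand == "+" else (s - 3, e)


def classify_specificity(
    candidate: GuideCandidate,
    site_context: str,
    counterpart_region: str,
    context_offset: int = 0,
    seed_len: int = 12,
    min_seed_mm: int = 3,
    pam_only: bool = False,
    scoring: Scoring | None = None,
) -> GuideCandidate:
    """Classify a guide against the homologous region of the other parent.

    ``site_context`` is the sequence around the site in the guide's own
    genome (chromosome coordinate of its first base in ``context_offset``),
    typically +/-200 nt; ``counterpart_region`` is the homologous interval
    from the other species. The two are locally aligned and the 23-nt site
    is projected through the alignment:

    * homologous PAM no longer NGG -> ``pam_disrupted`` (species-specific);
    * PAM intact but >= ``min_seed_mm`` mismatches within the ``seed_len``
      PAM-proximal protospacer bases -> ``seed_mismatch`` (species-specific,
      disabled by ``pam_only``);
    * otherwise ``conserved``;
    * site not alignable/covered -> ``counterpart_missing`` (treated as
      species-specific but flagged).
    """
    scoring = scoring or Scoring()
    res = align_local(site_context, counterpart_region, scoring)
    ws, we = _site_forward_window(candidate)
    ws -= context_offset
    we -= context_offset
    if res is None:
        candidate.counterpart_status = "counterpart_missing"
        return candidate

    # project each site position through the alignment columns
    proj: dict[int, int | None] = {}
    for ia, ib in zip(res.a_cols, res.b_cols):
        if ia >= 0:
            proj[int(ia)] = int(ib) if ib >= 0 else None
    # extend the projection ungapped past the alignment ends (local
    # alignments trim terminal mismatches, which would otherwise hide
    # polymorphisms at the very edge of the aligned region)
    for p in range(res.a_end, min(res.a_end + 25, len(site_context))):
        j = res.b_end + (p - res.a_end)
        proj.setdefault(p, j if j < len(counterpart_region) else None)
    for p in range(res.a_start - 1, max(res.a_start - 26, -1), -1):
        j = res.b_start - (res.a_start - p)
        proj.setdefault(p, j if j >= 0 else None)
    covered = [p for p in range(ws, we) if p in proj]
    if len(covered) < we - ws:
        candidate.counterpart_status = "counterpart_missing"
        return candidate

    def counterpart_base(pos: int) -> str | None:
        j = proj.get(pos)
        return counterpart_region[j] if j is not None else None

    # PAM GG positions on the forward strand of the site window
    if candidate.strand == "+":
        gg_pos = [we - 2, we - 1]
        gg_expect = "GG"
    else:
        gg_pos = [ws, ws + 1]
        gg_expect = "CC"
    pam_ok = all(counterpart_base(p) == exp for p, exp in zip(gg_pos, gg_expect))
    if not pam_ok:
        candidate.counterpart_status = "pam_disrupted"
        return candidate

    # seed = PAM-proximal protospacer bases
    if candidate.strand == "+":
        seed_positions = range(we - 3 - seed_len, we - 3)
    else:
        seed_positions = range(ws + 3, ws + 3 + seed_len)
    mm = 0
    for p in seed_positions:
        if counterpart_base(p) != site_context[p]:
            mm += 1
    candidate.seed_mismatches = mm
    if not pam_only and mm >= min_seed_mm:
        candidate.counterpart_status = "seed_mismatch"
    else:
        candidate.counterpart_status = "conserved"
    return candidate


def design_guides(
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    region_a: tuple[int, int],
    region_b: tuple[int, int],
    context: int = 200,
    seed_len: int = 12,
    min_seed_mm: int = 3,
    pam_only: bool = False,
) -> list[GuideCandidate]:
    """Enumerate guides in a species-A window and classify each against B.

    ``region_b`` should be the homologous species-B window (e.g. the
    ortholog gene span); each candidate's +/-``context`` nt neighborhood is
    aligned against it to locate the counterpart site.
    """
    s, e = region_a
    cands = enumerate_targets(genome_a.sequence[s:e], genome_a.species_label, genome_a.chrom_id, offset=s)
    bs, be = region_b
    counterpart = genome_b.sequence[bs:be]
    for cand in cands:
        ws, we = _site_forward_window(cand)
        cs = max(ws - context, 0)
        ce = min(we + context, len(genome_a.sequence))
        classify_specificity(
            cand,
            genome_a.sequence[cs:ce],
            counterpart,
            context_offset=cs,
            seed_len=seed_len,
            min_seed_mm=min_seed_mm,
            pam_only=pam_only,
        )
    return cands
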