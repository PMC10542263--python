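"""Boundary-read detection and junction calling on synthetic recombinants."""

import numpy as np
import pytest

from hybrec._align import revcomp
from hybrec.guides import CutSite
from hybrec.io import GenomeSequence, ReadAlignment
from hybrec.junctions import (
    build_junction_template,
    call_junction,
    calls_to_dataframe,
    find_boundary_reads,
    map_reads,
    validate_support,
)
from hybrec.simulate import (
    JunctionSpec,
    ReadSimParams,
    simulate_hybrid_recombinant,
    simulate_long_reads,
)


def _aln(rid, species, rs, re, ts, te, strand="+", read_len=1000, ident=0.95):
    block = re - rs
    return ReadAlignment(
        read_id=rid, read_len=read_len, read_start=rs, read_end=re,
        target_species=species, chrom_id="c", target_start=ts, target_end=te,
        strand=strand, matches=int(block * ident), block_len=block, score=block,
    )


def _pipeline(A, B, spec, read_params, cuts=True, **call_kw):
    rec, truth = simulate_hybrid_recombinant(A, B, spec)
    reads, _ = simulate_long_reads(rec, read_params)
    alns = map_reads([(r[0], r[1]) for r in reads], [truth.genome_a, truth.genome_b])
    br = find_boundary_reads(alns, "speciesA", "speciesB")
    cut_a = CutSite("speciesA", A.chrom_id, spec.cut_a) if cuts else None
    cut_b = CutSite("speciesB", B.chrom_id, spec.cut_b) if cuts else None
    calls = call_junction(br, truth.genome_a, truth.genome_b, cut_a, cut_b, **call_kw)
    return rec, truth, reads, br, calls


# ---------------------------------------------------------------------------
# boundary-read selection rules
# ---------------------------------------------------------------------------

def test_single_species_read_excluded():
    alns = [_aln("r1", "speciesA", 0, 900, 100, 1000)]
    assert find_boundary_reads(alns, "speciesA", "speciesB") == []


def test_short_second_segment_excluded():
    alns = [
        _aln("r1", "speciesA", 0, 860, 100, 960),
        _aln("r1", "speciesB", 860, 900, 0, 40),  # 40 nt < min_seg_len
    ]
    assert find_boundary_reads(alns, "speciesA", "speciesB") == []


def test_low_identity_segment_excluded():
    alns = [
        _aln("r1", "speciesA", 0, 500, 100, 600),
        _aln("r1", "speciesB", 500, 900, 0, 400, ident=0.5),
    ]
    assert find_boundary_reads(alns, "speciesA", "speciesB") == []


def test_large_read_gap_excluded():
    alns = [
        _aln("r1", "speciesA", 0, 400, 100, 500),
        _aln("r1", "speciesB", 600, 900, 0, 300),  # 200 nt unaligned gap
    ]
    assert find_boundary_reads(alns, "speciesA", "speciesB") == []


def test_qualifying_chimeric_read_included_with_gap():
    alns = [
        _aln("r1", "speciesA", 0, 500, 100, 600),
        _aln("r1", "speciesB", 510, 900, 0, 390),
    ]
    out = find_boundary_reads(alns, "speciesA", "speciesB")
    assert len(out) == 1
    assert out[0].read_gap == 10
    assert out[0].orientation == "collinear"


def test_error_free_chimeric_read_has_zero_gap(parent_genomes):
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=3000, del_a=4, del_b=8)
    rec, truth = simulate_hybrid_recombinant(A, B, spec)
    read = rec.sequence[2500:3500]
    alns = map_reads([("r", read)], [truth.genome_a, truth.genome_b])
    br = find_boundary_reads(alns, "speciesA", "speciesB")
    assert len(br) == 1
    assert br[0].read_gap == 0


# ---------------------------------------------------------------------------
# junction calls
# ---------------------------------------------------------------------------

def test_collinear_junction_recovered_exactly(parent_genomes):
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=3000, del_a=4, del_b=8)
    _, truth, _, br, calls = _pipeline(A, B, spec, ReadSimParams(coverage=20, seed=1))
    assert len(calls) == 1
    c = calls[0]
    assert c.breakpoint_a == truth.junction["breakpoint_a"]
    assert c.breakpoint_b == truth.junction["breakpoint_b"]
    assert c.del_a_range == (4, 4)
    assert c.del_b_range == (8, 8)
    assert c.microhomology_len == 0
    assert not c.distal


def test_microhomology_widens_deletion_ranges(parent_genomes):
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=3000, del_a=4, del_b=8, microhomology_len=1)
    _, truth, _, _, calls = _pipeline(A, B, spec, ReadSimParams(coverage=20, seed=2))
    c = calls[0]
    assert c.microhomology_len == 1
    # ranges of width mh containing the true values (the "8-9"/"4-5" style)
    assert c.del_a_range[1] - c.del_a_range[0] == 1
    assert c.del_b_range[1] - c.del_b_range[0] == 1
    assert c.del_a_range[0] <= 4 <= c.del_a_range[1]
    assert c.del_b_range[0] <= 8 <= c.del_b_range[1]


def test_inverted_junction_orientation_and_breakpoints(parent_genomes):
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=3000, del_a=5, del_b=10, orientation="inverted")
    _, truth, _, _, calls = _pipeline(A, B, spec, ReadSimParams(coverage=20, seed=3))
    assert len(calls) == 1
    c = calls[0]
    assert c.orientation == "inverted"
    assert c.breakpoint_a == truth.junction["breakpoint_a"]
    assert c.breakpoint_b == truth.junction["breakpoint_b"]
    assert c.del_a_range == (5, 5)
    assert c.del_b_range == (10, 10)


def test_orientation_inference_invariant_under_read_reverse_complement(parent_genomes):
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=3000, del_a=4, del_b=8)
    rec, truth = simulate_hybrid_recombinant(A, B, spec)
    reads, _ = simulate_long_reads(rec, ReadSimParams(coverage=10, seed=4))
    flipped = [(rid, revcomp(seq)) for rid, seq, _ in reads]
    alns = map_reads(flipped, [truth.genome_a, truth.genome_b])
    br = find_boundary_reads(alns, "speciesA", "speciesB")
    calls = call_junction(
        br, truth.genome_a, truth.genome_b,
        CutSite("speciesA", "chrA", 3000), CutSite("speciesB", "chrB", 3000),
    )
    assert len(calls) == 1
    assert calls[0].orientation == "collinear"
    assert calls[0].breakpoint_a == truth.junction["breakpoint_a"]
    assert calls[0].breakpoint_b == truth.junction["breakpoint_b"]


def test_missing_cut_sites_still_reports_breakpoints(parent_genomes):
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=3000, del_a=4, del_b=8)
    _, truth, _, _, calls = _pipeline(A, B, spec, ReadSimParams(coverage=10, seed=5), cuts=False)
    c = calls[0]
    assert c.del_a_range is None and c.del_b_range is None
    assert c.breakpoint_a == truth.junction["breakpoint_a"]


def test_no_false_calls_on_parental_reads(parent_genomes):
    A, B = parent_genomes
    for seed in range(3):
        reads, _ = simulate_long_reads(A, ReadSimParams(coverage=8, seed=seed))
        alns = map_reads([(r[0], r[1]) for r in reads], [A, B])
        br = find_boundary_reads(alns, "speciesA", "speciesB")
        calls = call_junction(br, A, B) if br else []
        assert calls == []


# ---------------------------------------------------------------------------
# templates and support validation
# ---------------------------------------------------------------------------

def test_template_is_hand_spliced_string(parent_genomes):
    A, B = parent_genomes
    t = build_junction_template(A, B, 3000, 3000, "collinear", flank=5)
    assert t.sequence == A.sequence[2995:3000] + B.sequence[3000:3005]
    assert t.junction_offset == 5
    ti = build_junction_template(A, B, 3000, 3000, "inverted", flank=5)
    assert ti.sequence == A.sequence[2995:3000] + revcomp(B.sequence[2995:3000])


def test_template_remaps_to_itself_full_length(parent_genomes):
    A, B = parent_genomes
    t = build_junction_template(A, B, 3000, 3000, flank=500)
    g = GenomeSequence("template", "t", t.sequence)
    alns = map_reads([("self", t.sequence)], [g])
    full = [a for a in alns if a.target_start == 0 and a.target_end == 1000]
    assert len(full) == 1
    assert full[0].identity == 1.0


def test_support_counting(parent_genomes):
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=3000, del_a=4, del_b=8)
    rec, truth = simulate_hybrid_recombinant(A, B, spec)
    template = build_junction_template(
        A, B, truth.junction["breakpoint_a"], truth.junction["breakpoint_b"], flank=1500
    )
    # error-free reads from the template itself: all junction spanners support
    reads, rtruth = simulate_long_reads(
        GenomeSequence("t", "t", template.sequence),
        ReadSimParams(coverage=5, sub_rate=0, ins_rate=0, del_rate=0, seed=6),
    )
    n, report = validate_support([(r[0], r[1]) for r in reads], template)
    off = template.junction_offset
    spanning = sum(
        1 for s, e, _ in rtruth.read_origins.values() if s <= off - 100 and e >= off + 100
    )
    assert n == spanning > 0
    # reads from pure parent A: no support
    reads_a, _ = simulate_long_reads(A, ReadSimParams(coverage=2, seed=7))
    n0, _ = validate_support([(r[0], r[1]) for r in reads_a], template)
    assert n0 == 0


def test_noisy_reads_recover_most_spanners(parent_genomes):
    """20x reads at 10% error: >=90% of junction-overlapping reads support."""
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=3000, del_a=4, del_b=8)
    rec, truth = simulate_hybrid_recombinant(A, B, spec)
    template = build_junction_template(
        A, B, truth.junction["breakpoint_a"], truth.junction["breakpoint_b"], flank=2000
    )
    reads, rtruth = simulate_long_reads(
        rec, ReadSimParams(coverage=20, sub_rate=0.06, ins_rate=0.02, del_rate=0.02, seed=8)
    )
    j = truth.junction["breakpoint_a"]  # junction position on the recombinant
    spanning = {
        rid for rid, (s, e, _) in rtruth.read_origins.items()
        if s <= j - 150 and e >= j + 150
    }
    n, report = validate_support([(r[0], r[1]) for r in reads], template)
    recovered = spanning & set(report["read_id"])
    assert len(spanning) >= 10
    assert len(recovered) / len(spanning) >= 0.9


def test_calls_dataframe_columns(parent_genomes):
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=3000, del_a=4, del_b=8)
    *_, calls = _pipeline(A, B, spec, ReadSimParams(coverage=10, seed=9))
    df = calls_to_dataframe(calls)
    assert {"breakpoint_a", "breakpoint_b", "del_a_min", "del_b_max", "n_support", "distal"} <= set(df.columns)
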