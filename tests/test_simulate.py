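"""Simulator contracts: determinism, truth completeness, recovery of rates."""

import numpy as np
import pytest
from scipy import stats as sps

from hybrec._align import revcomp
from hybrec.simulate import (
    JunctionSpec,
    ReadSimParams,
    SpeciesPairParams,
    default_size_dists,
    simulate_hybrid_recombinant,
    simulate_introgression_table,
    simulate_long_reads,
    simulate_screen,
    simulate_species_pair,
)


# ---------------------------------------------------------------------------
# species pair
# ---------------------------------------------------------------------------

def test_zero_divergence_yields_identical_genomes():
    p = SpeciesPairParams(
        seed=2, cds_divergence=0, intron_divergence=0, intron_indel_rate=0,
        intergenic_unalignable_frac=0, n_genes=8, chrom_len=24_000,
    )
    ga, gb, gna, gnb, omap, _ = simulate_species_pair(p)
    assert ga[0].sequence == gb[0].sequence
    assert len(omap) == 8


def test_species_pair_is_deterministic():
    p = SpeciesPairParams(seed=9, n_genes=6, chrom_len=18_000)
    out1 = simulate_species_pair(p)
    out2 = simulate_species_pair(SpeciesPairParams(seed=9, n_genes=6, chrom_len=18_000))
    assert out1[0][0].sequence == out2[0][0].sequence
    assert out1[1][0].sequence == out2[1][0].sequence


def test_cds_divergence_recovers_requested_rate():
    """Realized CDS mismatch fraction within 3 binomial SE of the parameter."""
    p = SpeciesPairParams(seed=4, cds_divergence=0.10, n_genes=20, chrom_len=60_000)
    *_, truth = simulate_species_pair(p)
    cds_len = sum(v["cds_len"] for v in truth.gene_divergence.values())
    subs = sum(v["cds_subs"] for v in truth.gene_divergence.values())
    assert cds_len >= 10_000
    se = np.sqrt(0.10 * 0.90 / cds_len)
    assert abs(subs / cds_len - 0.10) <= 3 * se


def test_ortholog_truth_is_one_to_one():
    p = SpeciesPairParams(seed=5, n_genes=10, chrom_len=30_000)
    _, _, gna, gnb, omap, _ = simulate_species_pair(p)
    assert len(omap) == len({a for a, _ in omap}) == len({b for _, b in omap}) == 10
    assert {g.gene_id for g in gna} == {a for a, _ in omap}
    assert {g.gene_id for g in gnb} == {b for _, b in omap}


def test_inversion_reverses_gene_order_and_strand():
    p = SpeciesPairParams(seed=6, n_genes=6, chrom_len=18_000,
                          inversion_specs=((0, (2800, 14_800)),))
    _, _, gna, gnb, omap, _ = simulate_species_pair(p)
    inside_a = [g for g in gna if 2800 <= g.span[0] and g.span[1] <= 14_800]
    assert len(inside_a) >= 2
    b_by_id = {g.gene_id: g for g in gnb}
    pair = dict(omap)
    strands_a = [g.strand for g in inside_a]
    strands_b = [b_by_id[pair[g.gene_id]].strand for g in inside_a]
    assert all(sa != sb for sa, sb in zip(strands_a, strands_b))
    # order along the B chromosome is reversed
    starts_b = [b_by_id[pair[g.gene_id]].span[0] for g in inside_a]
    assert starts_b == sorted(starts_b, reverse=True)


def test_inversion_overlapping_chromosome_end_errors():
    p = SpeciesPairParams(seed=1, inversion_specs=((0, (0, 70_000)),))
    with pytest.raises(ValueError):
        simulate_species_pair(p)


# ---------------------------------------------------------------------------
# hybrid recombinant
# ---------------------------------------------------------------------------

def test_recombinant_length_arithmetic(parent_genomes):
    A, B = parent_genomes
    rec0, _ = simulate_hybrid_recombinant(A, B, JunctionSpec(cut_a=3000, cut_b=3000))
    assert len(rec0) == 3000 + (len(B) - 3000)
    rec1, _ = simulate_hybrid_recombinant(
        A, B, JunctionSpec(cut_a=3000, cut_b=3000, del_a=4, del_b=8)
    )
    assert len(rec0) - len(rec1) == 12


def test_inverted_recombinant_suffix_is_reverse_complement(parent_genomes):
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=3000, del_a=5, del_b=7, orientation="inverted")
    rec, truth = simulate_hybrid_recombinant(A, B, spec)
    e, s = truth.junction["breakpoint_a"], truth.junction["breakpoint_b"]
    assert rec.sequence[e:] == revcomp(truth.genome_b.sequence[:s])
    assert rec.sequence[:e] == truth.genome_a.sequence[:e]


def test_junction_rederivable_by_string_comparison_without_microhomology(parent_genomes):
    """With mh=0, longest prefix/suffix matches recover (cut, del) exactly."""
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=2900, del_a=6, del_b=3)
    rec, truth = simulate_hybrid_recombinant(A, B, spec)
    a = truth.genome_a.sequence
    b = truth.genome_b.sequence
    lcp = 0
    while rec.sequence[lcp] == a[lcp]:
        lcp += 1
    assert lcp == spec.cut_a - spec.del_a
    lcs = 0
    while rec.sequence[-1 - lcs] == b[-1 - lcs]:
        lcs += 1
    assert len(b) - lcs == spec.cut_b + spec.del_b


def test_microhomology_forced_into_parental_flanks(parent_genomes):
    A, B = parent_genomes
    spec = JunctionSpec(cut_a=3000, cut_b=3000, del_a=4, del_b=8, microhomology_len=3)
    rec, truth = simulate_hybrid_recombinant(A, B, spec)
    e, s = truth.junction["breakpoint_a"], truth.junction["breakpoint_b"]
    a, b = truth.genome_a.sequence, truth.genome_b.sequence
    assert a[e : e + 3] == b[s : s + 3]          # shared window across the join
    assert a[e + 3] != b[s + 3]                  # window is exactly 3
    assert a[e - 1] != b[s - 1]


def test_deletion_exceeding_flank_errors(parent_genomes):
    A, B = parent_genomes
    with pytest.raises(ValueError):
        simulate_hybrid_recombinant(A, B, JunctionSpec(cut_a=10, cut_b=3000, del_a=9))


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def test_error_free_reads_are_exact_substrings(parent_genomes):
    A, _ = parent_genomes
    params = ReadSimParams(coverage=2, mean_len=500, sd_len=100,
                           sub_rate=0, ins_rate=0, del_rate=0, seed=3)
    reads, truth = simulate_long_reads(A, params)
    for rid, seq, _ in reads:
        start, end, strand = truth.read_origins[rid]
        frag = A.sequence[start:end]
        assert seq == (frag if strand == "+" else revcomp(frag))


def test_read_simulation_hits_coverage_and_is_deterministic(parent_genomes):
    A, _ = parent_genomes
    params = ReadSimParams(coverage=20, mean_len=1000, sd_len=250, seed=8)
    reads, truth = simulate_long_reads(A, params)
    total = sum(e - s for s, e, _ in truth.read_origins.values())
    assert abs(total - 20 * len(A)) <= 0.10 * 20 * len(A)
    assert len(truth.read_origins) == len(reads)  # truth completeness
    reads2, _ = simulate_long_reads(A, ReadSimParams(coverage=20, mean_len=1000, sd_len=250, seed=8))
    assert reads == reads2


# ---------------------------------------------------------------------------
# swPCR screen
# ---------------------------------------------------------------------------

def test_screen_pattern_logic():
    t0, _ = simulate_screen(50, true_rate=0.0, seed=1)
    assert (t0["upstream_pcr"] == "present").all()
    assert (t0["downstream_pcr"] == "present").all()
    t1, _ = simulate_screen(50, true_rate=1.0, seed=1)
    assert (t1["upstream_pcr"] == "absent").all()
    assert (t1["downstream_pcr"] == "present").all()


def test_screen_count_within_binomial_interval():
    table, truth = simulate_screen(2000, true_rate=0.06, seed=12)
    x = sum(truth.worm_labels.values())
    lo = sps.binom.ppf(0.005, 2000, 0.06)
    hi = sps.binom.ppf(0.995, 2000, 0.06)
    assert lo <= x <= hi
    assert len(truth.worm_labels) == 2000


# ---------------------------------------------------------------------------
# introgression tables
# ---------------------------------------------------------------------------

def test_point_mass_sizes_reproduced_exactly():
    dists = {"I": ("point", 5.0), "IV": ("point", 9.5)}
    table = simulate_introgression_table(10, dists, seed=0)
    assert set(table.loc[table.chromosome == "I", "size_mb"]) == {5.0}
    assert set(table.loc[table.chromosome == "IV", "size_mb"]) == {9.5}


def test_introgression_table_deterministic():
    t1 = simulate_introgression_table(30, default_size_dists(), seed=4)
    t2 = simulate_introgression_table(30, default_size_dists(), seed=4)
    assert t1.equals(t2)
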