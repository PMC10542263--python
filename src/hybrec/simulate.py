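"""Synthetic parental genomes, hybrid recombinants, long reads and screens.

Every simulator is a pure function of its parameters and an explicit seed,
and emits a machine-readable truth record so downstream recovery tests can
compare calls against ground truth.

The species-pair generator emulates the divergence regime of a closely
related nematode pair: coding sequence largely alignable at high identity,
introns and intergenic sequence much more divergent, a configurable fraction
of intergenic intervals fully unalignable, and optional genomic inversions
that reverse local gene order and orientation.

The hybrid-recombinant generator builds a non-homologous end-joining (NHEJ)
style junction: each parent loses a configurable number of bases at its cut
site, optionally with a short microhomology shared by the joined flanks.
Because microhomology makes the exact junction placement ambiguous over a
window, the generator engineers the parental sequences so that the ambiguity
window has exactly the requested length (junction-adjacent bases outside the
microhomology block are forced to mismatch between the parents); the
adjusted parental chromosomes are part of the truth record and should be
used for downstream mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneModel, GenomeSequence
from ._align import revcomp

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPairParams:
    """Parameters of the two-species genome simulator.

    Rates are per site. Defaults emulate the regime reported for the
    *C. briggsae* / *C. nigoni* pair: ~91.4% coding-sequence similarity
    (divergence 0.086), heavily divergent introns, and ~21.1% of intergenic
    intervals unalignable.
    """

    n_chroms: int = 1
    chrom_len: int = 60_000
    n_genes: int = 20
    cds_divergence: float = 0.086
    intron_divergence: float = 0.25
    intron_indel_rate: float = 0.05
    intergenic_unalignable_frac: float = 0.211
    inversion_specs: tuple[tuple[int, tuple[int, int]], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "cds_divergence",
            "intron_divergence",
            "intron_indel_rate",
            "intergenic_unalignable_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        for ci, (s, e) in self.inversion_specs:
            if not (0 <= ci < self.n_chroms):
                raise ValueError(f"inversion on unknown chromosome {ci}")
            if not (0 < s < e < self.chrom_len):
                raise ValueError(f"inversion ({s},{e}) overlaps a chromosome end")


@dataclass
class JunctionSpec:
    """One NHEJ junction between a species-A and a species-B chromosome.

    ``cut_a``/``cut_b`` are between-base coordinates of the Cas9 blunt cuts;
    ``del_a``/``del_b`` count bases resected from each cut toward the
    junction. Orientation ``inverted`` joins the reverse complement of the
    species-B left flank (the layout produced when the targeted region has
    undergone an inversion between the parents).
    """

    cut_a: int
    cut_b: int
    del_a: int = 0
    del_b: int = 0
    microhomology_len: int = 0
    orientation: str = "collinear"

    def validate(self, len_a: int, len_b: int) -> None:
        if self.del_a < 0 or self.del_b < 0 or self.microhomology_len < 0:
            raise ValueError("deletions and microhomology must be >= 0")
        if self.orientation not in ("collinear", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not 0 <= self.cut_a <= len_a or not 0 <= self.cut_b <= len_b:
            raise ValueError("cut coordinate outside chromosome")
        margin = max(20, self.microhomology_len + 15)
        if self.cut_a - self.del_a < margin:
            raise ValueError("del_a exceeds available left flank")
        s = self.cut_b + self.del_b if self.orientation == "collinear" else self.cut_b - self.del_b
        if not margin < s < len_b - margin:
            raise ValueError("del_b exceeds available flank")


@dataclass
class ReadSimParams:
    """Long-read simulator parameters (log-normal lengths, uniform errors)."""

    coverage: float = 20.0
    mean_len: int = 1200
    sd_len: int = 300
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.3:
                raise ValueError(f"{name}={v} outside [0,0.3]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the simulators (fields filled as relevant)."""

    gene_divergence: dict = field(default_factory=dict)
    ortholog_map: list = field(default_factory=list)
    intergenic_randomized: dict = field(default_factory=dict)
    junction: dict = field(default_factory=dict)
    genome_a: GenomeSequence | None = None
    genome_b: GenomeSequence | None = None
    read_origins: dict = field(default_factory=dict)
    worm_labels: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# species pair
# ---------------------------------------------------------------------------

def _rand_seq(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _substitute(rng, seq: str, rate: float) -> tuple[str, int]:
    if rate <= 0 or not seq:
        return seq, 0
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq, 0
    out = list(seq)
    for i in hits:
        old = out[i]
        choices = [b for b in _BASES if b != old]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out), int(hits.size)


def _indel(rng, seq: str, rate: float) -> str:
    """Apply geometric-length (mean 3 nt) insertions/deletions at ``rate``."""
    if rate <= 0 or not seq:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    out = seq
    for i in hits[::-1]:  # right-to-left keeps earlier positions valid
        length = int(rng.geometric(1.0 / 3.0))
        if rng.random() < 0.5:
            out = out[:i] + out[i + length:]
        else:
            out = out[:i] + _rand_seq(rng, length) + out[i:]
    return out


def _gene_structure(rng, slot_len: int) -> list[tuple[str, int]]:
    """Random exon/intron length layout fitting comfortably inside a slot."""
    n_exons = int(rng.integers(3, 6))
    parts: list[tuple[str, int]] = []
    for i in range(n_exons):
        parts.append(("exon", int(rng.integers(90, 241))))
        if i < n_exons - 1:
            parts.append(("intron", int(rng.integers(60, 181))))
    return parts


def simulate_species_pair(params: SpeciesPairParams):
    """Generate a syntenic genome pair with region-class-dependent divergence.

    Returns ``(genomes_a, genomes_b, genes_a, genes_b, ortholog_map, truth)``.
    Genome B is derived from genome A piecewise: coding exons receive
    substitutions only (frame-preserving), introns receive substitutions and
    short indels, and an exact ``intergenic_unalignable_frac`` fraction of
    the intergenic intervals (randomly placed) is fully randomized and hence
    unalignable, the rest mutated like introns. Inversions reverse-complement the
    specified species-B interval, reversing gene order and orientation.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    genomes_a: list[GenomeSequence] = []
    genomes_b: list[GenomeSequence] = []
    genes_a: list[GeneModel] = []
    genes_b: list[GeneModel] = []
    truth = SyntheticTruth()

    per_chrom = [params.n_genes // params.n_chroms] * params.n_chroms
    for i in range(params.n_genes % params.n_chroms):
        per_chrom[i] += 1

    for ci in range(params.n_chroms):
        chrom_a = f"chrA{ci + 1}"
        chrom_b = f"chrB{ci + 1}"
        n_genes = per_chrom[ci]
        seq_a = _rand_seq(rng, params.chrom_len)
        slot = params.chrom_len // max(n_genes, 1)

        # lay out genes on A; record pieces in chromosome order
        pieces: list[dict] = []  # kind, a_interval, gene (or None)
        prev = 0
        gene_layouts = []
        for gi in range(n_genes):
            gene_id = f"gA_{ci + 1}_{gi + 1:03d}"
            start = slot * gi + int(rng.integers(300, 600))
            parts = _gene_structure(rng, slot)
            total = sum(l for _, l in parts)
            if start + total > slot * (gi + 1) - 200:
                start = slot * gi + 300
            strand = "+" if rng.random() < 0.5 else "-"
            pieces.append({"kind": "intergenic", "a": (prev, start), "gene": None})
            pos = start
            exon_iv = []
            for kind, length in parts:
                piece = {"kind": kind, "a": (pos, pos + length), "gene": gene_id}
                pieces.append(piece)
                if kind == "exon":
                    exon_iv.append((pos, pos + length))
                pos += length
            prev = pos
            gene_layouts.append((gene_id, strand, exon_iv))
            genes_a.append(
                GeneModel(gene_id, chrom_a, strand, tuple(exon_iv), (exon_iv[0][0], exon_iv[-1][1]))
            )
        pieces.append({"kind": "intergenic", "a": (prev, params.chrom_len), "gene": None})

        # derive B pieces; an exact fraction of the non-empty intergenic
        # intervals (randomly chosen) is fully randomized ("unalignable")
        ig_ids = [id(p) for p in pieces if p["kind"] == "intergenic" and p["a"][1] > p["a"][0]]
        n_random = int(round(params.intergenic_unalignable_frac * len(ig_ids)))
        chosen = set(
            rng.choice(len(ig_ids), size=n_random, replace=False).tolist()
        ) if n_random else set()
        randomized_ids = {ig_ids[i] for i in chosen}
        ig_index = 0
        for piece in pieces:
            s, e = piece["a"]
            sub = seq_a[s:e]
            if piece["kind"] == "exon":
                mutated, nsub = _substitute(rng, sub, params.cds_divergence)
                piece["b_seq"] = mutated
                gd = truth.gene_divergence.setdefault(
                    piece["gene"], {"cds_len": 0, "cds_subs": 0}
                )
                gd["cds_len"] += len(sub)
                gd["cds_subs"] += nsub
            elif piece["kind"] == "intron":
                mutated, _ = _substitute(rng, sub, params.intron_divergence)
                piece["b_seq"] = _indel(rng, mutated, params.intron_indel_rate)
            else:
                randomized = id(piece) in randomized_ids
                if randomized:
                    piece["b_seq"] = _rand_seq(rng, len(sub))
                else:
                    mutated, _ = _substitute(rng, sub, params.intron_divergence)
                    piece["b_seq"] = _indel(rng, mutated, params.intron_indel_rate)
                truth.intergenic_randomized[f"{chrom_a}:ig{ig_index}"] = randomized
                ig_index += 1
            piece["inverted"] = False

        # apply inversions on the B side (coordinates given on A)
        for inv_ci, (inv_s, inv_e) in params.inversion_specs:
            if inv_ci != ci:
                continue
            first = last = None
            for idx, piece in enumerate(pieces):
                ps, pe = piece["a"]
                if ps >= inv_s and pe <= inv_e:
                    if first is None:
                        first = idx
                    last = idx
                elif ps < inv_e and pe > inv_s:
                    if piece["gene"] is not None:
                        raise ValueError("inversion boundary cuts a gene")
            if first is None:
                raise ValueError("inversion interval contains no complete piece")
            block = pieces[first : last + 1]
            for p in block:
                p["b_seq"] = revcomp(p["b_seq"])
                p["inverted"] = not p["inverted"]
            pieces[first : last + 1] = block[::-1]

        # assemble B and compute B gene models
        offset = 0
        b_parts = []
        gene_b_exons: dict[str, list[tuple[int, int]]] = {}
        gene_b_inverted: dict[str, bool] = {}
        for piece in pieces:
            b_parts.append(piece["b_seq"])
            b_iv = (offset, offset + len(piece["b_seq"]))
            offset = b_iv[1]
            if piece["kind"] == "exon":
                gene_b_exons.setdefault(piece["gene"], []).append(b_iv)
                gene_b_inverted[piece["gene"]] = piece["inverted"]
        seq_b = "".join(b_parts)

        genomes_a.append(GenomeSequence("speciesA", chrom_a, seq_a))
        genomes_b.append(GenomeSequence("speciesB", chrom_b, seq_b))

        for gene_id, strand, _ in gene_layouts:
            exons = sorted(gene_b_exons[gene_id])
            b_strand = strand
            if gene_b_inverted[gene_id]:
                b_strand = "-" if strand == "+" else "+"
            gene_b_id = gene_id.replace("gA_", "gB_")
            genes_b.append(
                GeneModel(gene_b_id, chrom_b, b_strand, tuple(exons), (exons[0][0], exons[-1][1]))
            )
            truth.ortholog_map.append((gene_id, gene_b_id))

    return genomes_a, genomes_b, genes_a, genes_b, list(truth.ortholog_map), truth


# ---------------------------------------------------------------------------
# hybrid recombinant
# ---------------------------------------------------------------------------

def _pick_base(avoid: set[str]) -> str:
    for b in _BASES:
        if b not in avoid:
            return b
    raise RuntimeError("unreachable: cannot avoid all four bases")


_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def simulate_hybrid_recombinant(
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    spec: JunctionSpec,
    guard: int = 12,
) -> tuple[GenomeSequence, SyntheticTruth]:
    """Build a recombinant chromosome with an NHEJ junction.

    Collinear: ``recombinant = A[0 : cut_a - del_a] + B[cut_b + del_b :]``.
    Inverted: the species-B contribution is the reverse complement of
    ``B[0 : cut_b - del_b]``. With ``microhomology_len = h > 0`` the h bases
    of parent A immediately after the junction are forced equal to the first
    h species-B bases entering the recombinant, so the two parental flanks
    share exactly h identical bases across the join and the junction
    placement is ambiguous over exactly that window. Junction-adjacent bases
    outside the window (up to ``guard`` positions) are forced to differ
    between the parents so the ambiguity is exactly ``h``; the adjusted
    parent A is returned in the truth record and must be used for mapping.
    """
    spec.validate(len(genome_a), len(genome_b))
    mh = spec.microhomology_len
    e = spec.cut_a - spec.del_a
    a = list(genome_a.sequence)
    b = genome_b.sequence
    if spec.orientation == "collinear":
        s = spec.cut_b + spec.del_b

        def entry(i: int) -> str:  # i-th species-B base entering after the junction
            return b[s + i]
    else:
        s = spec.cut_b - spec.del_b

        def entry(i: int) -> str:
            return _COMP1[b[s - 1 - i]]

    if e - guard < 0 or e + mh + guard > len(a):
        raise ValueError("junction too close to a chromosome end for guard window")

    # force the microhomology block into parent A just past the junction
    for i in range(mh):
        a[e + i] = entry(i)
    # forward guard: no chance extension of the A flank beyond the block
    for t in range(guard):
        if a[e + mh + t] == entry(mh + t):
            a[e + mh + t] = _pick_base({entry(mh + t)})
    # backward guard: no chance backward extension of the B flank, and no
    # spurious lengthening of the shared window
    if spec.orientation == "collinear":
        def pre(j: int) -> str:  # species-B base j positions before its flank start
            return b[s - j]
    else:
        def pre(j: int) -> str:
            return _COMP1[b[s - 1 + j]]

    for j in range(1, guard + 1):
        avoid = {pre(j), entry(0)}
        if a[e - j] in avoid:
            a[e - j] = _pick_base(avoid)

    seq_a = "".join(a)
    b_part = b[s:] if spec.orientation == "collinear" else revcomp(b[:s])
    rec_seq = seq_a[:e] + b_part
    rec = GenomeSequence("hybrid", f"{genome_a.chrom_id}x{genome_b.chrom_id}", rec_seq)
    adj_a = GenomeSequence(genome_a.species_label, genome_a.chrom_id, seq_a)
    truth = SyntheticTruth(
        genome_a=adj_a,
        genome_b=genome_b,
        junction={
            "breakpoint_a": e,
            "breakpoint_b": s,
            "cut_a": spec.cut_a,
            "cut_b": spec.cut_b,
            "del_a": spec.del_a,
            "del_b": spec.del_b,
            "microhomology_len": mh,
            "orientation": spec.orientation,
        },
    )
    return rec, truth


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def _mutate_read(rng, seq: str, p: ReadSimParams) -> str:
    total = p.sub_rate + p.ins_rate + p.del_rate
    if total <= 0:
        return seq
    rolls = rng.random(len(seq))
    out = []
    for i, base in enumerate(seq):
        r = rolls[i]
        if r < p.del_rate:
            continue
        if r < p.del_rate + p.ins_rate:
            out.append(base)
            out.append(_BASES[rng.integers(0, 4)])
        elif r < total:
            choices = [x for x in _BASES if x != base]
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(base)
    return "".join(out)


def simulate_long_reads(
    template: GenomeSequence, params: ReadSimParams, min_len: int = 60
) -> tuple[list[tuple[str, str, str]], SyntheticTruth]:
    """Simulate error-bearing long reads to ``coverage`` fold.

    Returns FASTQ-ready ``(read_id, sequence, quality)`` tuples plus a truth
    record mapping read_id to its (start, end, strand) source interval on the
    template. Read lengths are log-normal with the requested mean/sd; reads
    are clipped at template ends.
    """
    params.validate()
    L = len(template)
    if L < params.mean_len / 4:
        raise ValueError("template shorter than mean_len/4")
    rng = np.random.default_rng(params.seed)
    sigma2 = np.log(1.0 + (params.sd_len / params.mean_len) ** 2)
    mu = np.log(params.mean_len) - sigma2 / 2.0
    target = params.coverage * L
    reads: list[tuple[str, str, str]] = []
    truth = SyntheticTruth(genome_a=template)
    total = 0
    i = 0
    while total < target:
        start = int(rng.integers(0, L))
        length = int(rng.lognormal(mu, np.sqrt(sigma2)))
        end = min(start + max(length, 1), L)
        if end - start < min_len:
            continue
        frag = template.sequence[start:end]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        seq = _mutate_read(rng, frag, params)
        rid = f"read{i:06d}"
        reads.append((rid, seq, "I" * len(seq)))
        truth.read_origins[rid] = (start, end, strand)
        total += end - start
        i += 1
    return reads, truth


# ---------------------------------------------------------------------------
# swPCR screen
# ---------------------------------------------------------------------------

def simulate_screen(
    n_worms: int,
    true_rate: float,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    fail_rate: float = 0.0,
    seed: int = 0,
    expected_pattern: tuple[str, str] = ("absent", "present"),
    n_replicates: int = 3,
):
    """Simulate dual-flank single-worm PCR outcomes for marker-positive worms.

    Each worm is a true targeted recombinant with probability ``true_rate``;
    recombinants show ``expected_pattern`` (default upstream absent,
    downstream present), non-recombinants show (present, present). Per flank,
    a band that should be absent appears with probability ``fp_rate``, a band
    that should be present drops with ``fn_rate``, and the reaction fails
    outright with ``fail_rate``. Returns (DataFrame, truth).
    """
    import pandas as pd

    for name, v in (("true_rate", true_rate), ("fp_rate", fp_rate), ("fn_rate", fn_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0,1]")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    rows = []

    def observe(state: str) -> str:
        if rng.random() < fail_rate:
            return "failed"
        if state == "present":
            return "absent" if rng.random() < fn_rate else "present"
        return "present" if rng.random() < fp_rate else "absent"

    for w in range(n_worms):
        wid = f"worm{w:05d}"
        is_rec = bool(rng.random() < true_rate)
        truth.worm_labels[wid] = is_rec
        up, down = expected_pattern if is_rec else ("present", "present")
        rows.append(
            {
                "worm_id": wid,
                "replicate": (w % n_replicates) + 1,
                "marker_positive": True,
                "upstream_pcr": observe(up),
                "downstream_pcr": observe(down),
            }
        )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# introgression lines
# ---------------------------------------------------------------------------

DEFAULT_CHROMS = ("I", "II", "III", "IV", "V", "X")


def default_size_dists(shift_iv: float = 0.0) -> dict[str, tuple]:
    """Per-chromosome introgression-size distributions (Mb).

    Baseline normal(7, 2.5) per chromosome, emulating the several-Mb
    introgressions retained after repeated backcrossing; ``shift_iv`` adds a
    known mean shift on chromosome IV for recovery tests.
    """
    d = {c: ("normal", 7.0, 2.5) for c in DEFAULT_CHROMS}
    if shift_iv:
        d["IV"] = ("normal", 7.0 + shift_iv, 2.5)
    return d


def simulate_introgression_table(
    n_lines: int, per_chrom_size_dists: dict[str, tuple], seed: int = 0
):
    """Draw an introgression-line size table (line_id, chromosome, size_mb)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    chroms = list(per_chrom_size_dists)
    rows = []
    for i in range(n_lines):
        chrom = chroms[i % len(chroms)]
        dist = per_chrom_size_dists[chrom]
        if dist[0] == "point":
            size = float(dist[1])
        elif dist[0] == "normal":
            size = float(max(rng.normal(dist[1], dist[2]), 0.2))
        else:
            raise ValueError(f"unknown distribution {dist[0]!r}")
        rows.append({"line_id": f"line{i:04d}", "chromosome": chrom, "size_mb": round(size, 3)})
    return pd.DataFrame(rows)
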