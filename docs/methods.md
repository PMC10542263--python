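# Methods notes

This note records the models, parameter choices and numerical conventions
behind `hybrec`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; cut sites and junction
breakpoints are between-base integers (position *i* = the bond between base
*i−1* and base *i*). Conversion to/from 1-based inclusive coordinates
happens only at the GFF3 and SAM file boundaries; PAF is native 0-based.
When reads are mapped jointly against two concatenated parental references,
target names carry a species prefix (`cbr|chrIV`) resolved through a
configurable prefix map. Multi-isoform genes keep the isoform with the
longest total CDS. `N` bases never match anything in alignments, including
other `N`s.

## Local alignment

The single pairwise engine is an affine-gap Smith–Waterman–Gotoh aligner
(numba-compiled) with blastn-default-like scoring: match +2, mismatch −3,
gap existence 5, gap extension 2 (a length-L gap costs 5 + 2L). Traceback
ties are broken deterministically — diagonal > up > left in the match state,
gap closure preferred over extension inside gap states, and the end cell is
the best-scoring cell earliest in row-major order — so percent identity is
reproducible. An alignment scoring below a floor (default 40, i.e. 20 exact
matches) is reported as absent; this floor is the deterministic desk-scale
analogue of "no output" from a word-seeded aligner, whose exact behaviour
depends on E-value and word size. The test suite checks the aligner
cell-for-cell against an independently written exhaustive DP oracle
(score, alignment length and identities) and against Biopython's
`PairwiseAligner` scores.

## Weighted ortholog similarity

For each one-to-one ortholog pair, sequences are extracted per region
class, strand-corrected to the gene's reading orientation:

* **CDS**: spliced exon portions inside the CDS span;
* **introns**: gaps between consecutive exons, in transcription order,
  paired across species by index;
* **intergenic**: the upstream flank (start codon to the facing CDS edge of
  the immediately 5′ gene) and downstream flank (stop codon to the facing
  CDS edge of the 3′ gene), each contributing its own record. A missing
  neighbor truncates the flank at the chromosome end and sets a flag; an
  overlapping neighbor is an error.

The similarity of an alignable pair is percent identity weighted by the
ratio of alignable length to the larger input length,
`w = pid × aln_len / max(len_a, len_b)` (ratio capped at 1 so gap-inflated
alignment lengths cannot exceed the identity). "Score" here is percent
identity rather than a raw alignment score: the weighted quantity is
reported on a 0–100% similarity scale and must be bounded, which a bitscore
is not. Per-class summaries report alignable fractions and medians/means,
with all pairwise class comparisons by Wilcoxon rank-sum and
Benjamini–Hochberg adjustment.

## Guide model

SpCas9 only: 20-nt protospacer, NGG PAM, blunt cut between protospacer
positions 17|18 (3 bp 5′ of the PAM) — standard SpCas9 biochemistry. A
guide is species-specific when the homologous counterpart site (located by
locally aligning the ±200 nt context and projecting the 23-nt site through
the alignment, with an ungapped extension of the projection up to 25 nt past
the trimmed alignment ends) has lost the GG of its PAM. A seed-mismatch rule
(≥3 mismatches in the 12 PAM-proximal bases) is available as an explicit
extension and is disabled by `pam_only`, since PAM polymorphism alone is the
established discrimination criterion. NAG and other non-canonical PAMs are
ignored.

## Screen statistics

A worm is called a targeted recombinant when its dual-flank swPCR pattern
equals the expected one-sided pattern (default upstream absent / downstream
present, matching a marker distal of the cut; configurable for the mirrored
design); both-present or both-absent is non-recombinant; a failed reaction
on either flank makes the worm ambiguous and removes it from the
denominator (flagged in the report, since published denominators count all
genotyped worms); the opposite one-sided pattern is counted separately as
unexpected. The TR frequency CI is Agresti–Coull with z fixed at 1.96.
Chi-square is Pearson's without continuity correction (a Yates flag is
provided); Fisher's exact test is two-sided by the probability-mass rule.
The Wilcoxon rank-sum test enumerates all group assignments exactly when
the pooled size is ≤ 12 (ties handled by the enumeration) and otherwise
uses the tie-corrected normal approximation without continuity correction.
BH adjustment follows the step-up definition; note it is *not* idempotent
on already-adjusted vectors, which is a property of the procedure itself.

Introgression summaries report overall and per-chromosome means/medians and
two determinations of chromosome-level size differences: the pairwise
chromosome-by-chromosome Wilcoxon grid (BH-adjusted), and a per-chromosome
"versus pooled rest" Wilcoxon (BH over chromosomes). The latter is the
better-powered form of the question "is chromosome IV's introgression size
distribution exceptional?" and is what the acceptance checks use: at 30
lines per chromosome, a +3 Mb mean shift (1.2 SD) does not always push all
five pairwise comparisons below 0.05 after FDR, while the versus-rest test
detects it essentially always.

## Junction calling

Boundary-spanning reads must have one segment per parental genome,
complementary on read coordinates, each ≥100 nt and ≥80% identity, with
≥100 nt clipped where the other segment aligns and at most 50 nt of
unaligned gap (or overlap) between the segments. These thresholds replace a
manual IGV-based selection and are deliberately permissive at Nanopore
error rates; all are configurable. Reads are clustered by junction-adjacent
coordinates (radius 50 nt) and orientation; consensus maximal segment ends
are medians (robust to single-read indel noise), and clusters below 3
supporting reads are suppressed but logged. Calls more than 10 kb from
either cut site are flagged distal, matching the observed ~90–100 kb
off-target recombination events.

Microhomology is computed from the parental genomes, not from the reads:
it is the largest h for which the h bases ending at the left flank's
maximal end equal the first h entering bases of the right flank, i.e. the
window over which the junction can slide without changing the recombinant
sequence. Breakpoints are reported at the leftmost placement and deletions
(counted from each cut toward the junction) as [min, max] ranges whose
width equals the microhomology; the range necessarily contains any
placement convention's value. An insertion at the junction would surface as
a read-gap > 0 and is reported with the call rather than as a negative
deletion.

At toy scale, reads are mapped by a built-in seed-and-extend mapper (exact
15-mer seeds grouped by diagonal, extended with the affine local aligner on
padded windows), so tests and the acceptance script need no external
binary; real datasets should be mapped externally and ingested as PAF/SAM.

## Synthetic data: what it emulates

The species-pair generator derives genome B from genome A piecewise:
substitutions only in coding exons (frame-preserving, default divergence
0.086 per site, matching ~91.4% CDS similarity), substitutions (0.25) plus
geometric mean-3 indels (0.05/site) in introns and alignable intergenic
intervals, and full randomization of an exact fraction (default 0.211) of
intergenic intervals so the "unalignable" code path is genuinely exercised.
Inversions reverse-complement a species-B interval, reversing gene order
and orientation. Default desk scale is one 60 kb chromosome with 20 genes
(~13 kb total CDS) — large enough that binomial noise on recovered rates is
a fraction of a percentage point, small enough that the full similarity
pipeline runs in seconds.

The recombinant generator implements
`A[0 : cut_a − del_a] + B[cut_b + del_b :]` (species-B part
reverse-complemented, taken left of the cut, for inverted junctions). A
requested microhomology of h is engineered by forcing the h parent-A bases
immediately past the junction equal to the first h entering species-B
bases, and forcing junction-adjacent bases outside that window to differ
between parents (guard window 12 nt), so the ambiguity window has exactly
the requested length and truth is well-defined; the adjusted parent A is
returned in the truth record and used for mapping.

Long reads have log-normal lengths (default mean 1200, SD 300 nt), uniform
start positions clipped at template ends, and independent per-base
substitution/insertion/deletion errors (defaults 3%/1%/1% ≈ 5% total).
The screen simulator draws Bernoulli recombinant status per worm and
applies per-flank false-positive/false-negative/failure rates to the
expected PCR pattern. Introgression tables draw per-chromosome sizes from
configurable distributions (default normal(7, 2.5) Mb, emulating
several-Mb introgressions after repeated backcrossing).

None of the generators model homopolymer-biased Nanopore errors, repeats
or transposons, recombination hotspots, or realistic genome-scale gene
density; passing recovery tests therefore demonstrate correctness of the
algorithms under the stated error models, not performance on real
*Caenorhabditis* assemblies, which additionally depends on the external
mapper and on ortholog-inference quality (both out of scope — the ortholog
map is an input).

## Problem sizes used by tests and the acceptance script

Chosen as the package's standard desk scale: similarity recovery on the
default 20-gene/60 kb pair; junction recovery over the
{0,4,8,12} deletion × {0,1,2} microhomology × {collinear, inverted} grid on
6 kb parental chromosomes at 20× coverage and 5% read error, with a
10-seed (tests) / 5-seed (script) parental-read false-call control;
introgression detection at 180 lines (30 per chromosome); screens of
400–2000 worms; Fisher validated against full hypergeometric enumeration
on every 2×2 table with total ≤ 40 (symmetry-deduplicated).

## Known limitations

* One junction per recombinant chromosome is assumed; multiple junctions
  phase into separate clusters but are not jointly phased.
* The internal mapper is exact-seed based; at read error above ~15% or
  segment lengths below ~60 nt its seed density becomes limiting.
* Intron records are paired by transcription-order index; orthologs with
  different intron counts compare only the shared prefix, with a warning.
* The weighted-similarity cap at ratio 1 makes the value equal pid for
  gap-free full-length alignments; heavily gapped alignments are otherwise
  down-weighted.
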