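"""Recombinant calling from swPCR patterns and the frequency/size statistics.

Covers the statistical workflow of a dual-flank targeted-recombination (TR)
screen: per-worm calls from the two flanking PCR bands, TR frequency with an
Agresti-Coull 95% confidence interval, chi-square / Fisher comparisons of
proportions with Benjamini-Hochberg FDR adjustment, Wilcoxon rank-sum tests,
and introgression-line size summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("hybrec")

PCR_STATES = ("present", "absent", "failed")


@dataclass
class ScreenRecord:
    """One worm's dual-flank swPCR outcome and the resulting call."""

    worm_id: str
    marker_positive: bool
    upstream_pcr: str
    downstream_pcr: str
    call: str


@dataclass
class FrequencyEstimate:
    """TR frequency x/n with a 95% Agresti-Coull confidence interval."""

    x: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None


def classify_swpcr(
    marker_positive: bool,
    upstream: str,
    downstream: str,
    expected_recombinant_pattern: tuple[str, str] = ("absent", "present"),
) -> str:
    """Call one worm from its two flanking PCR bands.

    The expected recombinant pattern defaults to (upstream absent,
    downstream present): the retained marker lies distal/right of the cut,
    so a recombinant keeps only the downstream species-specific fragment.
    Both bands present or both absent means no targeted recombination; a
    failed reaction on either flank makes the worm ambiguous; the mirrored
    one-sided pattern is flagged separately as unexpected.
    """
    if not marker_positive:
        raise ValueError("marker-negative worm should not have been genotyped")
    for state in (upstream, downstream):
        if state not in PCR_STATES:
            raise ValueError(f"unknown PCR state {state!r}")
    if upstream == "failed" or downstream == "failed":
        return "ambiguous"
    if (upstream, downstream) == expected_recombinant_pattern:
        return "targeted_recombinant"
    if upstream == downstream:
        return "non_recombinant"
    return "unexpected_recombinant"


def call_screen_table(
    table: pd.DataFrame,
    expected_recombinant_pattern: tuple[str, str] = ("absent", "present"),
) -> pd.DataFrame:
    """Apply :func:`classify_swpcr` to a screen table, adding a ``call`` column."""
    out = table.copy()
    out["call"] = [
        classify_swpcr(bool(r.marker_positive), r.upstream_pcr, r.downstream_pcr, expected_recombinant_pattern)
        for r in table.itertuples()
    ]
    return out


def agresti_coull_interval(x: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Adjusted-count binomial CI: p~ = (x + z^2/2)/(n + z^2), clamped to [0,1]."""
    n_t = n + z * z
    p_t = (x + z * z / 2.0) / n_t
    half = z * math.sqrt(p_t * (1.0 - p_t) / n_t)
    return max(p_t - half, 0.0), min(p_t + half, 1.0)


def tr_frequency(records: pd.DataFrame | None = None, x: int | None = None, n: int | None = None,
                 z: float = 1.96) -> FrequencyEstimate:
    """TR frequency from called screen records, or directly from counts.

    Ambiguous (failed-PCR) worms are excluded from the denominator. The
    confidence interval is Agresti-Coull at z=1.96 (95%), cross-checked in
    the test suite against the closed form.
    """
    if records is not None:
        usable = records[records["call"] != "ambiguous"]
        x = int((usable["call"] == "targeted_recombinant").sum())
        n = int(len(usable))
    if x is None or n is None:
        raise ValueError("provide either records or both x and n")
    if n < 1:
        raise ValueError("no genotyped worms after excluding ambiguous calls")
    if not 0 <= x <= n:
        raise ValueError("x must be between 0 and n")
    lo, hi = agresti_coull_interval(x, n, z)
    return FrequencyEstimate(x, n, x / n, lo, hi)


def compare_proportions(
    x1: int, n1: int, x2: int, n2: int, test: str = "chi_square", yates: bool = False
) -> ComparisonResult:
    """Compare two TR frequencies with a 2x2 chi-square or Fisher exact test.

    Chi-square is Pearson's without continuity correction unless ``yates``;
    Fisher is two-sided by the probability-mass rule (all tables with
    hypergeometric probability at most that of the observed table).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample size must be positive")
        if not 0 <= x <= n:
            raise ValueError("x must be between 0 and n")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    if test == "chi_square":
        res = sps.chi2_contingency(table, correction=yates)
        return ComparisonResult("chi_square", float(res.statistic), float(res.pvalue))
    if test == "fisher_exact":
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return ComparisonResult("fisher_exact", float(odds), float(min(p, 1.0)))
    raise ValueError(f"unknown test {test!r}")


def adjust_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = list(p_values)
    if not p:
        return []
    if any(not 0.0 <= v <= 1.0 for v in p):
        raise ValueError("p-values must lie in [0,1]")
    return list(multipletests(p, method="fdr_bh")[1])


def wilcoxon_ranksum(sample_a, sample_b) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact by enumeration of all group assignments when the pooled size is at
    most 12 (ties handled naturally by the enumeration); otherwise the
    normal approximation with tie correction and no continuity correction.
    The statistic reported is U for sample_a.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 + n2 <= 12:
        total = 0
        extreme = 0
        lo_obs = min(u_obs, n1 * n2 - u_obs)
        idx = range(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            rsum = ranks[list(comb)].sum()
            u = rsum - n1 * (n1 + 1) / 2.0
            total += 1
            if min(u, n1 * n2 - u) <= lo_obs + 1e-9:
                extreme += 1
        p = extreme / total
        return ComparisonResult("wilcoxon_ranksum", u_obs, min(p, 1.0))

    # normal approximation with tie correction
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return ComparisonResult("wilcoxon_ranksum", u_obs, 1.0)
    z = (u_obs - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return ComparisonResult("wilcoxon_ranksum", u_obs, float(min(p, 1.0)))


def replicate_homogeneity(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Fisher tests of TR frequency across technical replicates.

    Expects a called screen table with a ``replicate`` column; returns the
    pairwise comparisons with BH-adjusted p-values.
    """
    counts = []
    for rep, sub in table[table["call"] != "ambiguous"].groupby("replicate"):
        counts.append((rep, int((sub["call"] == "targeted_recombinant").sum()), len(sub)))
    rows = []
    for (r1, x1, n1), (r2, x2, n2) in itertools.combinations(counts, 2):
        res = compare_proportions(x1, n1, x2, n2, test="fisher_exact")
        rows.append({"replicate_a": r1, "replicate_b": r2, "p_value": res.p_value})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = adjust_fdr(df["p_value"].tolist())
    return df


def summarize_introgressions(records: pd.DataFrame) -> dict:
    """Introgression-size summary with pairwise per-chromosome Wilcoxon tests.

    ``records`` needs columns chromosome and size_mb. Medians are the
    midpoint of the central order statistics. Chromosomes with fewer than
    two lines are excluded from pairwise testing; p-values are BH-adjusted.
    """
    if records.empty:
        raise ValueError("no introgression records")
    sizes = records["size_mb"].to_numpy(dtype=float)
    summary: dict = {
        "n_lines": int(len(records)),
        "overall_median_mb": float(np.median(sizes)),
        "overall_mean_mb": float(np.mean(sizes)),
        "overall_max_mb": float(np.max(sizes)),
        "per_chromosome": {},
        "comparisons": [],
    }
    groups: dict[str, np.ndarray] = {}
    for chrom, sub in records.groupby("chromosome"):
        vals = sub["size_mb"].to_numpy(dtype=float)
        groups[str(chrom)] = vals
        summary["per_chromosome"][str(chrom)] = {
            "n": int(vals.size),
            "mean_mb": float(np.mean(vals)),
            "median_mb": float(np.median(vals)),
        }
    testable = {c: v for c, v in groups.items() if v.size >= 2}
    pairs = list(itertools.combinations(sorted(testable), 2))
    results = [wilcoxon_ranksum(testable[c1], testable[c2]) for c1, c2 in pairs]
    if results:
        adj = adjust_fdr([r.p_value for r in results])
        for (c1, c2), res, p_adj in zip(pairs, results, adj):
            summary["comparisons"].append(
                {"chrom_a": c1, "chrom_b": c2, "p_value": res.p_value, "p_adjusted": float(p_adj)}
            )
    # per-chromosome flag: is this chromosome's size distribution different
    # from all other lines pooled? (better powered than the pairwise grid)
    summary["vs_rest"] = {}
    if len(testable) >= 2:
        chroms = sorted(testable)
        ps = []
        for c in chroms:
            rest = np.concatenate([v for k, v in testable.items() if k != c])
            ps.append(wilcoxon_ranksum(testable[c], rest).p_value)
        for c, p, p_adj in zip(chroms, ps, adjust_fdr(ps)):
            summary["vs_rest"][c] = {"p_value": float(p), "p_adjusted": float(p_adj)}
    return summary
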