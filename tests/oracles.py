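"""Independent reference implementations used as test oracles.

These deliberately mirror the *documented rules* (scoring convention,
tie-break order) with a different code structure from the package
implementations, so that agreement is a meaningful check.
"""

from __future__ import annotations

import math
from itertools import combinations


def oracle_local_align(a: str, b: str, match=2, mismatch=-3, gap_open=5, gap_extend=2):
    """Exhaustive affine-gap local alignment on small instances.

    Plain dict-based Gotoh recurrences evaluated cell by cell, followed by a
    traceback applying the documented tie order (diagonal > up > left in the
    match state; closing a gap preferred over extending inside gap states).
    Returns (score, aln_len, identities); (0, 0, 0) when nothing aligns.
    """
    la, lb = len(a), len(b)
    g1 = gap_open + gap_extend
    NEG = -(10**9)
    H = {}
    E = {}
    F = {}
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 or j == 0:
                H[i, j] = 0
                E[i, j] = NEG
                F[i, j] = NEG
                continue
            E[i, j] = max(H[i, j - 1] - g1, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - g1, F[i - 1, j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] and a[i - 1] in "ACGT" else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
    best, bi, bj = 0, 0, 0
    for i in range(la + 1):
        for j in range(lb + 1):
            if H[i, j] > best:
                best, bi, bj = H[i, j], i, j
    if best == 0:
        return 0, 0, 0
    i, j, state = bi, bj, "H"
    aln_len = ident = 0
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            s = match if a[i - 1] == b[j - 1] and a[i - 1] in "ACGT" else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                aln_len += 1
                if s == match:
                    ident += 1
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            aln_len += 1
            state = "H" if F[i, j] == H[i - 1, j] - g1 else "F"
            i -= 1
        else:
            aln_len += 1
            state = "H" if E[i, j] == H[i, j - 1] - g1 else "E"
            j -= 1
    return best, aln_len, ident


def oracle_fisher_two_sided(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration.

    Sums P(tables) with probability <= that of the observed table, for fixed
    margins, using exact binomial coefficients.
    """
    k = x1 + x2
    lo = max(0, k - n2)
    hi = min(k, n1)
    denom = math.comb(n1 + n2, k)
    probs = {t: math.comb(n1, t) * math.comb(n2, k - t) / denom for t in range(lo, hi + 1)}
    p_obs = probs[x1]
    return min(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)), 1.0)


def oracle_wilcoxon_exact(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    from scipy.stats import rankdata

    n1, n2 = len(a), len(b)
    pooled = list(a) + list(b)
    ranks = rankdata(pooled)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    lo_obs = min(u_obs, n1 * n2 - u_obs)
    count = total = 0
    for comb in combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in comb) - n1 * (n1 + 1) / 2
        total += 1
        if min(u, n1 * n2 - u) <= lo_obs + 1e-9:
            count += 1
    return count / total


def oracle_bh(pvals):
    """Benjamini-Hochberg step-up computed straight from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def oracle_scan_guides(region: str):
    """Brute-force SpCas9 site scan, written independently of the package.

    Scans the forward strand of the region and of its reverse complement,
    mirroring minus-strand coordinates back, and returns a set of
    (strand, start, end, protospacer, pam, cut) tuples.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = lambda s: "".join(comp[c] for c in reversed(s))
    n = len(region)
    found = set()
    for i in range(n - 22):
        w = region[i : i + 23]
        if w[21] == "G" and w[22] == "G":
            found.add(("+", i, i + 20, w[:20], w[20:], i + 17))
    rev = rc(region)
    for i in range(n - 22):
        w = rev[i : i + 23]
        if w[21] == "G" and w[22] == "G":
            # mirror coordinates: position p on rev = n-1-p on forward
            start = n - (i + 20)
            end = n - i
            cut = n - (i + 17)
            found.add(("-", start, end, w[:20], w[20:], cut))
    return found
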