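"""Affine-gap local alignment (Gotoh algorithm) with deterministic traceback.

This is the single pairwise-alignment engine of the package. It is used for
ortholog similarity scoring, for locating homologous guide-RNA counterpart
sites, and (via seed-and-extend in :mod:`hybrec.junctions`) for mapping
simulated long reads at toy scale.

Scoring follows the blastn-style convention: a gap of length L costs
``gap_open + gap_extend * L``, i.e. the first gap position is charged
``gap_open + gap_extend``. ``N`` (or any non-ACGT symbol) never matches
anything, including another ``N``.

Traceback ties are broken in a fixed order so results are reproducible:
in the match state, diagonal > up (gap in b) > left (gap in a); inside a gap
state, closing the gap (origin in the match state) is preferred over
extending it. The optimal end cell is the highest-scoring cell with the
smallest (row, column) in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


# base encoding: A=0 C=1 G=2 T=3, everything else (incl. N) = 4
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring scheme (blastn-default-like).

    ``gap_open`` is the gap existence cost; a length-L gap costs
    ``gap_open + gap_extend * L``. ``min_score`` is the floor below which an
    alignment is reported as absent ("unalignable"); 40 corresponds to 20
    exactly matching bases at the default match reward.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    min_score: int = 40


@njit(cache=True)
def _gotoh_kernel(a, b, match, mismatch, gopen1, gext, out_ai, out_bi):  # pragma: no cover - exercised via wrapper
    """Forward DP + traceback.

    ``gopen1`` is the cost of the first gap position (gap_open + gap_extend).
    Returns (score, n_cols, a_start, a_end, b_start, b_end); aligned column
    indices are written into out_ai/out_bi (-1 denotes a gap), in reverse
    order (the wrapper reverses them).
    """
    la = a.shape[0]
    lb = b.shape[0]
    NEG = -(10 ** 9)
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    E = np.full((la + 1, lb + 1), NEG, dtype=np.int64)
    F = np.full((la + 1, lb + 1), NEG, dtype=np.int64)

    best = 0
    bi_ = 0
    bj_ = 0
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            e = E[i, j - 1] - gext
            t = H[i, j - 1] - gopen1
            if t > e:
                e = t
            E[i, j] = e
            f = F[i - 1, j] - gext
            t = H[i - 1, j] - gopen1
            if t > f:
                f = t
            F[i, j] = f
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi_ = i
                bj_ = j

    # traceback
    n = 0
    i = bi_
    j = bj_
    state = 0  # 0=H, 1=F(up), 2=E(left)
    while True:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                s = match
            else:
                s = mismatch
            if h == H[i - 1, j - 1] + s:
                out_ai[n] = i - 1
                out_bi[n] = j - 1
                n += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            out_ai[n] = i - 1
            out_bi[n] = -1
            n += 1
            if F[i, j] == H[i - 1, j] - gopen1:
                state = 0
            i -= 1
        else:
            out_ai[n] = -1
            out_bi[n] = j - 1
            n += 1
            if E[i, j] == H[i, j - 1] - gopen1:
                state = 0
            j -= 1

    return best, n, i, bi_, j, bj_


@dataclass
class AlignmentResult:
    """A best local alignment between two sequences.

    ``pid`` is percent identity over aligned columns (gap columns count
    against identity). Coordinate intervals are 0-based half-open on the
    input sequences. ``a_cols``/``b_cols`` give, per alignment column, the
    participating index in each sequence (-1 = gap).
    """

    score: int
    aln_len: int
    identities: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    a_cols: np.ndarray
    b_cols: np.ndarray

    @property
    def pid(self) -> float:
        return 100.0 * self.identities / self.aln_len if self.aln_len else 0.0


def gotoh_local(a, b, scoring: Scoring = Scoring()) -> AlignmentResult:
    """Best local alignment of ``a`` vs ``b`` under affine-gap scoring.

    Accepts DNA strings or pre-encoded uint8 arrays. Returns a zero-score,
    zero-length result when nothing aligns positively.
    """
    ea = a if isinstance(a, np.ndarray) else encode(a)
    eb = b if isinstance(b, np.ndarray) else encode(b)
    if ea.size == 0 or eb.size == 0:
        raise ValueError("cannot align an empty sequence")
    cap = ea.size + eb.size
    out_ai = np.empty(cap, dtype=np.int64)
    out_bi = np.empty(cap, dtype=np.int64)
    gopen1 = scoring.gap_open + scoring.gap_extend
    score, n, a0, a1, b0, b1 = _gotoh_kernel(
        ea, eb, scoring.match, scoring.mismatch, gopen1, scoring.gap_extend, out_ai, out_bi
    )
    a_cols = out_ai[:n][::-1].copy()
    b_cols = out_bi[:n][::-1].copy()
    ident = 0
    for k in range(n):
        ia = a_cols[k]
        ib = b_cols[k]
        if ia >= 0 and ib >= 0 and ea[ia] == eb[ib] and ea[ia] < 4:
            ident += 1
    if score == 0:
        return AlignmentResult(0, 0, 0, 0, 0, 0, 0, a_cols[:0], b_cols[:0])
    return AlignmentResult(int(score), int(n), int(ident), int(a0), int(a1), int(b0), int(b1), a_cols, b_cols)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]
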