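"""Affine-gap pairwise alignment core.

Implements Gotoh's three-state dynamic programme in two flavours:

* local (Smith-Waterman) — used for germline segment assignment;
* overlap (global with free end gaps) — used for template comparison.

Scoring convention: a gap of length ``L`` scores ``gap_open + (L - 1) *
gap_extend``, i.e. the opening penalty is charged on the first gapped
position.  ``N`` (code 4) scores as a mismatch against every base,
including itself.

The kernels are numba-compiled; the first call in a fresh interpreter
pays a one-off JIT cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba as nb
import numpy as np

# cigar-style op codes used throughout the package
OP_MATCH = 0  # '='
OP_MISMATCH = 1  # 'X'
OP_INS = 2  # 'I': base present in the query (read), absent from the target
OP_DEL = 3  # 'D': base present in the target (germline), absent from the read

OP_CHARS = np.array(["=", "X", "I", "D"])

_NEG = -(10**9)

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap parameters, integer scoring units."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2

    def key(self) -> tuple[int, int, int, int]:
        return (self.match, self.mismatch, self.gap_open, self.gap_extend)

    def matrix(self) -> np.ndarray:
        """5x5 substitution matrix over {A,C,G,T,N}; N mismatches everything."""
        key = self.key()
        m = _NT_MATRIX_CACHE.get(key)
        if m is None:
            m = np.full((5, 5), self.mismatch, dtype=np.int32)
            for i in range(4):
                m[i, i] = self.match
            _NT_MATRIX_CACHE[key] = m
        return m


_NT_MATRIX_CACHE: dict[tuple[int, int, int, int], np.ndarray] = {}


DEFAULT_SCORING = ScoringScheme()


@nb.njit(cache=True, nogil=True)
def _local_score(x, y, sub, gap_open, gap_ext):  # pragma: no cover - jit
    m, n = x.shape[0], y.shape[0]
    H = np.zeros(n + 1, dtype=np.int32)
    Fcol = np.full(n + 1, _NEG, dtype=np.int32)
    best = np.int32(0)
    bi = np.int32(0)
    bj = np.int32(0)
    for i in range(m):
        diag = np.int32(0)
        h_left = np.int32(0)
        e = _NEG
        subrow = sub[x[i]]
        for j in range(n):
            eo = h_left + gap_open
            ee = e + gap_ext
            e = eo if eo > ee else ee
            hj = H[j + 1]
            fo = hj + gap_open
            fe = Fcol[j + 1] + gap_ext
            f = fo if fo > fe else fe
            h = diag + subrow[y[j]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = hj
            H[j + 1] = h
            h_left = h
            Fcol[j + 1] = f
            if h > best:
                best = h
                bi = np.int32(i + 1)
                bj = np.int32(j + 1)
    return best, bi, bj


@nb.njit(cache=True, nogil=True)
def _local_align(x, y, sub, gap_open, gap_ext):  # pragma: no cover - jit
    """Full SW with traceback.

    Returns (score, x_start, x_end, y_start, y_end, ops) where ops is an
    int8 array over OP_* codes, ordered 5'->3'.
    Tie-break inside the DP: diagonal > target-gap (D) > query-gap (I);
    the best cell is the first maximum in row-major order.
    """
    m, n = x.shape[0], y.shape[0]
    H = np.zeros(n + 1, dtype=np.int32)
    E = np.full(n + 1, _NEG, dtype=np.int32)
    # pointers: pH 0=stop 1=diag 2=fromE(D) 3=fromF(I); pE/pF 1=open 0=extend
    pH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = np.int32(0)
    bj = np.int32(0)
    Fcol = np.full(n + 1, _NEG, dtype=np.int32)
    for i in range(1, m + 1):
        diag = np.int32(0)
        h_left = np.int32(0)
        e_left = _NEG
        subrow = sub[x[i - 1]]
        for j in range(1, n + 1):
            e_open = h_left + gap_open
            e_ext = e_left + gap_ext
            if e_open >= e_ext:
                e = e_open
                pE[i, j] = 1
            else:
                e = e_ext
                pE[i, j] = 0
            f_open = H[j] + gap_open
            f_ext = Fcol[j] + gap_ext
            if f_open >= f_ext:
                f = f_open
                pF[i, j] = 1
            else:
                f = f_ext
                pF[i, j] = 0
            h = diag + subrow[y[j - 1]]
            p = np.uint8(1)
            if e > h:
                h = e
                p = np.uint8(2)
            if f > h:
                h = f
                p = np.uint8(3)
            if h <= 0:
                h = 0
                p = np.uint8(0)
            pH[i, j] = p
            diag = H[j]
            H[j] = h
            h_left = h
            e_left = e
            Fcol[j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    ops = np.empty(m + n, dtype=np.int8)
    k = m + n
    i = bi
    j = bj
    state = 0  # 0=H 1=E 2=F
    while i > 0 or j > 0:
        if state == 0:
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                k -= 1
                ops[k] = OP_MATCH if x[i - 1] == y[j - 1] else OP_MISMATCH
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ops[k] = OP_DEL
            p = pE[i, j]
            j -= 1
            if p == 1:
                state = 0
        else:
            k -= 1
            ops[k] = OP_INS
            p = pF[i, j]
            i -= 1
            if p == 1:
                state = 0
    return best, i, bi, j, bj, ops[k:]


@nb.njit(cache=True, nogil=True)
def _overlap_align(x, y, sub, gap_open, gap_ext):  # pragma: no cover - jit
    """Global alignment with free end gaps (overlap/"glocal" mode).

    Returns (score, x_start, x_end, y_start, y_end, ops); the free end
    gaps are outside the reported intervals and not part of ops.
    """
    m, n = x.shape[0], y.shape[0]
    H = np.zeros(n + 1, dtype=np.int32)
    E = np.full(n + 1, _NEG, dtype=np.int32)
    pH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    Fcol = np.full(n + 1, _NEG, dtype=np.int32)
    Hrow = np.zeros(m + 1, dtype=np.int32)  # H[:, n] column store
    for i in range(1, m + 1):
        diag = H[0]
        H[0] = 0  # free left end gap in y
        h_left = np.int32(0)
        e_left = _NEG
        subrow = sub[x[i - 1]]
        for j in range(1, n + 1):
            e_open = h_left + gap_open
            e_ext = e_left + gap_ext
            if e_open >= e_ext:
                e = e_open
                pE[i, j] = 1
            else:
                e = e_ext
                pE[i, j] = 0
            f_open = H[j] + gap_open
            f_ext = Fcol[j] + gap_ext
            if f_open >= f_ext:
                f = f_open
                pF[i, j] = 1
            else:
                f = f_ext
                pF[i, j] = 0
            h = diag + subrow[y[j - 1]]
            p = np.uint8(1)
            if e > h:
                h = e
                p = np.uint8(2)
            if f > h:
                h = f
                p = np.uint8(3)
            pH[i, j] = p
            diag = H[j]
            H[j] = h
            h_left = h
            e_left = e
            Fcol[j] = f
        Hrow[i] = H[n]
    # best over last row and last column (free trailing end gaps)
    best = H[n]
    bi = np.int32(m)
    bj = np.int32(n)
    for j in range(n + 1):
        if H[j] > best:
            best = H[j]
            bi = m
            bj = j
    for i in range(m + 1):
        if Hrow[i] > best:
            best = Hrow[i]
            bi = i
            bj = n
    ops = np.empty(m + n, dtype=np.int8)
    k = m + n
    i = bi
    j = bj
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            p = pH[i, j]
            if p == 1:
                k -= 1
                ops[k] = OP_MATCH if x[i - 1] == y[j - 1] else OP_MISMATCH
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ops[k] = OP_DEL
            p = pE[i, j]
            j -= 1
            if p == 1:
                state = 0
        else:
            k -= 1
            ops[k] = OP_INS
            p = pF[i, j]
            i -= 1
            if p == 1:
                state = 0
    return best, i, bi, j, bj, ops[k:]


@nb.njit(cache=True, nogil=True)
def _banded_local_align(x, y, dlo, dhi, sub, gap_open, gap_ext):  # pragma: no cover - jit
    """Smith-Waterman restricted to diagonals dlo <= (i - j) <= dhi.

    Exact when the optimal path stays inside the band; used as the
    pipeline fast path with the band centred on seed diagonals.
    """
    m, n = x.shape[0], y.shape[0]
    H = np.zeros(n + 1, dtype=np.int32)
    Fcol = np.full(n + 1, _NEG, dtype=np.int32)
    pH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = np.int32(0)
    bj = np.int32(0)
    for i in range(1, m + 1):
        jlo = i - dhi
        if jlo < 1:
            jlo = 1
        jhi = i - dlo
        if jhi > n:
            jhi = n
        if jlo > jhi:
            continue
        diag = H[jlo - 1] if jlo - 1 <= i - 1 - dlo else np.int32(0)
        h_left = np.int32(0)
        e = _NEG
        subrow = sub[x[i - 1]]
        # column jhi may be newly entered this row: its stored H is stale
        if jhi == i - dlo and jhi <= n and i > 1:
            H[jhi] = 0
            Fcol[jhi] = _NEG
        for j in range(jlo, jhi + 1):
            e_open = h_left + gap_open
            e_ext = e + gap_ext
            if e_open >= e_ext:
                e = e_open
                pE[i, j] = 1
            else:
                e = e_ext
                pE[i, j] = 0
            f_open = H[j] + gap_open
            f_ext = Fcol[j] + gap_ext
            if f_open >= f_ext:
                f = f_open
                pF[i, j] = 1
            else:
                f = f_ext
                pF[i, j] = 0
            h = diag + subrow[y[j - 1]]
            p = np.uint8(1)
            if e > h:
                h = e
                p = np.uint8(2)
            if f > h:
                h = f
                p = np.uint8(3)
            if h <= 0:
                h = 0
                p = np.uint8(0)
            pH[i, j] = p
            diag = H[j]
            H[j] = h
            h_left = h
            Fcol[j] = f
            if h > best:
                best = h
                bi = np.int32(i)
                bj = np.int32(j)
    ops = np.empty(m + n, dtype=np.int8)
    k = m + n
    i = bi
    j = bj
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                k -= 1
                ops[k] = OP_MATCH if x[i - 1] == y[j - 1] else OP_MISMATCH
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ops[k] = OP_DEL
            p = pE[i, j]
            j -= 1
            if p == 1:
                state = 0
        else:
            k -= 1
            ops[k] = OP_INS
            p = pF[i, j]
            i -= 1
            if p == 1:
                state = 0
    return best, i, bi, j, bj, ops[k:]


@dataclass
class PairwiseAlignment:
    """Result of aligning a query against a target.

    Intervals are 0-based half-open on the respective sequences; ``ops``
    covers exactly those intervals.
    """

    score: int
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    ops: np.ndarray

    @property
    def identity_fraction(self) -> float:
        if self.ops.size == 0:
            return 0.0
        return float(np.count_nonzero(self.ops == OP_MATCH)) / self.ops.size

    @property
    def n_aligned_columns(self) -> int:
        return int(self.ops.size)

    def cigar(self) -> str:
        """Compact run-length op string, e.g. '120=1X2I57='."""
        if self.ops.size == 0:
            return ""
        parts = []
        run_op = self.ops[0]
        run_len = 0
        for op in self.ops:
            if op == run_op:
                run_len += 1
            else:
                parts.append(f"{run_len}{OP_CHARS[run_op]}")
                run_op = op
                run_len = 1
        parts.append(f"{run_len}{OP_CHARS[run_op]}")
        return "".join(parts)


def _as_codes(seq: str | np.ndarray) -> np.ndarray:
    return seq if isinstance(seq, np.ndarray) else encode(seq)


def local_score(
    query: str | np.ndarray,
    target: str | np.ndarray,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> int:
    """Best Smith-Waterman score of query vs target (score only, faster)."""
    s, _, _ = _local_score(
        _as_codes(query), _as_codes(target), scoring.matrix(), scoring.gap_open, scoring.gap_extend
    )
    return int(s)


def local_align(
    query: str | np.ndarray,
    target: str | np.ndarray,
    scoring: ScoringScheme = DEFAULT_SCORING,
    band: tuple[int, int] | None = None,
) -> PairwiseAlignment:
    """Best local alignment of query vs target with full edit path.

    ``band``, if given, restricts the search to diagonals
    ``band[0] <= query_pos - target_pos <= band[1]`` (a seed-guided
    heuristic; the result is exact whenever the optimal path lies inside
    the band).
    """
    x = _as_codes(query)
    y = _as_codes(target)
    if band is None:
        score, qs, qe, ts, te, ops = _local_align(
            x, y, scoring.matrix(), scoring.gap_open, scoring.gap_extend
        )
    else:
        score, qs, qe, ts, te, ops = _banded_local_align(
            x, y, band[0], band[1], scoring.matrix(), scoring.gap_open, scoring.gap_extend
        )
    return PairwiseAlignment(int(score), (int(qs), int(qe)), (int(ts), int(te)), ops)


def overlap_align(
    query: str | np.ndarray,
    target: str | np.ndarray,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> PairwiseAlignment:
    """End-gap-free global alignment (overlap mode) with full edit path."""
    x = _as_codes(query)
    y = _as_codes(target)
    score, qs, qe, ts, te, ops = _overlap_align(
        x, y, scoring.matrix(), scoring.gap_open, scoring.gap_extend
    )
    return PairwiseAlignment(int(score), (int(qs), int(qe)), (int(ts), int(te)), ops)


def global_identity(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Identity fraction from an overlap alignment of two sequences.

    Matches divided by aligned columns; internal gap columns count as
    non-matching, free end gaps are excluded.
    """
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    return overlap_align(a, b, scoring).identity_fraction


_AA_ENCODE = np.full(256, 25, dtype=np.int8)
for _i, _a in enumerate("ACDEFGHIKLMNPQRSTVWY*X"):
    _AA_ENCODE[ord(_a)] = _i

_AA_MATRIX_CACHE: dict[tuple[int, int, int, int], np.ndarray] = {}


def overlap_align_aa(
    a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Overlap alignment of two amino-acid strings (identity scoring)."""
    key = scoring.key()
    mat = _AA_MATRIX_CACHE.get(key)
    if mat is None:
        mat = np.full((26, 26), scoring.mismatch, dtype=np.int32)
        for i in range(25):
            mat[i, i] = scoring.match
        mat[25, :] = scoring.mismatch
        mat[:, 25] = scoring.mismatch
        _AA_MATRIX_CACHE[key] = mat
    x = _AA_ENCODE[np.frombuffer(a.encode("ascii"), dtype=np.uint8)]
    y = _AA_ENCODE[np.frombuffer(b.encode("ascii"), dtype=np.uint8)]
    score, qs, qe, ts, te, ops = _overlap_align(x, y, mat, scoring.gap_open, scoring.gap_extend)
    return PairwiseAlignment(int(score), (int(qs), int(qe)), (int(ts), int(te)), ops)
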