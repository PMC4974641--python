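"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own alignment kernels: local
alignment scores come from Biopython's PairwiseAligner, and the
end-gap-free global aligner is a plain-Python Needleman-Wunsch-Gotoh
with the same stated conventions (gap of length L costs
open + (L-1)*extend; diagonal preferred on ties).
"""

from __future__ import annotations

from Bio import Align

NEG = float("-inf")


def biopython_local_aligner(match=2, mismatch=-2, gap_open=-5, gap_extend=-2):
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def local_best_call(read: str, segments: dict[str, str], aligner=None):
    """Best (segment_id, score, flipped) over all segments and strands,
    ties broken toward higher score, forward strand, smallest id."""
    from abpipe.align import reverse_complement

    aligner = aligner or biopython_local_aligner()
    best = None
    for seg_id in sorted(segments):
        for flipped, seq in ((False, read), (True, reverse_complement(read))):
            score = int(aligner.score(seq, segments[seg_id]))
            key = (-score, flipped, seg_id)
            if best is None or key < best[0]:
                best = (key, seg_id, score, flipped)
    return best[1], best[2], best[3]


def overlap_align_python(a: str, b: str, match=2, mismatch=-2, gap_open=-5, gap_extend=-2):
    """End-gap-free global alignment, plain Python Gotoh.

    Returns (score, n_matches, n_columns) for the traceback path
    (diagonal > gap-in-b > gap-in-a on ties), end gaps free and
    excluded from the column count.
    """
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (consumes b)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (consumes a)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    # free trailing end gaps: best over last row/column
    best = (H[m][n], m, n)
    for j in range(n + 1):
        if H[m][j] > best[0]:
            best = (H[m][j], m, j)
    for i in range(m + 1):
        if H[i][n] > best[0]:
            best = (H[i][n], i, n)
    score, i, j = best
    matches = cols = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            s = match if a[i - 1] == b[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                cols += 1
                matches += a[i - 1] == b[j - 1]
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            if E[i][j] == H[i][j - 1] + gap_open:
                state = "H"
            j -= 1
        else:
            cols += 1
            if F[i][j] == H[i - 1][j] + gap_open:
                state = "H"
            i -= 1
    return score, matches, cols


def scan_anchor_v(sequence: str, frame: int, window: int = 45):
    """Exhaustive in-frame codon scan: 3'-most Cys codon in the final window."""
    hits = [
        off
        for off in range(frame, len(sequence) - 2, 3)
        if off >= len(sequence) - window and sequence[off : off + 3] in ("TGT", "TGC")
    ]
    return hits[-1] if hits else None


def scan_anchor_j(sequence: str, frame: int):
    """Exhaustive in-frame codon scan: first W/F followed by GG, else first W/F."""
    wf = [
        off
        for off in range(frame, len(sequence) - 2, 3)
        if sequence[off : off + 3] in ("TGG", "TTT", "TTC")
    ]
    for off in wf:
        if sequence[off + 3 : off + 5] == "GG":
            return off
    return wf[0] if wf else None
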