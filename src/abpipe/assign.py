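"""Read indexing, germline segment assignment and E-value filtering.

Each read is aligned against every germline segment of a type (both
orientations for V) by affine-gap Smith-Waterman; the best-scoring
segment is called.  Statistical significance of the V call is expressed
as a Karlin-Altschul E-value ``E = K * m * n * exp(-lambda * S)`` with
``m`` the read length and ``n`` the total library length; reads whose V
E-value exceeds 1e-3 are removed (strictly greater; a read at exactly
the threshold is retained).

The ``(K, lambda)`` pair for the default scoring scheme was fitted once
by :func:`calibrate_evalue_params` (Gumbel fit to best-score maxima of
random reads against a shuffled-sequence library, both strands) and
ships as a frozen constant so that runs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align import (
    DEFAULT_SCORING,
    OP_MATCH,
    OP_MISMATCH,
    PairwiseAlignment,
    ScoringScheme,
    encode,
    local_align,
    local_score,
    reverse_complement,
)
from .germline import GermlineLibrary

E_VALUE_MAX = 1e-3  # V-assignment removal threshold (strictly greater)
MIN_READ_LENGTH = 30
MIN_D_ALIGNED_NT = 5

# (K, lambda) per scoring-scheme key, fitted by calibrate_evalue_params
# with its default sampling parameters (seed 20160712); see docs.
EVALUE_CALIBRATION: dict[tuple[int, int, int, int], tuple[float, float]] = {
    (2, -2, -5, -2): (0.10518, 0.44600),
}


class CalibrationError(RuntimeError):
    """E-value requested for a scoring scheme with no fitted constants."""


class AssignmentError(ValueError):
    pass


@dataclass
class ReadRecord:
    """One indexed repertoire read.

    ``sequence`` is kept uppercase and, once a V call has been made, in
    germline (plus-strand) orientation; ``strand_flipped`` records
    whether the input was reverse-complemented to get there.
    """

    read_id: str
    raw_id: str
    sequence: str
    strand_flipped: bool = False


@dataclass
class SegmentAlignment:
    """Best local alignment of a read against one germline segment."""

    segment_id: str
    score: int
    read_interval: tuple[int, int]
    germline_interval: tuple[int, int]
    ops: np.ndarray
    e_value: float | None = None

    @property
    def identity_fraction(self) -> float:
        if self.ops.size == 0:
            return 0.0
        return float(np.count_nonzero(self.ops == OP_MATCH)) / self.ops.size

    @property
    def alignment_length(self) -> int:
        """Aligned read-interval length (the quantity the 220 bp filter tests)."""
        return self.read_interval[1] - self.read_interval[0]


@dataclass
class GeneAssignment:
    """Per-read V/(D)/J calls with scores and E-values (pipeline step 2)."""

    read: ReadRecord
    locus: str
    v: SegmentAlignment | None = None
    d: SegmentAlignment | None = None
    j: SegmentAlignment | None = None
    v_family: str | None = None
    d_family: str | None = None
    j_family: str | None = None
    v_runner_up_score: int | None = None
    status: str = "assigned"  # assigned | removed_evalue | unalignable
    flags: set[str] = field(default_factory=set)


def index_reads(records) -> list[ReadRecord]:
    """Pipeline step 1: reformat and label reads with unique index numbers.

    ``records`` is an iterable of ``(raw_id, sequence)`` pairs or
    Biopython SeqRecords.  Reads receive sequential zero-padded ids in
    input order; sequences are uppercased.
    """
    reads = []
    for k, rec in enumerate(records, start=1):
        if hasattr(rec, "seq"):
            raw_id, seq = rec.id, str(rec.seq)
        else:
            raw_id, seq = rec
        reads.append(
            ReadRecord(read_id=f"READ{k:06d}", raw_id=str(raw_id), sequence=seq.upper())
        )
    if not reads:
        raise AssignmentError("no reads")
    return reads


class KmerIndex:
    """Exact k-mer index over germline segments, used as an alignment
    prescreen (seed-and-rank, IgBLAST-style).

    For a read it ranks (segment, orientation) pairs by shared-k-mer
    count and reports the seed diagonal range, which centres the banded
    alignment.  A heuristic: the exhaustive search remains the
    reference behaviour.
    """

    def __init__(self, segments, k: int = 12):
        self.k = k
        self.segments = list(segments)
        self._table: dict[str, list[tuple[int, int]]] = {}
        for idx, seg in enumerate(self.segments):
            seq = seg.sequence
            for pos in range(len(seq) - k + 1):
                self._table.setdefault(seq[pos : pos + k], []).append((idx, pos))

    def rank(
        self, sequence: str, top_k: int = 3, min_count: int = 2
    ) -> list[tuple[int, bool, int, int, int]]:
        """Rank candidates for a read.

        Returns up to ``top_k`` tuples ``(segment_index, flipped,
        diag_min, diag_max, kmer_count)`` sorted by decreasing count.
        """
        k = self.k
        table = self._table
        stats: dict[tuple[int, bool], list[int]] = {}
        for flipped, seq in ((False, sequence), (True, reverse_complement(sequence))):
            for pos in range(len(seq) - k + 1):
                hits = table.get(seq[pos : pos + k])
                if not hits:
                    continue
                for idx, segpos in hits:
                    d = pos - segpos
                    st = stats.get((idx, flipped))
                    if st is None:
                        stats[(idx, flipped)] = [1, d, d]
                    else:
                        st[0] += 1
                        if d < st[1]:
                            st[1] = d
                        elif d > st[2]:
                            st[2] = d
        ranked = sorted(
            (
                (count, idx, flipped, dmin, dmax)
                for (idx, flipped), (count, dmin, dmax) in stats.items()
            ),
            key=lambda t: (-t[0], self.segments[t[1]].segment_id, t[2]),
        )
        out = []
        for count, idx, flipped, dmin, dmax in ranked[: max(top_k, 1)]:
            if count < min_count:
                break
            out.append((idx, flipped, dmin, dmax, count))
        return out


def _to_segment_alignment(
    segment_id: str, aln: PairwiseAlignment, read_offset: int = 0
) -> SegmentAlignment:
    qs, qe = aln.query_interval
    return SegmentAlignment(
        segment_id=segment_id,
        score=aln.score,
        read_interval=(qs + read_offset, qe + read_offset),
        germline_interval=aln.target_interval,
        ops=aln.ops,
    )


def align_segment(
    read: ReadRecord,
    library: GermlineLibrary,
    segment_type: str,
    locus: str = "IGH",
    scoring: ScoringScheme = DEFAULT_SCORING,
    region: tuple[int, int] | None = None,
    index: KmerIndex | None = None,
    top_k: int = 3,
    band_pad: int = 24,
) -> tuple[SegmentAlignment | None, int, bool]:
    """Align a read against every library segment of one type.

    Returns ``(best alignment, runner-up score, flipped)``.  For V both
    orientations of the read are searched; for D and J the read is
    assumed oriented and ``region`` (0-based half-open on the read)
    restricts the search to the part 3' of the V alignment.  Ties are
    broken toward the lexicographically smallest segment id, then the
    forward orientation.  When ``index`` is given, only its top-ranked
    candidates are aligned, inside a seed-centred diagonal band;
    otherwise the search is exhaustive and exact.

    Reads shorter than 30 nt are not aligned (unalignable).
    """
    segments = library.segments_of(locus, segment_type)
    if not segments:
        raise AssignmentError(f"library has no {segment_type} segments for {locus}")
    seq = read.sequence
    offset = 0
    if region is not None:
        start, end = max(0, region[0]), min(len(seq), region[1])
        seq = seq[start:end]
        offset = start
    if len(read.sequence) < MIN_READ_LENGTH or not seq:
        return None, 0, False

    both_strands = segment_type == "V" and region is None
    best = None
    best_key = None
    best_flipped = False
    runner_up = 0

    if index is not None and both_strands:
        candidates = index.rank(seq, top_k=top_k)
        if candidates:
            rc = reverse_complement(seq)
            for idx, flipped, dmin, dmax, _count in candidates:
                seg = index.segments[idx]
                aln = local_align(
                    rc if flipped else seq,
                    seg.sequence,
                    scoring,
                    band=(dmin - band_pad, dmax + band_pad),
                )
                key = (-aln.score, flipped, seg.segment_id)
                if best_key is None or key < best_key:
                    if best is not None:
                        runner_up = max(runner_up, best.score)
                    best, best_key, best_flipped = aln, key, flipped
                    best_seg = seg
                else:
                    runner_up = max(runner_up, aln.score)
            if best is not None and best.score > 0:
                return _to_segment_alignment(best_seg.segment_id, best, offset), runner_up, best_flipped
        # fall through to exhaustive search when seeding finds nothing

    strands = [(False, seq)]
    if both_strands:
        strands.append((True, reverse_complement(seq)))
    enc = {flipped: encode(s) for flipped, s in strands}
    for seg in sorted(segments, key=lambda s: s.segment_id):
        for flipped, _s in strands:
            aln = local_align(enc[flipped], seg.sequence, scoring)
            key = (-aln.score, flipped, seg.segment_id)
            if best_key is None or key < best_key:
                if best is not None:
                    runner_up = max(runner_up, best.score)
                best, best_key, best_flipped = aln, key, flipped
                best_seg = seg
            else:
                runner_up = max(runner_up, aln.score)
    if best is None or best.score <= 0:
        return None, runner_up, False
    return _to_segment_alignment(best_seg.segment_id, best, offset), runner_up, best_flipped


def compute_e_value(
    score: float,
    read_length: int,
    library_total_length: int,
    scoring: ScoringScheme = DEFAULT_SCORING,
    params: tuple[float, float] | None = None,
) -> float:
    """Karlin-Altschul E-value of an alignment score.

    ``E = K * m * n * exp(-lambda * score)`` with m the read length and
    n the total library length.  Monotonically decreasing in score and
    linear in both m and n.
    """
    if score < 0:
        raise AssignmentError("score must be non-negative")
    if params is None:
        params = EVALUE_CALIBRATION.get(scoring.key())
        if params is None:
            raise CalibrationError(
                f"no E-value calibration for scoring scheme {scoring.key()}; "
                "run calibrate_evalue_params and pass params"
            )
    k, lam = params
    return k * read_length * library_total_length * math.exp(-lam * score)


def calibrate_evalue_params(
    scoring: ScoringScheme = DEFAULT_SCORING,
    n_samples: int = 500,
    read_length: int = 500,
    n_segments: int = 50,
    segment_length: int = 300,
    seed: int = 20160712,
) -> tuple[float, float]:
    """Fit (K, lambda) for a scoring scheme by null simulation.

    Draws random reads, aligns each against a fixed library of random
    (shuffled-composition) segments on both strands, and fits a Gumbel
    distribution to the per-read maximum scores: under the
    Karlin-Altschul model S_max ~ Gumbel(loc=ln(K m n)/lambda,
    scale=1/lambda).  The both-strand search is absorbed into K.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    segs = ["".join("ACGT"[b] for b in rng.integers(0, 4, segment_length)) for _ in range(n_segments)]
    enc_segs = [encode(s) for s in segs]
    maxima = np.empty(n_samples)
    for i in range(n_samples):
        read = "".join("ACGT"[b] for b in rng.integers(0, 4, read_length))
        best = 0
        for s_enc in enc_segs:
            for q in (read, reverse_complement(read)):
                best = max(best, local_score(q, s_enc, scoring))
        maxima[i] = best
    loc, scale = sps.gumbel_r.fit(maxima)
    lam = 1.0 / scale
    n_total = n_segments * segment_length
    k = math.exp(loc / scale) / (read_length * n_total)
    return k, lam


def assign_read(
    read: ReadRecord,
    library: GermlineLibrary,
    locus: str = "IGH",
    scoring: ScoringScheme = DEFAULT_SCORING,
    v_index: KmerIndex | None = None,
    top_k: int = 3,
    align_jd: bool = True,
) -> GeneAssignment:
    """Pipeline step 2 for one read: V, then J, then D (IGH) assignment.

    Orients the read by the V call (reverse-complementing when the
    minus strand wins), restricts the J search to 3' of the V alignment
    and the D search to the V-J interval, and records the V E-value.
    D calls shorter than 5 aligned nt are dropped (flag
    ``d_ambiguous``): short D segments align spuriously.

    With ``align_jd=False`` only the V assignment is made; call
    :func:`assign_jd` later (the pipeline does this after indel
    correction so that J/D coordinates refer to the corrected read).
    """
    assignment = GeneAssignment(read=read, locus=locus)
    v, runner_up, flipped = align_segment(
        read, library, "V", locus, scoring, index=v_index, top_k=top_k
    )
    if v is None:
        assignment.status = "unalignable"
        return assignment
    if flipped:
        # alignment was computed on the reverse complement, so its read
        # coordinates already refer to the oriented sequence
        read.sequence = reverse_complement(read.sequence)
        read.strand_flipped = True
    v.e_value = compute_e_value(
        v.score, len(read.sequence), library.total_length(locus, "V"), scoring
    )
    assignment.v = v
    assignment.v_runner_up_score = runner_up
    assignment.v_family = library[v.segment_id].family
    if align_jd:
        assign_jd(assignment, library, scoring)
    return assignment


def assign_jd(
    assignment: GeneAssignment,
    library: GermlineLibrary,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> GeneAssignment:
    """Assign J (and D for IGH) 3' of the V alignment on the current read."""
    read = assignment.read
    locus = assignment.locus
    v = assignment.v
    if v is None:
        return assignment
    j_region = (v.read_interval[1], len(read.sequence))
    j, _, _ = align_segment(read, library, "J", locus, scoring, region=j_region)
    if j is not None:
        j.e_value = compute_e_value(
            j.score, len(read.sequence), library.total_length(locus, "J"), scoring
        )
        assignment.j = j
        assignment.j_family = library[j.segment_id].family
    else:
        assignment.flags.add("j_unassigned")

    if locus == "IGH":
        d_end = j.read_interval[0] if j is not None else len(read.sequence)
        d, _, _ = align_segment(
            read, library, "D", locus, scoring, region=(v.read_interval[1], d_end)
        )
        if d is not None and d.alignment_length >= MIN_D_ALIGNED_NT:
            d.e_value = compute_e_value(
                d.score, len(read.sequence), library.total_length(locus, "D"), scoring
            )
            assignment.d = d
            assignment.d_family = library[d.segment_id].family
        else:
            assignment.flags.add("d_ambiguous")
    return assignment


def filter_by_evalue(
    assignments: list[GeneAssignment], threshold: float = E_VALUE_MAX
) -> tuple[list[GeneAssignment], list[GeneAssignment]]:
    """Partition assignments by the V E-value cutoff.

    Reads with ``v.e_value > threshold`` (strictly greater) get status
    ``removed_evalue``; the filter applies to the V assignment only.
    Returns ``(kept, removed)``; unalignable reads stay in neither.
    """
    kept, removed = [], []
    for a in assignments:
        if a.status == "unalignable":
            continue
        if a.v is not None and a.v.e_value is not None and a.v.e_value > threshold:
            a.status = "removed_evalue"
            removed.append(a)
        else:
            kept.append(a)
    return kept, removed
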