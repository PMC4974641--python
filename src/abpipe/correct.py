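"""Template-based indel error correction in the V segment (step 3).

Short indels in the V region of a read, detected from its alignment to
the assigned germline gene, are treated as platform errors and reverted
toward the germline template: insertions are excised, deletions are
filled with the germline bases.  Only indels of less than three
nucleotides are corrected; longer ones are recorded but left untouched
(codon-multiple indels can be genuine), and a read whose uncorrected
indel lengths do not sum to a multiple of three is flagged
``frameshift_suspect``.  Substitutions are never corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import DEFAULT_SCORING, OP_DEL, OP_INS, ScoringScheme, local_align
from .assign import GeneAssignment, _to_segment_alignment
from .germline import GermlineLibrary

MAX_CORRECTABLE_INDEL = 2  # "less than three nucleotides"
MIN_FLANK_SUPPORT = 6  # aligned columns required on each side of an indel


@dataclass
class IndelEvent:
    """One contiguous insertion or deletion run in the V alignment.

    ``read_pos`` is on the pre-correction read: for an insertion, the
    first inserted base; for a deletion, the position where the missing
    germline bases would be re-inserted.
    """

    read_pos: int
    kind: str  # "insertion" | "deletion"
    length: int
    germline_bases: str = ""  # filled for deletions
    germline_span: tuple[int, int] | None = None
    flank_5p: int = 0  # aligned (non-indel) columns before the event
    flank_3p: int = 0  # aligned columns after the event


@dataclass
class CorrectionRecord:
    read_id: str
    edits_applied: list[IndelEvent] = field(default_factory=list)
    edits_skipped: list[IndelEvent] = field(default_factory=list)
    corrected_sequence: str = ""
    flags: set[str] = field(default_factory=set)


def detect_indels(assignment: GeneAssignment) -> list[IndelEvent]:
    """Run-length encode the indel ops of the V alignment edit path."""
    if assignment.v is None or assignment.v.ops is None:
        raise ValueError("assignment lacks a V edit path")
    v = assignment.v
    events: list[IndelEvent] = []
    r = v.read_interval[0]
    g = v.germline_interval[0]
    ops = v.ops
    i = 0
    n = len(ops)
    aligned_since_last = 0
    while i < n:
        op = ops[i]
        if op == OP_INS or op == OP_DEL:
            j = i
            while j < n and ops[j] == op:
                j += 1
            length = j - i
            if events:
                events[-1].flank_3p = aligned_since_last
            if op == OP_INS:
                events.append(
                    IndelEvent(
                        read_pos=r, kind="insertion", length=length,
                        flank_5p=aligned_since_last,
                    )
                )
                r += length
            else:
                events.append(
                    IndelEvent(
                        read_pos=r, kind="deletion", length=length,
                        germline_span=(g, g + length),
                        flank_5p=aligned_since_last,
                    )
                )
                g += length
            aligned_since_last = 0
            i = j
        else:
            r += 1
            g += 1
            i += 1
            aligned_since_last += 1
    if events:
        events[-1].flank_3p = aligned_since_last
    return events


def correct_indels(
    assignment: GeneAssignment,
    events: list[IndelEvent],
    library: GermlineLibrary,
    max_len: int = MAX_CORRECTABLE_INDEL,
    min_flank: int = MIN_FLANK_SUPPORT,
) -> CorrectionRecord:
    """Revert short V-segment indels toward the germline template.

    Events of length <= ``max_len`` are applied (3'-to-5' so earlier
    positions stay valid); longer events are recorded in
    ``edits_skipped`` and the read left unmodified there.

    An event is corrected only when supported by at least ``min_flank``
    aligned germline columns on each side: unflanked terminal indels
    are indistinguishable from the local alignment chance-extending
    over untemplated junction (or adapter) nucleotides, and reverting
    those would corrupt genuine junctional sequence.
    """
    read = assignment.read
    germ_seq = library[assignment.v.segment_id].sequence
    record = CorrectionRecord(read_id=read.read_id)
    seq = read.sequence
    for ev in sorted(events, key=lambda e: e.read_pos, reverse=True):
        if ev.kind == "deletion" and ev.germline_span is not None:
            gs, ge = ev.germline_span
            ev.germline_bases = germ_seq[gs:ge]
        if ev.length > max_len or min(ev.flank_5p, ev.flank_3p) < min_flank:
            record.edits_skipped.append(ev)
            continue
        if ev.kind == "insertion":
            seq = seq[: ev.read_pos] + seq[ev.read_pos + ev.length :]
        else:
            seq = seq[: ev.read_pos] + ev.germline_bases + seq[ev.read_pos :]
        record.edits_applied.append(ev)
    record.edits_applied.reverse()
    record.edits_skipped.reverse()
    record.corrected_sequence = seq
    uncorrected = sum(ev.length for ev in record.edits_skipped)
    if uncorrected % 3 != 0:
        record.flags.add("frameshift_suspect")
    return record


def realign_after_correction(
    assignment: GeneAssignment,
    record: CorrectionRecord,
    library: GermlineLibrary,
    scoring: ScoringScheme = DEFAULT_SCORING,
    band_pad: int = 24,
) -> GeneAssignment:
    """Recompute the V alignment on the corrected sequence.

    The call itself is kept (correction is defined relative to the
    assigned template); the alignment, intervals and identity are
    refreshed so steps 4-5 see consistent coordinates.  The search is
    banded around the previous alignment's diagonal, widened by any
    skipped indel length.
    """
    if not record.edits_applied:
        return assignment
    v_old = assignment.v
    seg = library[v_old.segment_id]
    read = assignment.read
    read.sequence = record.corrected_sequence
    d0 = v_old.read_interval[0] - v_old.germline_interval[0]
    slack = band_pad + sum(e.length for e in record.edits_skipped) + sum(
        e.length for e in record.edits_applied
    )
    aln = local_align(
        read.sequence, seg.sequence, scoring, band=(d0 - slack, d0 + slack)
    )
    v_new = _to_segment_alignment(seg.segment_id, aln)
    v_new.e_value = v_old.e_value  # filter decision was made pre-correction
    if v_new.identity_fraction < v_old.identity_fraction:
        # banded realignment should never be worse; keep the better one
        v_new = v_old
    assignment.v = v_new
    record.flags |= {"indel_corrected"}
    return assignment


def correct_assignment(
    assignment: GeneAssignment,
    library: GermlineLibrary,
    scoring: ScoringScheme = DEFAULT_SCORING,
    max_len: int = MAX_CORRECTABLE_INDEL,
    min_flank: int = MIN_FLANK_SUPPORT,
) -> CorrectionRecord:
    """Detect, correct and realign in one step (the step-3 entry point)."""
    events = detect_indels(assignment)
    record = correct_indels(assignment, events, library, max_len=max_len, min_flank=min_flank)
    realign_after_correction(assignment, record, library, scoring)
    assignment.flags |= record.flags
    return record
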