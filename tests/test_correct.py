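"""Template-based indel correction: detection, the less-than-three rule,
idempotence and locality."""

import numpy as np
import pytest

from abpipe.align import OP_DEL, OP_INS, OP_MATCH, OP_MISMATCH
from abpipe.assign import GeneAssignment, ReadRecord, SegmentAlignment
from abpipe.correct import (
    correct_assignment,
    correct_indels,
    detect_indels,
    realign_after_correction,
)
from abpipe.germline import GermlineLibrary, GermlineSegment


def _make_assignment(read_seq, germ_seq, ops, read_start=0, germ_start=0):
    n_i = int((ops == OP_INS).sum())
    n_d = int((ops == OP_DEL).sum())
    n_mx = int(((ops == OP_MATCH) | (ops == OP_MISMATCH)).sum())
    aln = SegmentAlignment(
        segment_id="IGHV1-1",
        score=0,
        read_interval=(read_start, read_start + n_mx + n_i),
        germline_interval=(germ_start, germ_start + n_mx + n_d),
        ops=ops,
    )
    read = ReadRecord("READ000001", "r", read_seq)
    return GeneAssignment(read=read, locus="IGH", v=aln)


def _lib(germ_seq):
    return GermlineLibrary([GermlineSegment("IGHV1-1", "IGH", "V", germ_seq)])


def test_perfect_path_yields_no_events():
    germ = "ACGTACGTACGTACGTACGT"
    a = _make_assignment(germ, germ, np.zeros(len(germ), dtype=np.int8))
    assert detect_indels(a) == []
    rec = correct_indels(a, [], _lib(germ))
    assert rec.corrected_sequence == germ
    assert rec.edits_applied == [] and rec.edits_skipped == []


def test_indel_runs_are_single_events():
    # 8 match, 2-nt insertion, 6 match, 1-nt deletion, 8 match
    ops = np.array(
        [OP_MATCH] * 8 + [OP_INS] * 2 + [OP_MATCH] * 6 + [OP_DEL] + [OP_MATCH] * 8,
        dtype=np.int8,
    )
    germ = "ACGTACGTACGTACGTACGTAGG"  # 23 nt (8+6+1+8)
    read = germ[:8] + "TT" + germ[8:14] + germ[15:]
    a = _make_assignment(read, germ, ops)
    events = detect_indels(a)
    assert [(e.kind, e.length, e.read_pos) for e in events] == [
        ("insertion", 2, 8),
        ("deletion", 1, 16),
    ]
    assert events[0].flank_5p == 8 and events[0].flank_3p == 6
    rec = correct_indels(a, events, _lib(germ), min_flank=3)
    assert rec.corrected_sequence == germ


def test_homopolymer_deletion_restores_germline_base():
    germ = "ACGTAC" + "GGGGG" + "TACGTACGTA"
    read = germ[:8] + germ[9:]  # drop one G
    ops = np.array(
        [OP_MATCH] * 8 + [OP_DEL] + [OP_MATCH] * 12, dtype=np.int8
    )
    a = _make_assignment(read, germ, ops)
    rec = correct_indels(a, detect_indels(a), _lib(germ), min_flank=3)
    assert rec.corrected_sequence == germ


def test_three_nt_indel_left_untouched():
    # 3 is NOT less than three: skipped and flagged, read unmodified
    germ = "ACGTACGTAC" + "GTACGTACGT" + "ACGTACGTAC"
    read = germ[:10] + "TTT" + germ[10:]
    ops = np.array(
        [OP_MATCH] * 10 + [OP_INS] * 3 + [OP_MATCH] * 20, dtype=np.int8
    )
    a = _make_assignment(read, germ, ops)
    rec = correct_indels(a, detect_indels(a), _lib(germ))
    assert rec.corrected_sequence == read
    assert [e.length for e in rec.edits_skipped] == [3]
    assert rec.edits_applied == []
    assert "frameshift_suspect" not in rec.flags  # 3 is a codon multiple


def test_uncorrected_frameshift_is_flagged():
    germ = "ACGTACGTAC" + "GTACGTACGT" + "ACGTACGTAC"
    read = germ[:10] + "TTTT" + germ[10:]
    ops = np.array(
        [OP_MATCH] * 10 + [OP_INS] * 4 + [OP_MATCH] * 20, dtype=np.int8
    )
    a = _make_assignment(read, germ, ops)
    rec = correct_indels(a, detect_indels(a), _lib(germ))
    assert "frameshift_suspect" in rec.flags


def test_unflanked_terminal_indels_not_corrected():
    # an indel 2 columns from the alignment end lacks 3' support
    germ = "ACGTACGTACGTACGTACGT"
    ops = np.array(
        [OP_MATCH] * 16 + [OP_INS] + [OP_MATCH] * 2, dtype=np.int8
    )
    read = germ[:16] + "T" + germ[16:18]
    a = _make_assignment(read, germ, ops)
    rec = correct_indels(a, detect_indels(a), _lib(germ))
    assert rec.edits_applied == []
    assert rec.corrected_sequence == read


def test_correction_recovers_injected_indels_on_simulation(default_run):
    """>=90% of injected short V indels exactly reverted at default noise."""
    from abpipe.benchmark import indel_correction_stats

    stats = indel_correction_stats(default_run)
    assert stats["short_indels"] > 300
    assert stats["short_reverted"] / stats["short_indels"] >= 0.90


def test_long_indels_never_modified(long_indel_run):
    from abpipe.benchmark import indel_correction_stats

    stats = indel_correction_stats(long_indel_run)
    assert stats["long_indels"] > 20
    assert stats["long_modified"] == 0
    for rec in long_indel_run.result.corrections.values():
        assert all(e.length <= 2 for e in rec.edits_applied)


def test_correction_is_idempotent(default_run, library):
    """A second correction pass applies no further edits."""
    from abpipe.correct import detect_indels as detect

    n_checked = 0
    for a in default_run.result.assignments:
        if a.status != "assigned":
            continue
        rec = default_run.result.corrections.get(a.read.read_id)
        if rec is None or not rec.edits_applied:
            continue
        rec2 = correct_assignment(a, library)
        assert rec2.edits_applied == []
        assert rec2.corrected_sequence == a.read.sequence
        n_checked += 1
        if n_checked >= 200:
            break
    assert n_checked > 50


def test_correction_never_touches_bases_outside_v_interval(default_run):
    for a in default_run.result.assignments[:300]:
        rec = default_run.result.corrections.get(a.read.read_id)
        if rec is None or a.v is None:
            continue
        rs, re_ = a.v.read_interval
        for ev in rec.edits_applied:
            assert rs <= ev.read_pos <= re_


def test_mean_identity_strictly_increases_with_correction(
    default_run, uncorrected_run
):
    from abpipe.benchmark import mean_v_identity

    with_corr = mean_v_identity(default_run.result)
    without = mean_v_identity(uncorrected_run.result)
    assert with_corr > without


def test_realign_noop_without_edits(library):
    germ = library.segments_of("IGH", "V")[0].sequence
    ops = np.zeros(len(germ), dtype=np.int8)
    a = _make_assignment(germ, germ, ops)
    a.v.segment_id = library.segments_of("IGH", "V")[0].segment_id
    rec = correct_indels(a, [], library)
    v_before = a.v
    realign_after_correction(a, rec, library)
    assert a.v is v_before
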