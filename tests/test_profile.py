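"""Full-length filter, usage frequencies and group fold-change comparison."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abpipe.annotate import AnnotatedRearrangement
from abpipe.profile import (
    ProfileError,
    RepertoireProfile,
    compare_groups,
    compare_replicate_groups,
    compute_usage,
    full_length_filter,
    read_rearrangements,
    write_rearrangements,
    REARRANGEMENT_COLUMNS,
)


def _rec(v_call="IGHV1-1", v_len=250, status="annotated", read_id="R1", seq="ACGT"):
    return AnnotatedRearrangement(
        read_id=read_id,
        locus="IGH",
        sequence=seq,
        v_call=v_call,
        v_family=v_call.split("-")[0],
        v_alignment_length=v_len,
        status=status,
    )


@pytest.mark.parametrize(
    "length,kept", [(219, False), (220, True), (287, True), (180, False)]
)
def test_full_length_filter_boundary(length, kept):
    records = [_rec(v_len=length)]
    survivors, removed = full_length_filter(records)
    assert (len(survivors) == 1) == kept
    if not kept:
        assert removed[0].status == "removed_swapped_segment"
        assert "swapped_segment_suspect" in removed[0].flags


def test_filter_removes_exactly_the_short_alignments():
    rng = random.Random(1)
    lengths = [rng.randint(180, 260) for _ in range(100)]
    records = [
        _rec(read_id=f"R{i}", v_len=L) for i, L in enumerate(lengths)
    ]
    survivors, removed = full_length_filter(records)
    kept_ids = {r.read_id for r in survivors}
    assert kept_ids == {f"R{i}" for i, L in enumerate(lengths) if L >= 220}


def test_usage_frequencies_arithmetic():
    records = [_rec(v_call="IGHV12-3", read_id=f"a{i}") for i in range(4)] + [
        _rec(v_call="IGHV1-1", read_id=f"b{i}") for i in range(6)
    ]
    prof = compute_usage(records, "s1", "WT")
    assert prof.denominator == 10
    assert prof.frequencies == {"IGHV12-3": 0.4, "IGHV1-1": 0.6}
    assert sum(prof.frequencies.values()) == pytest.approx(1.0, abs=1e-9)


def test_empty_repertoire_is_an_error():
    with pytest.raises(ProfileError, match="empty repertoire"):
        compute_usage([_rec(status="removed_evalue")], "s1", "WT")


def test_usage_estimates_recover_simulation_weights(default_run):
    prof = compute_usage(default_run.result.rearrangements, "sim", "WT")
    # uniform usage over 20 genes; each frequency within 3 s.e. of 0.05
    se = np.sqrt(0.05 * 0.95 / prof.denominator)
    for gene, freq in prof.frequencies.items():
        assert abs(freq - 0.05) < 4 * se


def test_fold_change_arithmetic_and_flagging():
    p_tg = RepertoireProfile("tg", "TG", "gene", {"A": 96, "B": 904})
    p_wt = RepertoireProfile("wt", "WT", "gene", {"A": 30, "B": 970})
    comp = compare_groups(p_tg, p_wt, pseudocount=0.0)
    row = comp.table.set_index("gene").loc["A"]
    assert row["fold_change"] == pytest.approx(3.2)
    assert bool(row["flagged"])
    assert comp.flagged_genes == ["A"]


def test_identical_profiles_fold_one_nothing_flagged():
    p = RepertoireProfile("s", "WT", "gene", {"A": 5, "B": 15})
    q = RepertoireProfile("s2", "TG", "gene", {"A": 5, "B": 15})
    comp = compare_groups(q, p)
    assert np.allclose(comp.table["fold_change"], 1.0)
    assert not comp.table["flagged"].any()


def test_gene_absent_from_denominator_stays_finite():
    p_num = RepertoireProfile("tg", "TG", "gene", {"A": 20, "B": 980})
    p_den = RepertoireProfile("wt", "WT", "gene", {"B": 1000})
    comp = compare_groups(p_num, p_den)
    row = comp.table.set_index("gene").loc["A"]
    p = 0.5 / 1000
    assert row["fold_change"] == pytest.approx((0.02 + p) / p)
    assert np.isfinite(row["fold_change"])


def test_mismatched_levels_rejected():
    p1 = RepertoireProfile("a", "TG", "gene", {"A": 1})
    p2 = RepertoireProfile("b", "WT", "family", {"A": 1})
    with pytest.raises(ProfileError):
        compare_groups(p1, p2)


def test_replicate_modes_agree_for_equal_sized_replicates():
    reps_tg = [
        RepertoireProfile(f"tg{i}", "TG", "gene", {"A": 30, "B": 70}) for i in range(3)
    ]
    reps_wt = [
        RepertoireProfile(f"wt{i}", "WT", "gene", {"A": 10, "B": 90}) for i in range(3)
    ]
    for mode in ("mean_frequency", "pooled"):
        comp = compare_replicate_groups(reps_tg, reps_wt, mode=mode, pseudocount=0.0)
        assert comp.table.set_index("gene").loc["A", "fold_change"] == pytest.approx(3.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.permutations(list(range(12))))
def test_frequencies_invariant_to_order_and_relabelling(perm):
    calls = ["IGHV1-1"] * 5 + ["IGHV2-1"] * 4 + ["IGHV3-1"] * 3
    base = compute_usage(
        [_rec(v_call=c, read_id=f"R{i}") for i, c in enumerate(calls)], "s", "g"
    )
    shuffled = compute_usage(
        [_rec(v_call=calls[i], read_id=f"X{k}") for k, i in enumerate(perm)], "s", "g"
    )
    assert base.frequencies == shuffled.frequencies


def test_rearrangement_tsv_round_trip(tmp_path, default_run):
    records = default_run.result.rearrangements[:200]
    path = write_rearrangements(records, tmp_path / "rearr.tsv")
    df = read_rearrangements(path)
    assert list(df.columns) == REARRANGEMENT_COLUMNS
    assert len(df) == len(records)
    by_id = {r.read_id: r for r in records}
    for row in df.itertuples():
        rec = by_id[row.sequence_id]
        assert row.status == rec.status
        assert row.v_call == (rec.v_call or "")
        assert row.d_call == (rec.d_call or "")
        assert row.j_call == (rec.j_call or "")
        assert row.junction == (rec.junction_nt or "")
    # writing the parsed table's records again is byte-identical
    df2 = read_rearrangements(path)
    assert df.equals(df2)
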