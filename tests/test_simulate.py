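"""Simulator: determinism, composition, error-model calibration and the
truth-reconstruction invariant."""

import numpy as np
import pytest

from abpipe.simulate import (
    DEFAULT_CONST_STUB_3P,
    DEFAULT_RACE_STUB_5P,
    SimulationConfig,
    SimulationError,
    apply_sequencing_errors,
    homopolymer_mask,
    make_synthetic_library,
    reconstruct_read,
    simulate_rearrangement,
    simulate_repertoire,
    upweighted_usage,
    write_dataset,
)


def test_no_noise_read_is_exact_concatenation(library):
    cfg = SimulationConfig(
        library=library,
        n_reads=5,
        shm_rate=0,
        seq_sub_rate=0,
        seq_indel_rate=0,
        trim_max=0,
        n_insert_max=0,
        seed=1,
    )
    reads, truths = simulate_repertoire(cfg)
    for (_, seq), t in zip(reads, truths):
        v = library[t.v_id].sequence
        d = library[t.d_id].sequence
        j = library[t.j_id].sequence
        assert seq == DEFAULT_RACE_STUB_5P + v + d + j + DEFAULT_CONST_STUB_3P


def test_same_seed_reproduces_reads_and_truth(library):
    cfg = SimulationConfig(library=library, n_reads=50, seed=99)
    r1, t1 = simulate_repertoire(cfg)
    r2, t2 = simulate_repertoire(cfg)
    assert r1 == r2
    assert [t.seq_edits for t in t1] == [t.seq_edits for t in t2]
    assert [t.cdr3_nt for t in t1] == [t.cdr3_nt for t in t2]


def test_usage_weights_recovered_binomially(library):
    # two-gene library, 3:1 weights; empirical usage within 3 s.e.
    v_ids = [s.segment_id for s in library.segments_of("IGH", "V")][:2]
    weights = {v_ids[0]: 3.0, v_ids[1]: 1.0}
    cfg = SimulationConfig(
        library=library, n_reads=10_000, usage_weights=weights, seed=3,
        shm_rate=0, seq_sub_rate=0, seq_indel_rate=0,
    )
    rng = np.random.default_rng(cfg.seed)
    draws = [simulate_rearrangement(cfg, rng)[1].v_id for _ in range(cfg.n_reads)]
    p_hat = sum(v == v_ids[0] for v in draws) / len(draws)
    se = np.sqrt(0.75 * 0.25 / len(draws))
    assert abs(p_hat - 0.75) < 3 * se


def test_zero_rates_leave_sequence_untouched(library):
    cfg = SimulationConfig(
        library=library, seq_sub_rate=0, seq_indel_rate=0, seed=0
    )
    rng = np.random.default_rng(0)
    seq = "ACGT" * 100
    noisy, edits = apply_sequencing_errors(seq, cfg, rng)
    assert noisy == seq and edits == []


def test_substitution_count_matches_expectation(library):
    cfg = SimulationConfig(
        library=library, seq_sub_rate=0.003, seq_indel_rate=0, seed=0
    )
    rng = np.random.default_rng(42)
    n = 100_000
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    _, edits = apply_sequencing_errors(seq, cfg, rng)
    n_subs = sum(1 for e in edits if e[1] == "sub")
    expected = n * 0.003
    se = np.sqrt(n * 0.003 * 0.997)
    assert abs(n_subs - expected) < 3 * se


def test_homopolymer_runs_boost_indel_rate(library):
    # one 6-nt run flanked by run-free sequence of equal total length:
    # the indel count ratio approaches homopolymer_boost
    boost = 5.0
    cfg = SimulationConfig(
        library=library, seq_sub_rate=0, seq_indel_rate=0.01,
        homopolymer_boost=boost, seed=0,
    )
    run_part = "AAAAAA"
    flat_part = "ACGTCA"
    assert homopolymer_mask(run_part).all()
    assert not homopolymer_mask(flat_part).any()
    rng = np.random.default_rng(7)
    in_run = in_flat = 0
    for _ in range(30_000):
        _, e1 = apply_sequencing_errors(run_part, cfg, rng)
        _, e2 = apply_sequencing_errors(flat_part, cfg, rng)
        in_run += sum(e[1] != "sub" for e in e1)
        in_flat += sum(e[1] != "sub" for e in e2)
    ratio = in_run / in_flat
    assert abs(ratio - boost) / boost < 0.15


def test_write_dataset_counts_and_round_trip(tmp_path, library):
    from Bio import SeqIO

    cfg = SimulationConfig(library=library, n_reads=5, seed=4)
    reads, truths = simulate_repertoire(cfg)
    fastq, truth_tsv = write_dataset(reads, truths, tmp_path / "sample")
    records = list(SeqIO.parse(str(fastq), "fastq"))
    assert len(records) == 5
    assert len({r.id for r in records}) == 5
    assert [str(r.seq) for r in records] == [s for _, s in reads]
    import pandas as pd

    df = pd.read_csv(truth_tsv, sep="\t")
    assert len(df) == 5
    assert list(df["read_id"]) == [rid for rid, _ in reads]


def test_amplicons_fall_in_expected_length_band(library):
    cfg = SimulationConfig(library=library, n_reads=400, seed=8)
    reads, _ = simulate_repertoire(cfg)
    lengths = np.array([len(s) for _, s in reads])
    assert np.mean((lengths >= 400) & (lengths <= 700)) >= 0.95


def test_truth_reconstruction_invariant(default_run, library):
    for t in default_run.truths[:500]:
        assert reconstruct_read(t, library) == t.sequence


def test_invalid_configurations_rejected(library):
    with pytest.raises(SimulationError):
        SimulationConfig(library=library, n_reads=0)
    with pytest.raises(SimulationError):
        SimulationConfig(library=library, shm_rate=1.5)
    with pytest.raises(SimulationError):
        SimulationConfig(library=library, usage_weights={"IGHV1-1": -1.0})
    # IGH requires D segments
    from abpipe.germline import GermlineLibrary

    no_d = GermlineLibrary(
        [s for s in library if s.segment_type != "D"]
    )
    with pytest.raises(SimulationError, match="D segments"):
        SimulationConfig(library=no_d)


def test_upweighted_usage_achieves_target_fold(library):
    targets = ["IGHV1-1", "IGHV2-1", "IGHV3-1"]
    w = upweighted_usage(library, "IGH", targets, usage_fold=4.0)
    total = sum(w.values())
    g = len(w)
    for t in targets:
        assert w[t] / total == pytest.approx(4.0 / g)
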