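"""Synthetic 5'-RACE V(D)J repertoire generator with full ground truth.

Emulates the statistical structure of semiconductor-sequenced antibody
amplicons: a rearranged V(D)J region (segment choice by configurable
usage weights, exonucleolytic junction trimming, untemplated N
insertions, somatic hypermutation) flanked by a 5'-RACE adapter stub
and a constant-region primer stub, then corrupted by substitution
errors and short homopolymer-enriched indel errors.

Every emitted read carries a :class:`TrueAnnotation` sidecar from which
the read can be reconstructed base-for-base, so downstream pipeline
stages are testable without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .germline import GermlineLibrary, GermlineSegment, LibraryError

BASES = "ACGT"

# Fixed flanking sequences standing in for the 5'-RACE adapter (with a
# UTR/leader-sized spacer) and the constant-region primer stretch; their
# lengths put default amplicons in the 500-600 nt band.
DEFAULT_RACE_STUB_5P = (
    "TAAGTATTCGTGAAGAGTGATTTAATGCCGCACTGGTCCTTCTTCTGGATCTTATTCTTAAACCTTACGCTCTAACCGAAGGGTTTTTAT"
)
DEFAULT_CONST_STUB_3P = (
    "CCTCTGTGGCGGCATAAGGCGGGCTTGCAATGTATTCTGTGCAAGGAGGTCTAAAGCATTTCTTCCCTTTATGTGGAACACACGTCCAAGATATACGTCACGACATATTG"
)

_STOP_CODONS = {"TAA", "TAG", "TGA"}


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated repertoire sample.

    Rates are per base; weights are relative (need not sum to 1).
    """

    library: GermlineLibrary
    locus: str = "IGH"
    n_reads: int = 1000
    usage_weights: dict[str, float] | None = None
    d_usage_weights: dict[str, float] | None = None
    j_usage_weights: dict[str, float] | None = None
    trim_max: int = 6
    n_insert_max: int = 10
    shm_rate: float = 0.005
    seq_sub_rate: float = 0.003
    seq_indel_rate: float = 0.001
    homopolymer_boost: float = 5.0
    indel_max_len: int = 2
    race_stub_5p: str = DEFAULT_RACE_STUB_5P
    const_stub_3p: str = DEFAULT_CONST_STUB_3P
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("shm_rate", "seq_sub_rate", "seq_indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {rate}")
        if self.n_reads < 1:
            raise SimulationError("n_reads must be >= 1")
        if self.trim_max < 0 or self.n_insert_max < 0:
            raise SimulationError("trim_max and n_insert_max must be >= 0")
        if self.homopolymer_boost < 0:
            raise SimulationError("homopolymer_boost must be >= 0")
        if self.indel_max_len < 1:
            raise SimulationError("indel_max_len must be >= 1")
        if not self.library.segments_of(self.locus, "V") or not self.library.segments_of(
            self.locus, "J"
        ):
            raise SimulationError(f"library lacks V or J segments for locus {self.locus}")
        if self.locus == "IGH" and not self.library.segments_of("IGH", "D"):
            raise SimulationError("locus IGH requires D segments in the library")
        for weights, seg_type in (
            (self.usage_weights, "V"),
            (self.d_usage_weights, "D"),
            (self.j_usage_weights, "J"),
        ):
            if weights is None:
                continue
            if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise SimulationError(
                    f"{seg_type} usage weights must be non-negative with positive sum"
                )


@dataclass
class TrueAnnotation:
    """Ground truth for one simulated read.

    ``clean`` coordinates refer to the pre-sequencing-error amplicon;
    ``seq_edits`` positions refer to that same coordinate system.
    """

    read_id: str
    locus: str
    v_id: str
    d_id: str | None
    j_id: str
    v_trim_3p: int
    d_trim_5p: int
    d_trim_3p: int
    j_trim_5p: int
    n1: str
    n2: str
    shm: list[tuple[int, str]]  # (clean position, substituted base)
    seq_edits: list[tuple[int, str, int, str]]  # (pos, sub|ins|del, length, bases)
    clean_sequence: str
    sequence: str  # emitted (noisy) read
    v_interval: tuple[int, int]  # V region on the clean read
    junction_interval: tuple[int, int] | None  # anchor-inclusive, clean coords
    cdr3_nt: str | None
    cdr3_aa: str | None


def _draw(rng: np.random.Generator, segments: list[GermlineSegment], weights) -> GermlineSegment:
    if weights is None:
        return segments[rng.integers(0, len(segments))]
    w = np.array([weights.get(s.segment_id, 0.0) for s in segments], dtype=float)
    total = w.sum()
    if total <= 0:
        raise SimulationError("usage weights assign zero mass to every library segment")
    return segments[rng.choice(len(segments), p=w / total)]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def simulate_rearrangement(
    config: SimulationConfig, rng: np.random.Generator, read_id: str = "SIM000001"
) -> tuple[str, TrueAnnotation]:
    """Draw one clean rearranged amplicon (no sequencing errors yet)."""
    lib, locus = config.library, config.locus
    v = _draw(rng, lib.segments_of(locus, "V"), config.usage_weights)
    j = _draw(rng, lib.segments_of(locus, "J"), config.j_usage_weights)
    v_trim = int(rng.integers(0, config.trim_max + 1))
    j_trim = int(rng.integers(0, config.trim_max + 1))
    v_part = v.sequence[: len(v.sequence) - v_trim]
    j_part = j.sequence[j_trim:]
    n1 = _random_bases(rng, int(rng.integers(0, config.n_insert_max + 1)))
    d = None
    d_trim5 = d_trim3 = 0
    d_part = ""
    n2 = ""
    if locus == "IGH":
        d = _draw(rng, lib.segments_of("IGH", "D"), config.d_usage_weights)
        d_trim5 = int(rng.integers(0, config.trim_max + 1))
        d_trim3 = int(rng.integers(0, config.trim_max + 1))
        d_part = d.sequence[d_trim5 : max(d_trim5, len(d.sequence) - d_trim3)]
        n2 = _random_bases(rng, int(rng.integers(0, config.n_insert_max + 1)))

    stub5 = config.race_stub_5p
    vdj = v_part + n1 + d_part + n2 + j_part
    # somatic hypermutation: uniform substitutions over the V(D)J region
    shm: list[tuple[int, str]] = []
    if config.shm_rate > 0:
        vdj_list = list(vdj)
        hits = np.nonzero(rng.random(len(vdj_list)) < config.shm_rate)[0]
        for pos in hits:
            old = vdj_list[pos]
            new = BASES[(BASES.index(old) + int(rng.integers(1, 4))) % 4]
            vdj_list[pos] = new
            shm.append((len(stub5) + int(pos), new))
        vdj = "".join(vdj_list)
    clean = stub5 + vdj + config.const_stub_3p

    v_start = len(stub5)
    v_end = v_start + len(v_part)
    junction = None
    cdr3_nt = cdr3_aa = None
    if v.anchor_offset is not None and j.anchor_offset is not None:
        cys = v_start + v.anchor_offset
        j_anchor_clean = (
            v_end + len(n1) + len(d_part) + len(n2) + (j.anchor_offset - j_trim)
        )
        anchors_intact = (
            v.anchor_offset + 3 <= len(v_part) and j.anchor_offset >= j_trim
        )
        if anchors_intact:
            junction = (cys, j_anchor_clean + 3)
            cdr3_nt = clean[cys + 3 : j_anchor_clean]
            if len(cdr3_nt) % 3 == 0 and cdr3_nt:
                cdr3_aa = str(Seq(cdr3_nt).translate())

    truth = TrueAnnotation(
        read_id=read_id,
        locus=locus,
        v_id=v.segment_id,
        d_id=d.segment_id if d is not None else None,
        j_id=j.segment_id,
        v_trim_3p=v_trim,
        d_trim_5p=d_trim5,
        d_trim_3p=d_trim3,
        j_trim_5p=j_trim,
        n1=n1,
        n2=n2,
        shm=shm,
        seq_edits=[],
        clean_sequence=clean,
        sequence=clean,
        v_interval=(v_start, v_end),
        junction_interval=junction,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
    )
    return clean, truth


def homopolymer_mask(sequence: str, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions lying inside a homopolymer run >= min_run."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    mask = np.zeros(len(arr), dtype=bool)
    start = 0
    for i in range(1, len(arr) + 1):
        if i == len(arr) or arr[i] != arr[start]:
            if i - start >= min_run:
                mask[start:i] = True
            start = i
    return mask


def _indel_length(rng: np.random.Generator, max_len: int) -> int:
    # geometric-ish: each extra base is 3x less likely, truncated at max_len
    weights = np.array([3.0 ** -(k - 1) for k in range(1, max_len + 1)])
    return int(rng.choice(np.arange(1, max_len + 1), p=weights / weights.sum()))


def apply_sequencing_errors(
    sequence: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, int, str]]]:
    """Corrupt a clean amplicon with platform-style errors.

    Substitutions occur at ``seq_sub_rate`` per base; insertions and
    deletions (lengths 1..indel_max_len, short-biased) at
    ``seq_indel_rate``, multiplied by ``homopolymer_boost`` inside
    homopolymer runs >= 3 nt.  Edit positions refer to the clean
    sequence; insertions are placed before the stated position.
    """
    if not sequence:
        raise SimulationError("cannot apply sequencing errors to an empty sequence")
    mask = homopolymer_mask(sequence)
    out: list[str] = []
    edits: list[tuple[int, str, int, str]] = []
    i = 0
    n = len(sequence)
    while i < n:
        indel_rate = config.seq_indel_rate * (config.homopolymer_boost if mask[i] else 1.0)
        u = rng.random()
        if u < config.seq_sub_rate:
            old = sequence[i]
            new = BASES[(BASES.index(old) + int(rng.integers(1, 4))) % 4]
            out.append(new)
            edits.append((i, "sub", 1, new))
            i += 1
        elif u < config.seq_sub_rate + indel_rate:
            length = _indel_length(rng, config.indel_max_len)
            if rng.random() < 0.5:
                ins = _random_bases(rng, length)
                out.append(ins)
                out.append(sequence[i])
                edits.append((i, "ins", length, ins))
                i += 1
            else:
                length = min(length, n - i)
                edits.append((i, "del", length, sequence[i : i + length]))
                i += length
        else:
            out.append(sequence[i])
            i += 1
    return "".join(out), edits


def reconstruct_read(
    truth: TrueAnnotation,
    library: GermlineLibrary,
    race_stub_5p: str = DEFAULT_RACE_STUB_5P,
    const_stub_3p: str = DEFAULT_CONST_STUB_3P,
) -> str:
    """Rebuild the emitted read from truth fields and germline segments.

    Assembles stub + trimmed V + N1 (+ trimmed D + N2) + trimmed J +
    stub, re-applies the recorded somatic mutations and sequencing
    edits, and returns the resulting sequence; equality with
    ``truth.sequence`` is the simulator's conservation invariant.
    """
    v = library[truth.v_id]
    j = library[truth.j_id]
    v_part = v.sequence[: len(v.sequence) - truth.v_trim_3p]
    j_part = j.sequence[truth.j_trim_5p :]
    d_part = ""
    if truth.d_id is not None:
        d = library[truth.d_id]
        d_part = d.sequence[
            truth.d_trim_5p : max(truth.d_trim_5p, len(d.sequence) - truth.d_trim_3p)
        ]
    clean = list(race_stub_5p + v_part + truth.n1 + d_part + truth.n2 + j_part + const_stub_3p)
    for pos, base in truth.shm:
        clean[pos] = base
    clean_seq = "".join(clean)
    out: list[str] = []
    i = 0
    edit_at = {pos: (kind, length, bases) for pos, kind, length, bases in truth.seq_edits}
    while i < len(clean_seq):
        if i in edit_at:
            kind, length, bases = edit_at[i]
            if kind == "sub":
                out.append(bases)
                i += 1
            elif kind == "ins":
                out.append(bases)
                out.append(clean_seq[i])
                i += 1
            else:
                i += length
        else:
            out.append(clean_seq[i])
            i += 1
    return "".join(out)


def simulate_repertoire(
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[TrueAnnotation]]:
    """Simulate a full sample: clean rearrangements plus sequencing errors.

    Returns ``(reads, truths)`` where reads are ``(read_id, sequence)``
    pairs in emission order.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    reads = []
    truths = []
    for k in range(config.n_reads):
        read_id = f"SIM{k + 1:06d}"
        clean, truth = simulate_rearrangement(config, rng, read_id)
        noisy, edits = apply_sequencing_errors(clean, config, rng)
        truth.sequence = noisy
        truth.seq_edits = edits
        reads.append((read_id, noisy))
        truths.append(truth)
    return reads, truths


def write_dataset(
    reads: list[tuple[str, str]],
    truths: list[TrueAnnotation],
    out_prefix: str | Path,
    quality: int = 30,
) -> tuple[Path, Path]:
    """Write reads as FASTQ (constant quality) and truth as a TSV sidecar."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fastq = out_prefix.with_suffix(".fastq")
    truth_tsv = out_prefix.with_suffix(".truth.tsv")
    qchar = chr(quality + 33)
    with open(fastq, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qchar * len(seq)}\n")
    rows = []
    for t in truths:
        rows.append(
            {
                "read_id": t.read_id,
                "locus": t.locus,
                "v_id": t.v_id,
                "d_id": t.d_id or "",
                "j_id": t.j_id,
                "v_trim_3p": t.v_trim_3p,
                "d_trim_5p": t.d_trim_5p,
                "d_trim_3p": t.d_trim_3p,
                "j_trim_5p": t.j_trim_5p,
                "n1": t.n1,
                "n2": t.n2,
                "shm": json.dumps(t.shm),
                "seq_edits": json.dumps(t.seq_edits),
                "v_start": t.v_interval[0],
                "v_end": t.v_interval[1],
                "junction_start": t.junction_interval[0] if t.junction_interval else -1,
                "junction_end": t.junction_interval[1] if t.junction_interval else -1,
                "cdr3_nt": t.cdr3_nt or "",
                "cdr3_aa": t.cdr3_aa or "",
                "clean_sequence": t.clean_sequence,
                "sequence": t.sequence,
            }
        )
    pd.DataFrame(rows).to_csv(truth_tsv, sep="\t", index=False)
    return fastq, truth_tsv


# ---------------------------------------------------------------------------
# synthetic germline libraries


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame codons avoiding stop codons."""
    out = []
    while len(out) < n_codons:
        codon = _random_bases(rng, 3)
        if codon not in _STOP_CODONS:
            out.append(codon)
    return "".join(out)


def make_synthetic_library(
    locus: str = "IGH",
    n_v: int = 20,
    n_families: int = 5,
    n_d: int = 5,
    n_j: int = 3,
    within_family_divergence: float = 0.05,
    seed: int = 0,
) -> GermlineLibrary:
    """Generate a synthetic germline segment library (stand-in reference).

    Synthetic by construction: sequences are random, not IMGT alleles,
    but reproduce the structural features the pipeline relies on — V
    segments of 293 nt with an in-frame 2nd-CYS anchor 11 nt from the
    3' end, J segments of 45 nt with a [WF]G.G anchor motif at offset
    6, short D segments, and family structure (members of a family
    differ by ~``within_family_divergence`` substitutions per site).
    """
    rng = np.random.default_rng(seed)
    prefix = {"IGH": "IGHV", "IGK": "IGKV", "IGL": "IGLV"}[locus]
    segments: list[GermlineSegment] = []

    members_per_family = [n_v // n_families] * n_families
    for i in range(n_v % n_families):
        members_per_family[i] += 1
    v_tail = "GCAAGAGA"  # fixed 8 nt after the Cys codon; no in-frame Cys
    for fam_idx, n_members in enumerate(members_per_family, start=1):
        founder_core = _random_codons(rng, 94)  # 282 nt before the anchor codon
        for member_idx in range(1, n_members + 1):
            core = list(founder_core)
            n_mut = rng.binomial(len(core), within_family_divergence)
            for pos in rng.choice(len(core), size=n_mut, replace=False):
                core[pos] = BASES[(BASES.index(core[pos]) + int(rng.integers(1, 4))) % 4]
            seq = "".join(core) + "TGT" + v_tail
            segments.append(
                GermlineSegment(
                    segment_id=f"{prefix}{fam_idx}-{member_idx}",
                    locus=locus,
                    segment_type="V",
                    sequence=seq,
                    anchor_offset=282,
                    reading_frame_offset=0,
                )
            )

    if locus == "IGH":
        for k in range(1, n_d + 1):
            length = int(rng.integers(10, 15))
            segments.append(
                GermlineSegment(
                    segment_id=f"IGHD{k}-1",
                    locus="IGH",
                    segment_type="D",
                    sequence=_random_bases(rng, length),
                )
            )

    j_prefix = {"IGH": "IGHJ", "IGK": "IGKJ", "IGL": "IGLJ"}[locus]
    for k in range(1, n_j + 1):
        # anchor Trp at offset 6, next codon starts GG ([WF]G.G motif)
        seq = "CACTAC" + "TGG" + "GG" + _random_bases(rng, 1) + _random_codons(rng, 11)
        segments.append(
            GermlineSegment(
                segment_id=f"{j_prefix}{k}",
                locus=locus,
                segment_type="J",
                sequence=seq,
                anchor_offset=6,
                reading_frame_offset=0,
            )
        )

    library = GermlineLibrary(segments)
    library.validate_complete()
    return library


def upweighted_usage(
    library: GermlineLibrary,
    locus: str,
    target_ids: list[str],
    usage_fold: float = 4.0,
) -> dict[str, float]:
    """Usage weights giving ``target_ids`` a frequency fold-change of
    ``usage_fold`` relative to a uniform-usage sample.

    Solves for the weight w such that after renormalisation each target
    gene's frequency is ``usage_fold`` times its uniform frequency 1/G.
    """
    v_ids = [s.segment_id for s in library.segments_of(locus, "V")]
    for t in target_ids:
        if t not in v_ids:
            raise SimulationError(f"target gene {t!r} not in library")
    g = len(v_ids)
    k = len(target_ids)
    if usage_fold * k >= g:
        raise SimulationError("usage_fold too large for library size")
    w = usage_fold * (g - k) / (g - usage_fold * k)
    return {vid: (w if vid in target_ids else 1.0) for vid in v_ids}
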