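"""End-to-end orchestration of the five-step annotation pipeline.

1. index reads; 2. assign V/(D)/J by local alignment and remove reads
failing the V E-value cutoff; 3. correct short V indels against the
assigned germline template; 4. compare to the template at nucleotide
and amino-acid level; 5. determine CDR3 and V(D)J boundaries — then
apply the swapped-segment (minimum V alignment length) filter.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml
from Bio import SeqIO

from .align import DEFAULT_SCORING, ScoringScheme
from .annotate import AnnotatedRearrangement, annotate_assignment
from .assign import (
    E_VALUE_MAX,
    GeneAssignment,
    KmerIndex,
    assign_jd,
    assign_read,
    filter_by_evalue,
    index_reads,
)
from .correct import MAX_CORRECTABLE_INDEL, correct_assignment
from .germline import GermlineLibrary
from .profile import MIN_V_ALIGNMENT_LENGTH, full_length_filter

logger = logging.getLogger("abpipe")


@dataclass
class PipelineConfig:
    """Tunable thresholds of the annotation pipeline."""

    locus: str = "IGH"
    evalue_max: float = E_VALUE_MAX
    min_v_alignment_length: int = MIN_V_ALIGNMENT_LENGTH
    max_correct_indel: int = MAX_CORRECTABLE_INDEL
    correction_enabled: bool = True
    scoring: ScoringScheme = field(default_factory=lambda: DEFAULT_SCORING)
    prescreen: bool = True  # k-mer seeded candidate screen + banded alignment
    prescreen_top_k: int = 3
    compute_identities: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        scoring = data.pop("scoring", None)
        cfg = cls(**data)
        if scoring:
            cfg = replace(cfg, scoring=ScoringScheme(**scoring))
        return cfg


@dataclass
class PipelineResult:
    rearrangements: list[AnnotatedRearrangement]
    assignments: list[GeneAssignment]
    accounting: dict[str, int]
    corrections: dict[str, object] = field(default_factory=dict)  # read_id -> CorrectionRecord


def run_pipeline(
    raw_records,
    library: GermlineLibrary,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full annotation pipeline over raw reads.

    ``raw_records`` is any iterable accepted by
    :func:`abpipe.assign.index_reads`.  Returns every read that entered
    the pipeline with its final status; per-stage read counts are
    reported in ``accounting`` and logged to stderr.
    """
    config = config or PipelineConfig()
    reads = index_reads(raw_records)
    accounting = {"input": len(reads)}

    v_index = None
    if config.prescreen:
        v_index = KmerIndex(library.segments_of(config.locus, "V"))

    assignments = [
        assign_read(
            read,
            library,
            config.locus,
            config.scoring,
            v_index=v_index,
            top_k=config.prescreen_top_k,
            align_jd=False,  # J/D are aligned after indel correction
        )
        for read in reads
    ]
    unalignable = [a for a in assignments if a.status == "unalignable"]
    kept, removed_evalue = filter_by_evalue(
        [a for a in assignments if a.status != "unalignable"], config.evalue_max
    )
    accounting["unalignable"] = len(unalignable)
    accounting["removed_evalue"] = len(removed_evalue)
    accounting["assigned"] = len(kept)

    corrected = 0
    corrections: dict[str, object] = {}
    if config.correction_enabled:
        for a in kept:
            record = correct_assignment(
                a, library, config.scoring, max_len=config.max_correct_indel
            )
            corrections[a.read.read_id] = record
            if record.edits_applied:
                corrected += 1
    accounting["indel_corrected"] = corrected
    for a in kept:
        assign_jd(a, library, config.scoring)

    rearrangements = [
        annotate_assignment(
            a, library, config.scoring, compute_identities=config.compute_identities
        )
        for a in assignments
    ]
    survivors, _removed = full_length_filter(
        rearrangements, config.min_v_alignment_length
    )
    accounting["removed_swapped_segment"] = sum(
        1 for r in rearrangements if r.status == "removed_swapped_segment"
    )
    accounting["full_length"] = len(survivors)
    for stage, count in accounting.items():
        logger.info("%s: %d reads", stage, count)
    return PipelineResult(
        rearrangements=rearrangements,
        assignments=assignments,
        accounting=accounting,
        corrections=corrections,
    )


def read_input_records(path: str | Path):
    """Load FASTA or FASTQ reads (format sniffed from the first byte)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return list(SeqIO.parse(str(path), fmt))


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
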