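"""Full-length filtering, germline gene usage and group comparison.

After annotation, a filter removes reads whose V gene alignment is
shorter than 220 bp — chimeric amplicons with swapped gene segments
produced by PCR jumping align only partially to any single V template.
Surviving reads are tallied into per-gene (or per-family) usage
frequencies, and two samples are compared gene-by-gene as fold changes
(numerator group over denominator group), flagging genes above an
arbitrary fold-change threshold (default 3).  The threshold is a
display convention, not a statistical test; no p-values are attached.

Counting is per read; an optional mode collapses identical nucleotide
sequences first.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .annotate import AnnotatedRearrangement

MIN_V_ALIGNMENT_LENGTH = 220  # bp; "swapped segment" filter
FOLD_CHANGE_THRESHOLD = 3.0


class ProfileError(ValueError):
    pass


@dataclass
class RepertoireProfile:
    """Per-sample germline gene usage: counts and frequencies."""

    sample_id: str
    group_label: str
    level: str  # "gene" | "family"
    counts: dict[str, int]
    denominator: int = 0
    frequencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.denominator = sum(self.counts.values())
        if self.denominator == 0:
            raise ProfileError("empty repertoire")
        self.frequencies = {
            gene: count / self.denominator for gene, count in self.counts.items()
        }


@dataclass
class UsageComparison:
    """Per-gene fold changes of one group's usage over another's."""

    table: pd.DataFrame  # gene, freq_num, freq_den, fold_change, flagged
    numerator_label: str
    denominator_label: str
    threshold: float
    pseudocount: float

    @property
    def flagged_genes(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "gene"])


def full_length_filter(
    records: list[AnnotatedRearrangement],
    min_v_alignment_length: int = MIN_V_ALIGNMENT_LENGTH,
) -> tuple[list[AnnotatedRearrangement], list[AnnotatedRearrangement]]:
    """Remove reads whose V gene alignment is shorter than the cutoff.

    Strictly-less-than semantics: a read aligned over exactly 220 bp is
    retained.  Removed reads get status ``removed_swapped_segment`` and
    the reason flag ``swapped_segment_suspect``.  Reads already removed
    upstream pass through untouched (in the removed list).
    """
    kept, removed = [], []
    for rec in records:
        if rec.status != "annotated":
            removed.append(rec)
            continue
        if rec.v_alignment_length < min_v_alignment_length:
            rec.status = "removed_swapped_segment"
            rec.flags.add("swapped_segment_suspect")
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


def compute_usage(
    records: list[AnnotatedRearrangement],
    sample_id: str,
    group_label: str,
    level: str = "gene",
    collapse_identical: bool = False,
) -> RepertoireProfile:
    """Tally V gene (or family) usage over surviving records.

    Each read counts once; with ``collapse_identical`` every distinct
    nucleotide sequence counts once instead.
    """
    if level not in ("gene", "family"):
        raise ProfileError(f"unknown level {level!r}")
    survivors = [r for r in records if r.status == "annotated" and r.v_call]
    if collapse_identical:
        seen: dict[str, AnnotatedRearrangement] = {}
        for r in survivors:
            seen.setdefault(r.sequence, r)
        survivors = list(seen.values())
    if not survivors:
        raise ProfileError("empty repertoire")
    key = (lambda r: r.v_call) if level == "gene" else (lambda r: r.v_family)
    return RepertoireProfile(
        sample_id=sample_id,
        group_label=group_label,
        level=level,
        counts=dict(Counter(key(r) for r in survivors)),
    )


def compare_groups(
    profile_num: RepertoireProfile,
    profile_den: RepertoireProfile,
    threshold: float = FOLD_CHANGE_THRESHOLD,
    pseudocount: float | None = None,
) -> UsageComparison:
    """Per-gene usage fold change of one group over another.

    ``fold_change = (freq_num + p) / (freq_den + p)`` with pseudocount
    ``p`` defaulting to half a count in the smaller sample (expressed
    as a frequency), which keeps fold changes finite for genes absent
    from one group.  Genes absent from both profiles are omitted.
    """
    if profile_num.level != profile_den.level:
        raise ProfileError(
            f"cannot compare {profile_num.level!r} vs {profile_den.level!r} profiles"
        )
    if pseudocount is None:
        pseudocount = 0.5 / min(profile_num.denominator, profile_den.denominator)
    genes = sorted(set(profile_num.frequencies) | set(profile_den.frequencies))
    rows = []
    for gene in genes:
        f_num = profile_num.frequencies.get(gene, 0.0)
        f_den = profile_den.frequencies.get(gene, 0.0)
        fold = (f_num + pseudocount) / (f_den + pseudocount)
        rows.append(
            {
                "gene": gene,
                f"freq_{profile_num.group_label}": f_num,
                f"freq_{profile_den.group_label}": f_den,
                "fold_change": fold,
                "flagged": fold > threshold,
            }
        )
    return UsageComparison(
        table=pd.DataFrame(rows),
        numerator_label=profile_num.group_label,
        denominator_label=profile_den.group_label,
        threshold=threshold,
        pseudocount=pseudocount,
    )


def compare_replicate_groups(
    profiles_num: list[RepertoireProfile],
    profiles_den: list[RepertoireProfile],
    threshold: float = FOLD_CHANGE_THRESHOLD,
    pseudocount: float | None = None,
    mode: str = "mean_frequency",
) -> UsageComparison:
    """Fold change between replicate groups.

    ``mean_frequency`` averages per-replicate frequencies within each
    group before forming the ratio; ``pooled`` sums counts across
    replicates first.
    """
    if mode not in ("mean_frequency", "pooled"):
        raise ProfileError(f"unknown replicate mode {mode!r}")

    def combine(profiles: list[RepertoireProfile]) -> RepertoireProfile:
        if mode == "pooled":
            counts: Counter = Counter()
            for p in profiles:
                counts.update(p.counts)
            return RepertoireProfile(
                sample_id="+".join(p.sample_id for p in profiles),
                group_label=profiles[0].group_label,
                level=profiles[0].level,
                counts=dict(counts),
            )
        genes = sorted({g for p in profiles for g in p.frequencies})
        n = len(profiles)
        mean_freq = {g: sum(p.frequencies.get(g, 0.0) for p in profiles) / n for g in genes}
        denom = min(p.denominator for p in profiles)
        synthetic_counts = {g: f * denom for g, f in mean_freq.items() if f > 0}
        prof = RepertoireProfile.__new__(RepertoireProfile)
        prof.sample_id = "+".join(p.sample_id for p in profiles)
        prof.group_label = profiles[0].group_label
        prof.level = profiles[0].level
        prof.counts = {g: int(round(c)) for g, c in synthetic_counts.items()}
        prof.denominator = denom
        prof.frequencies = mean_freq
        return prof

    return compare_groups(
        combine(profiles_num), combine(profiles_den), threshold, pseudocount
    )


REARRANGEMENT_COLUMNS = [
    "sequence_id",
    "status",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "v_alignment_length",
    "v_evalue",
    "filter_flags",
]


def write_rearrangements(
    records: list[AnnotatedRearrangement], path: str | Path
) -> Path:
    """Write an AIRR Rearrangement-style TSV, one row per read that
    entered gene assignment; removed reads keep their status for audit."""
    rows = []
    for r in records:
        junction_aa = None
        if r.junction_nt is not None and len(r.junction_nt) % 3 == 0 and r.junction_nt:
            junction_aa = str(Seq(r.junction_nt).translate())
        rows.append(
            {
                "sequence_id": r.read_id,
                "status": r.status,
                "v_call": r.v_call or "",
                "d_call": r.d_call or "",
                "j_call": r.j_call or "",
                "junction": r.junction_nt or "",
                "junction_aa": junction_aa or "",
                "productive": "T" if r.productive else "F",
                "v_alignment_length": r.v_alignment_length,
                "v_evalue": "" if r.v_evalue is None else f"{r.v_evalue:.6g}",
                "filter_flags": ",".join(sorted(r.flags)),
            }
        )
    path = Path(path)
    pd.DataFrame(rows, columns=REARRANGEMENT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_rearrangements(path: str | Path) -> pd.DataFrame:
    """Read back a rearrangement TSV (strings preserved, NaN-free)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(REARRANGEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ProfileError(f"rearrangement file missing columns {sorted(missing)}")
    return df


def write_usage(profile: RepertoireProfile, path: str | Path) -> Path:
    rows = [
        {
            "sample_id": profile.sample_id,
            "group": profile.group_label,
            profile.level: gene,
            "count": profile.counts[gene],
            "frequency": profile.frequencies[gene],
        }
        for gene in sorted(profile.counts)
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_comparison(comparison: UsageComparison, path: str | Path) -> Path:
    path = Path(path)
    meta = (
        f"# fold change: {comparison.numerator_label} over {comparison.denominator_label}; "
        f"threshold {comparison.threshold}; pseudocount {comparison.pseudocount:.3g}\n"
    )
    with open(path, "w") as fh:
        fh.write(meta)
        comparison.table.to_csv(fh, sep="\t", index=False)
    return path
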