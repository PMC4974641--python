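"""Germline V/(D)/J segment libraries and their CDR3 anchor annotations.

A library holds the reference templates against which repertoire reads
are assigned, corrected and annotated.  Anchors follow the IMGT
conserved-residue convention: the 2nd-CYS codon near the 3' end of a V
segment and the J-TRP/J-PHE codon of a J segment delimit the junction.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

LOCI = ("IGH", "IGK", "IGL")
SEGMENT_TYPES = ("V", "D", "J")

_VALID_SEQ = re.compile(r"^[ACGT]+$")

V_ANCHOR_WINDOW = 45  # 2nd-CYS is searched within the final 45 nt of V


class LibraryError(ValueError):
    """Malformed or invalid germline library input."""


@dataclass
class GermlineSegment:
    """One germline V, D or J gene segment.

    ``anchor_offset`` is the 0-based offset of the first base of the
    conserved CDR3 anchor codon (2nd-CYS for V, J-TRP/J-PHE for J;
    absent for D).  ``reading_frame_offset`` is the offset from which
    translation is in frame with the anchor codon (V and J only).
    """

    segment_id: str
    locus: str
    segment_type: str
    sequence: str
    family: str | None = None
    anchor_offset: int | None = None
    reading_frame_offset: int | None = None

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise LibraryError(f"{self.segment_id}: unknown locus {self.locus!r}")
        if self.segment_type not in SEGMENT_TYPES:
            raise LibraryError(f"{self.segment_id}: unknown segment type {self.segment_type!r}")
        if not self.sequence or not _VALID_SEQ.match(self.sequence):
            raise LibraryError(
                f"segment {self.segment_id}: sequence must be non-empty uppercase A/C/G/T "
                "(ambiguity codes are rejected)"
            )
        if self.segment_type == "D" and self.locus != "IGH":
            raise LibraryError(
                f"segment {self.segment_id}: D segments exist only for locus IGH"
            )
        if self.family is None:
            self.family = default_family(self.segment_id)
        if self.anchor_offset is not None:
            self._check_anchor()

    def _check_anchor(self) -> None:
        off = self.anchor_offset
        if off is None:
            return
        if off < 0 or off + 3 > len(self.sequence):
            raise LibraryError(
                f"segment {self.segment_id}: anchor offset {off} outside sequence"
            )
        aa = str(Seq(self.sequence[off : off + 3]).translate())
        expected = {"V": "C", "J": "WF", "D": ""}[self.segment_type]
        if aa not in expected:
            raise LibraryError(
                f"segment {self.segment_id}: anchor codon translates to {aa!r}, "
                f"expected one of {expected!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def default_family(segment_id: str) -> str:
    """Family label defaulting rule: segment id up to the first hyphen."""
    return segment_id.split("-", 1)[0]


def locate_anchor(segment: GermlineSegment) -> int | None:
    """Locate the CDR3 anchor codon on a V or J germline segment.

    V: the 3'-most in-frame Cys codon (TGT/TGC) within the final 45 nt.
    J: the 5'-most in-frame Trp (TGG) or Phe (TTT/TTC) codon that is
    followed by ``GG`` in the next codon (the [WF]G.G motif) when such a
    candidate exists, otherwise the 5'-most in-frame Trp/Phe.

    Returns the 0-based offset of the codon's first base, or None when
    no candidate exists.  Calling on a D segment is a usage error.
    """
    if segment.segment_type == "D":
        raise LibraryError("D segments carry no CDR3 anchor")
    seq = segment.sequence
    frame = segment.reading_frame_offset
    if frame is None:
        raise LibraryError(
            f"segment {segment.segment_id}: reading_frame_offset required to locate anchor"
        )
    if segment.segment_type == "V":
        found = None
        for off in range(frame, len(seq) - 2, 3):
            if off < len(seq) - V_ANCHOR_WINDOW:
                continue
            if seq[off : off + 3] in ("TGT", "TGC"):
                found = off  # keep scanning: 3'-most wins
        return found
    fallback = None
    for off in range(frame, len(seq) - 2, 3):
        if seq[off : off + 3] in ("TGG", "TTT", "TTC"):
            if fallback is None:
                fallback = off
            if seq[off + 3 : off + 5] == "GG":
                return off
    return fallback


def infer_j_frame(sequence: str) -> int | None:
    """Infer the reading frame of a J segment from its [WF]G.G motif.

    Returns the frame (0..2) of the 5'-most Trp/Phe codon followed by
    ``GG``, or None when no such motif exists in any frame.
    """
    candidates = []
    for frame in range(3):
        for off in range(frame, len(sequence) - 2, 3):
            if sequence[off : off + 3] in ("TGG", "TTT", "TTC") and sequence[
                off + 3 : off + 5
            ] == "GG":
                candidates.append((off, frame))
                break
    if not candidates:
        return None
    return min(candidates)[1]


@dataclass
class GermlineLibrary:
    """A validated collection of germline segments, indexable by id."""

    segments: list[GermlineSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id: dict[str, GermlineSegment] = {}
        for seg in self.segments:
            if seg.segment_id in self._by_id:
                raise LibraryError(f"duplicate segment id {seg.segment_id!r}")
            self._by_id[seg.segment_id] = seg

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[GermlineSegment]:
        return iter(self.segments)

    def __getitem__(self, segment_id: str) -> GermlineSegment:
        return self._by_id[segment_id]

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._by_id

    @property
    def counts_by_type(self) -> dict[tuple[str, str], int]:
        return dict(Counter((s.locus, s.segment_type) for s in self.segments))

    def segments_of(self, locus: str, segment_type: str) -> list[GermlineSegment]:
        return [
            s for s in self.segments if s.locus == locus and s.segment_type == segment_type
        ]

    def total_length(self, locus: str, segment_type: str) -> int:
        return sum(len(s) for s in self.segments_of(locus, segment_type))

    def validate_complete(self) -> None:
        """Check that every locus present has at least one V and one J."""
        by_locus: dict[str, set[str]] = {}
        for s in self.segments:
            by_locus.setdefault(s.locus, set()).add(s.segment_type)
        for locus, types in by_locus.items():
            missing = {"V", "J"} - types
            if missing:
                raise LibraryError(
                    f"locus {locus}: missing segment type(s) {sorted(missing)}"
                )

    @staticmethod
    def merge(*fragments: "GermlineLibrary") -> "GermlineLibrary":
        """Combine library fragments into one complete, validated library."""
        merged = GermlineLibrary(
            [seg for frag in fragments for seg in frag.segments]
        )
        merged.validate_complete()
        return merged

    def annotate_anchors(self) -> None:
        """Fill in missing frames and anchor offsets for V and J segments."""
        for seg in self.segments:
            if seg.segment_type == "D":
                continue
            if seg.reading_frame_offset is None:
                if seg.segment_type == "V":
                    seg.reading_frame_offset = 0
                else:
                    seg.reading_frame_offset = infer_j_frame(seg.sequence) or 0
            if seg.anchor_offset is None:
                seg.anchor_offset = locate_anchor(seg)
                if seg.anchor_offset is not None:
                    seg._check_anchor()


def read_germline_library(
    path: str | Path, locus: str, segment_type: str
) -> GermlineLibrary:
    """Read one FASTA of germline segments as a library fragment.

    Header dialect: ``>segment_id[|family[|anchor_offset]]``.  Family
    defaults to the segment id up to the first hyphen.  Sequences with
    ambiguity codes are rejected; duplicate ids are rejected.
    """
    path = Path(path)
    segments = []
    for record in SeqIO.parse(str(path), "fasta"):
        if not record.id:
            raise LibraryError(f"{path}: FASTA record with empty header")
        parts = record.description.split()[0].split("|")
        segment_id = parts[0]
        family = parts[1] if len(parts) > 1 and parts[1] else None
        anchor = int(parts[2]) if len(parts) > 2 and parts[2] else None
        seq = str(record.seq).upper()
        if not seq:
            raise LibraryError(f"{path}: record {segment_id!r} has an empty sequence")
        segments.append(
            GermlineSegment(
                segment_id=segment_id,
                locus=locus,
                segment_type=segment_type,
                sequence=seq,
                family=family,
                anchor_offset=anchor,
            )
        )
    if not segments:
        raise LibraryError(f"{path}: no FASTA records found")
    fragment = GermlineLibrary(segments)
    fragment.annotate_anchors()
    return fragment


def write_library(library: GermlineLibrary | Iterable[GermlineSegment], path: str | Path) -> None:
    """Write segments as FASTA using the ``id|family|anchor`` header dialect."""
    with open(path, "w") as fh:
        for seg in library:
            anchor = "" if seg.anchor_offset is None else str(seg.anchor_offset)
            fh.write(f">{seg.segment_id}|{seg.family}|{anchor}\n{seg.sequence}\n")
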