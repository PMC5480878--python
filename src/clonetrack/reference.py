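"""Germline V/D/J segment references with framework/CDR region annotations.

A :class:`GermlineReference` holds the segment set a V(D)J annotator aligns
against.  V segments carry an ordered FR1/CDR1/FR2/CDR2/FR3 region map
(0-based half-open coordinates on the segment); the portion of a V segment
after FR3, together with the junction, forms the CDR3.  J segments carry the
position of the conserved Trp codon (the 3' CDR3 anchor).  Full IMGT unique
numbering is deliberately not recomputed here: anchors and region bounds
travel with the reference, fixture-style.

On disk a reference is a FASTA of segment sequences plus a sidecar TSV of
region bounds (columns: segment, region, start, end).  The pseudo-regions
``ANCHOR`` (J Trp codon) and ``FRAME`` (reading-frame offset, stored in
``start``) ride in the same TSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

V_REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

_VALID_CLASSES = {"V", "D", "J"}


class ReferenceFormatError(ValueError):
    """Raised when a reference FASTA/TSV pair is malformed."""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline allele (V, D or J).

    ``region_bounds`` is only populated for V segments and must partition a
    prefix of the sequence in the order FR1, CDR1, FR2, CDR2, FR3.
    ``anchor`` is only set for J segments: the start of the conserved Trp
    codon, i.e. the nucleotide at which the CDR3 ends.
    """

    name: str
    segment_class: str
    sequence: str
    region_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)
    reading_frame: int = 0
    anchor: int | None = None

    def __post_init__(self) -> None:
        if self.segment_class not in _VALID_CLASSES:
            raise ReferenceFormatError(
                f"segment {self.name!r}: class must be V, D or J, "
                f"got {self.segment_class!r}"
            )
        if not self.sequence:
            raise ReferenceFormatError(f"segment {self.name!r}: empty sequence")
        if self.reading_frame not in (0, 1, 2):
            raise ReferenceFormatError(
                f"segment {self.name!r}: reading_frame must be 0-2"
            )
        if self.segment_class == "V":
            self._validate_v_bounds()
        else:
            if self.region_bounds:
                raise ReferenceFormatError(
                    f"segment {self.name!r}: only V segments carry region bounds"
                )
        if self.segment_class == "J":
            if self.anchor is None:
                raise ReferenceFormatError(
                    f"segment {self.name!r}: J segment needs a Trp-codon anchor"
                )
            if not 0 <= self.anchor <= len(self.sequence) - 3:
                raise ReferenceFormatError(
                    f"segment {self.name!r}: anchor {self.anchor} outside sequence"
                )
        elif self.anchor is not None:
            raise ReferenceFormatError(
                f"segment {self.name!r}: anchor only valid on J segments"
            )

    def _validate_v_bounds(self) -> None:
        missing = [r for r in V_REGION_ORDER if r not in self.region_bounds]
        if missing:
            raise ReferenceFormatError(
                f"segment {self.name!r}: missing region bounds {missing}"
            )
        prev_end = 0
        for region in V_REGION_ORDER:
            start, end = self.region_bounds[region]
            if start != prev_end:
                raise ReferenceFormatError(
                    f"segment {self.name!r}: region {region} starts at {start}, "
                    f"expected {prev_end} (regions must partition a prefix "
                    "without overlap)"
                )
            if end <= start:
                raise ReferenceFormatError(
                    f"segment {self.name!r}: region {region} is empty or reversed"
                )
            prev_end = end
        if prev_end > len(self.sequence):
            raise ReferenceFormatError(
                f"segment {self.name!r}: region bounds exceed sequence length"
            )

    @property
    def gene(self) -> str:
        """Gene name without the allele suffix (``IGHV3-S01*01`` -> ``IGHV3-S01``)."""
        return self.name.split("*")[0]

    @property
    def fr3_end(self) -> int:
        """End of FR3 on a V segment: the point where the CDR3 begins."""
        return self.region_bounds["FR3"][1]


@dataclass(frozen=True)
class GermlineReference:
    """Immutable set of germline segments with unique names."""

    segments: tuple[GermlineSegment, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ReferenceFormatError(f"duplicate segment names: {dupes}")

    @classmethod
    def from_segments(cls, segments: Iterable[GermlineSegment]) -> "GermlineReference":
        return cls(tuple(segments))

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def of_class(self, segment_class: str) -> tuple[GermlineSegment, ...]:
        return tuple(s for s in self.segments if s.segment_class == segment_class)

    @property
    def v_segments(self) -> tuple[GermlineSegment, ...]:
        return self.of_class("V")

    @property
    def d_segments(self) -> tuple[GermlineSegment, ...]:
        return self.of_class("D")

    @property
    def j_segments(self) -> tuple[GermlineSegment, ...]:
        return self.of_class("J")

    def __getitem__(self, name: str) -> GermlineSegment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(f"unknown segment {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(seg.name == name for seg in self.segments)

    # ---------------------------------------------------------------- I/O

    def write(self, fasta_path: str | Path, bounds_path: str | Path) -> None:
        """Write FASTA + region-bounds TSV."""
        records = [
            SeqRecord(Seq(s.sequence), id=s.name, description=s.segment_class)
            for s in self.segments
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        rows = []
        for s in self.segments:
            for region in V_REGION_ORDER:
                if region in s.region_bounds:
                    start, end = s.region_bounds[region]
                    rows.append((s.name, region, start, end))
            if s.anchor is not None:
                rows.append((s.name, "ANCHOR", s.anchor, s.anchor + 3))
            rows.append((s.name, "FRAME", s.reading_frame, s.reading_frame))
        pd.DataFrame(rows, columns=["segment", "region", "start", "end"]).to_csv(
            bounds_path, sep="\t", index=False
        )

    @classmethod
    def read(cls, fasta_path: str | Path, bounds_path: str | Path) -> "GermlineReference":
        """Load FASTA + region-bounds TSV, validating every record."""
        bounds = pd.read_csv(bounds_path, sep="\t")
        expected_cols = {"segment", "region", "start", "end"}
        if not expected_cols.issubset(bounds.columns):
            raise ReferenceFormatError(
                f"bounds TSV must have columns {sorted(expected_cols)}"
            )
        per_segment: dict[str, dict] = {}
        for row in bounds.itertuples(index=False):
            info = per_segment.setdefault(row.segment, {"bounds": {}, "anchor": None, "frame": 0})
            if row.region == "ANCHOR":
                info["anchor"] = int(row.start)
            elif row.region == "FRAME":
                info["frame"] = int(row.start)
            else:
                info["bounds"][row.region] = (int(row.start), int(row.end))

        segments = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            cls_token = rec.description.split()[-1] if rec.description else ""
            if cls_token not in _VALID_CLASSES:
                raise ReferenceFormatError(
                    f"FASTA record {rec.id!r}: description must end with the "
                    f"segment class (V, D or J), got {rec.description!r}"
                )
            info = per_segment.get(rec.id, {"bounds": {}, "anchor": None, "frame": 0})
            segments.append(
                GermlineSegment(
                    name=rec.id,
                    segment_class=cls_token,
                    sequence=str(rec.seq).upper(),
                    region_bounds=info["bounds"],
                    reading_frame=info["frame"],
                    anchor=info["anchor"],
                )
            )
        if not segments:
            raise ReferenceFormatError(f"no FASTA records in {fasta_path}")
        return cls.from_segments(segments)


def replace_segment(segment: GermlineSegment, **changes) -> GermlineSegment:
    """Dataclass ``replace`` passthrough (kept for test ergonomics)."""
    return dataclasses.replace(segment, **changes)
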