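"""Somatic-hypermutation and antigen-selection statistics.

Mutations are called per non-N column against the germline projection of an
annotated read; each mutation is classified replacement (R) or silent (S)
against its germline codon context, with the single position mutated and the
other codon positions held at germline (co-mutated codons are therefore
classified per mutation independently).  Region R/S ratios are compared with
2.845, the inherent mean R/S ratio of human germline VH genes, to read out
structural selection in the frameworks; the 12-entry substitution spectrum
flags formalin-type deamination artifact patterns (G>A / C>T dominance).
N-glycosylation sequons (Asn-X-Ser/Thr) are scanned on amino-acid sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._seq import translate_codon
from .vdj import VDJAligner, VDJAnnotation

#: Inherent mean R/S ratio of human germline VH genes (literature constant).
GERMLINE_EXPECTED_RS = 2.845

CDR_REGIONS = ("CDR1", "CDR2", "CDR3")
FR_REGIONS = ("FR1", "FR2", "FR3")


@dataclass(frozen=True)
class MutationRecord:
    position: int  # read coordinate (0-based)
    germline_position: int  # coordinate on the aligned germline segment
    segment: str  # segment name the germline base came from
    region: str  # FR2 | CDR2 | FR3 | CDR3 | J ...
    from_base: str
    to_base: str
    rs_class: str  # "R" | "S" | "unclassified"
    codon_index: int  # codon number in the read frame

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError("mutation must change the base")


def call_mutations(
    annotation: VDJAnnotation, aligner: VDJAligner
) -> list[MutationRecord]:
    """One record per mismatched non-N column of the germline projection.

    The unsequenced gap (N on the read) and junction N-regions (N on the
    germline projection) are excluded by construction.
    """
    if not annotation.specific:
        return []
    gl = aligner.germline_projection(annotation)
    seq = annotation.sequence
    regions = sorted(annotation.region_map.items(), key=lambda kv: kv[1][0])

    def region_of(p: int) -> str | None:
        for name, (lo, hi) in regions:
            if lo <= p < hi:
                return name
        return None

    def segment_of(p: int) -> tuple[str, int]:
        if annotation.cdr3_interval and annotation.cdr3_interval[0] <= p < annotation.cdr3_interval[1]:
            d = annotation.d_alignment
            if d is not None:
                base = annotation.cdr3_interval[0] + d.junction_start
                if base <= p < base + d.length:
                    return d.name, d.d_start + (p - base)
            return "junction", p - annotation.cdr3_interval[0]
        if annotation.j_alignment and p >= -annotation.j_alignment.offset:
            return annotation.j_alignment.name, p + annotation.j_alignment.offset
        if annotation.v_alignment:
            return annotation.v_alignment.name, p + annotation.v_alignment.offset
        return "?", p

    frame = annotation.frame_offset
    records = []
    for p in range(len(seq)):
        if seq[p] == "N" or gl[p] == "N" or seq[p] == gl[p]:
            continue
        region = region_of(p)
        if region is None:
            continue
        codon_index = (p - frame) // 3 if p >= frame else -1
        rs = classify_rs(gl, p, seq[p], frame)
        segment, gpos = segment_of(p)
        records.append(
            MutationRecord(
                position=p,
                germline_position=gpos,
                segment=segment,
                region=region,
                from_base=gl[p],
                to_base=seq[p],
                rs_class=rs,
                codon_index=codon_index,
            )
        )
    return records


def classify_rs(germline: str, position: int, to_base: str, frame_offset: int = 0) -> str:
    """R (replacement) / S (silent) against the germline codon context.

    The single ``position`` is mutated to ``to_base`` with the other codon
    positions held at germline; R iff the encoded amino acid changes.
    Unclassified when the position lies before the first full codon, the
    codon is truncated, or any codon base is N.
    """
    if position < frame_offset:
        return "unclassified"
    c0 = frame_offset + 3 * ((position - frame_offset) // 3)
    codon = germline[c0 : c0 + 3]
    if len(codon) < 3 or "N" in codon or "N" == to_base:
        return "unclassified"
    mutant = codon[: position - c0] + to_base + codon[position - c0 + 1 :]
    aa_old = translate_codon(codon)
    aa_new = translate_codon(mutant)
    if aa_old == "X" or aa_new == "X":
        return "unclassified"
    return "R" if aa_old != aa_new else "S"


@dataclass
class RegionRS:
    region: str
    r_count: int
    s_count: int

    @property
    def ratio(self) -> float | None:
        """R/S ratio; undefined (None) when S = 0."""
        return self.r_count / self.s_count if self.s_count else None

    @property
    def undefined(self) -> bool:
        return self.s_count == 0


@dataclass
class SelectionSummary:
    """Per-region R/S accounting with the germline expectation attached."""

    per_region: dict[str, RegionRS]
    cdr: RegionRS
    fr: RegionRS
    j: RegionRS
    n_unclassified: int
    germline_expected_ratio: float = GERMLINE_EXPECTED_RS
    spectrum: Counter = field(default_factory=Counter)
    artifact_flag: bool = False

    @property
    def fr_below_germline_expectation(self) -> bool | None:
        """Structural-selection readout: is the framework R/S below 2.845?"""
        if self.fr.ratio is None:
            return None
        return self.fr.ratio < self.germline_expected_ratio


def region_rs_ratio(records: list[MutationRecord], regions: tuple[str, ...], label: str) -> RegionRS:
    r = sum(1 for m in records if m.region in regions and m.rs_class == "R")
    s = sum(1 for m in records if m.region in regions and m.rs_class == "S")
    return RegionRS(label, r, s)


def substitution_spectrum(
    records: list[MutationRecord], artifact_fraction_threshold: float = 0.6
) -> tuple[Counter, bool]:
    """12-entry substitution table (sense strand) plus a deamination flag.

    The flag is raised when G>A and C>T transitions together exceed
    ``artifact_fraction_threshold`` of all mutations — the formalin-fixation
    signature (deamination of cytosines).
    """
    spectrum: Counter = Counter()
    for m in records:
        spectrum[f"{m.from_base}>{m.to_base}"] += 1
    total = sum(spectrum.values())
    flag = (
        total > 0
        and (spectrum["G>A"] + spectrum["C>T"]) / total > artifact_fraction_threshold
    )
    return spectrum, flag


def selection_summary(
    records: list[MutationRecord], artifact_fraction_threshold: float = 0.6
) -> SelectionSummary:
    """Aggregate R/S per region plus CDR-pooled, FR-pooled and J entries."""
    per_region: dict[str, RegionRS] = {}
    for region in sorted({m.region for m in records}):
        per_region[region] = region_rs_ratio(records, (region,), region)
    spectrum, flag = substitution_spectrum(records, artifact_fraction_threshold)
    return SelectionSummary(
        per_region=per_region,
        cdr=region_rs_ratio(records, CDR_REGIONS, "CDR"),
        fr=region_rs_ratio(records, FR_REGIONS, "FR"),
        j=region_rs_ratio(records, ("J",), "J"),
        n_unclassified=sum(1 for m in records if m.rs_class == "unclassified"),
        spectrum=spectrum,
        artifact_flag=flag,
    )


def scan_sequons(aa_sequence: str, mode: str = "paper-literal") -> list[int]:
    """Positions of N-glycosylation sequons (Asn-X-Ser/Thr) in an aa string.

    ``paper-literal`` (default) places no constraint on the middle residue;
    ``strict`` additionally excludes proline there (the biochemical rule).
    An unknown residue (X) at any of the three motif positions never
    matches.
    """
    if mode not in ("paper-literal", "strict"):
        raise ValueError(f"unknown sequon mode {mode!r}")
    hits = []
    for i in range(len(aa_sequence) - 2):
        n, x, st = aa_sequence[i], aa_sequence[i + 1], aa_sequence[i + 2]
        if n != "N" or st not in "ST" or "X" in (n, x, st):
            continue
        if mode == "strict" and x == "P":
            continue
        hits.append(i)
    return hits


def mutations_to_table(records_by_uid: dict[str, list[MutationRecord]]) -> pd.DataFrame:
    rows = []
    for uid, records in records_by_uid.items():
        for m in records:
            rows.append(
                {
                    "sequence_id": uid,
                    "position": m.position,
                    "germline_position": m.germline_position,
                    "segment": m.segment,
                    "region": m.region,
                    "from_base": m.from_base,
                    "to_base": m.to_base,
                    "rs_class": m.rs_class,
                    "codon_index": m.codon_index,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "position", "germline_position", "segment",
            "region", "from_base", "to_base", "rs_class", "codon_index",
        ],
    )
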