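"""Clone-specific read discrimination and CDR3 clonotype grouping.

Reads are discriminated against the monoclonal reference rearrangement (the
Sanger-derived clonal sequence): a read is clone-specific when its V gene,
J gene and CDR3 amino-acid length agree with the reference and its CDR3
amino-acid identity reaches the threshold.  Clone-specific reads are then
partitioned into groups of identical CDR3 amino-acid sequence; unproductive
rearrangements form their own groups.  D-gene agreement is deliberately not
required for membership — junction mutations readily obscure the short D
match — and "profound difference" is operationalized as failing any of the
four rules above.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .read_processing import UniqueSequence
from .vdj import VDJAligner, VDJAnnotation


class CloneAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class CloneReference:
    """The monoclonal reference rearrangement (annotated)."""

    sequence: str
    annotation: VDJAnnotation
    label: str = "monoclonal-reference"

    def __post_init__(self) -> None:
        if not self.annotation.productive:
            raise CloneAnalysisError(
                "the monoclonal reference must be a productive rearrangement"
            )

    @classmethod
    def from_sequence(cls, sequence: str, aligner: VDJAligner, label: str = "monoclonal-reference") -> "CloneReference":
        return cls(sequence, aligner.annotate(sequence), label)


@dataclass(frozen=True)
class CloneDecision:
    clone_specific: bool
    reason: str | None  # failed criterion, None when clone-specific
    cdr3_identity: float


def classify_against_reference(
    annotation: VDJAnnotation,
    clone_reference: CloneReference,
    cdr3_identity_threshold: float = 0.70,
) -> CloneDecision:
    """Clone-specific iff V gene, J gene, CDR3 length and CDR3 identity all
    agree with the monoclonal reference.

    The decision records which criterion failed.  CDR3 identity is the
    fraction of equal amino-acid positions (X counts as a mismatch against
    anything but X).
    """
    ref = clone_reference.annotation
    if not annotation.specific:
        return CloneDecision(False, "nonspecific", 0.0)
    if annotation.v_gene != ref.v_gene:
        return CloneDecision(False, "V-mismatch", 0.0)
    if annotation.j_gene != ref.j_gene:
        return CloneDecision(False, "J-mismatch", 0.0)
    if len(annotation.cdr3_aa) != len(ref.cdr3_aa):
        return CloneDecision(False, "CDR3-length", 0.0)
    matches = sum(a == b for a, b in zip(annotation.cdr3_aa, ref.cdr3_aa))
    identity = matches / len(ref.cdr3_aa) if ref.cdr3_aa else 0.0
    if identity < cdr3_identity_threshold:
        return CloneDecision(False, "CDR3-identity", identity)
    return CloneDecision(True, None, identity)


@dataclass
class CloneGroup:
    """Clone-specific unique sequences sharing an identical CDR3 aa sequence."""

    group_id: str
    cdr3_aa: str
    productive: bool
    members: list[str]  # unique-sequence ids
    per_sample_counts: dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.per_sample_counts.values())


@dataclass(frozen=True)
class AnnotatedUnique:
    """One unique sequence with its annotation and clone decision."""

    uid: str
    unique: UniqueSequence
    annotation: VDJAnnotation
    decision: CloneDecision


def group_by_cdr3(members: list[AnnotatedUnique]) -> list[CloneGroup]:
    """Exact-string partition of clone-specific uniques on CDR3 aa.

    Productive and unproductive rearrangements never share a group.  Group
    ids G1, G2, ... are assigned by descending total read count, then
    lexicographic CDR3.  The partition is invariant to input order.
    """
    buckets: dict[tuple[str, bool], list[AnnotatedUnique]] = {}
    for m in members:
        if not m.decision.clone_specific:
            raise CloneAnalysisError(
                f"unique {m.uid!r} is not clone-specific; filter before grouping"
            )
        buckets.setdefault((m.annotation.cdr3_aa, m.annotation.productive), []).append(m)
    provisional = []
    for (cdr3_aa, productive), bucket in buckets.items():
        per_sample: dict[str, int] = {}
        for m in bucket:
            per_sample[m.unique.sample_id] = (
                per_sample.get(m.unique.sample_id, 0) + m.unique.count
            )
        provisional.append(
            (sum(per_sample.values()), cdr3_aa, productive, sorted(m.uid for m in bucket), per_sample)
        )
    provisional.sort(key=lambda g: (-g[0], g[1]))
    return [
        CloneGroup(f"G{i + 1}", cdr3_aa, productive, members, per_sample)
        for i, (_, cdr3_aa, productive, members, per_sample) in enumerate(provisional)
    ]


def sample_composition(
    annotated: list[AnnotatedUnique],
    totals: dict[str, int],
    groups: list[CloneGroup],
) -> pd.DataFrame:
    """Per-sample accounting of specific / clone-specific / unproductive reads.

    ``totals`` gives each sample's merged high-quality read count.  A sample
    without any clone-specific reads is flagged not evaluable.  Percentages
    are on the 0-100 scale.
    """
    by_sample: dict[str, dict[str, int]] = {
        s: {"igh_specific": 0, "clone": 0, "unrelated": 0, "clone_unproductive": 0}
        for s in totals
    }
    for m in annotated:
        acc = by_sample.setdefault(
            m.unique.sample_id,
            {"igh_specific": 0, "clone": 0, "unrelated": 0, "clone_unproductive": 0},
        )
        n = m.unique.count
        if m.annotation.specific:
            acc["igh_specific"] += n
        if m.decision.clone_specific:
            acc["clone"] += n
            if not m.annotation.productive:
                acc["clone_unproductive"] += n
        else:
            acc["unrelated"] += n

    group_presence: dict[str, int] = {s: 0 for s in by_sample}
    for g in groups:
        for s, n in g.per_sample_counts.items():
            if n > 0 and s in group_presence:
                group_presence[s] += 1

    rows = []
    for sample_id in sorted(by_sample):
        acc = by_sample[sample_id]
        total = totals.get(sample_id, 0)
        clone = acc["clone"]
        rows.append(
            {
                "sample_id": sample_id,
                "total_reads": total,
                "igh_specific_reads": acc["igh_specific"],
                "clone_specific_reads": clone,
                "pct_clone_specific": 100.0 * clone / total if total else 0.0,
                "pct_unrelated": 100.0 * acc["unrelated"] / total if total else 0.0,
                "pct_unproductive_of_clone": (
                    100.0 * acc["clone_unproductive"] / clone if clone else 0.0
                ),
                "n_groups": group_presence.get(sample_id, 0),
                "evaluable": clone > 0,
            }
        )
    return pd.DataFrame(rows)


def groups_to_table(groups: list[CloneGroup], sample_ids: list[str]) -> pd.DataFrame:
    rows = []
    for g in groups:
        row = {
            "group_id": g.group_id,
            "cdr3_aa": g.cdr3_aa,
            "productive": g.productive,
            "total_count": g.total_count,
        }
        for s in sample_ids:
            row[s] = g.per_sample_counts.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)
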