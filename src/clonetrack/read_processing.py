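"""Read cleanup for FR2 amplicon runs.

Demultiplex barcoded pairs, trim the consensus primers, enforce the
every-base quality floor, merge mates across the unsequenced FR3 gap with a
fixed run of N bases, dereplicate into unique sequences, and drop
sub-threshold-frequency uniques as noise.

Conventions chosen here (documented because the underlying method leaves
them open):

* "per base quality above 20" is read literally: the default floor is
  phred 21 and a base at exactly Q20 fails (configurable).
* the noise-frequency denominator is the sample's total merged high-quality
  read count, i.e. the filter runs before any annotation;
* mate 2 is reverse-complemented before concatenation so the merged
  sequence is on the sense strand;
* barcode matching is exact by default (mismatch allowance is a flag).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from ._seq import hamming, revcomp


class ProcessingError(ValueError):
    pass


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    mate1: str
    qual1: str
    mate2: str
    qual2: str
    barcode: str = ""

    def __post_init__(self) -> None:
        if len(self.mate1) != len(self.qual1) or len(self.mate2) != len(self.qual2):
            raise ProcessingError(
                f"read {self.read_id!r}: sequence/quality length mismatch"
            )


@dataclass(frozen=True)
class UniqueSequence:
    """Dereplicated merged read (N-gap included) with per-sample frequency."""

    sequence: str
    count: int
    frequency: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ProcessingError("unique sequence count must be >= 1")


@dataclass
class ProcessingConfig:
    min_base_quality: int = 21  # strict reading of "above 20"
    noise_frequency_threshold: float = 0.001
    gap_n_count: int = 44
    fwd_primer: str = ""
    rev_primer: str = ""
    max_primer_mismatches: int = 0
    max_barcode_mismatches: int = 0
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.min_base_quality <= 0 or self.noise_frequency_threshold < 0:
            raise ProcessingError("thresholds must be positive")
        if self.gap_n_count < 0:
            raise ProcessingError("gap_n_count must be >= 0")


# -- demultiplexing ----------------------------------------------------------


def demultiplex(
    reads: Iterable[ReadPair],
    barcode_map: dict[str, str],
    max_mismatches: int = 0,
) -> tuple[dict[str, list[ReadPair]], list[ReadPair]]:
    """Partition reads by barcode.

    ``barcode_map`` maps sample_id -> barcode.  Each read goes to the unique
    sample whose barcode matches within ``max_mismatches`` (default exact);
    ambiguous or unmatched reads land in the unassigned set.  The partition
    property (sum of sample sizes + unassigned = input size) always holds.
    """
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ProcessingError("duplicate barcodes in the sample sheet")
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise ProcessingError("barcodes must all have equal length")
    by_barcode = {b: s for s, b in barcode_map.items()}
    assigned: dict[str, list[ReadPair]] = {s: [] for s in barcode_map}
    unassigned: list[ReadPair] = []
    for read in reads:
        if max_mismatches == 0:
            sample = by_barcode.get(read.barcode)
            if sample is None:
                unassigned.append(read)
            else:
                assigned[sample].append(read)
            continue
        hits = [
            s
            for b, s in by_barcode.items()
            if len(read.barcode) == len(b) and hamming(read.barcode, b) <= max_mismatches
        ]
        if len(hits) == 1:
            assigned[hits[0]].append(read)
        else:
            unassigned.append(read)
    return assigned, unassigned


# -- primer trimming ---------------------------------------------------------


@dataclass(frozen=True)
class TrimResult:
    pair: ReadPair | None
    reason: str | None  # None when trimmed successfully


def trim_primers(
    pair: ReadPair,
    fwd_primer: str,
    rev_primer: str,
    max_mismatches: int = 0,
) -> TrimResult:
    """Remove the forward primer from mate 1 and the reverse primer from
    mate 2 (both at the 5' end); reject pairs lacking either primer."""
    for mate, primer, reason in (
        (pair.mate1, fwd_primer, "missing-forward-primer"),
        (pair.mate2, rev_primer, "missing-reverse-primer"),
    ):
        if len(mate) < len(primer) or hamming(mate[: len(primer)], primer) > max_mismatches:
            return TrimResult(None, reason)
    nf, nr = len(fwd_primer), len(rev_primer)
    trimmed = ReadPair(
        read_id=pair.read_id,
        mate1=pair.mate1[nf:],
        qual1=pair.qual1[nf:],
        mate2=pair.mate2[nr:],
        qual2=pair.qual2[nr:],
        barcode=pair.barcode,
    )
    return TrimResult(trimmed, None)


# -- quality filter ----------------------------------------------------------


def quality_filter(pair: ReadPair, min_base_quality: int = 21, phred_offset: int = 33) -> bool:
    """Pass iff every base of both mates has phred >= ``min_base_quality``."""
    floor = chr(phred_offset + min_base_quality)
    return (not pair.qual1 or min(pair.qual1) >= floor) and (
        not pair.qual2 or min(pair.qual2) >= floor
    )


# -- merging -----------------------------------------------------------------


def merge_with_gap(pair: ReadPair, gap_n_count: int = 44) -> str:
    """mate1 + N*gap + revcomp(mate2): the sense-strand merged sequence.

    The merged length is always ``|mate1| + gap + |mate2|``; with untrimmed
    112 nt mates and the default 44 nt gap this reproduces the 268 bp design
    length of the clonal amplicon.
    """
    return pair.mate1 + "N" * gap_n_count + revcomp(pair.mate2)


# -- dereplication and noise filtering --------------------------------------


def dereplicate(merged: Sequence[str], sample_id: str) -> list[UniqueSequence]:
    """Exact-string grouping; frequencies are computed against the sample's
    merged total (the pre-noise-filter denominator).  Sorted by descending
    count, then sequence."""
    if not merged:
        raise ProcessingError(f"sample {sample_id!r}: no merged reads to dereplicate")
    counts: dict[str, int] = {}
    for seq in merged:
        counts[seq] = counts.get(seq, 0) + 1
    total = len(merged)
    uniques = [
        UniqueSequence(seq, n, n / total, sample_id) for seq, n in counts.items()
    ]
    uniques.sort(key=lambda u: (-u.count, u.sequence))
    return uniques


def noise_filter(
    uniques: Sequence[UniqueSequence], threshold: float = 0.001
) -> list[UniqueSequence]:
    """Drop uniques with frequency strictly below ``threshold``.

    A unique at exactly the threshold is retained ("below 0.1%" excludes the
    boundary).  Counts and frequencies of retained uniques are unchanged, so
    the filter is idempotent.
    """
    return [u for u in uniques if u.frequency >= threshold]


# -- per-sample orchestration ------------------------------------------------


@dataclass
class SampleReads:
    """Processing output for one sample."""

    sample_id: str
    uniques: list[UniqueSequence]
    n_merged: int  # high-quality merged reads (noise-filter denominator)
    read_ids: dict[str, list[str]] = field(default_factory=dict)  # seq -> read ids


@dataclass
class ProcessingResult:
    samples: dict[str, SampleReads]
    unassigned: int
    rejections: pd.DataFrame  # sample_id, reason, count


def process_reads(
    reads: Iterable[ReadPair],
    barcode_map: dict[str, str],
    config: ProcessingConfig,
    keep_read_ids: bool = False,
) -> ProcessingResult:
    """Full cleanup: demultiplex -> trim -> quality filter -> merge ->
    dereplicate -> noise filter, with a rejection log."""
    assigned, unassigned = demultiplex(
        reads, barcode_map, config.max_barcode_mismatches
    )
    samples: dict[str, SampleReads] = {}
    log_rows: list[tuple[str, str, int]] = []
    for sample_id, sample_reads in assigned.items():
        merged: list[str] = []
        ids_by_seq: dict[str, list[str]] = {}
        reasons: dict[str, int] = {}
        for pair in sample_reads:
            trim = trim_primers(
                pair, config.fwd_primer, config.rev_primer, config.max_primer_mismatches
            )
            if trim.pair is None:
                reasons[trim.reason] = reasons.get(trim.reason, 0) + 1
                continue
            if not quality_filter(trim.pair, config.min_base_quality, config.phred_offset):
                reasons["low-quality"] = reasons.get("low-quality", 0) + 1
                continue
            seq = merge_with_gap(trim.pair, config.gap_n_count)
            merged.append(seq)
            if keep_read_ids:
                ids_by_seq.setdefault(seq, []).append(pair.read_id)
        for reason, n in sorted(reasons.items()):
            log_rows.append((sample_id, reason, n))
        if not merged:
            samples[sample_id] = SampleReads(sample_id, [], 0, {})
            continue
        uniques = dereplicate(merged, sample_id)
        kept = noise_filter(uniques, config.noise_frequency_threshold)
        n_noise = len(uniques) - len(kept)
        if n_noise:
            log_rows.append((sample_id, "noise-frequency", n_noise))
        samples[sample_id] = SampleReads(
            sample_id,
            kept,
            len(merged),
            {u.sequence: ids_by_seq.get(u.sequence, []) for u in kept}
            if keep_read_ids
            else {},
        )
    rejections = pd.DataFrame(log_rows, columns=["sample_id", "reason", "count"])
    return ProcessingResult(samples, len(unassigned), rejections)


# -- FASTQ I/O ---------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from mate FASTQ files (gzip ok).

    The sample barcode is expected as a ``BC:<seq>`` token on the header
    line (the generator's header dialect); headers without the tag yield an
    empty barcode.
    """
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        while True:
            h1 = f1.readline().strip()
            if not h1:
                return
            s1 = f1.readline().strip()
            f1.readline()
            q1 = f1.readline().strip()
            h2 = f2.readline().strip()
            s2 = f2.readline().strip()
            f2.readline()
            q2 = f2.readline().strip()
            rid = h1[1:].split()[0]
            rid2 = h2[1:].split()[0]
            if rid != rid2:
                raise ProcessingError(f"mate files out of sync at {rid!r} / {rid2!r}")
            barcode = ""
            for token in h1.split()[1:]:
                if token.startswith("BC:"):
                    barcode = token[3:]
            yield ReadPair(rid, s1, q1, s2, q2, barcode)


def write_unique_fasta(sample: SampleReads, path: str | Path) -> None:
    """Per-sample FASTA of unique sequences, headers ``>uid;count=N;freq=F``."""
    with open(path, "w") as fh:
        for i, u in enumerate(sample.uniques, start=1):
            fh.write(
                f">{sample.sample_id}_U{i:04d};count={u.count};freq={u.frequency:.6f}\n"
                f"{u.sequence}\n"
            )
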