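"""Small nucleotide/codon helpers shared across modules."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
NON_STOP_CODONS = tuple(sorted(set(CODON_TABLE) - STOP_CODONS))

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing a non-ACGT base is unknown (X)."""
    return CODON_TABLE.get(codon, "X")


def translate(seq: str, frame_offset: int = 0) -> str:
    """Codon-wise translation from ``frame_offset``; trailing partial codon dropped.

    Codons containing N (or any ambiguity) translate to ``X`` and are never
    treated as stops.
    """
    aa = []
    for i in range(frame_offset, len(seq) - 2, 3):
        aa.append(translate_codon(seq[i : i + 3]))
    return "".join(aa)


def hamming(a: str, b: str) -> int:
    """Mismatch count over the shared prefix of two strings."""
    return sum(1 for x, y in zip(a, b) if x != y)
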