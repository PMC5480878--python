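from itertools import product

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrack.pipeline import merged_view
from clonetrack.shm import (
    GERMLINE_EXPECTED_RS,
    call_mutations,
    classify_rs,
    region_rs_ratio,
    scan_sequons,
    selection_summary,
    substitution_spectrum,
)
from clonetrack.simulate import simulate_lineage

BASES = "ACGT"


# -- R/S classification ------------------------------------------------------


def test_classify_rs_agrees_with_exhaustive_codon_enumeration():
    """All 64 codons x 3 positions x 3 alternative bases against a
    translation oracle built directly on Biopython's Seq.translate."""
    for codon_tuple in product(BASES, repeat=3):
        codon = "".join(codon_tuple)
        for pos in range(3):
            for alt in BASES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                aa_old = str(Seq(codon).translate())
                aa_new = str(Seq(mutant).translate())
                want = "R" if aa_old != aa_new else "S"
                assert classify_rs(codon, pos, alt) == want, (codon, pos, alt)


@pytest.mark.parametrize(
    "codon,pos,alt,expected",
    [
        ("GAG", 2, "A", "S"),  # Glu -> Glu
        ("AGT", 1, "A", "R"),  # Ser -> Asn
        ("GAN", 1, "C", "unclassified"),
        ("NAG", 2, "A", "unclassified"),
    ],
)
def test_classify_rs_examples(codon, pos, alt, expected):
    assert classify_rs(codon, pos, alt) == expected


def test_classify_rs_respects_frame_offset():
    germ = "TGAGG"  # frame 1 -> codon GAG at positions 1-3
    assert classify_rs(germ, 3, "A", frame_offset=1) == "S"
    assert classify_rs(germ, 0, "A", frame_offset=1) == "unclassified"


# -- mutation calling --------------------------------------------------------


def test_germline_read_yields_no_mutations(reference, founder_spec, aligner, design):
    lin = simulate_lineage(reference, founder_spec, 0, 0.0, seed=0)
    ann = aligner.annotate(merged_view(lin.amplicon(lin.founder), design))
    assert call_mutations(ann, aligner) == []


def test_engineered_cdr2_substitution_called_once(reference, founder_spec, aligner, design):
    lin = simulate_lineage(reference, founder_spec, 0, 0.0, seed=0)
    merged = merged_view(lin.amplicon(lin.founder), design)
    ann0 = aligner.annotate(merged)
    lo, hi = ann0.region_map["CDR2"]
    pos = next(p for p in range(lo, hi) if merged[p] == "A")
    mutated = merged[:pos] + "G" + merged[pos + 1 :]
    records = call_mutations(aligner.annotate(mutated), aligner)
    assert len(records) == 1
    rec = records[0]
    assert (rec.region, rec.from_base, rec.to_base, rec.position) == ("CDR2", "A", "G", pos)


def test_called_mutations_match_simulator_root_path(reference, founder_spec, aligner, design):
    """Every called mutation is a true root-path mutation; every true
    mutation at a germline-covered, sequenced position is called."""
    lin = simulate_lineage(
        reference, founder_spec, n_rounds=3, mutation_rate=0.01, seed=23,
        children_per_node=2, cdr_bias=1.0,
    )
    node = max(lin.nodes.values(), key=lambda n: n.divergence)
    assert node.divergence > 0
    truth = {}
    cur = node
    while cur is not None:
        for pos, old, new in cur.mutations_from_parent:
            truth.setdefault(pos, (old, new))
        cur = lin.nodes.get(cur.parent_id) if cur.parent_id else None

    merged = merged_view(lin.amplicon(node), design)
    ann = aligner.annotate(merged)
    gl = aligner.germline_projection(ann)
    records = call_mutations(ann, aligner)
    offset = lin.amplicon_start + len(design.fwd_primer)  # merged pos 0 on the full sequence

    called = {r.position: (r.from_base, r.to_base) for r in records}
    for read_pos, (frm, to) in called.items():
        full_pos = read_pos + offset
        assert full_pos in truth
        assert truth[full_pos][1] == to
    for full_pos, (old, new) in truth.items():
        read_pos = full_pos - offset
        if 0 <= read_pos < len(merged) and merged[read_pos] != "N" and gl[read_pos] != "N":
            if gl[read_pos] == lin.germline_sequence[full_pos]:
                assert read_pos in called


# -- region ratios -----------------------------------------------------------


def _mk_records(region, n_r, n_s):
    from clonetrack.shm import MutationRecord

    recs = []
    for i in range(n_r):
        recs.append(MutationRecord(i, i, "V", region, "A", "G", "R", i // 3))
    for i in range(n_s):
        recs.append(MutationRecord(100 + i, 100 + i, "V", region, "C", "T", "S", i))
    return recs


def test_region_ratio_arithmetic():
    assert region_rs_ratio(_mk_records("CDR2", 11, 1), ("CDR2",), "CDR").ratio == pytest.approx(11.0)
    assert region_rs_ratio(_mk_records("FR3", 9, 5), ("FR3",), "FR").ratio == pytest.approx(1.8)


def test_zero_silent_ratio_undefined_but_counted():
    entry = region_rs_ratio(_mk_records("FR2", 3, 0), ("FR2",), "FR")
    assert entry.ratio is None and entry.undefined and entry.r_count == 3


def test_fr_comparison_against_germline_expectation():
    summary = selection_summary(_mk_records("FR3", 9, 5))
    assert summary.germline_expected_ratio == 2.845
    assert summary.fr_below_germline_expectation is True
    high = selection_summary(_mk_records("FR3", 30, 5))
    assert high.fr_below_germline_expectation is False


# -- sequons -----------------------------------------------------------------


def test_sequon_basic_and_proline_modes():
    assert scan_sequons("ANGSW") == [1]
    assert scan_sequons("NPT") == [0]  # paper-literal: no proline rule
    assert scan_sequons("NPT", mode="strict") == []
    assert scan_sequons("NXT") == []  # unknown residue blocks the motif
    assert scan_sequons("QNGTNAS") == [1, 4]


def _sequon_oracle(aa, mode):
    hits = []
    for i in range(len(aa) - 2):
        w = aa[i : i + 3]
        if w[0] == "N" and w[2] in "ST" and "X" not in w:
            if mode == "strict" and w[1] == "P":
                continue
            hits.append(i)
    return hits


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX*", min_size=0, max_size=60))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_sequon_scan_equals_sliding_window_oracle(aa):
    for mode in ("paper-literal", "strict"):
        assert scan_sequons(aa, mode) == _sequon_oracle(aa, mode)


# -- spectrum ----------------------------------------------------------------


def test_spectrum_flags_deamination_dominance():
    recs = _mk_records("FR3", 0, 0)
    from clonetrack.shm import MutationRecord

    recs = [MutationRecord(i, i, "V", "FR3", "G", "A", "R", i) for i in range(3)]
    spectrum, flag = substitution_spectrum(recs)
    assert spectrum == {"G>A": 3} and flag


def test_uniform_spectrum_not_flagged():
    from clonetrack.shm import MutationRecord

    recs = []
    i = 0
    for a in BASES:
        for b in BASES:
            if a != b:
                recs.append(MutationRecord(i, i, "V", "FR3", a, b, "R", i))
                i += 1
    spectrum, flag = substitution_spectrum(recs)
    assert len(spectrum) == 12 and not flag


def test_cdr_bias_raises_cdr_mutation_density(reference, founder_spec, design, aligner):
    """With a 3x CDR rate multiplier, per-site mutation density in the CDRs
    exceeds the frameworks (free SHM, no selection)."""
    lin = simulate_lineage(
        reference, founder_spec, n_rounds=5, mutation_rate=0.004, seed=31,
        children_per_node=3, cdr_bias=3.0, fr_replacement_retention=1.0,
    )
    v = reference[founder_spec.v_allele]
    cdr_sites = set(range(*v.region_bounds["CDR2"])) | set(
        range(lin.cdr3_start, lin.cdr3_end)
    )
    fr_sites = set(range(*v.region_bounds["FR2"])) | set(range(*v.region_bounds["FR3"]))
    lo = lin.amplicon_start + len(design.fwd_primer)
    hi = len(lin.germline_sequence) - len(design.rev_primer)
    cdr_sites = {p for p in cdr_sites if lo <= p < hi}
    fr_sites = {p for p in fr_sites if lo <= p < hi}
    cdr_hits = fr_hits = 0
    for node in lin.nodes.values():
        for pos, _, _ in node.mutations_from_parent:
            if pos in cdr_sites:
                cdr_hits += 1
            elif pos in fr_sites:
                fr_hits += 1
    assert cdr_hits / len(cdr_sites) > fr_hits / len(fr_sites)
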