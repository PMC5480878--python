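import numpy as np
import pytest

from clonetrack.pipeline import merged_view
from clonetrack.shm import substitution_spectrum
from clonetrack.simulate import (
    AmpliconDesign,
    LineageError,
    FounderSpec,
    SimulationConfig,
    SimulationConfigError,
    build_germline_set,
    default_founder_spec,
    distribute_to_follicles,
    hbl1_control_preset,
    simulate_lineage,
    simulate_run,
    synthesize_reads,
)


def test_reference_deterministic_for_seed(base_config):
    a = build_germline_set(base_config)
    b = build_germline_set(base_config)
    assert a == b


def test_rates_validated():
    with pytest.raises(SimulationConfigError, match="migration_rate"):
        SimulationConfig(migration_rate=1.5, random_seed=0)


def test_zero_mutation_rate_keeps_all_nodes_identical(reference, founder_spec):
    lin = simulate_lineage(reference, founder_spec, n_rounds=3, mutation_rate=0.0, seed=3)
    founder = lin.founder.full_sequence
    assert all(n.full_sequence == founder for n in lin.nodes.values())


def test_unknown_founder_allele_rejected(reference, founder_spec):
    bad = FounderSpec("IGHV9-NOPE*01", founder_spec.d_allele, founder_spec.j_allele,
                      founder_spec.n1, founder_spec.n2)
    with pytest.raises(LineageError, match="IGHV9-NOPE"):
        simulate_lineage(reference, bad, 1, 0.0, seed=0)


def test_mutations_from_parent_reconstruct_child(reference, founder_spec):
    lin = simulate_lineage(reference, founder_spec, n_rounds=3, mutation_rate=0.01, seed=5)
    for node in lin.nodes.values():
        if node.parent_id is None:
            parent_seq = lin.germline_sequence
        else:
            parent_seq = lin.nodes[node.parent_id].full_sequence
        arr = list(parent_seq)
        for pos, old, new in node.mutations_from_parent:
            assert arr[pos] == old
            arr[pos] = new
        assert "".join(arr) == node.full_sequence


def test_per_child_mutation_count_matches_binomial_mean(reference, founder_spec):
    """One round, one child, rate r: mean mutations = r * L within 3 SE."""
    rate = 0.01
    counts = []
    for seed in range(1000):
        lin = simulate_lineage(
            reference, founder_spec, n_rounds=1, mutation_rate=rate, seed=seed,
            children_per_node=1, cdr_bias=1.0,
        )
        child = next(n for n in lin.nodes.values() if n.generation == 1)
        counts.append(len(child.mutations_from_parent))
        L = lin.n_mutable_sites
    expected = rate * L
    se = np.sqrt(L * rate * (1 - rate)) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - expected) <= 3 * se


def test_founder_round_trips_through_annotation(reference, founder_spec, aligner, design):
    """The recombined founder annotates back to its own V/D/J alleles."""
    lin = simulate_lineage(reference, founder_spec, 0, 0.0, seed=0)
    ann = aligner.annotate(merged_view(lin.amplicon(lin.founder), design))
    assert ann.v_call == founder_spec.v_allele
    assert ann.j_call == founder_spec.j_allele
    assert ann.d_call == founder_spec.d_allele
    assert ann.productive


def test_fixed_group_mode_yields_exact_group_count(small_lineage):
    groups = small_lineage.truth_groups()
    assert len(groups) == 5
    labels = list(groups)
    assert sum(1 for l in labels if l.endswith("|U")) == 1
    assert small_lineage.founder_group_label in labels


def test_zero_migration_makes_every_group_private(small_lineage):
    _, occupancy = distribute_to_follicles(small_lineage, 4, 0.0, seed=1)
    assert ((occupancy > 0).sum(axis=1) == 1).all()


def test_full_migration_seeds_every_sample(small_lineage):
    _, occupancy = distribute_to_follicles(small_lineage, 4, 1.0, seed=1)
    assert (occupancy > 0).all().all()


def test_migration_rate_recovers_binomial_mean(small_lineage):
    """Extra-sample seedings per group ~ Binomial(n_samples-1, m)."""
    m, n_samples, n_groups = 0.3, 5, 5
    extra = []
    for seed in range(400):
        _, occ = distribute_to_follicles(small_lineage, n_samples, m, seed=seed)
        extra.extend(((occ > 0).sum(axis=1) - 1).tolist())
    trials = len(extra) * (n_samples - 1)
    se = np.sqrt(m * (1 - m) / trials) * (n_samples - 1)
    assert abs(np.mean(extra) - m * (n_samples - 1)) <= 3 * se


def test_noiseless_pairs_reconstruct_the_true_amplicon(reference, founder_spec):
    cfg = SimulationConfig(
        n_samples=1, n_groups=1, unproductive_groups=0, n_rounds=0, coverage=50,
        contamination_range=(0.0, 0.0), sequencing_error_rate=0.0,
        low_quality_read_fraction=0.0, founder_mutation_count=0, random_seed=3,
    )
    lin = simulate_lineage(reference, founder_spec, 0, 0.0, seed=3)
    samples, _ = distribute_to_follicles(lin, 1, 0.0, seed=3, contamination_range=(0, 0))
    run = synthesize_reads(samples, lin, reference, cfg)
    amplicon = lin.amplicon(lin.founder)
    assert len(amplicon) == 268
    from clonetrack._seq import revcomp
    for r in run.reads:
        assert r.mate1 == amplicon[:112]
        assert revcomp(r.mate2) == amplicon[-112:]


def test_read_pair_count_equals_configured_coverage():
    cfg = SimulationConfig(n_samples=3, coverage=300, random_seed=9)
    run = simulate_run(cfg)
    per_sample = run.truth.groupby("sample_id").size()
    assert (per_sample == 300).all()
    assert len(run.reads) == 900


def test_contamination_fraction_recovered_in_truth(reference, founder_spec):
    cfg = SimulationConfig(
        n_samples=1, coverage=10000, contamination_range=(0.5, 0.5),
        sequencing_error_rate=0.0, low_quality_read_fraction=0.0, random_seed=4,
    )
    lin = simulate_lineage(reference, founder_spec, 1, 0.002, seed=4, n_groups=3)
    samples, _ = distribute_to_follicles(lin, 1, 0.0, seed=4, contamination_range=(0.5, 0.5))
    run = synthesize_reads(samples, lin, reference, cfg)
    n_bg = (run.truth["origin_node_id"] == "background").sum()
    se = np.sqrt(10000 * 0.25)
    assert abs(n_bg - 5000) <= 3 * se


def test_deamination_preset_spectrum_dominated_by_g_to_a_and_c_to_t():
    """Formalin-control preset: called substitutions are G>A / C>T."""
    cfg = hbl1_control_preset(seed=2, coverage=2000)
    run = simulate_run(cfg)
    lin = run.lineage
    founder_amp = lin.amplicon(lin.founder)
    from collections import Counter
    spectrum = Counter()
    node_reads = run.truth[run.truth["origin_node_id"] != "background"]
    for r, origin in zip(run.reads, run.truth["origin_node_id"]):
        read_amp = r.mate1  # artifacts visible on mate 1's sense strand
        for a, b in zip(founder_amp[:112], read_amp):
            if a != b:
                spectrum[f"{a}>{b}"] += 1
    total = sum(spectrum.values())
    assert total > 0
    assert (spectrum["G>A"] + spectrum["C>T"]) == total


def test_run_is_deterministic_per_seed():
    cfg = SimulationConfig(n_samples=2, coverage=200, random_seed=21)
    r1, r2 = simulate_run(cfg), simulate_run(cfg)
    assert [a.__dict__ for a in r1.reads] == [b.__dict__ for b in r2.reads]
    assert r1.truth.equals(r2.truth)
    assert r1.occupancy.equals(r2.occupancy)


def test_written_fastq_round_trips(tmp_path):
    from clonetrack.read_processing import read_fastq_pairs

    cfg = SimulationConfig(n_samples=2, coverage=50, random_seed=13)
    run = simulate_run(cfg, out_dir=tmp_path)
    pairs = list(read_fastq_pairs(tmp_path / "reads_R1.fastq.gz", tmp_path / "reads_R2.fastq.gz"))
    assert len(pairs) == len(run.reads)
    for p, r in zip(pairs, run.reads):
        assert (p.read_id, p.mate1, p.mate2, p.barcode) == (
            r.read_id, r.mate1, r.mate2, r.barcode
        )
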