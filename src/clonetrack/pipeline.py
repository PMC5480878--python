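"""End-to-end orchestration: simulate -> process -> annotate -> clones ->
SHM statistics -> genealogy and trafficking.

R/S statistics are pooled over unique clone-specific sequences (each unique
sequence contributes its mutations once, not read-count-weighted), matching
an analysis that runs on dereplicated sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .clones import (
    AnnotatedUnique,
    CloneGroup,
    CloneReference,
    classify_against_reference,
    group_by_cdr3,
    groups_to_table,
    sample_composition,
)
from .lineage import (
    DistanceMatrix,
    RootedGenealogy,
    TraffickingMatrix,
    build_tree,
    group_consensus,
    pairwise_distances,
    root_to_germline,
    trafficking_matrix,
)
from .read_processing import ProcessingConfig, ProcessingResult, ReadPair, process_reads
from .shm import MutationRecord, SelectionSummary, call_mutations, scan_sequons, selection_summary
from .simulate import AmpliconDesign, SimulationConfig, SyntheticRun, simulate_run
from .vdj import VDJAligner, VDJAnnotation


def merged_view(amplicon: str, design: AmpliconDesign) -> str:
    """What the pipeline's merged read of this amplicon looks like: trimmed
    mate 1, the fixed N gap, trimmed reverse mate."""
    rl = design.read_length
    f = len(design.fwd_primer)
    r = len(design.rev_primer)
    return (
        amplicon[f:rl]
        + "N" * design.gap_n_count
        + amplicon[len(amplicon) - rl : len(amplicon) - r]
    )


@dataclass
class PipelineResult:
    config: SimulationConfig
    run: SyntheticRun
    processing: ProcessingResult
    annotated: list[AnnotatedUnique]
    clone_reference: CloneReference
    groups: list[CloneGroup]
    composition: pd.DataFrame
    mutation_records: dict[str, list[MutationRecord]]
    selection: SelectionSummary | None
    sequons: pd.DataFrame
    distance_matrix: DistanceMatrix | None
    genealogy: RootedGenealogy | None
    trafficking: TraffickingMatrix | None
    group_consensus: dict[str, str] = field(default_factory=dict)

    def groups_table(self) -> pd.DataFrame:
        return groups_to_table(self.groups, list(self.run.sample_sheet["sample_id"]))


def analyze_run(
    run: SyntheticRun,
    processing_config: ProcessingConfig | None = None,
    cdr3_identity_threshold: float = 0.70,
    sim_config: SimulationConfig | None = None,
) -> PipelineResult:
    """Analyze a synthetic (or externally loaded) run end to end."""
    design = run.design
    if processing_config is None:
        processing_config = ProcessingConfig(
            fwd_primer=design.fwd_primer,
            rev_primer=design.rev_primer,
            gap_n_count=design.gap_n_count,
        )
    barcode_map = dict(
        zip(run.sample_sheet["sample_id"], run.sample_sheet["barcode"])
    )
    pairs = [
        ReadPair(r.read_id, r.mate1, r.qual1, r.mate2, r.qual2, r.barcode)
        for r in run.reads
    ]
    processing = process_reads(pairs, barcode_map, processing_config)

    aligner = VDJAligner(run.lineage.reference)
    founder_amplicon = run.lineage.amplicon(run.lineage.founder)
    clone_ref = CloneReference.from_sequence(founder_amplicon, aligner)

    ann_cache: dict[str, VDJAnnotation] = {}
    annotated: list[AnnotatedUnique] = []
    for sample_id in sorted(processing.samples):
        sample = processing.samples[sample_id]
        for i, u in enumerate(sample.uniques, start=1):
            ann = ann_cache.get(u.sequence)
            if ann is None:
                ann = aligner.annotate(u.sequence)
                ann_cache[u.sequence] = ann
            decision = classify_against_reference(ann, clone_ref, cdr3_identity_threshold)
            annotated.append(
                AnnotatedUnique(f"{sample_id}_U{i:04d}", u, ann, decision)
            )

    clone_specific = [a for a in annotated if a.decision.clone_specific]
    groups = group_by_cdr3(clone_specific)
    totals = {s.sample_id: s.n_merged for s in processing.samples.values()}
    composition = sample_composition(annotated, totals, groups)

    # SHM statistics over unique clone-specific sequences (one vote each)
    records: dict[str, list[MutationRecord]] = {}
    seen_seqs: set[str] = set()
    for a in clone_specific:
        if a.unique.sequence in seen_seqs:
            continue
        seen_seqs.add(a.unique.sequence)
        records[a.uid] = call_mutations(a.annotation, aligner)
    # pool distinct mutation events: a mutation shared by many uniques is one
    # event of the clone's history, not one per sequence carrying it
    seen_events: set[tuple[int, str, str]] = set()
    all_records = []
    for recs in records.values():
        for m in recs:
            key = (m.position, m.from_base, m.to_base)
            if key not in seen_events:
                seen_events.add(key)
                all_records.append(m)
    selection = selection_summary(all_records) if all_records else None

    sequon_rows = []
    for g in groups:
        hits = scan_sequons(g.cdr3_aa)
        sequon_rows.append(
            {
                "group_id": g.group_id,
                "cdr3_aa": g.cdr3_aa,
                "productive": g.productive,
                "n_sequons": len(hits),
                "sequon_positions": ",".join(map(str, hits)),
            }
        )
    sequons = pd.DataFrame(
        sequon_rows,
        columns=["group_id", "cdr3_aa", "productive", "n_sequons", "sequon_positions"],
    )

    # genealogy on group consensus sequences, rooted at the germline
    dm = None
    genealogy = None
    consensus: dict[str, str] = {}
    if groups:
        ref_view = merged_view(founder_amplicon, design)
        seq_by_uid = {a.uid: a.unique.sequence for a in clone_specific}
        for g in groups:
            consensus[g.group_id] = group_consensus(
                [seq_by_uid[m] for m in g.members], ref_view
            )
        germ_view = merged_view(
            run.lineage.germline_sequence[run.lineage.amplicon_start :], design
        )
        dm = pairwise_distances({**consensus, "germline": germ_view})
        if len(dm.labels) >= 3:
            tree = build_tree(dm)
            genealogy = root_to_germline(tree, dm, "germline")

    sites = dict(zip(run.sample_sheet["sample_id"], run.sample_sheet["site_label"]))
    trafficking = trafficking_matrix(groups, sites) if groups else None

    return PipelineResult(
        config=sim_config,
        run=run,
        processing=processing,
        annotated=annotated,
        clone_reference=clone_ref,
        groups=groups,
        composition=composition,
        mutation_records=records,
        selection=selection,
        sequons=sequons,
        distance_matrix=dm,
        genealogy=genealogy,
        trafficking=trafficking,
        group_consensus=consensus,
    )


def run_pipeline(
    config: SimulationConfig,
    processing_config: ProcessingConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Simulate a run under ``config`` and analyze it end to end."""
    run = simulate_run(config, out_dir=out_dir)
    result = analyze_run(run, processing_config, sim_config=config)
    if out_dir is not None:
        write_result_tables(result, out_dir)
    return result


def write_result_tables(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.composition.to_csv(out / "composition.tsv", sep="\t", index=False)
    result.groups_table().to_csv(out / "groups.tsv", sep="\t", index=False)
    result.sequons.to_csv(out / "sequons.tsv", sep="\t", index=False)
    if result.trafficking is not None:
        result.trafficking.counts.to_csv(out / "trafficking.tsv", sep="\t")
    if result.genealogy is not None:
        (out / "genealogy.nwk").write_text(result.genealogy.tree.to_newick() + "\n")
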