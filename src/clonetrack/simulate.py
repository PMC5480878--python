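"""Synthetic data generator for clonal IGH FR2 amplicon sequencing studies.

Emulates the experiment this package analyzes: a single t(14;18)-like
founder clone carrying a productive VH3-family rearrangement, diversified by
somatic hypermutation (SHM) into CDR3-defined subclone groups, distributed
with migration across microdissected follicle samples, mixed with polyclonal
contaminating rearrangements, and sequenced as barcoded 2x112 bp paired-end
reads whose fixed read length leaves a 44 nt unsequenced gap in FR3 of the
268 bp clonal amplicon.

The model is substitution-only: SHM, sequencing error and formalin-type
deamination artifacts all preserve sequence length, so alignment stays
ungapped throughout the pipeline.  Ground truth (lineage, group labels,
per-sample occupancy, per-read origin) is carried alongside every output.

Default segment architecture (all coordinates 0-based half-open):

* V: 294 nt; FR1 [0,75) CDR1 [75,99) FR2 [99,150) CDR2 [150,174) FR3 [174,294),
  FR3 ending on the conserved Cys codon.  All V alleles share a 21 nt
  consensus forward-primer site at [105,126) inside FR2.
* J: 46 nt with the conserved Trp codon (CDR3 3' anchor) at [15,18); all J
  alleles share their final 21 nt, the reverse (JH consensus) primer site.
* D: 21 nt.
* Founder junction: 9 nt N1 + D + 3 nt N2 = 33 nt, so the amplicon
  (primer start to primer end) is 189 + 33 + 46 = 268 bp and the CDR3 spans
  16 codons (11 junction + 5 J codons before the Trp anchor).  The N1 region
  is built to encode an N-glycosylation sequon (Asn-X-Thr) as observed for
  follicular-lymphoma-type receptors.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, NON_STOP_CODONS, STOP_CODONS, revcomp, translate
from .reference import GermlineReference, GermlineSegment

# -- default architecture ----------------------------------------------------

V_LEN = 294
V_REGIONS = {
    "FR1": (0, 75),
    "CDR1": (75, 99),
    "FR2": (99, 150),
    "CDR2": (150, 174),
    "FR3": (174, 294),
}
FWD_PRIMER_SITE = (105, 126)  # inside FR2, codon-aligned
J_LEN = 46
J_ANCHOR = 15  # start of conserved Trp codon
REV_PRIMER_SITE = (25, 46)  # on J; shared across alleles
D_LEN = 21
FOUNDER_N1_LEN = 9
FOUNDER_N2_LEN = 3


class SimulationConfigError(ValueError):
    """Raised for invalid simulation settings."""


@dataclass
class SimulationConfig:
    """Experimental-condition knobs for the generator.

    Defaults emulate a multi-follicle clonality experiment at desk scale:
    2x112 bp reads over a 268 bp amplicon (44 nt FR3 gap), eleven
    CDR3 groups of which three are unproductive, per-sample polyclonal
    contamination between 15% and 96%, and one barcode per sample.
    """

    read_length: int = 112
    target_amplicon_length: int = 268
    n_v: int = 4
    n_d: int = 2
    n_j: int = 2
    allele_divergence: int = 20  # nt differences between V alleles
    n_samples: int = 8
    n_groups: int | None = 11
    unproductive_groups: int = 3
    founder_mutation_count: int = 10  # founder divergence from germline
    mutation_rate_per_round: float = 0.002
    n_rounds: int = 4
    children_per_node: int = 2
    cdr_bias: float = 3.0
    fr_replacement_retention: float = 0.5
    migration_rate: float = 0.3
    contamination_range: tuple[float, float] = (0.15, 0.96)
    contaminant_frameshift_prob: float = 0.2
    sequencing_error_rate: float = 0.001
    deamination_artifact_rate: float = 0.0
    coverage: int = 5000
    low_quality_read_fraction: float = 0.02
    barcode_length: int = 7
    random_seed: int = 0
    reference_fasta: str | None = None
    reference_bounds: str | None = None

    def __post_init__(self) -> None:
        rates = {
            "mutation_rate_per_round": self.mutation_rate_per_round,
            "migration_rate": self.migration_rate,
            "contaminant_frameshift_prob": self.contaminant_frameshift_prob,
            "sequencing_error_rate": self.sequencing_error_rate,
            "deamination_artifact_rate": self.deamination_artifact_rate,
            "low_quality_read_fraction": self.low_quality_read_fraction,
            "fr_replacement_retention": self.fr_replacement_retention,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0,1], got {value}")
        lo, hi = self.contamination_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise SimulationConfigError(
                f"contamination_range must satisfy 0 <= lo <= hi <= 1, got {self.contamination_range}"
            )
        if self.read_length < 1:
            raise SimulationConfigError("read_length must be >= 1")
        if self.random_seed is None:
            raise SimulationConfigError("random_seed is mandatory")
        if self.n_groups is not None and self.unproductive_groups >= self.n_groups:
            raise SimulationConfigError(
                "unproductive_groups must be smaller than n_groups"
            )


def hbl1_control_preset(seed: int = 0, coverage: int = 20000) -> SimulationConfig:
    """Formalin-artifact control preset.

    A monoclonal sample without ongoing SHM, sequenced after formalin
    fixation: no contamination, no migration, and a cytosine-deamination
    artifact process (G>A / C>T on the amplicon sense strand).  The per-base
    artifact rate 0.0018 is set so that roughly one fifth of reads carry at
    least one artifact over the ~134 deaminable (G/C) amplicon positions,
    matching the burden expected for an archival fixed cell-line control.
    """
    return SimulationConfig(
        n_samples=1,
        n_groups=1,
        unproductive_groups=0,
        n_rounds=0,
        founder_mutation_count=10,
        migration_rate=0.0,
        contamination_range=(0.0, 0.0),
        sequencing_error_rate=0.0,
        deamination_artifact_rate=0.0018,
        low_quality_read_fraction=0.0,
        coverage=coverage,
        random_seed=seed,
    )


# -- amplicon design ---------------------------------------------------------


@dataclass(frozen=True)
class AmpliconDesign:
    """Primer pair and read geometry of the FR2 assay."""

    fwd_primer: str
    rev_primer: str
    v_start: int  # forward primer start on every V segment
    read_length: int
    target_amplicon_length: int

    @property
    def gap_n_count(self) -> int:
        """Unsequenced gap for the design-length amplicon: 268 - 2*112 = 44."""
        return self.target_amplicon_length - 2 * self.read_length

    @classmethod
    def from_reference(
        cls,
        reference: GermlineReference,
        read_length: int = 112,
        target_amplicon_length: int = 268,
    ) -> "AmpliconDesign":
        v = reference.v_segments[0]
        fwd = v.sequence[FWD_PRIMER_SITE[0] : FWD_PRIMER_SITE[1]]
        for other in reference.v_segments[1:]:
            if other.sequence[FWD_PRIMER_SITE[0] : FWD_PRIMER_SITE[1]] != fwd:
                raise SimulationConfigError(
                    "V segments do not share the consensus forward-primer site"
                )
        j = reference.j_segments[0]
        tail = j.sequence[REV_PRIMER_SITE[0] : REV_PRIMER_SITE[1]]
        for other in reference.j_segments[1:]:
            if other.sequence[REV_PRIMER_SITE[0] : REV_PRIMER_SITE[1]] != tail:
                raise SimulationConfigError(
                    "J segments do not share the consensus reverse-primer site"
                )
        if target_amplicon_length < len(fwd) + len(tail):
            raise SimulationConfigError("amplicon shorter than the primer pair")
        return cls(
            fwd_primer=fwd,
            rev_primer=revcomp(tail),
            v_start=FWD_PRIMER_SITE[0],
            read_length=read_length,
            target_amplicon_length=target_amplicon_length,
        )


# -- germline synthesis ------------------------------------------------------


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(NON_STOP_CODONS), size=n)
    return "".join(NON_STOP_CODONS[i] for i in idx)


def _repair_stops(seq: str, rng: np.random.Generator) -> str:
    """Replace any in-frame stop codon with a random non-stop codon."""
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            codons[i] = NON_STOP_CODONS[rng.integers(0, len(NON_STOP_CODONS))]
    return "".join(codons) + seq[len(codons) * 3 :]


def build_germline_set(config: SimulationConfig) -> GermlineReference:
    """Synthesize (or load) a germline V/D/J reference.

    When ``config.reference_fasta`` is set, the reference is read from disk
    and validated.  Otherwise ``n_v``/``n_d``/``n_j`` alleles are generated
    deterministically from ``random_seed``; V alleles share the consensus
    forward-primer site and the terminal Cys codon, J alleles share the
    reverse-primer tail and the Trp anchor, and extra alleles diverge from
    the first by ``allele_divergence`` substitutions (VH-family style).
    """
    if config.reference_fasta is not None:
        if config.reference_bounds is None:
            raise SimulationConfigError(
                "reference_fasta requires reference_bounds as well"
            )
        return GermlineReference.read(config.reference_fasta, config.reference_bounds)

    if config.n_v < 2 or config.n_d < 2 or config.n_j < 2:
        raise SimulationConfigError("need at least 2 alleles per segment class")
    rng = np.random.default_rng(config.random_seed)

    base_v = _random_codons(rng, V_LEN // 3 - 1) + "TGT"  # conserved Cys closes FR3
    segments: list[GermlineSegment] = []
    protected = set(range(*FWD_PRIMER_SITE)) | set(range(V_LEN - 3, V_LEN))
    for i in range(config.n_v):
        seq = base_v
        if i > 0:
            arr = list(seq)
            candidates = [p for p in range(V_LEN) if p not in protected]
            picks = rng.choice(len(candidates), size=config.allele_divergence, replace=False)
            for p in picks:
                pos = candidates[p]
                choices = [b for b in BASES if b != arr[pos]]
                arr[pos] = choices[rng.integers(0, 3)]
            seq = _repair_stops("".join(arr), rng)
            # repair may touch primer-site codons; restore the shared site
            seq = (
                seq[: FWD_PRIMER_SITE[0]]
                + base_v[FWD_PRIMER_SITE[0] : FWD_PRIMER_SITE[1]]
                + seq[FWD_PRIMER_SITE[1] : -3]
                + "TGT"
            )
        segments.append(
            GermlineSegment(
                name=f"IGHV3-S{i + 1:02d}*01",
                segment_class="V",
                sequence=seq,
                region_bounds=dict(V_REGIONS),
            )
        )

    seen_d: set[str] = set()
    for i in range(config.n_d):
        # stop-free in frame 0 so a frame-preserving junction with the D in
        # frame stays productive
        while True:
            d = _random_codons(rng, D_LEN // 3)
            if d not in seen_d:
                seen_d.add(d)
                break
        segments.append(
            GermlineSegment(name=f"IGHD2-S{i + 1:02d}*01", segment_class="D", sequence=d)
        )

    j_shared = "TGG" + _random_codons(rng, 9) + BASES[rng.integers(0, 4)]
    assert len(j_shared) == J_LEN - J_ANCHOR
    seen_j: set[str] = set()
    for i in range(config.n_j):
        while True:
            prefix = _random_codons(rng, J_ANCHOR // 3)
            if prefix not in seen_j:
                seen_j.add(prefix)
                break
        segments.append(
            GermlineSegment(
                name=f"IGHJ4-S{i + 1:02d}*01",
                segment_class="J",
                sequence=prefix + j_shared,
                anchor=J_ANCHOR,
            )
        )
    return GermlineReference.from_segments(segments)


# -- lineage simulation ------------------------------------------------------


@dataclass(frozen=True)
class FounderSpec:
    """Names the founder's alleles and junction N-nucleotides."""

    v_allele: str
    d_allele: str
    j_allele: str
    n1: str
    n2: str


def default_founder_spec(reference: GermlineReference, seed: int = 0) -> FounderSpec:
    """Founder rearrangement with a sequon-bearing junction.

    N1 encodes Asn-X-Thr (AAT / random codon / ACT), placing one
    N-glycosylation sequon at the start of the CDR3, as characteristic of
    FL-type receptors; N2 pads the junction to a multiple of three so the
    rearrangement is productive and the default amplicon is exactly 268 bp.
    """
    rng = np.random.default_rng(seed)
    n1 = "AAT" + _random_codons(rng, 1) + "ACT"
    n2 = _random_codons(rng, FOUNDER_N2_LEN // 3)  # in-frame, stop-free pad
    return FounderSpec(
        v_allele=reference.v_segments[0].name,
        d_allele=reference.d_segments[0].name,
        j_allele=reference.j_segments[0].name,
        n1=n1,
        n2=n2,
    )


@dataclass(frozen=True)
class LineageNode:
    """One subclone in the SHM genealogy (substitution-only model)."""

    node_id: str
    parent_id: str | None
    full_sequence: str
    mutations_from_parent: tuple[tuple[int, str, str], ...]
    generation: int
    cdr3_aa: str
    productive: bool
    divergence: int  # substitutions vs the germline recombination


@dataclass
class Lineage:
    """Rooted SHM genealogy plus the germline recombination it grew from."""

    founder_id: str
    nodes: dict[str, LineageNode]
    germline_sequence: str
    cdr3_start: int
    cdr3_end: int
    amplicon_start: int
    n_mutable_sites: int
    reference: GermlineReference
    founder_spec: FounderSpec

    @property
    def founder(self) -> LineageNode:
        return self.nodes[self.founder_id]

    def group_label(self, node: LineageNode) -> str:
        return f"{node.cdr3_aa}|{'P' if node.productive else 'U'}"

    def truth_groups(self) -> dict[str, list[str]]:
        """Ground-truth CDR3 groups: label -> node ids, founder group first."""
        groups: dict[str, list[str]] = {}
        order = sorted(self.nodes.values(), key=lambda n: (n.generation, n.node_id))
        for node in order:
            groups.setdefault(self.group_label(node), []).append(node.node_id)
        return groups

    @property
    def founder_group_label(self) -> str:
        return self.group_label(self.founder)

    def amplicon(self, node: LineageNode) -> str:
        return node.full_sequence[self.amplicon_start :]


class LineageError(ValueError):
    pass


def _recombine(reference: GermlineReference, spec: FounderSpec) -> tuple[str, int, int]:
    """Germline V+N1+D+N2+J sequence and its CDR3 interval."""
    for allele in (spec.v_allele, spec.d_allele, spec.j_allele):
        if allele not in reference:
            raise LineageError(f"founder spec references unknown allele {allele!r}")
    v = reference[spec.v_allele]
    d = reference[spec.d_allele]
    j = reference[spec.j_allele]
    if v.segment_class != "V" or d.segment_class != "D" or j.segment_class != "J":
        raise LineageError("founder spec alleles have wrong segment classes")
    junction = spec.n1 + d.sequence + spec.n2
    full = v.sequence + junction + j.sequence
    cdr3_start = v.fr3_end  # = len(v) in the default architecture
    cdr3_end = len(v.sequence) + len(junction) + (j.anchor or 0)
    return full, cdr3_start, cdr3_end


def _node_from_sequence(
    node_id: str,
    parent: LineageNode | None,
    seq: str,
    muts: tuple[tuple[int, str, str], ...],
    generation: int,
    cdr3_start: int,
    cdr3_end: int,
) -> LineageNode:
    cdr3 = seq[cdr3_start:cdr3_end]
    aa_full = translate(seq)
    productive = (cdr3_end - cdr3_start) % 3 == 0 and "*" not in aa_full
    divergence = (0 if parent is None else parent.divergence) + len(muts)
    return LineageNode(
        node_id=node_id,
        parent_id=None if parent is None else parent.node_id,
        full_sequence=seq,
        mutations_from_parent=muts,
        generation=generation,
        cdr3_aa=translate(cdr3),
        productive=productive,
        divergence=divergence,
    )


def _draw_mutations(
    seq: str,
    positions: np.ndarray,
    weights: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    forbid_stops: bool,
    fr_mask: np.ndarray | None = None,
    fr_replacement_retention: float = 1.0,
) -> tuple[str, tuple[tuple[int, str, str], ...]]:
    """One SHM round on one child.

    Positions mutate independently at ``rate * weight``.  Replacement
    (amino-acid-changing) mutations at framework positions survive only with
    probability ``fr_replacement_retention`` — purifying selection on the
    receptor scaffold, the process that pushes the framework R/S ratio below
    the germline expectation.  With ``forbid_stops`` set, mutations creating
    an in-frame stop are discarded (lineage conditioned on viability).
    """
    probs = np.minimum(rate * weights, 1.0)
    chosen = rng.random(len(positions)) < probs
    hits = positions[chosen]
    if len(hits) == 0:
        return seq, ()
    hit_fr = fr_mask[chosen] if fr_mask is not None else np.zeros(len(hits), bool)
    arr = list(seq)
    muts = []
    for pos, in_fr in zip(hits, hit_fr):
        old = arr[pos]
        new = [b for b in BASES if b != old][rng.integers(0, 3)]
        c0 = (pos // 3) * 3
        codon = "".join(arr[c0 : c0 + 3])
        if len(codon) == 3:
            mutant = codon[: pos - c0] + new + codon[pos - c0 + 1 :]
            if forbid_stops and mutant in STOP_CODONS:
                continue
            if (
                in_fr
                and fr_replacement_retention < 1.0
                and translate(codon) != translate(mutant)
                and rng.random() >= fr_replacement_retention
            ):
                continue
        arr[pos] = new
        muts.append((int(pos), old, new))
    return "".join(arr), tuple(muts)


def simulate_lineage(
    reference: GermlineReference,
    founder_spec: FounderSpec,
    n_rounds: int,
    mutation_rate: float,
    seed: int,
    *,
    children_per_node: int = 2,
    cdr_bias: float = 3.0,
    n_groups: int | None = None,
    unproductive_groups: int = 0,
    founder_mutation_count: int = 0,
    fr_replacement_retention: float = 1.0,
    amplicon_start: int = FWD_PRIMER_SITE[0],
) -> Lineage:
    """Grow a rooted SHM genealogy from the founder rearrangement.

    Two modes:

    * free (``n_groups is None``): every node spawns ``children_per_node``
      children per round; each child mutates every amplified, non-primer site
      independently at ``mutation_rate`` (CDR sites weighted ``cdr_bias``).
      CDR3 groups emerge naturally.
    * fixed (``n_groups`` set): the founder receives ``n_groups - 1``
      generation-1 subclones, each carrying one engineered amino-acid-changing
      CDR3 mutation (a stop codon for the ``unproductive_groups`` last ones);
      SHM rounds then diversify every subtree outside the CDR3 and without
      creating stops, so the ground-truth group count is exactly ``n_groups``.

    The founder itself diverges from the germline recombination by
    ``founder_mutation_count`` substitutions outside the CDR3 (the clone has
    a mutation history of its own before the sampled time point).
    """
    rng = np.random.default_rng(seed)
    germline, cdr3_start, cdr3_end = _recombine(reference, founder_spec)
    full_len = len(germline)
    rev_primer_len = REV_PRIMER_SITE[1] - REV_PRIMER_SITE[0]
    fwd_primer_len = FWD_PRIMER_SITE[1] - FWD_PRIMER_SITE[0]
    mutable_lo = amplicon_start + fwd_primer_len
    mutable_hi = full_len - rev_primer_len
    positions = np.arange(mutable_lo, mutable_hi)

    v = reference[founder_spec.v_allele]
    cdr_sites = set(range(*v.region_bounds["CDR2"])) | set(range(cdr3_start, cdr3_end))
    if "CDR1" in v.region_bounds:
        cdr_sites |= set(range(*v.region_bounds["CDR1"]))
    weights = np.array(
        [cdr_bias if p in cdr_sites else 1.0 for p in positions], dtype=float
    )
    non_cdr3_mask = np.array(
        [not (cdr3_start <= p < cdr3_end) for p in positions], dtype=bool
    )
    fr_sites: set[int] = set()
    for region in ("FR1", "FR2", "FR3"):
        if region in v.region_bounds:
            fr_sites |= set(range(*v.region_bounds[region]))
    fr_mask = np.array([p in fr_sites for p in positions], dtype=bool)

    counter = 0

    def next_id() -> str:
        nonlocal counter
        nid = f"N{counter:04d}"
        counter += 1
        return nid

    # founder: germline recombination + pre-existing SHM load outside the CDR3
    founder_seq = germline
    founder_muts: tuple[tuple[int, str, str], ...] = ()
    if founder_mutation_count > 0:
        # the founder's own mutation history passed through the same
        # selection: no stops, framework replacements partially purged
        cand = positions[non_cdr3_mask]
        cand_fr = fr_mask[non_cdr3_mask]
        arr = list(founder_seq)
        muts: list[tuple[int, str, str]] = []
        used: set[int] = set()
        attempts = 0
        while len(muts) < founder_mutation_count and attempts < 100000:
            attempts += 1
            i = int(rng.integers(0, len(cand)))
            p = int(cand[i])
            if p in used:
                continue
            old = arr[p]
            new = [b for b in BASES if b != old][rng.integers(0, 3)]
            c0 = (p // 3) * 3
            codon = "".join(arr[c0 : c0 + 3])
            if len(codon) == 3:
                mutant = codon[: p - c0] + new + codon[p - c0 + 1 :]
                if mutant in STOP_CODONS:
                    continue
                if (
                    cand_fr[i]
                    and fr_replacement_retention < 1.0
                    and translate(codon) != translate(mutant)
                    and rng.random() >= fr_replacement_retention
                ):
                    continue
            arr[p] = new
            used.add(p)
            muts.append((p, old, new))
        muts.sort()
        founder_seq = "".join(arr)
        founder_muts = tuple(muts)

    founder = _node_from_sequence(
        next_id(), None, founder_seq, founder_muts, 0, cdr3_start, cdr3_end
    )
    nodes = {founder.node_id: founder}

    if n_groups is None:
        frontier = [founder]
        for round_no in range(1, n_rounds + 1):
            new_frontier = []
            for parent in frontier:
                for _ in range(children_per_node):
                    seq, muts = _draw_mutations(
                        parent.full_sequence, positions, weights, mutation_rate,
                        rng, False, fr_mask, fr_replacement_retention,
                    )
                    child = _node_from_sequence(
                        next_id(), parent, seq, muts, round_no, cdr3_start, cdr3_end
                    )
                    nodes[child.node_id] = child
                    new_frontier.append(child)
            frontier = new_frontier
    else:
        cdr3_aa_len = (cdr3_end - cdr3_start) // 3
        # codons available for engineered group mutations: keep the sequon
        # (codons 0-2) and the J-derived tail intact
        junction_codons = (cdr3_end - cdr3_start - (reference[founder_spec.j_allele].anchor or 0)) // 3
        editable = list(range(3, junction_codons))
        if not editable:
            raise LineageError("junction too short to engineer subclone groups")
        subfounders = [founder]
        used_aa: dict[int, set[str]] = {}
        founder_cdr3_nt = founder.full_sequence[cdr3_start:cdr3_end]
        for g in range(1, n_groups):
            codon_idx = editable[(g - 1) % len(editable)]
            c0 = codon_idx * 3
            old_codon = founder_cdr3_nt[c0 : c0 + 3]
            old_aa = translate(old_codon)
            taken = used_aa.setdefault(codon_idx, {old_aa})
            make_stop = g > n_groups - 1 - unproductive_groups
            pool = sorted(STOP_CODONS) if make_stop else list(NON_STOP_CODONS)
            choice = None
            for _ in range(100):
                cand = pool[rng.integers(0, len(pool))]
                if translate(cand) not in taken and sum(
                    a != b for a, b in zip(cand, old_codon)
                ) >= 1:
                    choice = cand
                    break
            if choice is None:
                raise LineageError("could not engineer a distinct CDR3 group")
            taken.add(translate(choice))
            arr = list(founder.full_sequence)
            muts = []
            for k in range(3):
                pos = cdr3_start + c0 + k
                if arr[pos] != choice[k]:
                    muts.append((pos, arr[pos], choice[k]))
                    arr[pos] = choice[k]
            child = _node_from_sequence(
                next_id(), founder, "".join(arr), tuple(muts), 1, cdr3_start, cdr3_end
            )
            nodes[child.node_id] = child
            subfounders.append(child)

        for sub in subfounders:
            frontier = [sub]
            for round_no in range(1, n_rounds + 1):
                new_frontier = []
                for parent in frontier:
                    for _ in range(children_per_node):
                        seq, muts = _draw_mutations(
                            parent.full_sequence,
                            positions[non_cdr3_mask],
                            weights[non_cdr3_mask],
                            mutation_rate,
                            rng,
                            True,
                            fr_mask[non_cdr3_mask],
                            fr_replacement_retention,
                        )
                        child = _node_from_sequence(
                            next_id(), parent, seq, muts, parent.generation + 1,
                            cdr3_start, cdr3_end,
                        )
                        nodes[child.node_id] = child
                        new_frontier.append(child)
                frontier = new_frontier

    return Lineage(
        founder_id=founder.node_id,
        nodes=nodes,
        germline_sequence=germline,
        cdr3_start=cdr3_start,
        cdr3_end=cdr3_end,
        amplicon_start=amplicon_start,
        n_mutable_sites=len(positions),
        reference=reference,
        founder_spec=founder_spec,
    )


# -- follicle distribution ---------------------------------------------------


@dataclass
class FollicleSample:
    """One microdissected sample: follicle (or pooled follicles) of a node."""

    sample_id: str
    site_label: str
    member_cells: dict[str, int]
    contamination_fraction: float
    barcode: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise SimulationConfigError("contamination_fraction must be in [0,1]")
        if any(c <= 0 for c in self.member_cells.values()):
            raise SimulationConfigError("member cell counts must be positive")


def _default_site_labels(n_samples: int) -> list[str]:
    """First half of the samples are follicles of one node; the rest are
    whole-node pools from further lymph nodes."""
    n_foll = max(1, (n_samples + 1) // 2)
    labels = ["LN16"] * n_foll
    other = ["LN09", "LN14", "LN15", "LN19"]
    for i in range(n_samples - n_foll):
        labels.append(other[i % len(other)] + ("" if i < len(other) else f"x{i // len(other)}"))
    return labels


def _make_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Distinct barcodes with pairwise Hamming distance >= 3."""
    codes: list[str] = []
    while len(codes) < n:
        cand = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
        if all(sum(a != b for a, b in zip(cand, c)) >= 3 for c in codes):
            codes.append(cand)
    return codes


def distribute_to_follicles(
    lineage: Lineage,
    n_samples: int,
    migration_rate: float,
    seed: int,
    *,
    site_labels: Sequence[str] | None = None,
    contamination_range: tuple[float, float] = (0.15, 0.96),
    barcode_length: int = 7,
    cell_count_mean: float = 8.0,
) -> tuple[list[FollicleSample], pd.DataFrame]:
    """Seed subclone groups into follicle samples with migration.

    Every group gets one home sample; each additional sample is seeded
    independently with probability ``migration_rate``.  Returns the samples
    and the ground-truth group x sample occupancy matrix (cell counts).
    """
    if n_samples < 1:
        raise SimulationConfigError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    groups = lineage.truth_groups()
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    sites = list(site_labels) if site_labels is not None else _default_site_labels(n_samples)
    if len(sites) != n_samples:
        raise SimulationConfigError("site_labels length must equal n_samples")
    barcodes = _make_barcodes(n_samples, barcode_length, rng)

    occupancy = pd.DataFrame(
        0, index=list(groups.keys()), columns=sample_ids, dtype=int
    )
    member_cells: list[dict[str, int]] = [{} for _ in range(n_samples)]
    for label, node_ids in groups.items():
        home = int(rng.integers(0, n_samples))
        seeded = [home] + [
            s
            for s in range(n_samples)
            if s != home and rng.random() < migration_rate
        ]
        for s in seeded:
            for nid in node_ids:
                cells = 1 + int(rng.poisson(max(cell_count_mean - 1, 0)))
                member_cells[s][nid] = cells
                occupancy.loc[label, sample_ids[s]] += cells

    lo, hi = contamination_range
    samples = [
        FollicleSample(
            sample_id=sample_ids[i],
            site_label=sites[i],
            member_cells=member_cells[i],
            contamination_fraction=float(rng.uniform(lo, hi)) if hi > 0 else 0.0,
            barcode=barcodes[i],
        )
        for i in range(n_samples)
    ]
    return samples, occupancy


# -- read synthesis ----------------------------------------------------------


@dataclass
class SyntheticRead:
    """One simulated read pair with its sample barcode."""

    read_id: str
    mate1: str
    qual1: str
    mate2: str
    qual2: str
    barcode: str


@dataclass
class SyntheticRun:
    """FASTQ-level output of the generator plus full ground truth."""

    reads: list[SyntheticRead]
    truth: pd.DataFrame  # read_id, sample_id, origin_node_id, n_true_mutations
    sample_sheet: pd.DataFrame  # sample_id, barcode, site_label
    design: AmpliconDesign
    lineage: Lineage
    occupancy: pd.DataFrame


def _contaminant_rearrangement(
    reference: GermlineReference,
    lineage: Lineage,
    frameshift_prob: float,
    rng: np.random.Generator,
) -> str:
    """Random productive-looking rearrangement with a junction clearly
    distinct (>= 6 nt) from the founder junction."""
    founder_junction = (
        lineage.founder.full_sequence[lineage.cdr3_start : lineage.cdr3_end]
    )
    v = reference.v_segments[int(rng.integers(0, len(reference.v_segments)))]
    d = reference.d_segments[int(rng.integers(0, len(reference.d_segments)))]
    j = reference.j_segments[int(rng.integers(0, len(reference.j_segments)))]
    for _ in range(200):
        n1_len = int(rng.integers(3, 10))
        n2_len = int(rng.integers(3, 10))
        junction_len = n1_len + len(d.sequence) + n2_len
        shift = rng.random() < frameshift_prob
        rem = junction_len % 3
        if not shift and rem:
            n2_len += 3 - rem
        elif shift and not rem:
            n2_len += 1
        n1 = "".join(BASES[b] for b in rng.integers(0, 4, size=n1_len))
        n2 = "".join(BASES[b] for b in rng.integers(0, 4, size=n2_len))
        junction = n1 + d.sequence + n2
        diff = sum(a != b for a, b in zip(junction, founder_junction))
        diff += abs(len(junction) - len(founder_junction))
        if diff >= 6:
            return v.sequence + junction + j.sequence
    raise SimulationConfigError("failed to draw a distinct contaminant junction")


def _apply_substitutions(
    seq: str, mask: np.ndarray, rng: np.random.Generator, targeted: dict[str, str] | None
) -> str:
    """Substitute at masked positions: random base changes, or G>A/C>T when
    ``targeted`` maps bases (deamination on the sense strand)."""
    if not mask.any():
        return seq
    arr = list(seq)
    for pos in np.flatnonzero(mask):
        old = arr[pos]
        if targeted is not None:
            if old in targeted:
                arr[pos] = targeted[old]
        else:
            arr[pos] = [b for b in BASES if b != old][rng.integers(0, 3)]
    return "".join(arr)


DEAMINATION_MAP = {"G": "A", "C": "T"}


def synthesize_reads(
    samples: Sequence[FollicleSample],
    lineage: Lineage,
    reference: GermlineReference,
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> SyntheticRun:
    """Emit barcoded paired-end reads per sample, with full per-read truth.

    Mate 1 reads the amplicon from the forward-primer end, mate 2 from the
    reverse-primer end (reverse-complemented).  Contaminating reads are
    random productive-looking rearrangements with distinct junctions, one
    junction per background read.  Deamination artifacts (G>A / C>T on the
    amplicon sense) are applied per molecule before slicing into mates;
    sequencing errors are applied per mate.  Exactly ``config.coverage``
    pairs are emitted per sample.
    """
    rng = np.random.default_rng(config.random_seed if seed is None else seed)
    design = AmpliconDesign.from_reference(
        reference, config.read_length, config.target_amplicon_length
    )
    rl = config.read_length
    q_good = "I" * rl  # constant Q40
    low_q_char = chr(33 + 15)  # one Q15 base to exercise the quality filter

    reads: list[SyntheticRead] = []
    truth_rows: list[tuple[str, str, str, int]] = []
    for sample in samples:
        node_ids = sorted(sample.member_cells)
        if node_ids:
            cells = np.array([sample.member_cells[n] for n in node_ids], dtype=float)
            probs = cells / cells.sum()
        for i in range(config.coverage):
            read_id = f"{sample.sample_id}:{i:06d}"
            is_background = (
                not node_ids or rng.random() < sample.contamination_fraction
            )
            if is_background:
                full = _contaminant_rearrangement(
                    reference, lineage, config.contaminant_frameshift_prob, rng
                )
                origin = "background"
                n_true = 0
            else:
                nid = node_ids[int(rng.choice(len(node_ids), p=probs))]
                node = lineage.nodes[nid]
                full = node.full_sequence
                origin = nid
                n_true = node.divergence
            amplicon = full[design.v_start :]
            if len(amplicon) < 2 * rl - design.gap_n_count:
                raise SimulationConfigError("amplicon too short for the read design")
            if config.deamination_artifact_rate > 0:
                mask = rng.random(len(amplicon)) < config.deamination_artifact_rate
                amplicon = _apply_substitutions(amplicon, mask, rng, DEAMINATION_MAP)
            mate1 = amplicon[:rl]
            mate2 = revcomp(amplicon[-rl:])
            if config.sequencing_error_rate > 0:
                m1 = rng.random(rl) < config.sequencing_error_rate
                m2 = rng.random(rl) < config.sequencing_error_rate
                mate1 = _apply_substitutions(mate1, m1, rng, None)
                mate2 = _apply_substitutions(mate2, m2, rng, None)
            qual1, qual2 = q_good, q_good
            if config.low_quality_read_fraction > 0 and rng.random() < config.low_quality_read_fraction:
                pos = int(rng.integers(0, rl))
                if rng.random() < 0.5:
                    qual1 = q_good[:pos] + low_q_char + q_good[pos + 1 :]
                else:
                    qual2 = q_good[:pos] + low_q_char + q_good[pos + 1 :]
            reads.append(
                SyntheticRead(read_id, mate1, qual1, mate2, qual2, sample.barcode)
            )
            truth_rows.append((read_id, sample.sample_id, origin, n_true))

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample_id", "origin_node_id", "n_true_mutations"]
    )
    sample_sheet = pd.DataFrame(
        [(s.sample_id, s.barcode, s.site_label) for s in samples],
        columns=["sample_id", "barcode", "site_label"],
    )
    run = SyntheticRun(
        reads=reads,
        truth=truth,
        sample_sheet=sample_sheet,
        design=design,
        lineage=lineage,
        occupancy=pd.DataFrame(),
    )
    if out_dir is not None:
        write_run(run, out_dir)
    return run


def write_run(run: SyntheticRun, out_dir: str | Path) -> None:
    """Write gzipped R1/R2 FASTQ (barcode as a header tag), truth table,
    sample sheet, and the germline reference."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with gzip.open(out / "reads_R1.fastq.gz", "wt") as f1, gzip.open(
        out / "reads_R2.fastq.gz", "wt"
    ) as f2:
        for r in run.reads:
            f1.write(f"@{r.read_id} BC:{r.barcode}\n{r.mate1}\n+\n{r.qual1}\n")
            f2.write(f"@{r.read_id} BC:{r.barcode}\n{r.mate2}\n+\n{r.qual2}\n")
    run.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    run.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    run.lineage.reference.write(out / "germline.fasta", out / "germline_bounds.tsv")


def simulate_run(config: SimulationConfig, out_dir: str | Path | None = None) -> SyntheticRun:
    """Convenience wrapper: reference -> lineage -> follicles -> reads."""
    reference = build_germline_set(config)
    founder = default_founder_spec(reference, config.random_seed)
    lineage = simulate_lineage(
        reference,
        founder,
        n_rounds=config.n_rounds,
        mutation_rate=config.mutation_rate_per_round,
        seed=config.random_seed + 1,
        children_per_node=config.children_per_node,
        cdr_bias=config.cdr_bias,
        n_groups=config.n_groups,
        unproductive_groups=config.unproductive_groups,
        founder_mutation_count=config.founder_mutation_count,
        fr_replacement_retention=config.fr_replacement_retention,
    )
    samples, occupancy = distribute_to_follicles(
        lineage,
        config.n_samples,
        config.migration_rate,
        seed=config.random_seed + 2,
        contamination_range=config.contamination_range,
        barcode_length=config.barcode_length,
    )
    run = synthesize_reads(
        samples, lineage, reference, config, out_dir=None, seed=config.random_seed + 3
    )
    run.occupancy = occupancy
    if out_dir is not None:
        write_run(run, out_dir)
        occupancy.to_csv(Path(out_dir) / "occupancy.tsv", sep="\t")
    return run
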