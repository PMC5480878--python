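# Methods

`clonetrack` analyzes deep amplicon sequencing of a clonal immunoglobulin
heavy-chain (IGH) rearrangement amplified with framework-2 (FR2) consensus
primers from microdissected germinal-center samples. The analysis tracks
three biological readouts of a t(14;18)+ B-cell clone: ongoing somatic
hypermutation (SHM, intraclonal diversity), antigen-selection signatures
(replacement/silent mutation ratios, N-glycosylation sequons), and
interfollicular/internodal trafficking (sharing of subclone groups across
samples). Because no public dataset accompanies this assay design, the
package ships a first-class synthetic-data generator that emulates the
experiment with full ground truth; all validation is property-based against
that truth and against independent brute-force oracles.

## The sequencing design and its consequences

The assay amplifies a 268 bp product from an FR2 consensus primer in IGHV to
a JH consensus primer. Sequencing is paired-end 2×112 bp with a 7 nt sample
barcode. Since 2×112 < 268, the mates do not overlap: after merging, a fixed
run of 44 ambiguous bases (`N`) stands in for the unsequenced middle of FR3
(268 = 112 + 44 + 112). Every identity, distance and translation in the
package excludes `N` columns; codons containing `N` translate to `X` and are
never counted as stop codons. A practical corollary of the fixed-length
merge is that junction-length differences between molecules are absorbed by
the constant gap, so clonotype discrimination rests on CDR3 amino-acid
*identity*, not apparent length.

## Read processing

1. **Demultiplexing** — exact barcode match by default (a mismatch allowance
   is a flag); ambiguous or unmatched reads are set aside. The partition
   property (sample sizes + unassigned = input) always holds.
2. **Primer trimming** — both primers are required at the 5' ends of their
   mates (configurable mismatch budget, default 0); pairs lacking a primer
   are rejected with a recorded reason.
3. **Quality filter** — *every* base of both mates must reach the phred
   floor. The floor defaults to 21, i.e. "quality above 20" read literally;
   a base at exactly Q20 fails. This is configurable.
4. **Merge** — `mate1 + N×44 + revcomp(mate2)`; mate 2 is
   reverse-complemented so the merged sequence is on the sense strand.
5. **Dereplication** — exact-string collapse to unique sequences with counts
   and frequencies; the frequency denominator is the sample's merged
   high-quality read total.
6. **Noise floor** — unique sequences with frequency strictly below 0.1%
   are dropped (the boundary value is retained). The floor runs before
   annotation; the filter is idempotent.

## V(D)J annotation

Alignment is ungapped (substitution-only), matching both the biology modeled
(SHM point mutations) and the generator. The best V is the segment/offset
pair maximizing percent identity over non-`N` columns (ties: longer
alignment, then lexicographic allele name); candidate offsets are seeded
from an 11-mer index with an exhaustive-scan fallback, so the seeded search
provably equals the full scan. J is aligned analogously over the 3' end. An
identity floor (60%) separates alignable IGH material — including
contaminating B-cell rearrangements — from unalignable reads
("nonspecific"). D is resolved as the longest exact stretch (≥5 nt) of a D
segment inside the junction.

Region delineation projects the germline FR/CDR bounds through the V
alignment; CDR3 runs from the end of FR3 to the conserved J-Trp anchor
carried as an annotation on each J segment (full IMGT unique numbering is
intentionally out of scope; anchors travel with the reference). Productivity
requires an in-frame CDR3 (length divisible by 3) and no stop codon in the
covered coding region.

## Clone discrimination and grouping

Reads are discriminated against the monoclonal reference rearrangement (in
practice the Sanger-derived clonal sequence; in simulations the founder
amplicon). A read is clone-specific iff its V gene, J gene and CDR3
amino-acid length match the reference and CDR3 identity is ≥ 0.70 (threshold
exposed; no authoritative value exists). D agreement is deliberately not
required — junction mutations readily destroy the short D match. Groups are
exact-string partitions of clone-specific uniques on CDR3 amino-acid
sequence, with unproductive rearrangements always forming their own groups;
group ids (`G1…`) are ordered by read count. Samples without clone-specific
reads are flagged not evaluable.

## SHM and selection statistics

Mutations are called per non-`N` column against a germline projection of the
read (V and J contribute aligned germline bases; the called D stretch fills
part of the junction; N-regions have no germline and yield no calls).
Each mutation is classified replacement (R) or silent (S) against its
germline codon with only the queried position mutated; co-mutated codons are
classified per mutation independently. Statistics are pooled over *distinct
mutation events* (position, from, to): a mutation shared by many unique
sequences is one event of the clone's history, not one per carrier —
per-carrier pooling would re-count the founder's ancestral mutations
hundreds of times and swamp the signal.

Region-pooled R/S ratios are reported for CDRs, FRs and J (J separately,
since its pooling with FR is a free choice), with the framework ratio
compared against 2.845, the inherent mean R/S of human germline VH genes; a
framework ratio below that constant indicates purifying (structural)
selection. The 12-entry substitution spectrum raises a formalin-artifact
flag when G>A plus C>T transitions exceed 60% of events (cytosine
deamination signature). N-glycosylation sequons (Asn-X-Ser/Thr) are scanned
in two modes: `paper-literal` (default; the motif read exactly as printed,
no constraint on X) and `strict` (X ≠ Pro, the biochemical rule); unknown
residues never match.

## Genealogy and trafficking

Each group is represented by its per-column majority consensus (N never
votes; ties fall back to the monoclonal reference base). Pairwise
p-distances (mismatches over comparable non-`N` columns, raw counts kept
alongside) feed a neighbor-joining tree. NJ is implemented in-package to
guarantee deterministic tie-breaking (label order) and zero-clamped branch
lengths — properties the validation suite checks against closed forms,
the four-point condition, and an independent library implementation. The
tree is rooted on the germline leaf's edge; the group nearest the germline
(minimal raw mismatches, tree-independent, ties reported) is the inferred
clonal origin. The group × sample count matrix classifies each group as
private or shared, and shared groups as interfollicular (≥2 samples of one
lymph node) and/or internodal (≥2 nodes).

## The synthetic-data generator

The generator builds, deterministically per seed:

* **Germline reference** — ≥2 alleles per segment class with a fixed
  architecture: V 294 nt (FR1 75, CDR1 24, FR2 51, CDR2 24, FR3 120, ending
  on the conserved Cys codon) with a shared 21 nt forward-primer site inside
  FR2; J 46 nt with the Trp anchor at position 15 and a shared 21 nt
  reverse-primer tail; D 21 nt, stop-free in frame 0. Alleles are synthetic
  (labelled `IGHV3-S..`-style) and diverge by 20 substitutions — an easier
  discrimination problem than real IGHV alleles, which the annotation
  accuracy results should be read against.
* **Founder rearrangement** — V + N1 + D + N2 + J with a 33 nt junction, so
  the default amplicon is exactly 268 bp and the CDR3 is 16 codons. N1 is
  built to encode one Asn-X-Thr sequon at the CDR3 start, the
  follicular-lymphoma-type glycosylation motif. The founder additionally
  carries 10 substitutions of pre-existing SHM relative to the germline
  recombination (clones are sampled mid-history; this also keeps the
  "nearest to germline" question non-degenerate).
* **SHM lineage** — substitution-only branching process. *Free mode*: every
  node spawns children each round, mutating amplified non-primer sites
  independently (default 0.002/site/round) with a 3× rate multiplier in
  CDRs. *Fixed-group mode* (default, 11 groups / 3 unproductive): the
  founder gets n−1 engineered subclones, each with one amino-acid-changing
  CDR3 codon (a stop codon for unproductive groups), after which SHM runs
  outside the CDR3 with stop-creating mutations vetoed — the ground-truth
  group count is exact, which turns "recover the simulated groups" into a
  well-posed check. Replacement mutations at framework sites survive with
  probability 0.5 (`fr_replacement_retention`), modeling purifying selection
  on the receptor scaffold; without it the per-mutation R/S ratio is
  region-independent and no CDR/FR selection signature can exist.
* **Follicle distribution** — each group gets one home sample; every other
  sample is seeded independently with the migration probability (default
  0.3). Half the samples share one lymph-node label (microdissected
  follicles of one node), the rest represent further nodes.
* **Read synthesis** — exactly `coverage` pairs per sample (default 5 000,
  a desk-scale stand-in for the 3×10⁴–1.4×10⁵ reads of a real run).
  Contaminating reads (per-sample fraction drawn from 15–96%) are random
  productive-looking rearrangements, one junction per read, constrained ≥6 nt
  different from the founder junction so ground-truth membership is
  unambiguous. Deamination artifacts (G>A/C>T on the sense strand) are
  applied per molecule; sequencing errors per mate; qualities are constant
  Q40 except a configurable fraction of reads carrying one sub-threshold
  base to exercise the quality filter. Barcodes (7 nt, pairwise Hamming ≥3)
  ride as a header tag; barcode reuse across lanes is not simulated.

The `hbl1_control_preset` emulates a formalin-fixed monoclonal control: no
SHM, no contamination, deamination at 0.0018 per G/C base, chosen so roughly
a fifth of reads carry at least one artifact over the ~134 deaminable
amplicon positions.

What the generator does **not** emulate: indels, PCR chimeras, primer-site
mutations, quality-score decay along the read, lane/flowcell structure,
polyclonal backgrounds with realistic clone-size distributions (every
background read has its own junction), or real IGHV/IGHD/IGHJ sequences.
Passing tests therefore demonstrate the pipeline's correctness under the
substitution-only model, not robustness to indel-rich or
quality-heterogeneous real data.

## Numerical and design choices

* 0-based half-open coordinates internally; merged-read positions map to
  germline by `offset + p` (ungapped).
* Ties everywhere are deterministic: lexicographic allele names (V/J/D),
  label order (NJ), reference base (consensus), lexicographic CDR3
  (group ids and nearest-germline reports, with an explicit tie flag).
* Degenerate inputs: <3 tree labels give a flagged degenerate tree, not an
  exception; S=0 makes an R/S ratio undefined (reported as such with the R
  count); an empty junction yields no D call.
* Validation problem sizes (noiseless 4×5 000-read round trips, 10 000-read
  discrimination mixtures, 100-replicate genealogies, 6-replicate pooled
  R/S runs) were chosen as the smallest sizes at which the binomial error
  bars of the checked quantities are decisively smaller than the effects
  being checked; R/S counts are pooled across replicate simulations because
  the finite mutable-site space saturates distinct events within one run.

## Known limitations

* Ungapped alignment cannot place reads from molecules whose true length
  differs from the design length correctly beyond the N gap; such reads
  (polyclonal background) are still classified correctly, but their FR3
  segment past the gap is misprojected. Clone reads are unaffected.
* CDR3 mutations in junction N-regions are invisible to mutation calling
  (no germline to compare against); only D-covered junction positions are
  called. CDR R/S statistics therefore understate junction evolution.
* The 2.845 germline expectation is a literature constant, not recomputed.
* Group consensus can mix mutations of sibling subclones into a sequence no
  cell carried; with the default within-group diversity this does not
  perturb the germline-distance ordering (checked over 100 replicates).
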