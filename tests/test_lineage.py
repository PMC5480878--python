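from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from clonetrack.clones import CloneGroup
from clonetrack.lineage import (
    DistanceMatrix,
    LineageAnalysisError,
    build_tree,
    group_consensus,
    pairwise_distances,
    root_to_germline,
    trafficking_matrix,
)

BASES = "ACGT"


# -- consensus ---------------------------------------------------------------


def test_single_member_consensus_is_that_sequence():
    assert group_consensus(["ACGT"], "TTTT") == "ACGT"


def test_majority_wins_and_tie_falls_back_to_reference():
    members = ["AAGT", "AAGT", "ACGT"]
    assert group_consensus(members, "TTTT") == "AAGT"
    tied = ["AAGT", "ACGT"]
    assert group_consensus(tied, "ACTT") == "ACGT"  # reference A?C breaks ties
    assert group_consensus(tied, "TTTT")[1] == "A"  # ref not among winners: first


def test_n_never_votes_and_all_n_column_uses_reference():
    members = ["ANGT", "NNGT"]
    assert group_consensus(members, "GCTT") == "ACGT"[0] + "C" + "GT"


def test_consensus_matches_naive_tally_oracle():
    rng = np.random.default_rng(5)
    ref = "".join(BASES[b] for b in rng.integers(0, 4, 40))
    members = []
    for _ in range(7):
        seq = [
            "N" if rng.random() < 0.1 else BASES[b]
            for b in rng.integers(0, 4, 40)
        ]
        members.append("".join(seq))
    got = group_consensus(members, ref)
    for col in range(40):
        votes = {}
        for m in members:
            if m[col] != "N":
                votes[m[col]] = votes.get(m[col], 0) + 1
        if not votes:
            assert got[col] == ref[col]
        else:
            top = max(votes.values())
            winners = sorted(b for b, v in votes.items() if v == top)
            if len(winners) == 1:
                assert got[col] == winners[0]
            else:
                assert got[col] == (ref[col] if ref[col] in winners else winners[0])


# -- distances ---------------------------------------------------------------


def test_identical_sequences_have_zero_distance():
    dm = pairwise_distances({"a": "ACGT", "b": "ACGT"})
    assert dm.values[0, 1] == 0.0 and dm.mismatches[0, 1] == 0


def test_p_distance_arithmetic_and_n_exclusion():
    a = "A" * 100
    b = "C" * 3 + "A" * 97
    dm = pairwise_distances({"a": a, "b": b})
    assert dm.values[0, 1] == pytest.approx(0.03)
    c = "N" * 50 + "A" * 47 + "CCC"
    dm2 = pairwise_distances({"a": a, "c": c})
    assert dm2.mismatches[0, 1] == 3
    assert dm2.values[0, 1] == pytest.approx(3 / 50)


def test_p_distance_matches_exhaustive_column_scan():
    rng = np.random.default_rng(9)
    seqs = {}
    for k in range(4):
        seqs[f"s{k}"] = "".join(
            "N" if rng.random() < 0.15 else BASES[b] for b in rng.integers(0, 4, 60)
        )
    dm = pairwise_distances(seqs)
    labels = list(seqs)
    for i, j in combinations(range(4), 2):
        a, b = seqs[labels[i]], seqs[labels[j]]
        cols = sum(1 for x, y in zip(a, b) if x != "N" and y != "N")
        mm = sum(1 for x, y in zip(a, b) if x != "N" and y != "N" and x != y)
        assert dm.mismatches[i, j] == mm
        assert dm.values[i, j] == pytest.approx(mm / cols if cols else 0.0)


def test_unequal_lengths_rejected():
    with pytest.raises(LineageAnalysisError):
        pairwise_distances({"a": "ACGT", "b": "ACG"})


# -- neighbor joining --------------------------------------------------------


def _dm(labels, arr):
    a = np.asarray(arr, dtype=float)
    return DistanceMatrix(labels, a, np.zeros_like(a, dtype=int))


def test_three_taxon_closed_form():
    dab, dac, dbc = 0.3, 0.5, 0.6
    dm = _dm(["a", "b", "c"], [[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]])
    tree = build_tree(dm)
    dists = tree.root.leaf_distances()
    # the unique 3-taxon tree is additive: path lengths reproduce the matrix
    assert dists.loc["a", "b"] == pytest.approx(dab, abs=1e-9)
    assert dists.loc["a", "c"] == pytest.approx(dac, abs=1e-9)
    assert dists.loc["b", "c"] == pytest.approx(dbc, abs=1e-9)
    # closed-form pendant branches: la = (dab + dac - dbc) / 2, etc.
    leaves = {l.name: l for l in tree.root.leaves()}
    la = (dab + dac - dbc) / 2
    found = [l.length for l in leaves.values()]
    assert any(abs(x - la) < 1e-9 for x in found)


def _additive_matrix(tree_dists, labels):
    n = len(labels)
    arr = np.zeros((n, n))
    for (a, b), d in tree_dists.items():
        i, j = labels.index(a), labels.index(b)
        arr[i, j] = arr[j, i] = d
    return _dm(labels, arr)


def _quartet_split(dm, labels):
    """Four-point-condition oracle: the true split pairs the two taxa whose
    sum-of-distances term is smallest."""
    (a, b, c, d) = labels
    i = {l: labels.index(l) for l in labels}
    sums = {
        (("a", "b"), ("c", "d")): dm.values[i[a], i[b]] + dm.values[i[c], i[d]],
        (("a", "c"), ("b", "d")): dm.values[i[a], i[c]] + dm.values[i[b], i[d]],
        (("a", "d"), ("b", "c")): dm.values[i[a], i[d]] + dm.values[i[b], i[c]],
    }
    return min(sums, key=sums.get)


def _splits(tree):
    """Non-trivial bipartitions of the leaf set induced by internal edges."""
    all_leaves = frozenset(tree.root.leaf_names())
    splits = set()

    def walk(node):
        for c in node.children:
            side = frozenset(c.leaf_names())
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(frozenset({side, all_leaves - side}))
            walk(c)

    walk(tree.root)
    return splits


def test_additive_four_taxon_topology_and_path_lengths():
    # tree: (a,b) | (c,d), internal edge 0.7
    td = {("a", "b"): 0.5, ("a", "c"): 1.4, ("a", "d"): 1.6,
          ("b", "c"): 1.5, ("b", "d"): 1.7, ("c", "d"): 0.7}
    labels = ["a", "b", "c", "d"]
    dm = _additive_matrix(td, labels)
    assert _quartet_split(dm, labels) == (("a", "b"), ("c", "d"))
    tree = build_tree(dm)
    splits = _splits(tree)
    assert frozenset({frozenset({"a", "b"}), frozenset({"c", "d"})}) in splits
    dists = tree.root.leaf_distances()
    for (x, y), d in td.items():
        assert dists.loc[x, y] == pytest.approx(d, abs=1e-9)


def test_additive_five_taxon_tree_recovered():
    # caterpillar: ((a,b),c,(d,e)) with known branch lengths
    pend = {"a": 0.2, "b": 0.3, "c": 0.25, "d": 0.15, "e": 0.4}
    # internal: (ab)-node to center 0.5; (de)-node to center 0.6
    labels = list("abcde")

    def dist(x, y):
        path = {"a": ["ab"], "b": ["ab"], "c": [], "d": ["de"], "e": ["de"]}
        internal = {"ab": 0.5, "de": 0.6}
        d = pend[x] + pend[y]
        seen = set(path[x]) ^ set(path[y])
        return d + sum(internal[e] for e in seen)

    td = {(x, y): dist(x, y) for x, y in combinations(labels, 2)}
    dm = _additive_matrix(td, labels)
    tree = build_tree(dm)
    splits = _splits(tree)
    leafset = frozenset(labels)
    assert frozenset({frozenset("ab"), leafset - frozenset("ab")}) in splits
    assert frozenset({frozenset("de"), leafset - frozenset("de")}) in splits
    dists = tree.root.leaf_distances()
    for (x, y), d in td.items():
        assert dists.loc[x, y] == pytest.approx(d, abs=1e-9)


def test_nj_topology_agrees_with_skbio_reference():
    import skbio

    rng = np.random.default_rng(2)
    seqs = {f"t{k}": "".join(BASES[b] for b in rng.integers(0, 4, 80)) for k in range(6)}
    dm = pairwise_distances(seqs)
    mine = build_tree(dm)
    sk_dm = skbio.DistanceMatrix(dm.values, ids=dm.labels)
    sk_tree = skbio.tree.nj(sk_dm)

    def unrooted_splits(t):
        tips = frozenset(x.name for x in t.tips())
        out = set()
        for node in t.non_tips(include_self=True):
            side = frozenset(x.name for x in node.tips())
            if 1 < len(side) < len(tips) - 1:
                out.add(frozenset({side, tips - side}))
        return out

    sk_parsed = skbio.TreeNode.read([mine.to_newick()])
    assert unrooted_splits(sk_parsed) == unrooted_splits(sk_tree)


def test_newick_round_trips_through_skbio():
    import skbio

    dm = _dm(["x", "y", "z"], [[0, 0.2, 0.4], [0.2, 0, 0.5], [0.4, 0.5, 0]])
    tree = build_tree(dm)
    parsed = skbio.TreeNode.read([tree.to_newick()])
    assert sorted(t.name for t in parsed.tips()) == ["x", "y", "z"]
    mine = {l.name: l.length for l in tree.root.leaves()}
    theirs = {t.name: t.length for t in parsed.tips()}
    for name in mine:
        assert theirs[name] == pytest.approx(mine[name], abs=1e-9)


def test_degenerate_two_taxon_tree_flagged():
    dm = _dm(["a", "b"], [[0, 0.4], [0.4, 0]])
    tree = build_tree(dm)
    assert tree.degenerate
    assert sorted(tree.leaf_labels) == ["a", "b"]


# -- rooting -----------------------------------------------------------------


def test_root_to_germline_places_germline_at_root():
    rng = np.random.default_rng(4)
    base = "".join(BASES[b] for b in rng.integers(0, 4, 90))

    def mutate(seq, k, seed):
        r = np.random.default_rng(seed)
        arr = list(seq)
        for p in r.choice(len(seq), size=k, replace=False):
            arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
        return "".join(arr)

    seqs = {
        "germline": base,
        "G1": mutate(base, 2, 1),
        "G2": mutate(base, 6, 2),
        "G3": mutate(base, 10, 3),
        "G4": mutate(mutate(base, 10, 3), 4, 4),
    }
    dm = pairwise_distances(seqs)
    tree = build_tree(dm)
    rooted = root_to_germline(tree, dm, "germline")
    assert "germline" in [c.name for c in rooted.tree.root.children]
    assert rooted.nearest_group == "G1"
    assert not rooted.nearest_tie
    assert list(rooted.distance_order.index)[0] == "G1"
    assert sorted(rooted.tree.leaf_labels) == sorted(seqs)


def test_equidistant_groups_tie_reported_lexicographically():
    arr = np.array([[0, 1, 1], [1, 0, 2], [1, 2, 0]], dtype=float) / 10
    mm = (arr * 10).astype(int)
    dm = DistanceMatrix(["germline", "Gb", "Ga"], arr, mm)
    tree = build_tree(dm)
    rooted = root_to_germline(tree, dm, "germline")
    assert rooted.nearest_tie
    assert rooted.nearest_group == "Ga"


def test_missing_germline_leaf_is_an_error():
    dm = _dm(["a", "b", "c"], [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    tree = build_tree(dm)
    with pytest.raises(LineageAnalysisError, match="germline"):
        root_to_germline(tree, dm, "germline")


# -- trafficking -------------------------------------------------------------


def _group(gid, counts, productive=True):
    return CloneGroup(gid, f"CDR3{gid}", productive, [f"{gid}_m"], counts)


def test_private_and_shared_classification():
    sites = {"S1": "LN16", "S2": "LN16", "S3": "LN14"}
    groups = [
        _group("G1", {"S1": 10}),                 # private
        _group("G2", {"S1": 5, "S2": 2}),         # interfollicular (same node)
        _group("G3", {"S1": 1, "S3": 4}),         # internodal
    ]
    tm = trafficking_matrix(groups, sites)
    assert tm.classification["G1"] == "private"
    assert tm.classification["G2"] == "shared"
    assert tm.summary["interfollicular_shared"] == ["G2"]
    assert tm.summary["internodal_shared"] == ["G3"]
    assert tm.summary["n_private"] == 1


def test_row_sums_conserve_group_totals():
    sites = {"S1": "LN16", "S2": "LN14"}
    groups = [_group("G1", {"S1": 7, "S2": 3}), _group("G2", {"S2": 9})]
    tm = trafficking_matrix(groups, sites)
    for g in groups:
        assert tm.counts.loc[g.group_id].sum() == g.total_count


def test_min_count_threshold_guards_presence():
    sites = {"S1": "LN16", "S2": "LN14"}
    groups = [_group("G1", {"S1": 7, "S2": 1})]
    assert trafficking_matrix(groups, sites, min_count=2).classification["G1"] == "private"
    assert trafficking_matrix(groups, sites, min_count=1).classification["G1"] == "shared"
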