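"""Germline-rooted genealogy of clone groups and trafficking maps.

Group representatives (per-column majority consensus) are compared by
p-distance over non-N columns, agglomerated with neighbor joining, and
rooted on the germline leaf's edge; the group with the smallest raw mismatch
count to the germline is reported as the genealogical origin.  Neighbor
joining is implemented here (rather than delegated) to guarantee
deterministic tie-breaking by label order and closed-form-checkable branch
lengths; negative branch lengths are clamped to zero.  Group x sample read
counts form the trafficking matrix, from which interfollicular (within one
lymph node) and internodal (across nodes) sharing is summarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clones import CloneGroup


class LineageAnalysisError(ValueError):
    pass


# -- consensus and distances -------------------------------------------------


def group_consensus(member_sequences: Sequence[str], reference_sequence: str) -> str:
    """Per-column majority base over members; N never votes; ties (or
    all-N columns) fall back to the reference base."""
    if not member_sequences:
        raise LineageAnalysisError("cannot build a consensus of zero sequences")
    lengths = {len(s) for s in member_sequences}
    if len(lengths) != 1:
        raise LineageAnalysisError("member sequences must have equal length")
    (length,) = lengths
    if len(reference_sequence) != length:
        raise LineageAnalysisError("reference length must match members")
    out = []
    for col in range(length):
        votes: dict[str, int] = {}
        for seq in member_sequences:
            b = seq[col]
            if b != "N":
                votes[b] = votes.get(b, 0) + 1
        if not votes:
            out.append(reference_sequence[col])
            continue
        top = max(votes.values())
        winners = sorted(b for b, v in votes.items() if v == top)
        if len(winners) > 1:
            ref = reference_sequence[col]
            out.append(ref if ref in winners else winners[0])
        else:
            out.append(winners[0])
    return "".join(out)


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix plus raw mismatch counts."""

    labels: list[str]
    values: np.ndarray  # p-distance: mismatches / comparable (non-N) columns
    mismatches: np.ndarray  # raw mismatch counts

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise LineageAnalysisError("matrix shape does not match labels")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise LineageAnalysisError(
                "distances must be symmetric, non-negative, zero-diagonal"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_distances(sequences: dict[str, str]) -> DistanceMatrix:
    """p-distance between equal-length sequences; columns with N in either
    sequence are excluded from numerator and denominator."""
    labels = list(sequences)
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise LineageAnalysisError("sequences must have equal length (substitution-only model)")
    n = len(labels)
    arrs = [np.frombuffer(sequences[l].encode(), dtype=np.uint8) for l in labels]
    n_code = ord("N")
    values = np.zeros((n, n))
    mism = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            valid = (arrs[i] != n_code) & (arrs[j] != n_code)
            cols = int(valid.sum())
            mm = int(((arrs[i] != arrs[j]) & valid).sum())
            mism[i, j] = mism[j, i] = mm
            values[i, j] = values[j, i] = mm / cols if cols else 0.0
    return DistanceMatrix(labels, values, mism)


# -- trees -------------------------------------------------------------------


@dataclass
class TreeNode:
    """Simple rooted tree node; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"

    def leaf_distances(self) -> pd.DataFrame:
        """Patristic (path-length) distances between all leaf pairs."""
        paths: dict[str, dict[int, float]] = {}

        def walk(node: "TreeNode", trail: list[tuple[int, float]], dist: float) -> None:
            trail = trail + [(id(node), dist)]
            if not node.children:
                paths[node.name] = dict(trail)
            for c in node.children:
                walk(c, trail, dist + c.length)

        walk(self, [], 0.0)
        names = list(paths)
        out = pd.DataFrame(0.0, index=names, columns=names)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                shared = set(paths[a]) & set(paths[b])
                lca_depth = max(paths[a][s] for s in shared)
                d = (
                    max(paths[a].values()) - lca_depth
                    + max(paths[b].values()) - lca_depth
                )
                out.loc[a, b] = out.loc[b, a] = d
        return out


@dataclass
class PhyloTree:
    root: TreeNode
    degenerate: bool = False  # fewer than 3 taxa: no NJ agglomeration ran

    def to_newick(self) -> str:
        return self.root.to_newick()

    @property
    def leaf_labels(self) -> list[str]:
        return self.root.leaf_names()


def build_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor joining on a distance matrix.

    Deterministic: the minimal-Q pair is chosen in label order on ties;
    negative branch lengths are clamped to zero.  With fewer than 3 labels
    the result is a degenerate star/edge tree flagged as such.
    """
    labels = matrix.labels
    n = len(labels)
    if n == 0:
        raise LineageAnalysisError("empty distance matrix")
    if n == 1:
        return PhyloTree(TreeNode(labels[0]), degenerate=True)
    if n == 2:
        d = float(matrix.values[0, 1])
        root = TreeNode(
            None, 0.0, [TreeNode(labels[0], d / 2), TreeNode(labels[1], d / 2)]
        )
        return PhyloTree(root, degenerate=True)

    nodes = [TreeNode(l) for l in labels]
    dist = matrix.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        r = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = dist[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(None, 0.0, [nodes[i], nodes[j]])
        new_index = dist.shape[0]
        new_row = np.zeros((1, dist.shape[1]))
        dist = np.vstack([dist, new_row])
        dist = np.hstack([dist, np.zeros((dist.shape[0], 1))])
        for k in active:
            if k in (i, j):
                continue
            d = (dist[i, k] + dist[j, k] - dist[i, j]) / 2
            dist[new_index, k] = dist[k, new_index] = max(d, 0.0)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_index]

    i, j = active
    nodes[i].length = 0.0
    nodes[j].length = max(float(dist[i, j]), 0.0)
    root = TreeNode(None, 0.0, [nodes[i], nodes[j]])
    return PhyloTree(root)


@dataclass
class RootedGenealogy:
    tree: PhyloTree
    germline_label: str
    nearest_group: str
    nearest_tie: bool
    distance_order: pd.Series  # raw mismatches to germline, ascending


def root_to_germline(
    tree: PhyloTree, matrix: DistanceMatrix, germline_label: str
) -> RootedGenealogy:
    """Root the genealogy on the germline leaf's edge and report the group
    genetically closest to germline.

    Nearest-group ranking uses the raw mismatch counts of the distance
    matrix (tree-independent); ties are reported and broken
    lexicographically.
    """
    if germline_label not in tree.leaf_labels:
        raise LineageAnalysisError(f"germline label {germline_label!r} not among leaves")

    # reroot at the internal endpoint of the germline leaf's edge by
    # reversing parent links along the path germ -> old root
    parents: dict[int, TreeNode] = {}

    def index(node: TreeNode) -> None:
        for c in node.children:
            parents[id(c)] = node
            index(c)

    index(tree.root)
    germ = next(l for l in tree.root.leaves() if l.name == germline_label)
    path = [germ]
    while id(path[-1]) in parents:
        path.append(parents[id(path[-1])])
    if len(path) <= 2:
        rooted = tree  # germline already hangs off the root
    else:
        orig_len = {id(n): n.length for n in path}
        for lower, upper in zip(path[:-1], path[1:]):
            upper.children.remove(lower)
        for i in range(1, len(path) - 1):
            node, upper = path[i], path[i + 1]
            node.children.append(upper)
            upper.length = orig_len[id(node)]
        new_root = path[1]
        new_root.children.append(germ)
        new_root.length = 0.0
        # splice out a degree-1 old root left over from the reversal
        old_root = path[-1]
        if len(old_root.children) == 1:
            holder = path[-2]
            child = old_root.children[0]
            child.length += old_root.length
            holder.children[holder.children.index(old_root)] = child
        rooted = PhyloTree(new_root, degenerate=tree.degenerate)

    gi = matrix.labels.index(germline_label)
    dists = pd.Series(
        {l: int(matrix.mismatches[gi, k]) for k, l in enumerate(matrix.labels) if l != germline_label}
    )
    dists = dists.sort_index(kind="stable").sort_values(kind="stable")
    nearest = dists.index[0]
    tie = (dists == dists.iloc[0]).sum() > 1
    return RootedGenealogy(rooted, germline_label, nearest, tie, dists)


# -- trafficking -------------------------------------------------------------


@dataclass
class TraffickingMatrix:
    counts: pd.DataFrame  # group x sample read counts
    classification: pd.Series  # "shared" | "private" per group
    summary: dict

    @property
    def shared_groups(self) -> list[str]:
        return list(self.classification[self.classification == "shared"].index)


def trafficking_matrix(
    groups: list[CloneGroup],
    sample_sites: dict[str, str],
    min_count: int = 1,
) -> TraffickingMatrix:
    """Group x sample matrix with shared/private and site-level sharing calls.

    A group present (count >= ``min_count``) in >= 2 samples is shared;
    shared within a single site label is interfollicular, across site labels
    internodal.  Row sums equal the group totals (count conservation).
    """
    sample_ids = list(sample_sites)
    counts = pd.DataFrame(0, index=[g.group_id for g in groups], columns=sample_ids, dtype=int)
    for g in groups:
        for s, c in g.per_sample_counts.items():
            if s in counts.columns:
                counts.loc[g.group_id, s] = c
    present = counts >= min_count
    n_samples_per_group = present.sum(axis=1)
    classification = pd.Series(
        np.where(n_samples_per_group >= 2, "shared", "private"),
        index=counts.index,
    )
    inter, internodal = [], []
    for gid in counts.index:
        sites = {sample_sites[s] for s in sample_ids if present.loc[gid, s]}
        samples_here = [s for s in sample_ids if present.loc[gid, s]]
        by_site: dict[str, int] = {}
        for s in samples_here:
            by_site[sample_sites[s]] = by_site.get(sample_sites[s], 0) + 1
        if any(v >= 2 for v in by_site.values()):
            inter.append(gid)
        if len(sites) >= 2:
            internodal.append(gid)
    n_groups = len(counts.index)
    n_shared = int((classification == "shared").sum())
    summary = {
        "n_groups": n_groups,
        "n_shared": n_shared,
        "n_private": n_groups - n_shared,
        "shared_fraction": n_shared / n_groups if n_groups else 0.0,
        "interfollicular_shared": inter,
        "internodal_shared": internodal,
    }
    return TraffickingMatrix(counts, classification, summary)
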