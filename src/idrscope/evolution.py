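"""Disorder-to-order transition (DOT) analysis over ortholog phylogenies.

Each alignment column becomes a binary character (1 = disordered,
0 = ordered, gaps missing).  The minimum number of state changes per
column is computed by parsimony: Fitch's set recursion on bifurcations,
generalized to polytomies with Hartigan's counting rule (at a node, keep
the states carried by the largest number of children; the deficit is the
change count).  Missing leaves are treated as fully ambiguous, which
yields the same score as pruning them.

"Changes per node" is the normalized DOT rate:
total minimum changes / (edge count x scored columns).

Per-clade net gain of disorder counts 0->1 minus 1->0 edges under a
deterministic ancestral assignment: changes are pushed toward the leaves
(a child keeps its parent's state whenever its state set allows), and
ambiguity at the root resolves to 0 (ordered).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import (OrthologFamily, Region, RegionKind, StatTestResult, Subtype)
from .regions import disorder_mask

MISSING = -1
BOTH = 3  # bitmask {0,1}


@dataclass
class TreeIndex:
    """Flattened rooted tree: postorder node arrays for fast parsimony.

    Node 0..n_leaves-1 are leaves (in ``leaf_labels`` order); internal
    nodes follow in postorder, the root last.  ``children`` lists child
    node indices per node (empty for leaves).
    """

    leaf_labels: list[str]
    children: list[list[int]]
    postorder: list[int]
    parent: list[int]

    @classmethod
    def from_dendropy(cls, tree) -> "TreeIndex":
        leaves = [lf for lf in tree.leaf_node_iter()]
        leaf_labels = [lf.taxon.label for lf in leaves]
        index = {id(lf): i for i, lf in enumerate(leaves)}
        children: list[list[int]] = [[] for _ in leaves]
        postorder: list[int] = []
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                postorder.append(index[id(node)])
                continue
            idx = len(children)
            index[id(node)] = idx
            children.append([index[id(c)] for c in node.child_nodes()])
            postorder.append(idx)
        parent = [-1] * len(children)
        for i, kids in enumerate(children):
            for k in kids:
                parent[k] = i
        return cls(leaf_labels, children, postorder, parent)

    @classmethod
    def from_nested(cls, nested) -> "TreeIndex":
        """Build from nested tuples of leaf labels, e.g. (("A","B"),("C","D"))."""
        leaf_labels: list[str] = []

        def collect(node):
            if not isinstance(node, tuple):
                leaf_labels.append(str(node))
            else:
                for c in node:
                    collect(c)
        collect(nested)
        children: list[list[int]] = [[] for _ in leaf_labels]
        postorder: list[int] = []
        counter = itertools.count()

        def build(node) -> int:
            if not isinstance(node, tuple):
                i = next(counter)
                postorder.append(i)
                return i
            kids = [build(c) for c in node]
            idx = len(children)
            children.append(kids)
            postorder.append(idx)
            return idx
        build(nested)
        parent = [-1] * len(children)
        for i, kids in enumerate(children):
            for k in kids:
                parent[k] = i
        return cls(leaf_labels, children, postorder, parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def root(self) -> int:
        return self.postorder[-1]


def _as_index(tree) -> TreeIndex:
    if isinstance(tree, TreeIndex):
        return tree
    if isinstance(tree, tuple):
        return TreeIndex.from_nested(tree)
    return TreeIndex.from_dendropy(tree)


def _hartigan_down(idx: TreeIndex, leaf_sets: list[int]):
    """Bottom-up pass; returns (state set bitmask per node, total changes).

    Bitmask 1 = {0}, 2 = {1}, 3 = {0,1}.  Missing leaves carry 3 and never
    force a change.
    """
    sets = [0] * idx.n_nodes
    changes = 0
    for node in idx.postorder:
        kids = idx.children[node]
        if not kids:
            sets[node] = leaf_sets[node]
            continue
        count0 = sum(1 for k in kids if sets[k] & 1)
        count1 = sum(1 for k in kids if sets[k] & 2)
        best = max(count0, count1)
        s = 0
        if count0 == best:
            s |= 1
        if count1 == best:
            s |= 2
        sets[node] = s
        changes += len(kids) - best
    return sets, changes


def fitch_changes(tree, column_states: dict[str, int | None]) -> int | None:
    """Minimum number of binary state changes on a rooted tree.

    ``column_states`` maps leaf label to 0, 1, or None (missing).  Columns
    with fewer than 2 informative leaves are unscored (returns None).
    Polytomies are handled by Hartigan's counting generalization of the
    Fitch recursion; missing leaves are fully ambiguous, equivalent to
    pruning them.
    """
    idx = _as_index(tree)
    informative = 0
    leaf_sets = [BOTH] * idx.n_nodes
    for i, label in enumerate(idx.leaf_labels):
        s = column_states.get(label)
        if s is None or s == MISSING:
            continue
        if s not in (0, 1):
            raise ValueError(f"leaf {label}: state must be 0/1/None, got {s}")
        leaf_sets[i] = 1 << s
        informative += 1
    if informative < 2:
        return None
    _, changes = _hartigan_down(idx, leaf_sets)
    return changes


def ancestral_states(idx: TreeIndex, leaf_sets: list[int]) -> list[int]:
    """Deterministic optimal assignment: root ambiguity -> 0; a child keeps
    its parent's state whenever its own set allows (changes pushed to the
    leaves)."""
    sets, _ = _hartigan_down(idx, leaf_sets)
    assign = [0] * idx.n_nodes
    order = list(reversed(idx.postorder))  # root first
    root = idx.root
    assign[root] = 0 if sets[root] & 1 else 1
    for node in order:
        for k in idx.children[node]:
            if sets[k] & (1 << assign[node]):
                assign[k] = assign[node]
            else:
                assign[k] = 0 if sets[k] & 1 else 1
    return assign


@dataclass
class ColumnCharacterMatrix:
    """Binary disorder characters per (leaf, alignment column).

    ``states`` is an int8 array (n_leaves x n_columns) over {1, 0, -1
    missing}; ``reference_map`` maps 1-based alignment column to 1-based
    ungapped reference residue (absent for reference-gap columns);
    ``scored`` flags columns with at most ``max_missing_frac`` missing
    leaves and at least 2 informative states.
    """

    family_id: str
    leaf_labels: list[str]
    states: np.ndarray
    reference_map: dict[int, int]
    scored: np.ndarray
    reference_label: str | None = None
    max_missing_frac: float = 0.5

    @property
    def n_columns(self) -> int:
        return self.states.shape[1]

    def column(self, col: int) -> dict[str, int | None]:
        """1-based column as a leaf->state mapping (None for missing)."""
        vec = self.states[:, col - 1]
        return {lab: (None if v == MISSING else int(v))
                for lab, v in zip(self.leaf_labels, vec)}


def build_character_matrix(family: OrthologFamily,
                           regions_by_sequence: dict[str, list[Region]],
                           max_missing_frac: float = 0.5) -> ColumnCharacterMatrix:
    """Map each ortholog's region calls onto alignment columns.

    Every non-gap aligned residue inherits its sequence's region kind
    (1 disordered / 0 ordered); gaps are missing.  Columns with more than
    ``max_missing_frac`` missing states, or fewer than two informative
    states, are flagged unscored.
    """
    idx = TreeIndex.from_dendropy(family.tree)
    leaf_labels = idx.leaf_labels
    n_cols = family.n_columns
    states = np.full((len(leaf_labels), n_cols), MISSING, dtype=np.int8)
    for row, label in enumerate(leaf_labels):
        aligned = family.alignment[label]
        regs = regions_by_sequence.get(label)
        if regs is None:
            raise ValueError(f"no regions supplied for sequence {label!r}")
        ungapped_len = sum(1 for c in aligned if c != "-")
        mask = disorder_mask(regs, ungapped_len)
        pos = 0
        for col, c in enumerate(aligned):
            if c != "-":
                states[row, col] = 1 if mask[pos] else 0
                pos += 1
    ref_aligned = family.alignment[family.reference_id]
    reference_map = {}
    pos = 0
    for col, c in enumerate(ref_aligned, start=1):
        if c != "-":
            pos += 1
            reference_map[col] = pos
    n_missing = (states == MISSING).sum(axis=0)
    n_info = states.shape[0] - n_missing
    scored = (n_missing <= max_missing_frac * states.shape[0]) & (n_info >= 2)
    return ColumnCharacterMatrix(
        family_id=family.family_id, leaf_labels=leaf_labels, states=states,
        reference_map=reference_map, scored=scored,
        reference_label=family.reference_id, max_missing_frac=max_missing_frac)


def per_column_changes(matrix: ColumnCharacterMatrix, tree) -> np.ndarray:
    """Fitch minimum changes per column; -1 for unscored columns."""
    idx = _as_index(tree)
    order = {lab: i for i, lab in enumerate(matrix.leaf_labels)}
    perm = [order[lab] for lab in idx.leaf_labels]
    out = np.full(matrix.n_columns, -1, dtype=int)
    for col in range(matrix.n_columns):
        if not matrix.scored[col]:
            continue
        vec = matrix.states[perm, col]
        leaf_sets = [BOTH] * idx.n_nodes
        info = 0
        for i, v in enumerate(vec):
            if v != MISSING:
                leaf_sets[i] = 1 << int(v)
                info += 1
        if info < 2:
            continue
        _, changes = _hartigan_down(idx, leaf_sets)
        out[col] = changes
    return out


def mann_whitney_u(a, b, alternative: str = "two_sided",
                   exact_max_n: int = 8) -> StatTestResult:
    """Mann-Whitney U with exact enumeration for small groups.

    When both groups have at most ``exact_max_n`` observations the exact
    null is obtained by enumerating every assignment of the pooled values
    to the two groups (tie-safe); otherwise the tie-corrected normal
    approximation with continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[
        alternative]
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 <= exact_max_n and n2 <= exact_max_n:
        mu = n1 * n2 / 2.0
        total = 0
        hits = 0
        idx_all = range(n1 + n2)
        for combo in itertools.combinations(idx_all, n1):
            u = float(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
            total += 1
            if alt == "two-sided":
                hits += abs(u - mu) >= abs(u_obs - mu) - 1e-9
            elif alt == "greater":
                hits += u >= u_obs - 1e-9
            else:
                hits += u <= u_obs + 1e-9
        p = hits / total
        method = f"mannwhitney_exact_{alternative}"
    else:
        res = stats.mannwhitneyu(a, b, alternative=alt, method="asymptotic",
                                 use_continuity=True)
        u_obs, p = float(res.statistic), float(res.pvalue)
        method = f"mannwhitney_normal_{alternative}"
    return StatTestResult(u_obs, float(min(p, 1.0)), method,
                          n={"n1": n1, "n2": n2})


def ss_idr_site_set(reference_regions: list[Region],
                    matrix: ColumnCharacterMatrix,
                    adjacency_cols: int = 1,
                    ortholog_ordered_frac: float = 0.5) -> set[int]:
    """Reference SS-IDR positions that border order, in-protein or in orthologs.

    A reference residue inside an SS-IDR qualifies when it lies within
    ``adjacency_cols`` alignment columns of an ordered reference region,
    or when at least ``ortholog_ordered_frac`` of the non-missing
    ortholog states at its column are ordered (0).
    """
    length = max(r.end for r in reference_regions)
    ss_mask = np.zeros(length + 1, dtype=bool)
    ordered_mask = np.zeros(length + 1, dtype=bool)
    for r in reference_regions:
        if r.kind is RegionKind.DISORDERED and r.subtype is Subtype.SS_IDR:
            ss_mask[r.start:r.end + 1] = True
        elif r.kind is RegionKind.ORDERED:
            ordered_mask[r.start:r.end + 1] = True
    col_of_ref = {ref: col for col, ref in matrix.reference_map.items()}
    qualifying: set[int] = set()
    for ref_pos in range(1, length + 1):
        if not ss_mask[ref_pos]:
            continue
        col = col_of_ref.get(ref_pos)
        if col is None:
            continue
        # in-protein adjacency, measured in alignment columns
        near_ordered = False
        for delta in range(-adjacency_cols, adjacency_cols + 1):
            other = matrix.reference_map.get(col + delta)
            if other is not None and ordered_mask[other]:
                near_ordered = True
                break
        if not near_ordered:
            states = matrix.states[:, col - 1]
            informative = states[states != MISSING]
            if len(informative) and \
                    (informative == 0).sum() / len(informative) >= ortholog_ordered_frac:
                near_ordered = True
        if near_ordered:
            qualifying.add(ref_pos)
    return qualifying


@dataclass
class DOTSummary:
    """Per-family DOT statistics."""

    family_id: str
    per_column_changes: np.ndarray
    changes_per_node: float
    group_comparison: StatTestResult | None
    clade_net_gain: dict[str, int]
    notes: list[str] = field(default_factory=list)


def net_disorder_gain(tree, matrix: ColumnCharacterMatrix) -> dict[str, int]:
    """Net gain of disorder per clade: #(0->1) - #(1->0) edges in the clade.

    Ancestral states follow the deterministic assignment of
    :func:`ancestral_states`; clades (internal nodes) are named by their
    lexicographically smallest leaf label; an edge belongs to every clade
    whose subtree contains it.  Summed over scored columns.
    """
    idx = _as_index(tree)
    order = {lab: i for i, lab in enumerate(matrix.leaf_labels)}
    perm = [order[lab] for lab in idx.leaf_labels]

    # smallest leaf label per internal node
    min_label = [""] * idx.n_nodes
    for node in idx.postorder:
        kids = idx.children[node]
        if not kids:
            min_label[node] = idx.leaf_labels[node]
        else:
            min_label[node] = min(min_label[k] for k in kids)

    gain = np.zeros(idx.n_nodes, dtype=int)   # per-edge 0->1 minus 1->0, child-indexed
    for col in range(matrix.n_columns):
        if not matrix.scored[col]:
            continue
        vec = matrix.states[perm, col]
        leaf_sets = [BOTH] * idx.n_nodes
        for i, v in enumerate(vec):
            if v != MISSING:
                leaf_sets[i] = 1 << int(v)
        assign = ancestral_states(idx, leaf_sets)
        for child in range(idx.n_nodes):
            par = idx.parent[child]
            if par < 0:
                continue
            if assign[par] == 0 and assign[child] == 1:
                gain[child] += 1
            elif assign[par] == 1 and assign[child] == 0:
                gain[child] -= 1

    # aggregate per clade (edges within the subtree of each internal node)
    subtree_gain = [0] * idx.n_nodes
    for node in idx.postorder:
        kids = idx.children[node]
        subtree_gain[node] = sum(subtree_gain[k] + gain[k] for k in kids)
    return {f"clade_{min_label[node]}": int(subtree_gain[node])
            for node in range(idx.n_nodes) if idx.children[node]}


def dot_summary(matrix: ColumnCharacterMatrix, tree,
                ss_idr_sites: set[int]) -> DOTSummary:
    """Full DOT summary for one ortholog family.

    Group A: scored columns mapping to SS-IDR reference positions (as
    defined by ``ss_idr_sites``); group B: other scored columns mapping to
    disordered reference positions.  Their per-column change counts are
    compared by a two-sided Mann-Whitney test (exact when both groups are
    small).
    """
    idx = _as_index(tree)
    changes = per_column_changes(matrix, idx)
    scored = changes >= 0
    n_scored = int(scored.sum())
    total = int(changes[scored].sum()) if n_scored else 0
    cpn = total / (idx.n_edges * n_scored) if n_scored else 0.0
    notes: list[str] = []

    group_a, group_b = [], []
    ref_states = None
    if matrix.reference_label and matrix.reference_label in matrix.leaf_labels:
        ref_states = matrix.states[matrix.leaf_labels.index(matrix.reference_label)]
    for col in range(matrix.n_columns):
        if not scored[col]:
            continue
        ref_pos = matrix.reference_map.get(col + 1)
        if ref_pos is None:
            continue
        if ref_pos in ss_idr_sites:
            group_a.append(changes[col])
        else:
            if ref_states is not None and ref_states[col] != 1:
                continue  # only disordered reference positions form group B
            group_b.append(changes[col])
    comparison = None
    if group_a and group_b:
        pooled = group_a + group_b
        if len(set(pooled)) > 1:
            comparison = mann_whitney_u(group_a, group_b,
                                        alternative="two_sided")
        else:
            notes.append("group comparison omitted: all change counts equal")
    else:
        notes.append("group comparison omitted: empty group A or B")
    return DOTSummary(
        family_id=matrix.family_id, per_column_changes=changes,
        changes_per_node=cpn, group_comparison=comparison,
        clade_net_gain=net_disorder_gain(idx, matrix), notes=notes)
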