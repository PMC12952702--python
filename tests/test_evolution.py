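import itertools

import numpy as np
import pytest
from scipy import stats

from idrscope import (Region, RegionKind, Subtype, build_character_matrix,
                      dot_summary, fitch_changes, mann_whitney_u,
                      net_disorder_gain, per_column_changes, ss_idr_site_set)
from idrscope.evolution import BOTH, TreeIndex, ancestral_states
from idrscope.io import read_family
from idrscope.model import OrthologFamily


def brute_force_min_changes(idx: TreeIndex, leaf_states):
    """Oracle: minimize edge mismatches over all ancestral assignments.

    Missing leaves (None) are free to take any state, which equals pruning
    them for binary characters.
    """
    internal = [n for n in range(idx.n_nodes) if idx.children[n]]
    free_leaves = [i for i, lab in enumerate(idx.leaf_labels)
                   if leaf_states.get(lab) is None]
    best = None
    for assign_internal in itertools.product((0, 1), repeat=len(internal)):
        for assign_free in itertools.product((0, 1), repeat=len(free_leaves)):
            state = {}
            for n, s in zip(internal, assign_internal):
                state[n] = s
            for n, s in zip(free_leaves, assign_free):
                state[n] = s
            for i, lab in enumerate(idx.leaf_labels):
                if leaf_states.get(lab) is not None:
                    state[i] = leaf_states[lab]
            changes = sum(1 for child in range(idx.n_nodes)
                          if idx.parent[child] >= 0
                          and state[child] != state[idx.parent[child]])
            if best is None or changes < best:
                best = changes
    return best


def all_rooted_trees(leaves):
    """Every rooted tree (multifurcations included) over the label set."""
    leaves = tuple(leaves)
    if len(leaves) == 1:
        return [leaves[0]]
    trees = []
    for partition in set_partitions(leaves):
        if len(partition) < 2:
            continue
        child_options = [all_rooted_trees(block) for block in partition]
        for combo in itertools.product(*child_options):
            trees.append(tuple(combo))
    return trees


def set_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [(first,) + part[i]] + part[i + 1:]
        yield [(first,)] + part


class TestFitchChanges:
    def test_two_clades(self):
        tree = (("A", "B"), ("C", "D"))
        assert fitch_changes(tree, {"A": 1, "B": 1, "C": 0, "D": 0}) == 1

    def test_all_identical_zero(self):
        tree = (("A", "B"), ("C", "D"))
        assert fitch_changes(tree, {"A": 1, "B": 1, "C": 1, "D": 1}) == 0

    def test_interleaved_two_changes(self):
        tree = (("A", "B"), ("C", "D"))
        assert fitch_changes(tree, {"A": 1, "B": 0, "C": 1, "D": 0}) == 2

    def test_polytomy_counting(self):
        # four children 0,0,1,1 under the root need two changes
        tree = ("A", "B", "C", "D")
        assert fitch_changes(tree, {"A": 0, "B": 0, "C": 1, "D": 1}) == 2

    def test_missing_leaves_pruned(self):
        tree = (("A", "B"), ("C", "D"))
        assert fitch_changes(tree, {"A": 1, "B": None, "C": 0, "D": None}) == 1

    def test_fewer_than_two_informative_unscored(self):
        tree = (("A", "B"), ("C", "D"))
        assert fitch_changes(tree, {"A": 1, "B": None, "C": None,
                                    "D": None}) is None

    @pytest.mark.parametrize("n_leaves", [2, 3, 4, 5])
    def test_exhaustive_small_trees(self, n_leaves):
        """Equality with brute-force minimization for every rooted tree
        shape (polytomies included) and every binary labeling."""
        labels = [chr(65 + i) for i in range(n_leaves)]
        for tree in all_rooted_trees(labels):
            if not isinstance(tree, tuple):
                continue
            idx = TreeIndex.from_nested(tree)
            for states in itertools.product((0, 1), repeat=n_leaves):
                mapping = dict(zip(labels, states))
                assert fitch_changes(idx, mapping) == \
                    brute_force_min_changes(idx, mapping)

    def test_exhaustive_with_missing_data(self):
        labels = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(0)
        trees = all_rooted_trees(labels)
        for _ in range(200):
            tree = trees[int(rng.integers(len(trees)))]
            if not isinstance(tree, tuple):
                continue
            idx = TreeIndex.from_nested(tree)
            states = {lab: (None if rng.random() < 0.3
                            else int(rng.integers(2))) for lab in labels}
            informative = sum(1 for v in states.values() if v is not None)
            got = fitch_changes(idx, states)
            if informative < 2:
                assert got is None
            else:
                assert got == brute_force_min_changes(idx, states)

    def test_invariant_to_leaf_order(self):
        rng = np.random.default_rng(1)
        states = {lab: int(rng.integers(2)) for lab in "ABCDEF"}
        t1 = ((("A", "B"), "C"), (("D", "E"), "F"))
        t2 = ((("E", "D"), "F"), (("B", "A"), "C"))  # same shape, leaves swapped
        assert fitch_changes(t1, states) == fitch_changes(t2, states)


class TestCharacterMatrix:
    def make_family(self, tmp_path, alignment, newick, ref):
        afa = tmp_path / "f.afa"
        afa.write_text("".join(f">{k}\n{v}\n" for k, v in alignment.items()))
        nwk = tmp_path / "f.nwk"
        nwk.write_text(newick + "\n")
        return read_family(afa, nwk, reference_id=ref)

    def full_tiling(self, pid, kinds):
        regs, start = [], 1
        for i in range(1, len(kinds) + 1):
            if i == len(kinds) or kinds[i] != kinds[start - 1]:
                regs.append(Region(pid, start, i,
                                   RegionKind.DISORDERED if kinds[start - 1]
                                   else RegionKind.ORDERED))
                start = i + 1
        return regs

    def test_all_disordered_all_ones(self, tmp_path):
        fam = self.make_family(
            tmp_path, {"A": "MKV", "B": "MKV"}, "(A:1,B:1);", "A")
        regions = {pid: [Region(pid, 1, 3, RegionKind.DISORDERED)]
                   for pid in "AB"}
        mat = build_character_matrix(fam, regions)
        assert (mat.states == 1).all()

    def test_gap_becomes_missing(self, tmp_path):
        fam = self.make_family(
            tmp_path, {"A": "MK-V", "B": "MKAV"}, "(A:1,B:1);", "A")
        regions = {"A": [Region("A", 1, 3, RegionKind.DISORDERED)],
                   "B": [Region("B", 1, 4, RegionKind.DISORDERED)]}
        mat = build_character_matrix(fam, regions)
        row_a = mat.states[mat.leaf_labels.index("A")]
        assert row_a[2] == -1
        assert mat.reference_map == {1: 1, 2: 2, 4: 3}

    def test_random_fixture_matches_position_lookup(self, tmp_path):
        rng = np.random.default_rng(3)
        names = ["A", "B", "C", "D"]
        kinds = {n: rng.integers(0, 2, size=12).astype(bool) for n in names}
        fam = self.make_family(
            tmp_path, {n: "M" * 12 for n in names},
            "((A:1,B:1):1,(C:1,D:1):1);", "A")
        regions = {n: self.full_tiling(n, kinds[n]) for n in names}
        mat = build_character_matrix(fam, regions)
        for n in names:
            row = mat.states[mat.leaf_labels.index(n)]
            assert (row == kinds[n].astype(int)).all()


class TestMannWhitney:
    def test_exact_agrees_with_scipy_no_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(size=7)
            mine = mann_whitney_u(a, b, "two_sided")
            ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)
            assert mine.statistic == pytest.approx(ref.statistic)

    def test_exact_handles_ties(self):
        a = [0, 0, 1, 1]
        b = [2, 2, 3, 3]
        res = mann_whitney_u(a, b, "two_sided")
        # complete separation of 4 vs 4: only the two extreme index subsets
        # ({all of a}, {all of b}) reach |U - mu| = 8, so p = 2 / C(8,4)
        assert res.p_value == pytest.approx(2 / 70)

    def test_large_sample_tie_corrected(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 4, size=60)
        b = rng.integers(0, 4, size=60) + 1
        mine = mann_whitney_u(a, b, "two_sided")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestDOTSummary:
    def make_matrix(self, states, ref_map, fam="F", labels=None, ref=None):
        states = np.asarray(states, dtype=np.int8)
        labels = labels or [f"L{i}" for i in range(states.shape[0])]
        n_missing = (states == -1).sum(axis=0)
        scored = (n_missing <= 0.5 * states.shape[0]) & \
            ((states.shape[0] - n_missing) >= 2)
        from idrscope.evolution import ColumnCharacterMatrix
        return ColumnCharacterMatrix(fam, labels, states, ref_map, scored,
                                     reference_label=ref)

    def test_changes_per_node_arithmetic(self):
        # columns with changes {0, 0, 2, 2} on a 6-edge tree -> 4/(6*4)
        tree = (("L0", "L1"), ("L2", "L3"))
        idx = TreeIndex.from_nested(tree)
        # column layout (rows = leaves L0..L3): all-1, all-0, interleaved x2
        states = np.array([[1, 0, 1, 1],
                           [1, 0, 0, 0],
                           [1, 0, 1, 0],
                           [1, 0, 0, 1]])
        mat = self.make_matrix(states, {c: c for c in range(1, 5)},
                               labels=idx.leaf_labels)
        changes = per_column_changes(mat, idx)
        assert list(changes) == [0, 0, 2, 2]
        summary = dot_summary(mat, idx, ss_idr_sites=set())
        assert summary.changes_per_node == pytest.approx(4 / (6 * 4))

    def test_all_constant_columns_degenerate(self):
        tree = (("L0", "L1"), ("L2", "L3"))
        mat = self.make_matrix(np.ones((4, 5), dtype=int), {c: c for c in
                                                            range(1, 6)})
        summary = dot_summary(mat, tree, ss_idr_sites=set())
        assert summary.changes_per_node == 0.0
        assert summary.group_comparison is None

    def test_simulated_contrast_detected(self):
        """Columns evolved at per-edge rate 0.1 show more changes than at
        0.01, and the two-group comparison is significant."""
        rng = np.random.default_rng(7)
        n_taxa, n_cols = 16, 200
        tree, idx = random_balanced_tree(n_taxa)
        states = []
        col_group = []
        for rate, group in ((0.01, "A"), (0.1, "B")):
            for _ in range(n_cols):
                states.append(evolve_column(idx, rate, rng))
                col_group.append(group)
        states = np.array(states).T
        ref_map = {i + 1: i + 1 for i in range(2 * n_cols)}
        mat = self.make_matrix(states, ref_map,
                               labels=idx.leaf_labels)
        changes = per_column_changes(mat, idx)
        a = changes[:n_cols]
        b = changes[n_cols:]
        assert b.mean() > a.mean()
        res = mann_whitney_u(a, b, "two_sided")
        assert res.p_value < 0.01


def random_balanced_tree(n_taxa):
    labels = [f"L{i}" for i in range(n_taxa)]

    def build(block):
        if len(block) == 1:
            return block[0]
        mid = len(block) // 2
        return (build(block[:mid]), build(block[mid:]))
    tree = build(labels)
    return tree, TreeIndex.from_nested(tree)


def evolve_column(idx, rate, rng, root_state=1):
    """Two-state Markov evolution down the tree; returns leaf states."""
    state = {idx.root: root_state}
    for node in reversed(idx.postorder):
        for child in idx.children[node]:
            s = state[node]
            state[child] = 1 - s if rng.random() < rate else s
    return [state[i] for i in range(idx.n_leaves)]


class TestSSIdrSiteSet:
    def make_matrix(self, states, ref_map, labels):
        states = np.asarray(states, dtype=np.int8)
        scored = np.ones(states.shape[1], dtype=bool)
        from idrscope.evolution import ColumnCharacterMatrix
        return ColumnCharacterMatrix("F", labels, states, ref_map, scored)

    def regions(self):
        return [Region("R", 1, 4, RegionKind.DISORDERED,
                       subtype=Subtype.SS_IDR),
                Region("R", 5, 8, RegionKind.ORDERED)]

    def test_border_residue_qualifies(self):
        states = np.ones((4, 8), dtype=int)
        mat = self.make_matrix(states, {i: i for i in range(1, 9)},
                               ["R", "B", "C", "D"])
        sites = ss_idr_site_set(self.regions(), mat, adjacency_cols=1,
                                ortholog_ordered_frac=0.5)
        assert 4 in sites          # borders the ordered region
        assert 1 not in sites      # interior, all orthologs disordered

    def test_ortholog_ordered_majority_qualifies(self):
        states = np.ones((4, 8), dtype=int)
        states[1:, 1] = 0          # 3/4 orthologs ordered at column 2
        mat = self.make_matrix(states, {i: i for i in range(1, 9)},
                               ["R", "B", "C", "D"])
        sites = ss_idr_site_set(self.regions(), mat, adjacency_cols=1,
                                ortholog_ordered_frac=0.5)
        assert 2 in sites


class TestNetDisorderGain:
    def test_no_changes_all_zero(self):
        tree = (("A", "B"), ("C", "D"))
        labels = ["A", "B", "C", "D"]
        states = np.ones((4, 6), dtype=np.int8)
        from idrscope.evolution import ColumnCharacterMatrix
        mat = ColumnCharacterMatrix("F", labels, states,
                                    {}, np.ones(6, dtype=bool))
        gains = net_disorder_gain(tree, mat)
        assert set(gains.values()) == {0}

    def test_single_gain_counted_in_containing_clades(self):
        # A=1, everyone else 0: one 0->1 change on the edge to A, inside
        # the (A,B) clade and the root clade
        tree = (("A", "B"), ("C", "D"))
        labels = ["A", "B", "C", "D"]
        states = np.array([[1], [0], [0], [0]], dtype=np.int8)
        from idrscope.evolution import ColumnCharacterMatrix
        mat = ColumnCharacterMatrix("F", labels, states, {},
                                    np.ones(1, dtype=bool))
        gains = net_disorder_gain(tree, mat)
        assert gains["clade_A"] == 1      # root clade contains the edge
        assert all(v in (0, 1) for v in gains.values())

    def test_gain_biased_evolution_positive_at_root(self):
        """With gain rate 3x loss, the root-level net gain is positive in
        nearly all replicates."""
        n_pos = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            tree, idx = random_balanced_tree(8)
            cols = []
            for _ in range(120):
                state = {idx.root: 0}
                for node in reversed(idx.postorder):
                    for child in idx.children[node]:
                        s = state[node]
                        p = 0.15 if s == 0 else 0.05
                        state[child] = 1 - s if rng.random() < p else s
                cols.append([state[i] for i in range(idx.n_leaves)])
            states = np.array(cols, dtype=np.int8).T
            from idrscope.evolution import ColumnCharacterMatrix
            mat = ColumnCharacterMatrix("F", idx.leaf_labels, states, {},
                                        np.ones(states.shape[1], dtype=bool))
            root_clade = f"clade_{min(idx.leaf_labels)}"
            if net_disorder_gain(idx, mat)[root_clade] > 0:
                n_pos += 1
        assert n_pos >= 0.95 * reps

    def test_ancestral_assignment_cost_matches_fitch(self):
        """The deterministic DELTRAN-style assignment realizes the Fitch
        minimum number of changes."""
        rng = np.random.default_rng(9)
        labels = list("ABCDEF")
        trees = all_rooted_trees(labels)
        for _ in range(100):
            tree = trees[int(rng.integers(len(trees)))]
            if not isinstance(tree, tuple):
                continue
            idx = TreeIndex.from_nested(tree)
            states = {lab: int(rng.integers(2)) for lab in labels}
            leaf_sets = [BOTH] * idx.n_nodes
            for i, lab in enumerate(idx.leaf_labels):
                leaf_sets[i] = 1 << states[lab]
            assign = ancestral_states(idx, leaf_sets)
            cost = sum(1 for child in range(idx.n_nodes)
                       if idx.parent[child] >= 0
                       and assign[child] != assign[idx.parent[child]])
            assert cost == fitch_changes(idx, states)


class TestParsimonyBound:
    def test_fitch_below_simulated_events(self, default_dataset):
        """Per-column Fitch changes never exceed the simulated flip count."""
        ds = default_dataset
        checked = 0
        for fam in ds.families:
            mat = build_character_matrix(fam, ds.family_regions[fam.family_id])
            changes = per_column_changes(mat, fam.tree)
            events = ds.truth.family_events[fam.family_id]
            for c, e in zip(changes, events):
                if c >= 0:
                    assert c <= e
                    checked += 1
        assert checked >= 1000

    def test_mean_changes_increase_with_rate(self):
        """Mean per-column changes rise monotonically over a rate grid."""
        means = []
        for rate in (0.01, 0.05, 0.2):
            vals = []
            for seed in range(1, 6):
                rng = np.random.default_rng(seed)
                tree, idx = random_balanced_tree(12)
                cols = [evolve_column(idx, rate, rng) for _ in range(100)]
                for col in cols:
                    vals.append(fitch_changes(
                        idx, dict(zip(idx.leaf_labels, col))))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
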