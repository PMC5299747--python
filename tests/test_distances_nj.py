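"""TN93 distance oracles and neighbor-joining tree recovery."""

import math

import numpy as np
import pytest

from caniglobin.distances import (
    distance_matrix,
    p_distance,
    tn93_distance,
    tn93_from_proportions,
)
from caniglobin.njtree import Tree, bootstrap_support, nj_tree


def independent_tn93(p1, p2, q, pa, pc, pg, pt):
    """Plug-in evaluation of the published TN93 closed form, written
    independently of the implementation."""
    pr, py = pa + pg, pc + pt
    t1 = -(2 * pa * pg / pr) * math.log(1 - pr / (2 * pa * pg) * p1 - q / (2 * pr))
    t2 = -(2 * pc * pt / py) * math.log(1 - py / (2 * pc * pt) * p2 - q / (2 * py))
    t3 = -2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py) * math.log(
        1 - q / (2 * pr * py)
    )
    return t1 + t2 + t3


def mutate(seq, changes):
    s = list(seq)
    for pos, base in changes:
        s[pos] = base
    return "".join(s)


@pytest.fixture
def toy_pair():
    """300-bp pair, equal base composition, 9 A<->G, 6 C<->T, 3 transversions.

    Substitutions are applied in complementary pairs (A->G and G->A, etc.)
    so both sequences keep the uniform composition exactly.
    """
    a = "ACGT" * 75
    changes = []
    # 9 purine transitions: alternate A->G (cols 0,8,16,...) and G->A (cols 2,...)
    a_sites = [0 + 8 * k for k in range(5)]  # A positions
    g_sites = [2 + 8 * k for k in range(4)]  # G positions
    changes += [(p, "G") for p in a_sites] + [(p, "A") for p in g_sites]
    # 6 pyrimidine transitions: 3 C->T, 3 T->C
    changes += [(1 + 8 * k, "T") for k in range(3)]
    changes += [(3 + 8 * k, "C") for k in range(3)]
    # 3 transversions: A->C, C->A, G->T (composition drifts by <1 base each)
    changes += [(96, "C"), (97, "A"), (102, "T")]
    b = mutate(a, changes)
    return a, b


class TestTN93:
    def test_identical_sequences_zero(self):
        assert tn93_distance("ACGTACGT" * 10, "ACGTACGT" * 10) == 0.0

    def test_matches_independent_plugin_evaluation(self, toy_pair):
        a, b = toy_pair
        n = len(a)
        pooled = a + b
        freqs = [pooled.count(c) / (2 * n) for c in "ACGT"]
        diffs = [(x, y) for x, y in zip(a, b) if x != y]
        p1 = sum({x, y} == {"A", "G"} for x, y in diffs) / n
        p2 = sum({x, y} == {"C", "T"} for x, y in diffs) / n
        q = (len(diffs)) / n - p1 - p2
        expected = independent_tn93(p1, p2, q, *freqs)
        assert tn93_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_reduces_to_k2p_under_equal_frequencies(self):
        """With uniform composition and balanced transition types, TN93
        equals the Kimura two-parameter closed form to 1e-9."""
        a = "ACGT" * 100
        changes = (
            [(8 * k, "G") for k in range(6)]  # A->G
            + [(8 * k + 2, "A") for k in range(6)]  # G->A
            + [(8 * k + 1, "T") for k in range(6)]  # C->T
            + [(8 * k + 3, "C") for k in range(6)]  # T->C
            + [(200, "C"), (201, "A"), (202, "T"), (203, "G")]  # transversions
        )
        b = mutate(a, changes)
        n = len(a)
        p = 24 / n
        q = 4 / n
        k2p = -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)
        assert tn93_distance(a, b) == pytest.approx(k2p, abs=1e-9)

    def test_symmetry_and_monotonicity(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), 500))
        prev = 0.0
        seq = base
        for k in range(1, 20):
            pos = int(rng.integers(0, 500))
            cur = seq[pos]
            seq = mutate(seq, [(pos, {"A": "G", "G": "A", "C": "T", "T": "C"}[cur])])
            d = tn93_distance(base, seq)
            assert d == pytest.approx(tn93_distance(seq, base))
            assert d >= prev - 1e-12 or math.isnan(d)
            if not math.isnan(d):
                prev = d

    def test_saturation_returns_nan(self):
        # maximally different sequences saturate the correction
        assert math.isnan(tn93_distance("AAAA" * 50, "GGGG" * 50))

    def test_gap_rejected(self):
        with pytest.raises(ValueError):
            tn93_distance("AC-T", "ACGT")


def random_additive_tree(n_taxa, rng):
    """A random binary tree topology with positive branch lengths and its
    additive distance matrix, computed by independent path summation."""
    import itertools

    nodes = {i: [f"t{i}"] for i in range(n_taxa)}  # node -> leaf set
    edges = {}  # (child_node_id) -> (parent, length)
    next_id = n_taxa
    active = list(range(n_taxa))
    parent_of = {}
    lengths = {}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        for child in (a, b):
            parent_of[child] = next_id
            lengths[child] = float(rng.uniform(0.05, 1.0))
        nodes[next_id] = nodes[a] + nodes[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    root = active[0]

    def path_to_root(x):
        out = {}
        total = 0.0
        while x in parent_of:
            total += lengths[x]
            x = parent_of[x]
            out[x] = total
        return out

    labels = [f"t{i}" for i in range(n_taxa)]
    dm = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        pi, pj = path_to_root(i), path_to_root(j)
        common = min(set(pi) & set(pj), key=lambda anc: pi[anc] + pj[anc])
        dm[i, j] = dm[j, i] = pi[common] + pj[common]
    # splits of internal edges, normalised away from t0
    taxa = set(labels)
    splits = set()
    for x, p in parent_of.items():
        side = frozenset(nodes[x])
        if "t0" in side:
            side = frozenset(taxa - side)
        if 2 <= len(side) <= n_taxa - 2:
            splits.add(side)
    return dm, labels, splits


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(dm, ["a", "b", "c"])
        edges = tree.edges()
        assert edges[frozenset({"b", "c"})] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert edges[frozenset({"b"})] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert edges[frozenset({"c"})] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_recovers_additive_trees_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            dm, labels, true_splits = random_additive_tree(n_taxa, rng)
            tree = nj_tree(dm, labels)
            assert tree.bipartitions() == true_splits
            # additivity: tree path lengths reproduce the matrix
            edges = tree.edges()
            for i, li in enumerate(labels):
                for j, lj in enumerate(labels):
                    if i >= j:
                        continue
                    path = sum(
                        length
                        for split, length in edges.items()
                        if (li in split) != (lj in split)
                    )
                    assert path == pytest.approx(dm[i, j], abs=1e-9)

    def test_tie_break_deterministic(self):
        # a star-like matrix where all Q values tie: lowest-index pair joins
        dm = np.ones((5, 5)) - np.eye(5)
        t1 = nj_tree(dm, list("abcde"))
        t2 = nj_tree(dm, list("abcde"))
        assert t1.newick() == t2.newick()
        assert "(a:" in t1.newick() or "a:" in t1.newick()

    def test_matches_dendropy_topology(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(12)
        dm, labels, _ = random_additive_tree(6, rng)
        # add noise so the matrix is non-additive (generic instance)
        noise = rng.uniform(0, 0.01, dm.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        dm = dm + noise
        mine = nj_tree(dm, labels).bipartitions()

        csv = "," + ",".join(labels) + "\n"
        for i, l in enumerate(labels):
            csv += l + "," + ",".join(f"{x:.10f}" for x in dm[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        theirs = set()
        taxa = set(labels)
        for edge in dtree.preorder_edge_iter():
            if edge.head_node and not edge.head_node.is_leaf() and edge.tail_node:
                side = frozenset(
                    l.taxon.label for l in edge.head_node.leaf_iter()
                )
                if labels[0] in side:
                    side = frozenset(taxa - side)
                if 2 <= len(side) <= len(labels) - 2:
                    theirs.add(side)
        assert mine == theirs

    def test_undefined_distance_rejected(self):
        dm = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(dm, list("abc"))


class TestBootstrap:
    def test_deep_split_gets_high_support(self):
        rng = np.random.default_rng(7)
        core = "".join(rng.choice(list("ACGT"), 200))
        # two clades separated by >= 20 fixed differences
        left = mutate(
            core, [(i, {"A": "G", "G": "A", "C": "T", "T": "C"}[core[i]]) for i in range(25)]
        )

        def jitter(s, k, seed):
            r = np.random.default_rng(seed)
            pos = r.choice(len(s), k, replace=False)
            return mutate(
                s, [(p, {"A": "C", "C": "A", "G": "T", "T": "G"}[s[p]]) for p in pos]
            )

        names = ["l1", "l2", "r1", "r2"]
        seqs = [jitter(left, 3, 1), jitter(left, 3, 2), jitter(core, 3, 3), jitter(core, 3, 4)]
        tree = bootstrap_support(names, seqs, b=500, seed=0)
        split = frozenset({"r1", "r2"})  # normalised away from l1
        assert tree.support[split] >= 99

    def test_identical_sequences_star_tree(self):
        names = list("abcd")
        seqs = ["ACGTACGT" * 5] * 4
        tree = bootstrap_support(names, seqs, b=20, seed=0)
        assert tree.bipartitions() == set()
        assert tree.support == {}

    def test_support_reproducible(self):
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list("ACGT"), 120))
        seqs = []
        for _ in range(5):
            pos = rng.choice(120, 10, replace=False)
            seqs.append(
                mutate(base, [(p, {"A": "C", "C": "A", "G": "T", "T": "G"}[base[p]]) for p in pos])
            )
        names = list("abcde")
        t1 = bootstrap_support(names, seqs, b=50, seed=5)
        t2 = bootstrap_support(names, seqs, b=50, seed=5)
        assert t1.support == t2.support


class TestPDistance:
    def test_basic_and_gap_handling(self):
        assert p_distance("AAAA", "AATA") == 0.25
        assert p_distance("AA-A", "AATA") == 0.0
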