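import random

import numpy as np
import pytest

from oracles import random_additive_tree
from iqdfam.io import IqdfamError, SequenceRecord
from iqdfam.phylogeny import (
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    assign_subfamilies,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
)


def _recs(seqs, names=None):
    names = names or [f"t{i}" for i in range(len(seqs))]
    return [SequenceRecord(n, n, s) for n, s in zip(names, seqs)]


def test_p_distance_examples():
    recs = _recs(["AAAA", "AAAT", "A-CD", "AXCD", "AXCA"])
    dm = p_distance_matrix(recs)
    i = {l: k for k, l in enumerate(dm.labels)}
    assert dm.d[i["t0"], i["t0"]] == 0.0
    assert dm.d[i["t0"], i["t1"]] == pytest.approx(0.25)
    # pairwise deletion: the gapped column drops, 3 comparable columns remain
    assert dm.d[i["t2"], i["t3"]] == pytest.approx(0.0)
    assert dm.d[i["t2"], i["t4"]] == pytest.approx(1 / 3)


def test_p_distance_contracts():
    with pytest.raises(IqdfamError, match="at least 3"):
        p_distance_matrix(_recs(["AA", "AT"]))
    with pytest.raises(IqdfamError, match="no comparable"):
        p_distance_matrix(_recs(["A-", "-A", "AA"]))


def test_three_taxon_closed_form():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], float))
    tree = nj_tree(dm)
    lengths = {c.name: c.branch_length for c in tree.root.children}
    assert lengths == {"A": pytest.approx(0.0), "B": pytest.approx(2.0), "C": pytest.approx(4.0)}


def test_asymmetric_matrix_rejected():
    with pytest.raises(IqdfamError, match="symmetric"):
        DistanceMatrix(["A", "B", "C"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))


def test_nj_recovers_additive_topology_and_total_length():
    rng = random.Random(42)
    for _ in range(50):
        n = rng.randint(6, 10)
        labels, d, true_bips, total = random_additive_tree(rng, n)
        tree = nj_tree(DistanceMatrix(labels, d))
        assert tree.bipartitions() == true_bips
        recovered = _total_length(tree)
        assert recovered == pytest.approx(total, rel=1e-9)


def _total_length(tree: PhyloTree) -> float:
    out = [0.0]
    def walk(node):
        for c in node.children:
            out[0] += c.branch_length
            walk(c)
    walk(tree.root)
    return out[0]


def test_total_length_invariant_to_label_permutation():
    rng = random.Random(7)
    labels, d, _, _ = random_additive_tree(rng, 8)
    tree1 = nj_tree(DistanceMatrix(labels, d))
    perm = rng.sample(range(len(labels)), len(labels))
    d2 = d[np.ix_(perm, perm)]
    tree2 = nj_tree(DistanceMatrix([labels[p] for p in perm], d2))
    assert _total_length(tree1) == pytest.approx(_total_length(tree2))
    assert tree1.bipartitions() == tree2.bipartitions()


def test_bootstrap_duplicated_clades_get_full_support():
    recs = _recs(["AAAA" * 5, "AAAA" * 5, "CCCC" * 5, "CCCC" * 5],
                 ["a1", "a2", "b1", "b2"])
    tree = bootstrap_support(recs, n_replicates=50, seed=1)
    supports = _collect_supports(tree)
    assert supports and all(s == 100.0 for s in supports)


def _collect_supports(tree: PhyloTree):
    out = []
    def walk(node):
        for c in node.children:
            if not c.is_leaf and c.support is not None:
                out.append(c.support)
            walk(c)
    walk(tree.root)
    return out


def test_bootstrap_seed_determinism_and_zero_replicates():
    rng = np.random.default_rng(0)
    seqs = ["".join(rng.choice(list("ACDE"), size=40)) for _ in range(6)]
    recs = _recs(seqs)
    t1 = bootstrap_support(recs, n_replicates=30, seed=9)
    t2 = bootstrap_support(recs, n_replicates=30, seed=9)
    assert t1.newick() == t2.newick()
    t0 = bootstrap_support(recs, n_replicates=0, seed=9)
    assert _collect_supports(t0) == []


def test_newick_roundtrip_via_dendropy():
    import dendropy

    rng = random.Random(2)
    labels, d, bips, _ = random_additive_tree(rng, 7)
    tree = nj_tree(DistanceMatrix(labels, d))
    parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
    assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(labels)


def test_subfamily_assignment_by_anchored_clades():
    # four clusters of similar sequences, one anchor per cluster
    rng = np.random.default_rng(5)
    seqs, names, anchors = [], [], {}
    for ci, base_letter in enumerate("ADKW"):
        base = [base_letter] * 60
        for m in range(3):
            s = list(base)
            for _ in range(4):
                s[rng.integers(0, 60)] = str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY")))
            name = f"c{ci}_m{m}"
            names.append(name)
            seqs.append("".join(s))
            if m == 0:
                anchors[name] = ["I", "II", "III", "IV"][ci]
    recs = _recs(seqs, names)
    tree = nj_tree(p_distance_matrix(recs))
    result = assign_subfamilies(tree, anchors)
    for leaf, sub in result.assignments.items():
        ci = int(leaf[1])
        assert sub == ["I", "II", "III", "IV"][ci]


def test_query_between_two_subfamilies_is_unresolved():
    #       root
    #      /  |  \
    #   q     A1   B1        -> q's smallest anchored clade is the whole tree
    root = TreeNode(children=[
        TreeNode(name="q", branch_length=1.0),
        TreeNode(name="A1", branch_length=1.0),
        TreeNode(name="B1", branch_length=1.0),
    ])
    result = assign_subfamilies(PhyloTree(root), {"A1": "I", "B1": "II"})
    assert result.assignments["q"] is None


def test_query_sister_to_anchor_inherits_subfamily():
    inner = TreeNode(children=[
        TreeNode(name="q", branch_length=1.0),
        TreeNode(name="A1", branch_length=1.0),
    ], branch_length=1.0)
    root = TreeNode(children=[
        inner,
        TreeNode(name="B1", branch_length=1.0),
        TreeNode(name="B2", branch_length=1.0),
    ])
    result = assign_subfamilies(PhyloTree(root), {"A1": "I", "B1": "II", "B2": "II"})
    assert result.assignments["q"] == "I"
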