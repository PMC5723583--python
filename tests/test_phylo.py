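"""Weighted squared-change parsimony / BM ancestral reconstruction."""

import numpy as np
import pytest
from scipy.optimize import minimize

from elevgrad import (
    ElevgradError,
    SpeciesRange,
    TimeTree,
    ancestral_bm,
    node_ranges,
)
from conftest import random_tree_newick


def weighted_ss(tree, states):
    return sum(
        (states[c] - states[p]) ** 2 / bl for p, c, bl in tree.edges()
    )


def numerical_oracle(tree, tip_values):
    """Generic optimizer over internal-node states (independent of the solver)."""
    internal = [n for n in tree.node_ids() if n not in tip_values]

    pos = {n: i for i, n in enumerate(internal)}

    def objective(x):
        states = dict(tip_values)
        states.update(dict(zip(internal, x)))
        return weighted_ss(tree, states)

    def gradient(x):
        states = dict(tip_values)
        states.update(dict(zip(internal, x)))
        g = np.zeros(len(internal))
        for p, c, bl in tree.edges():
            diff = 2 * (states[c] - states[p]) / bl
            if c in pos:
                g[pos[c]] += diff
            if p in pos:
                g[pos[p]] -= diff
        return g

    x0 = np.full(len(internal), np.mean(list(tip_values.values())))
    res = minimize(objective, x0, jac=gradient, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 10_000})
    return dict(zip(internal, res.x))


def gls_root_mean(tree, tip_values):
    """Phylogenetic (GLS) mean via explicit covariance-matrix inversion."""
    tips = tree.tip_labels
    depth = {tree.root.label: 0.0}
    for p, c, bl in tree.edges():
        depth[c] = depth[p] + bl
    # shared path length = depth of MRCA
    C = np.zeros((len(tips), len(tips)))
    import dendropy

    pdm = {}
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            if i == j:
                C[i, j] = depth[a]
            else:
                mrca = tree.mrca({a, b})
                C[i, j] = depth[mrca.label]
    ones = np.ones(len(tips))
    Cinv = np.linalg.inv(C)
    x = np.array([tip_values[t] for t in tips])
    return float(ones @ Cinv @ x / (ones @ Cinv @ ones))


def test_two_tip_symmetry(cherry_tree):
    states = ancestral_bm(cherry_tree, {"A": 0.0, "B": 10.0})
    assert states["N0"] == pytest.approx(5.0)


def test_two_tip_weighted():
    tree = TimeTree.from_newick("(A:1,B:3);")
    states = ancestral_bm(tree, {"A": 0.0, "B": 8.0})
    assert states["N0"] == pytest.approx(2.0)  # argmin x^2/1 + (x-8)^2/3


def test_matches_numerical_minimizer_on_small_trees(rng):
    for _ in range(8):
        n = int(rng.integers(3, 7))
        tree = TimeTree.from_newick(random_tree_newick(rng, n, ultrametric=False))
        tips = {t: float(rng.normal(0, 10)) for t in tree.tip_labels}
        exact = ancestral_bm(tree, tips)
        approx = numerical_oracle(tree, tips)
        for node, v in approx.items():
            assert exact[node] == pytest.approx(v, abs=1e-6)


def test_internal_states_within_tip_hull(rng):
    for _ in range(5):
        tree = TimeTree.from_newick(random_tree_newick(rng, 8))
        tips = {t: float(rng.normal(0, 100)) for t in tree.tip_labels}
        states = ancestral_bm(tree, tips)
        lo, hi = min(tips.values()), max(tips.values())
        for node, v in states.items():
            assert lo - 1e-9 <= v <= hi + 1e-9


def test_root_equals_gls_mean(rng):
    for _ in range(5):
        n = int(rng.integers(3, 9))
        tree = TimeTree.from_newick(random_tree_newick(rng, n, ultrametric=False))
        tips = {t: float(rng.normal(0, 10)) for t in tree.tip_labels}
        states = ancestral_bm(tree, tips)
        assert states[tree.root.label] == pytest.approx(
            gls_root_mean(tree, tips), abs=1e-8
        )


def test_missing_tip_value_and_zero_terminal_branch():
    tree = TimeTree.from_newick("(A:1,B:1);")
    with pytest.raises(ElevgradError, match="missing"):
        ancestral_bm(tree, {"A": 1.0})
    tree0 = TimeTree.from_newick("(A:0,B:1);")
    with pytest.raises(ElevgradError, match="terminal"):
        ancestral_bm(tree0, {"A": 1.0, "B": 2.0})


def test_zero_internal_branch_collapsed():
    tree = TimeTree.from_newick("((A:1,B:1):0,C:1);")
    states = ancestral_bm(tree, {"A": 0.0, "B": 0.0, "C": 3.0})
    # collapse -> star tree with equal branches: root is the plain mean
    assert states[tree.root.label] == pytest.approx(1.0)


def test_node_ranges_constant_trait(cherry_tree):
    ranges = [SpeciesRange("A", 1000, 1400), SpeciesRange("B", 1000, 1400)]
    out = node_ranges(cherry_tree, ranges)
    root = out[cherry_tree.root.label]
    assert (root.lo, root.hi) == (1000, 1400)


def test_node_ranges_symmetric_means(cherry_tree):
    ranges = [SpeciesRange("A", 700, 900), SpeciesRange("B", 900, 1500)]
    root = node_ranges(cherry_tree, ranges)[cherry_tree.root.label]
    assert root.midpoint == pytest.approx(1000)
    assert root.size == pytest.approx(400)
    assert (root.lo, root.hi) == (pytest.approx(800), pytest.approx(1200))


def test_node_ranges_tips_reproduce_inputs(rng):
    tree = TimeTree.from_newick(random_tree_newick(rng, 6))
    ranges = [
        SpeciesRange(t, lo, lo + rng.uniform(0, 500))
        for t, lo in ((t, rng.uniform(600, 3800)) for t in tree.tip_labels)
    ]
    out = node_ranges(tree, ranges)
    for r in ranges:
        assert out[r.species].midpoint == pytest.approx(r.midpoint)
        assert out[r.species].size == pytest.approx(r.size)
        assert out[r.species].age == pytest.approx(0.0, abs=1e-6)


def test_node_ranges_species_mismatch(cherry_tree):
    with pytest.raises(ElevgradError, match="mismatch"):
        node_ranges(cherry_tree, [SpeciesRange("A", 1, 2), SpeciesRange("C", 1, 2)])
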