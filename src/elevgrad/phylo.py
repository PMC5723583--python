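"""Ancestral reconstruction of elevational midpoints and range sizes.

Internal-node states are the weighted squared-change parsimony estimates,
i.e. the values minimising

    sum over edges of (x_child - x_parent)^2 / branch_length

with tips pinned at their observed values.  These are also the joint
maximum-likelihood ancestral states under Brownian motion, and are obtained
exactly by solving one sparse linear system over the internal nodes.

Midpoint and range size are reconstructed as two independent univariate
traits (optionally log-size); reconstructed sizes are clamped at zero and
the implied interval ``[midpoint - size/2, midpoint + size/2]`` attached to
every node together with its age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import ElevgradError, SpeciesRange, TimeTree


@dataclass(frozen=True)
class NodeElevRange:
    """Reconstructed elevational interval and age at one tree node."""

    node: str
    midpoint: float
    size: float
    age: float

    def __post_init__(self):
        if self.size < 0:
            raise ElevgradError(f"node {self.node}: negative size {self.size}")

    @property
    def lo(self) -> float:
        return self.midpoint - self.size / 2.0

    @property
    def hi(self) -> float:
        return self.midpoint + self.size / 2.0


def _collapse_zero_branches(tree: TimeTree) -> list[tuple[str, str, float]]:
    """Edge list with zero-length internal edges collapsed into polytomies.

    Returns (parent, child, length) triples over a reduced node set in which
    every internal node keeps a strictly positive path to its parent.  A
    zero-length *terminal* branch cannot be collapsed (the tip value would
    pin its parent) and is an error.
    """
    # map each node to its surviving representative
    rep: dict[str, str] = {}
    tip_set = set(tree.tip_labels)
    edges = []
    for parent, child, bl in tree.edges():
        p = rep.get(parent, parent)
        if bl == 0.0:
            if child in tip_set:
                raise ElevgradError(
                    f"zero-length terminal branch at tip {child!r}"
                )
            rep[child] = p
            continue
        edges.append((p, child, bl))
    return edges


def ancestral_bm(tree: TimeTree, tip_values: dict[str, float]) -> dict[str, float]:
    """ML Brownian-motion ancestral states for one continuous trait.

    Solves the first-order conditions of the weighted squared-change
    criterion: at each internal node the state is the branch-length-weighted
    harmonic average of its neighbours' states.  Collapsed (zero-length)
    internal nodes inherit their representative's state.
    """
    tips = set(tree.tip_labels)
    missing = tips - set(tip_values)
    if missing:
        raise ElevgradError(f"missing tip values: {sorted(missing)}")

    edges = _collapse_zero_branches(tree)
    internal = sorted({p for p, _, _ in edges} | {c for _, c, _ in edges if c not in tips}
                      - tips)
    if not internal:
        # single tip or fully collapsed tree
        root = tree.root.label
        vals = dict(tip_values)
        if root not in vals:
            vals[root] = float(np.mean(list(tip_values.values())))
        return vals
    pos = {n: i for i, n in enumerate(internal)}
    k = len(internal)
    A = np.zeros((k, k))
    rhs = np.zeros(k)
    for p, c, bl in edges:
        w = 1.0 / bl
        pi = pos.get(p)
        if c in tips:
            A[pi, pi] += w
            rhs[pi] += w * tip_values[c]
        else:
            ci = pos[c]
            A[pi, pi] += w
            A[ci, ci] += w
            A[pi, ci] -= w
            A[ci, pi] -= w
    sol = np.linalg.solve(A, rhs)

    states = {t: float(tip_values[t]) for t in tips}
    states.update({n: float(sol[pos[n]]) for n in internal})
    # collapsed nodes take their representative's state
    rep: dict[str, str] = {}
    for parent, child, bl in tree.edges():
        if bl == 0.0 and child not in tips:
            rep[child] = rep.get(parent, parent)
    for node, r in rep.items():
        while r in rep:
            r = rep[r]
        states[node] = states[r]
    return states


def node_ranges(
    tree: TimeTree,
    tip_ranges: list[SpeciesRange],
    log_size: bool = False,
) -> dict[str, NodeElevRange]:
    """Reconstruct midpoint and size at every node and attach ages.

    ``log_size=True`` reconstructs log(size) instead (useful when sizes span
    orders of magnitude); zero-size tips force the linear scale.
    """
    tip_set = set(tree.tip_labels)
    range_set = {r.species for r in tip_ranges}
    if tip_set != range_set:
        raise ElevgradError(
            f"tree/range species mismatch: only in tree {sorted(tip_set - range_set)}, "
            f"only in ranges {sorted(range_set - tip_set)}"
        )
    mids = {r.species: r.midpoint for r in tip_ranges}
    sizes = {r.species: r.size for r in tip_ranges}

    mid_states = ancestral_bm(tree, mids)
    if log_size:
        if any(s <= 0 for s in sizes.values()):
            raise ElevgradError("log_size requires strictly positive tip sizes")
        log_states = ancestral_bm(tree, {k: math.log(v) for k, v in sizes.items()})
        size_states = {k: math.exp(v) for k, v in log_states.items()}
    else:
        size_states = ancestral_bm(tree, sizes)

    out = {}
    for node in tree.node_ids():
        size = max(size_states[node], 0.0)
        if node in tip_set:
            # tips reproduce their input exactly
            size = sizes[node]
        out[node] = NodeElevRange(
            node=node,
            midpoint=mid_states[node],
            size=size,
            age=tree.ages[node],
        )
    return out
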