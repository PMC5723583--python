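"""CRRL colonization events: closed-form entry times vs a lattice oracle."""

import numpy as np
import pytest

from elevgrad import (
    SpeciesRange,
    TimeTree,
    colonization_summary,
    edge_colonizations,
    interpolate_richness,
    make_grid,
    node_ranges,
)
from elevgrad.colonization import ColonizationEvent
from elevgrad.phylo import NodeElevRange
from conftest import random_tree_newick


def lattice_oracle(tree, nodes, grid, n_steps=10_000):
    """Brute-force fine-time scan of band entries along each edge."""
    events = []
    root = tree.root.label
    r = nodes[root]
    for b, (a, bb) in enumerate(grid.bands):
        if r.lo < bb and r.hi > a:
            events.append((b, "root", r.age))
    for parent, child, _bl in tree.edges():
        p, c = nodes[parent], nodes[child]
        for b, (a, bb) in enumerate(grid.bands):
            if p.lo < bb and p.hi > a:
                continue
            for k in range(1, n_steps + 1):
                s = k / n_steps
                lo = p.lo + s * (c.lo - p.lo)
                hi = p.hi + s * (c.hi - p.hi)
                if lo < bb and hi > a:
                    events.append((b, f"{parent}->{child}",
                                   p.age - s * (p.age - c.age)))
                    break
    return events


def test_root_seeding_single_lineage(grid600):
    tree = TimeTree.from_newick("(A:10,B:10);")
    nodes = {
        "N0": NodeElevRange("N0", midpoint=1200, size=400, age=10),
        "A": NodeElevRange("A", midpoint=1200, size=400, age=0),
        "B": NodeElevRange("B", midpoint=1200, size=400, age=0),
    }
    events = edge_colonizations(tree, nodes, grid600)
    root_events = [e for e in events if e.edge == "root"]
    assert sorted(e.band for e in root_events) == [2, 3]  # [1000,1200), [1200,1400)
    assert all(e.age == 10 for e in root_events)
    # children never leave the root interval: no edge events
    assert len(events) == 2


def test_linear_entry_time_hand_example(grid600):
    """Root [1000,1400] at age 10; tip [600,1000]: band [600,800) entered at 5.0."""
    tree = TimeTree.from_newick("(A:10,B:10);")
    nodes = {
        "N0": NodeElevRange("N0", midpoint=1200, size=400, age=10),
        "A": NodeElevRange("A", midpoint=800, size=400, age=0),
        "B": NodeElevRange("B", midpoint=1200, size=400, age=0),
    }
    events = edge_colonizations(tree, nodes, grid600)
    band0 = [e for e in events if e.band == 0]
    assert len(band0) == 1
    assert band0[0].age == pytest.approx(5.0)
    assert band0[0].edge == "N0->A"


def test_event_age_modes(grid600):
    tree = TimeTree.from_newick("(A:10,B:10);")
    nodes = {
        "N0": NodeElevRange("N0", midpoint=1200, size=400, age=10),
        "A": NodeElevRange("A", midpoint=800, size=400, age=0),
        "B": NodeElevRange("B", midpoint=1200, size=400, age=0),
    }
    child = edge_colonizations(tree, nodes, grid600, event_age="child")
    parent = edge_colonizations(tree, nodes, grid600, event_age="parent")
    a_child = [e for e in child if e.band == 0][0]
    a_parent = [e for e in parent if e.band == 0][0]
    assert a_child.age == 0.0
    assert a_parent.age == 10.0


def test_events_match_lattice_oracle_on_random_trees(rng):
    grid = make_grid(0, 3000, 250)
    for _ in range(6):
        n = int(rng.integers(3, 7))
        tree = TimeTree.from_newick(random_tree_newick(rng, n))
        ranges = [
            SpeciesRange(t, lo, lo + rng.uniform(100, 1200))
            for t, lo in ((t, rng.uniform(0, 1700)) for t in tree.tip_labels)
        ]
        nodes = node_ranges(tree, ranges)
        got = edge_colonizations(tree, nodes, grid)
        want = lattice_oracle(tree, nodes, grid)
        assert len(got) == len(want)
        got_s = sorted((e.band, e.edge, e.age) for e in got)
        want_s = sorted(want)
        for (gb, ge, ga), (wb, we, wa) in zip(got_s, want_s):
            assert (gb, ge) == (wb, we)
            assert ga == pytest.approx(wa, abs=1e-3 * tree.root_age)


def test_no_duplicate_edge_band_events(rng):
    grid = make_grid(0, 3000, 300)
    tree = TimeTree.from_newick(random_tree_newick(rng, 6))
    ranges = [
        SpeciesRange(t, lo, lo + rng.uniform(100, 900))
        for t, lo in ((t, rng.uniform(0, 2000)) for t in tree.tip_labels)
    ]
    events = edge_colonizations(tree, node_ranges(tree, ranges), grid)
    keys = [(e.edge, e.band) for e in events]
    assert len(keys) == len(set(keys))


def test_occupied_bands_have_events(rng):
    """Every band holding an extant species was colonized at some point."""
    grid = make_grid(0, 3000, 300)
    for _ in range(4):
        tree = TimeTree.from_newick(random_tree_newick(rng, 5))
        ranges = [
            SpeciesRange(t, lo, lo + rng.uniform(150, 900))
            for t, lo in ((t, rng.uniform(0, 2000)) for t in tree.tip_labels)
        ]
        events = edge_colonizations(tree, node_ranges(tree, ranges), grid)
        summary = colonization_summary(events, grid)
        richness = interpolate_richness(ranges, grid)
        assert (summary.frequency[richness.counts > 0] >= 1).all()


def test_summary_arithmetic(grid600):
    events = [
        ColonizationEvent(band=3, edge="root", age=10.0),
        ColonizationEvent(band=3, edge="N0->A", age=4.0),
    ]
    s = colonization_summary(events, grid600)
    assert s.frequency[3] == 2
    assert s.oldest_age[3] == 10.0
    assert s.summed_age[3] == 14.0
    assert s.average_age[3] == 7.0
    # untouched band
    assert s.frequency[5] == 0
    assert np.isnan(s.oldest_age[5]) and np.isnan(s.average_age[5])
    assert s.summed_age[5] == 0.0


def test_sac_bounds(rng):
    grid = make_grid(0, 3000, 300)
    tree = TimeTree.from_newick(random_tree_newick(rng, 6))
    ranges = [
        SpeciesRange(t, lo, lo + rng.uniform(150, 900))
        for t, lo in ((t, rng.uniform(0, 2000)) for t in tree.tip_labels)
    ]
    s = colonization_summary(
        edge_colonizations(tree, node_ranges(tree, ranges), grid), grid
    )
    occupied = s.frequency >= 1
    assert (s.summed_age[occupied] >= s.oldest_age[occupied] - 1e-12).all()
    single = s.frequency == 1
    assert np.allclose(s.summed_age[single], s.oldest_age[single])
    assert (s.oldest_age[occupied] <= tree.root_age + 1e-9).all()
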