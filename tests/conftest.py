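import numpy as np
import pytest

from elevgrad import TimeTree, make_grid, synthetic_loach_ranges


@pytest.fixture
def grid600():
    """The 19-band, 200-m grid on the 600-4,300 m domain."""
    return make_grid(600, 4300, 200)


@pytest.fixture
def standin_ranges():
    """Deterministic 19-species synthetic range table."""
    return synthetic_loach_ranges()


@pytest.fixture
def cherry_tree():
    return TimeTree.from_newick("(A:1,B:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_tree_newick(rng, n_tips: int, ultrametric: bool = True) -> str:
    """Random rooted binary tree via recursive splitting (test helper).

    Ultrametric trees are built by assigning each internal node an age
    strictly below its parent's; tips sit at age 0.
    """
    labels = [f"t{i}" for i in range(n_tips)]

    def build_ultra(names, age):
        if len(names) == 1:
            return names[0], 0.0
        k = int(rng.integers(1, len(names)))
        parts = []
        for sub in (names[:k], names[k:]):
            child_age = float(rng.uniform(0.1, 0.9)) * age if len(sub) > 1 else 0.0
            nwk, child_age = build_ultra(sub, child_age)
            parts.append(f"{nwk}:{age - child_age:.6f}")
        return f"({parts[0]},{parts[1]})", age

    def build_free(names):
        if len(names) == 1:
            return f"{names[0]}:{rng.uniform(0.1, 2.0):.6f}"
        k = int(rng.integers(1, len(names)))
        return (f"({build_free(names[:k])},{build_free(names[k:])})"
                f":{rng.uniform(0.1, 2.0):.6f}")

    if ultrametric:
        nwk, _ = build_ultra(labels, float(rng.uniform(5.0, 15.0)))
        return nwk + ";"
    k = max(1, n_tips // 2)
    return f"({build_free(labels[:k])},{build_free(labels[k:])});"
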