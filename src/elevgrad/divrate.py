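"""Method-of-moments net diversification rates per clade.

The classical closed-form estimators give the net diversification rate
(speciation minus extinction, lineages/Myr) of a clade from its extant
species count and its stem or crown age, under an assumed relative
extinction fraction epsilon = mu/lambda:

    stem:  r = ln(n (1 - eps) + eps) / t
    crown: r = [ ln( n (1 - eps^2)/2 + 2 eps
                     + (1 - eps)/2 * sqrt( n (n eps^2 - 8 eps + 2 n eps + n) ) )
                 - ln 2 ] / t

At eps = 0 these reduce exactly to ln(n)/t and (ln n - ln 2)/t.  Because
the true extinction fraction is unknowable from extant taxa alone, rates
are conventionally reported at several epsilons (0, 0.45 and 0.9 by
default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import ElevgradError, SpeciesRange, TimeTree
from .phylo import NodeElevRange

DEFAULT_EPSILONS = (0.0, 0.45, 0.9)


def ms_rate(n: int, t: float, epsilon: float, mode: str) -> float:
    """Method-of-moments net diversification rate for one clade.

    ``mode`` is "stem" (n >= 1, t the stem age) or "crown" (n >= 2, t the
    crown age).
    """
    if mode not in ("stem", "crown"):
        raise ElevgradError(f"mode must be 'stem' or 'crown', got {mode!r}")
    if t <= 0:
        raise ElevgradError(f"clade age must be positive, got {t}")
    if not (0 <= epsilon < 1):
        raise ElevgradError(f"epsilon must be in [0, 1), got {epsilon}")
    if n < (1 if mode == "stem" else 2):
        raise ElevgradError(f"{mode} estimator needs n >= {1 if mode == 'stem' else 2}")
    if mode == "stem":
        return math.log(n * (1 - epsilon) + epsilon) / t
    inner = n * (n * epsilon**2 - 8 * epsilon + 2 * n * epsilon + n)
    arg = (
        n * (1 - epsilon**2) / 2.0
        + 2.0 * epsilon
        + (1 - epsilon) / 2.0 * math.sqrt(inner)
    )
    return (math.log(arg) - math.log(2.0)) / t


@dataclass(frozen=True)
class CladeRateRow:
    """Diversification rates and elevation summaries for one clade."""

    clade: str
    n: int
    t_stem: float | None
    t_crown: float | None
    rates_stem: dict[float, float | None]   # epsilon -> rate (None if no stem age)
    rates_crown: dict[float, float | None]  # epsilon -> rate (None if n < 2)
    mean_elevation: float
    ancestral_elevation: float


def default_clades(tree: TimeTree, min_size: int = 2) -> dict[str, set[str]]:
    """All internal-node subtrees with >= ``min_size`` tips, for exploration."""
    out = {}
    for node in tree.tree.preorder_internal_node_iter():
        tips = tree.leaf_labels_under(node)
        if len(tips) >= min_size:
            out[node.label] = tips
    return out


def clade_rate_table(
    tree: TimeTree,
    clades: dict[str, set[str]],
    ranges: list[SpeciesRange],
    nodes: dict[str, NodeElevRange],
    epsilons=DEFAULT_EPSILONS,
) -> list[CladeRateRow]:
    """Per-clade rates at each epsilon plus mean and ancestral elevations.

    Each clade must be a monophyletic tip set; its crown age is the MRCA
    age and its stem age the MRCA's parent age (absent for the root clade).
    Mean elevation averages the tip range midpoints; ancestral elevation is
    the reconstructed midpoint at the MRCA.
    """
    mids = {r.species: r.midpoint for r in ranges}
    rows = []
    for name, tips in clades.items():
        tips = set(tips)
        if len(tips) == 1:
            # a single tip: its own node is the "MRCA"
            mrca_label = next(iter(tips))
            mrca = None
            for lf in tree.tree.leaf_node_iter():
                if lf.taxon.label == mrca_label:
                    mrca = lf
                    break
            if mrca is None:
                raise ElevgradError(f"clade {name!r}: tip not in tree: {mrca_label}")
        else:
            mrca = tree.mrca(tips)
            under = tree.leaf_labels_under(mrca)
            if under != tips:
                raise ElevgradError(
                    f"clade {name!r} is not monophyletic; intruding tips: "
                    f"{sorted(under - tips)}"
                )
        n = len(tips)
        t_crown = tree.ages[mrca.label] if n >= 2 else None
        t_stem = (
            tree.ages[mrca.parent_node.label] if mrca.parent_node is not None else None
        )
        rates_stem = {
            float(e): (ms_rate(n, t_stem, e, "stem") if t_stem and t_stem > 0 else None)
            for e in epsilons
        }
        rates_crown = {
            float(e): (
                ms_rate(n, t_crown, e, "crown") if n >= 2 and t_crown and t_crown > 0
                else None
            )
            for e in epsilons
        }
        missing_mid = tips - set(mids)
        if missing_mid:
            raise ElevgradError(f"clade {name!r}: no range for {sorted(missing_mid)}")
        rows.append(
            CladeRateRow(
                clade=name,
                n=n,
                t_stem=t_stem,
                t_crown=t_crown,
                rates_stem=rates_stem,
                rates_crown=rates_crown,
                mean_elevation=float(np.mean([mids[t] for t in tips])),
                ancestral_elevation=nodes[mrca.label].midpoint,
            )
        )
    return rows
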