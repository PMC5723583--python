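"""Domain types, elevational band grid, and readers/writers.

Everything downstream consumes the types defined here: the half-open band
decomposition of a bounded elevational domain (:class:`ElevationGrid`), a
species' interpolated elevational interval (:class:`SpeciesRange`), survey
occurrence records, the per-band climate/area covariate table, and a
time-calibrated tree (:class:`TimeTree`, a thin wrapper over dendropy).

Conventions
-----------
* Bands are half-open ``[lo, hi)`` in metres.  The final band is extended up
  to the next multiple of the band width, so a 600-4,300 m domain cut at
  200 m yields 19 bands ending with ``[4200, 4400)``.
* Species intervals are closed ``[lo, hi]``.  A species overlaps a band iff
  ``lo < band_hi and hi > band_lo`` (strict, so touching a boundary does not
  count), except a point range (``lo == hi``) which occupies exactly the
  band containing the point under the half-open rule.
* Node age = (maximum root-to-tip depth) - (node depth); the present is
  age 0.  A tree is flagged ultrametric when all root-to-tip path lengths
  agree to relative tolerance 1e-6.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("elevgrad")

#: Relative tolerance used when testing whether a tree is ultrametric.
ULTRAMETRIC_RTOL = 1e-6

#: Climate covariate columns expected in a per-band climate table.
CLIMATE_COLUMNS = ("MAT", "MDR", "TS", "AP", "PS", "PDQ")
#: Area columns (river basin area and total drainage area, km^2).
AREA_COLUMNS = ("area_river", "area_total")


class ElevgradError(ValueError):
    """Base class for invalid inputs to this package."""


# ---------------------------------------------------------------------------
# Elevation grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElevationGrid:
    """A contiguous half-open band decomposition of an elevational domain.

    ``n_bands = ceil((domain_hi - domain_lo) / band_width)``; the last band
    may extend beyond ``domain_hi`` to the next band boundary (``grid_hi``).
    """

    domain_lo: float
    domain_hi: float
    band_width: float

    @property
    def n_bands(self) -> int:
        return math.ceil((self.domain_hi - self.domain_lo) / self.band_width)

    @property
    def grid_hi(self) -> float:
        """Upper edge of the last band (>= domain_hi)."""
        return self.domain_lo + self.n_bands * self.band_width

    @property
    def band_edges(self) -> np.ndarray:
        """Array of n_bands+1 edges."""
        return self.domain_lo + self.band_width * np.arange(self.n_bands + 1)

    @property
    def bands(self) -> list[tuple[float, float]]:
        e = self.band_edges
        return [(float(e[i]), float(e[i + 1])) for i in range(self.n_bands)]

    @property
    def band_midpoints(self) -> np.ndarray:
        e = self.band_edges
        return (e[:-1] + e[1:]) / 2.0

    def band_index(self, elevation: float) -> int:
        """Index of the band containing ``elevation`` (half-open rule).

        Raises :class:`ElevgradError` for elevations outside
        ``[domain_lo, grid_hi)``.
        """
        if not (self.domain_lo <= elevation < self.grid_hi):
            raise ElevgradError(
                f"elevation {elevation} outside grid [{self.domain_lo}, {self.grid_hi})"
            )
        idx = int((elevation - self.domain_lo) // self.band_width)
        idx = min(max(idx, 0), self.n_bands - 1)
        # floor division and the edge array can round differently; settle
        # against the edges actually used everywhere else
        edges = self.band_edges
        if elevation < edges[idx] and idx > 0:
            idx -= 1
        elif elevation >= edges[idx + 1] and idx < self.n_bands - 1:
            idx += 1
        return idx


def make_grid(domain_lo: float, domain_hi: float, band_width: float) -> ElevationGrid:
    """Build the band grid for a bounded elevational domain.

    >>> g = make_grid(600, 4300, 200)
    >>> g.n_bands, g.bands[0], g.bands[-1]
    (19, (600.0, 800.0), (4200.0, 4400.0))
    """
    if band_width <= 0:
        raise ElevgradError(f"band_width must be positive, got {band_width}")
    if domain_lo >= domain_hi:
        raise ElevgradError(
            f"domain_lo ({domain_lo}) must be below domain_hi ({domain_hi})"
        )
    return ElevationGrid(float(domain_lo), float(domain_hi), float(band_width))


def range_overlaps_band(lo: float, hi: float, band_lo: float, band_hi: float) -> bool:
    """Overlap rule between a closed species interval and a half-open band.

    Strict overlap (boundary touches do not count), except that a point
    range sits in exactly the band containing it.
    """
    if lo == hi:
        return band_lo <= lo < band_hi
    return lo < band_hi and hi > band_lo


def overlap_matrix(los: np.ndarray, his: np.ndarray, grid: ElevationGrid) -> np.ndarray:
    """Boolean (n_species, n_bands) occupancy matrix under the overlap rule.

    Vectorised workhorse shared by the richness, MDE and Rapoport layers.
    """
    los = np.asarray(los, dtype=float)[:, None]
    his = np.asarray(his, dtype=float)[:, None]
    edges = grid.band_edges
    b_lo, b_hi = edges[None, :-1], edges[None, 1:]
    strict = (los < b_hi) & (his > b_lo)
    point = (b_lo <= los) & (los < b_hi)
    return np.where(los == his, point, strict)


# ---------------------------------------------------------------------------
# Species ranges and occurrence records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesRange:
    """One species' elevational interval ``[lo, hi]`` in metres."""

    species: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ElevgradError(f"{self.species}: non-finite range limits")
        if self.lo > self.hi:
            raise ElevgradError(
                f"{self.species}: min elevation {self.lo} exceeds max {self.hi}"
            )

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0

    @property
    def size(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single survey detection of a species at an elevation."""

    species: str
    elevation: float
    site: str = ""

    def __post_init__(self):
        if not math.isfinite(self.elevation):
            raise ElevgradError(f"{self.species}: non-finite record elevation")


def read_species_ranges(path) -> list[SpeciesRange]:
    """Read a ``species,min_elev,max_elev`` CSV into SpeciesRange objects."""
    df = pd.read_csv(path)
    required = {"species", "min_elev", "max_elev"}
    missing = required - set(df.columns)
    if missing:
        raise ElevgradError(f"ranges file missing columns: {sorted(missing)}")
    dup = df["species"][df["species"].duplicated()]
    if not dup.empty:
        raise ElevgradError(f"duplicate species in ranges file: {sorted(set(dup))}")
    return [
        SpeciesRange(str(r.species), float(r.min_elev), float(r.max_elev))
        for r in df.itertuples()
    ]


def write_species_ranges(ranges: list[SpeciesRange], path) -> None:
    pd.DataFrame(
        {
            "species": [r.species for r in ranges],
            "min_elev": [r.lo for r in ranges],
            "max_elev": [r.hi for r in ranges],
        }
    ).to_csv(path, index=False)


def read_occurrences(path) -> list[OccurrenceRecord]:
    """Read a ``species,elevation[,site]`` CSV of survey records."""
    df = pd.read_csv(path)
    required = {"species", "elevation"}
    missing = required - set(df.columns)
    if missing:
        raise ElevgradError(f"occurrence file missing columns: {sorted(missing)}")
    sites = df["site"] if "site" in df.columns else [""] * len(df)
    return [
        OccurrenceRecord(str(s), float(e), str(t))
        for s, e, t in zip(df["species"], df["elevation"], sites)
    ]


def write_occurrences(records: list[OccurrenceRecord], path) -> None:
    pd.DataFrame(
        {
            "species": [r.species for r in records],
            "elevation": [r.elevation for r in records],
            "site": [r.site for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Climate table
# ---------------------------------------------------------------------------

def read_band_climate(path, grid: ElevationGrid) -> pd.DataFrame:
    """Read and validate a per-band climate/area covariate table.

    The file must contain one row per grid band, keyed by a ``band`` index
    column (0-based) or a ``band_lo`` lower-edge column.  Unknown covariate
    columns are kept but logged as a warning; missing bands are an error.

    TS and PS are passed through in whatever unit dialect the source used
    (WorldClim stores TS as SD x 100 and PS as CV %); all downstream
    regressions standardize predictors, so the analyses are scale-invariant.
    """
    df = pd.read_csv(path)
    if "band" in df.columns:
        idx = df["band"].astype(int).to_numpy()
    elif "band_lo" in df.columns:
        idx = np.array([grid.band_index(float(b)) for b in df["band_lo"]])
    else:
        raise ElevgradError("climate file needs a 'band' or 'band_lo' key column")
    present = set(idx.tolist())
    missing = [b for b in range(grid.n_bands) if b not in present]
    if missing:
        raise ElevgradError(f"climate file missing band rows: {missing}")
    known = set(CLIMATE_COLUMNS) | set(AREA_COLUMNS) | {"band", "band_lo"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("climate file: ignoring unknown columns %s", unknown)
    out = df.assign(band=idx).set_index("band").sort_index()
    out = out[[c for c in out.columns if c in known and c != "band_lo"]]
    return out


def write_band_climate(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True, index_label="band")


# ---------------------------------------------------------------------------
# Time tree
# ---------------------------------------------------------------------------

@dataclass
class TimeTree:
    """A rooted time-calibrated tree with node ages.

    Wraps a dendropy tree.  Internal nodes are labelled ``N0, N1, ...`` in
    preorder (the root is ``N0``); leaves are identified by their taxon
    label.  ``ages`` maps node id -> time before present (Myr), where the
    deepest tip sits at age 0.
    """

    tree: dendropy.Tree
    ages: dict[str, float] = field(default_factory=dict)
    is_ultrametric: bool = False

    # -- construction -------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TimeTree":
        tree.is_rooted = True
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(tips) != len(set(tips)):
            seen, dups = set(), set()
            for t in tips:
                (dups if t in seen else seen).add(t)
            raise ElevgradError(f"duplicate tip labels: {sorted(dups)}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ElevgradError(f"negative branch length {edge.length}")
        # stable internal ids in preorder
        i = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                node.label = node.taxon.label
            else:
                node.label = f"N{i}"
                i += 1
        # depths and ages
        depth: dict[str, float] = {}
        for node in tree.preorder_node_iter():
            bl = node.edge.length or 0.0
            depth[node.label] = (depth[node.parent_node.label] + bl
                                 if node.parent_node else 0.0)
        max_depth = max(depth[lf.label] for lf in tree.leaf_node_iter())
        ages = {k: max_depth - d for k, d in depth.items()}
        tip_depths = [depth[lf.label] for lf in tree.leaf_node_iter()]
        scale = max(max_depth, 1.0)
        ultra = (max(tip_depths) - min(tip_depths)) <= ULTRAMETRIC_RTOL * scale
        return cls(tree=tree, ages=ages, is_ultrametric=ultra)

    @classmethod
    def from_newick(cls, source: str) -> "TimeTree":
        tree = dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree)

    # -- queries -------------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def root_age(self) -> float:
        return self.ages[self.root.label]

    def node_ids(self) -> list[str]:
        return [n.label for n in self.tree.preorder_node_iter()]

    def edges(self):
        """Yield (parent_label, child_label, branch_length) for every edge."""
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                yield node.parent_node.label, node.label, float(node.edge.length or 0.0)

    def mrca(self, tips: set[str]) -> dendropy.Node:
        taxa = [self.tree.taxon_namespace.get_taxon(t) for t in tips]
        if any(t is None for t in taxa):
            missing = [lbl for lbl, t in zip(tips, taxa) if t is None]
            raise ElevgradError(f"tips not in tree: {sorted(missing)}")
        return self.tree.mrca(taxa=taxa)

    def leaf_labels_under(self, node: dendropy.Node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_tree(path) -> TimeTree:
    """Read a rooted Newick tree with branch lengths in time units."""
    if hasattr(path, "read"):
        return TimeTree.from_newick(path.read())
    with open(path) as fh:
        return TimeTree.from_newick(fh.read())


def write_tree(tree: TimeTree, path) -> None:
    out = tree.as_newick() + "\n"
    if hasattr(path, "write"):
        path.write(out)
    else:
        with open(path, "w") as fh:
            fh.write(out)
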