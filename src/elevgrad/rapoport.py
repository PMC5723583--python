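"""Rapoport's-rule statistics for elevational ranges.

Two classical views of how range size varies with elevation:

* Stevens' method — the mean range size of the species co-occurring in each
  band, plotted against the band midpoint (bands share species, so points
  are not independent).
* the cross-species method — one (midpoint, range size) point per species.

Trend tests (OLS of the profiles on elevation) live in the stats module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ElevationGrid, SpeciesRange, overlap_matrix


@dataclass(frozen=True)
class StevensProfile:
    """Band-mean range size of co-occurring species (NaN where empty)."""

    grid: ElevationGrid
    band_midpoint: np.ndarray
    mean_range_size: np.ndarray  # NaN when no species occupies the band
    species_count: np.ndarray  # equals interpolated richness per band


def stevens_profile(ranges: list[SpeciesRange], grid: ElevationGrid) -> StevensProfile:
    """Mean range size per band over the species overlapping it."""
    mids = grid.band_midpoints
    if not ranges:
        return StevensProfile(
            grid, mids, np.full(grid.n_bands, np.nan), np.zeros(grid.n_bands, int)
        )
    occ = overlap_matrix(
        np.array([r.lo for r in ranges]),
        np.array([r.hi for r in ranges]),
        grid,
    )
    sizes = np.array([r.size for r in ranges], dtype=float)
    count = occ.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, (occ * sizes[:, None]).sum(axis=0)
                        / np.maximum(count, 1), np.nan)
    return StevensProfile(grid, mids, mean, count.astype(int))


def cross_species_table(ranges: list[SpeciesRange]) -> list[tuple[float, float]]:
    """One (midpoint, range size) pair per species, in input order."""
    return [(r.midpoint, r.size) for r in ranges]
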