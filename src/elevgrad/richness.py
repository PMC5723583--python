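"""Species richness per elevational band (interpolated and observed).

Interpolated richness assumes each species occupies every band between its
lowest and highest recorded elevations (range-through richness); observed
richness counts distinct species actually detected in each band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import (
    ElevationGrid,
    ElevgradError,
    OccurrenceRecord,
    SpeciesRange,
    overlap_matrix,
)

logger = logging.getLogger("elevgrad")


@dataclass(frozen=True)
class RichnessProfile:
    """Per-band species counts on a grid; ``method`` is how they were made."""

    grid: ElevationGrid
    counts: np.ndarray  # int, length n_bands
    method: str  # "interpolated" | "observed"

    def __post_init__(self):
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        if len(self.counts) != self.grid.n_bands:
            raise ElevgradError("counts length does not match grid")
        if (self.counts < 0).any():
            raise ElevgradError("negative band count")


def interpolate_richness(
    ranges: list[SpeciesRange], grid: ElevationGrid
) -> RichnessProfile:
    """Count, per band, the species whose interpolated interval overlaps it."""
    outside = [
        r.species
        for r in ranges
        if r.lo < grid.domain_lo or r.hi > grid.grid_hi
    ]
    if outside:
        raise ElevgradError(f"ranges outside grid domain: {outside}")
    if not ranges:
        return RichnessProfile(grid, np.zeros(grid.n_bands, dtype=int), "interpolated")
    occ = overlap_matrix(
        np.array([r.lo for r in ranges]),
        np.array([r.hi for r in ranges]),
        grid,
    )
    return RichnessProfile(grid, occ.sum(axis=0), "interpolated")


def observed_richness(
    records: list[OccurrenceRecord], grid: ElevationGrid
) -> RichnessProfile:
    """Count, per band, the distinct species with >=1 record in the band.

    Records outside the grid are dropped with a logged warning.
    """
    per_band: list[set] = [set() for _ in range(grid.n_bands)]
    dropped = 0
    for rec in records:
        if not (grid.domain_lo <= rec.elevation < grid.grid_hi):
            dropped += 1
            continue
        per_band[grid.band_index(rec.elevation)].add(rec.species)
    if dropped:
        logger.warning("observed_richness: dropped %d out-of-grid records", dropped)
    counts = np.array([len(s) for s in per_band], dtype=int)
    return RichnessProfile(grid, counts, "observed")


def range_from_records(records: list[OccurrenceRecord]) -> list[SpeciesRange]:
    """Interpolate each species' range as [min, max] over its records."""
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    order: list[str] = []
    for rec in records:
        if rec.species not in lo:
            order.append(rec.species)
            lo[rec.species] = hi[rec.species] = rec.elevation
        else:
            lo[rec.species] = min(lo[rec.species], rec.elevation)
            hi[rec.species] = max(hi[rec.species], rec.elevation)
    return [SpeciesRange(s, lo[s], hi[s]) for s in order]
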