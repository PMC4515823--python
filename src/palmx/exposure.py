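"""Climate winner/loser classification and exposure statistics.

For each species and scenario combination the change in climatic suitability
delta = future - baseline is computed cellwise.  Inside the predicted current
range a negative delta makes the cell a 'local climate loser' cell and a
positive delta a 'local climate winner' cell, regardless of magnitude; in
the dispersal buffer ring a positive delta marks an 'immigrant climate
winner' cell.  A species can be a loser in one cell and a winner in another.

Two headline per-species statistics follow:

* percentage of current-range cells losing suitability,
* overall loss net of buffer colonisation:
  (n_loser_cells - n_buffer_gain_cells) / n_range_cells * 100,

where the buffer-gain count is forced to zero under the no-dispersal
scenario.  The net statistic may be negative (net expansion) and is reported
as-is.  Category maps are stacked into richness and proportion-lost maps,
with a high-loss flag where 80-100% of the locally occurring species lose
suitability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

from .rasters import Raster
from .sdm.threshold import RangeMask

HIGH_LOSS_BAND = (0.8, 1.0)


class Category(IntEnum):
    """Cell categories of an exposure map (uint8 raster code table)."""

    OUTSIDE = 0
    LOCAL_LOSER = 1
    LOCAL_WINNER = 2
    UNCHANGED = 3
    IMMIGRANT_WINNER = 4


def delta_suitability(baseline: Raster, future: Raster) -> Raster:
    """Cellwise suitability change future - baseline, nodata-propagating."""
    if baseline.grid != future.grid:
        raise ValueError("baseline and future surfaces live on different grids")
    b_sp = baseline.provenance.get("species_id")
    f_sp = future.provenance.get("species_id")
    if b_sp is not None and f_sp is not None and b_sp != f_sp:
        raise ValueError(f"species mismatch: {b_sp!r} vs {f_sp!r}")
    values = future.values - baseline.values  # NaN propagates
    return future.copy_with(values, name=f"delta_{future.name}",
                            provenance={**future.provenance, "delta": True})


def classify_exposure(delta: Raster, mask: RangeMask,
                      epsilon: float = 0.0) -> np.ndarray:
    """Categorise every cell of one species' reachable footprint.

    In the current range: delta < -epsilon -> local loser, delta > epsilon ->
    local winner, otherwise unchanged (exact zero with the default
    epsilon=0).  In the buffer ring only gains count (immigrant winner);
    non-gaining ring cells stay outside.  Returns a uint8 category array.
    """
    if delta.grid != mask.grid:
        raise ValueError("delta surface and range mask live on different grids")
    d_sp = delta.provenance.get("species_id")
    if d_sp is not None and mask.species_id and d_sp != mask.species_id:
        raise ValueError(f"species mismatch: {d_sp!r} vs {mask.species_id!r}")
    d = delta.values
    cat = np.full(delta.grid.shape, Category.OUTSIDE, dtype=np.uint8)
    in_range = mask.current & delta.mask
    cat[in_range & (d < -epsilon)] = Category.LOCAL_LOSER
    cat[in_range & (d > epsilon)] = Category.LOCAL_WINNER
    cat[in_range & (np.abs(d) <= epsilon)] = Category.UNCHANGED
    ring = mask.buffer_ring & delta.mask
    cat[ring & (d > epsilon)] = Category.IMMIGRANT_WINNER
    return cat


@dataclass
class SpeciesExposureSummary:
    species_id: str
    scenario: dict
    n_range_cells: int
    n_loser_cells: int
    n_winner_cells: int
    n_unchanged_cells: int
    n_buffer_gain_cells: int
    pct_loss_in_range: float
    pct_overall_loss: float

    def to_row(self) -> dict:
        row = {"species_id": self.species_id, **self.scenario}
        for k in ("n_range_cells", "n_loser_cells", "n_winner_cells",
                  "n_unchanged_cells", "n_buffer_gain_cells",
                  "pct_loss_in_range", "pct_overall_loss"):
            row[k] = getattr(self, k)
        return row


def summarize_species(categories: np.ndarray, mask: RangeMask,
                      scenario: dict | None = None) -> SpeciesExposureSummary:
    """The two per-species exposure percentages from cell counts.

    ``pct_overall_loss`` nets buffer-ring gains against in-range losses over
    the current range size; with ``buffer_km = 0`` the gain count is zero by
    construction and the two percentages coincide.
    """
    n_range = int(mask.current.sum())
    if n_range == 0:
        raise ValueError(f"{mask.species_id}: empty current range")
    n_loser = int((categories == Category.LOCAL_LOSER).sum())
    n_winner = int((categories == Category.LOCAL_WINNER).sum())
    n_unchanged = int((categories == Category.UNCHANGED).sum())
    n_gain = int((categories == Category.IMMIGRANT_WINNER).sum())
    if mask.buffer_km == 0:
        n_gain = 0
    pct_loss = 100.0 * n_loser / n_range
    pct_overall = 100.0 * (n_loser - n_gain) / n_range
    return SpeciesExposureSummary(
        species_id=mask.species_id, scenario=dict(scenario or {}),
        n_range_cells=n_range, n_loser_cells=n_loser,
        n_winner_cells=n_winner, n_unchanged_cells=n_unchanged,
        n_buffer_gain_cells=n_gain, pct_loss_in_range=pct_loss,
        pct_overall_loss=pct_overall)


@dataclass
class RichnessMaps:
    group: str
    richness: np.ndarray            # species whose current range covers the cell
    losers: np.ndarray
    winners: np.ndarray
    immigrant_winners: np.ndarray
    proportion_lost: np.ndarray     # losers / richness; NaN where richness 0
    high_loss: np.ndarray           # proportion in [0.8, 1.0], inclusive
    provenance: dict = field(default_factory=dict)


def stack_richness(category_maps: Sequence[np.ndarray],
                   masks: Sequence[RangeMask],
                   group: str = "all") -> RichnessMaps:
    """Stack one group's per-species exposure maps into community maps.

    Per-species inputs may be fractional (consensus means over model
    combinations); counts then average accordingly, as in ensemble-mean
    richness surfaces.
    """
    if len(category_maps) == 0:
        raise ValueError("empty species list")
    if len(category_maps) != len(masks):
        raise ValueError("one mask per category map required")
    shape = masks[0].grid.shape
    richness = np.zeros(shape)
    losers = np.zeros(shape)
    winners = np.zeros(shape)
    immigrants = np.zeros(shape)
    for cat, mask in zip(category_maps, masks):
        if cat.shape != shape:
            raise ValueError("category map shape mismatch")
        richness += mask.current
        if cat.dtype == np.uint8 or np.issubdtype(cat.dtype, np.integer):
            losers += cat == Category.LOCAL_LOSER
            winners += cat == Category.LOCAL_WINNER
            immigrants += cat == Category.IMMIGRANT_WINNER
        else:
            raise ValueError("category maps must be integer-coded")
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(richness > 0, losers / np.maximum(richness, 1e-300), np.nan)
    lo, hi = HIGH_LOSS_BAND
    high = np.isfinite(prop) & (prop >= lo) & (prop <= hi)
    return RichnessMaps(group=group, richness=richness, losers=losers,
                        winners=winners, immigrant_winners=immigrants,
                        proportion_lost=prop, high_loss=high)


def stack_fractional(loser_fraction_maps: Sequence[np.ndarray],
                     masks: Sequence[RangeMask], group: str = "all") -> RichnessMaps:
    """Like :func:`stack_richness` but from per-species consensus loser
    fractions (mean over combinations of the loser indicator per cell)."""
    if len(loser_fraction_maps) == 0:
        raise ValueError("empty species list")
    shape = masks[0].grid.shape
    richness = np.zeros(shape)
    losers = np.zeros(shape)
    for frac, mask in zip(loser_fraction_maps, masks):
        richness += mask.current
        losers += np.where(mask.current, frac, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(richness > 0, losers / np.maximum(richness, 1e-300), np.nan)
    lo, hi = HIGH_LOSS_BAND
    high = np.isfinite(prop) & (prop >= lo) & (prop <= hi)
    return RichnessMaps(group=group, richness=richness, losers=losers,
                        winners=np.zeros(shape), immigrant_winners=np.zeros(shape),
                        proportion_lost=prop, high_loss=high)


def summaries_to_frame(summaries: Sequence[SpeciesExposureSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])
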