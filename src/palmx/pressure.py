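"""Human-population pressure within species ranges.

Two analyses connect climate exposure with people:

* the suitability-weighted mean human population density (HPD) a species
  experiences across its dispersal mask — sum(s_i h_i) / sum(s_i) over
  reachable cells, i.e. HPD weighted by each cell's share of the species'
  climate suitability;
* the spatial overlap between cells where 80-100% of the local species pool
  loses suitability and cells whose HPD exceeds a high-pressure benchmark
  (default: the continental year-2000 average, CON-HPD = 50.14 people/km^2;
  the Rwanda year-2000 density, 307 people/km^2, is carried as a report
  annotation only).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .sdm.threshold import RangeMask

CON_HPD = 50.14          # people/km^2, continental average benchmark
RWANDA_HPD = 307.0       # people/km^2, densest-country annotation


class ZeroWeightError(ValueError):
    """Total suitability weight on the mask is zero; the mean is undefined."""


def weighted_hpd(suitability: np.ndarray, hpd: np.ndarray,
                 mask: RangeMask) -> float:
    """Suitability-share-weighted mean HPD over the reachable mask.

    Invariant to uniform rescaling of the weights and bounded by the min/max
    HPD on the mask.  Raises :class:`ZeroWeightError` when the mask carries
    no suitability weight instead of silently returning 0.
    """
    s = np.asarray(suitability, dtype=float)
    h = np.asarray(hpd, dtype=float)
    m = mask.reachable & np.isfinite(s) & np.isfinite(h)
    if not m.any():
        raise ZeroWeightError(f"{mask.species_id}: empty reachable mask")
    w = s[m]
    total = w.sum()
    if total <= 0:
        raise ZeroWeightError(
            f"{mask.species_id}: zero total suitability weight on mask")
    return float((w * h[m]).sum() / total)


class OverlapCategory(IntEnum):
    """Cell codes of the climate-loss x HPD overlap map."""

    NONE = 0
    CC_ONLY = 1                 # high climate loss, HPD below threshold
    HPD_FUTURE_ONLY = 2         # future HPD high, no high loss
    HPD_NOW_AND_FUTURE = 3      # HPD high now and in the future, no high loss
    OVERLAP_FUTURE = 4          # high loss and future HPD high
    OVERLAP_NOW_AND_FUTURE = 5  # high loss and HPD high now and in the future


@dataclass
class OverlapSummary:
    threshold: float
    n_high_loss_cells: int
    pct_high_loss_cells_over_threshold_future: float | None
    pct_high_loss_cells_over_threshold_now: float | None

    @property
    def defined(self) -> bool:
        return self.n_high_loss_cells > 0


def threat_overlap(high_loss: np.ndarray, hpd_future: np.ndarray,
                   hpd_now: np.ndarray, footprint: np.ndarray,
                   threshold: float = CON_HPD,
                   ) -> tuple[np.ndarray, OverlapSummary]:
    """Overlay high-climate-loss cells with high-HPD cells.

    ``high_loss`` flags cells where the local loser proportion falls in the
    high band; ``footprint`` restricts the map to the family's range (cells
    where any species occurs or can reach).  The summary percentages are
    computed over high-loss cells only; with no high-loss cells they are
    undefined and flagged as such rather than reported as zero.
    """
    if threshold <= 0:
        raise ValueError("HPD threshold must be positive")
    hl = np.asarray(high_loss, dtype=bool) & footprint
    fut_hi = np.asarray(hpd_future) >= threshold
    now_hi = np.asarray(hpd_now) >= threshold
    cat = np.full(hl.shape, OverlapCategory.NONE, dtype=np.uint8)
    fp = np.asarray(footprint, dtype=bool)
    cat[fp & ~hl & fut_hi & ~now_hi] = OverlapCategory.HPD_FUTURE_ONLY
    cat[fp & ~hl & fut_hi & now_hi] = OverlapCategory.HPD_NOW_AND_FUTURE
    cat[hl & ~fut_hi] = OverlapCategory.CC_ONLY
    cat[hl & fut_hi & ~now_hi] = OverlapCategory.OVERLAP_FUTURE
    cat[hl & fut_hi & now_hi] = OverlapCategory.OVERLAP_NOW_AND_FUTURE
    n_hl = int(hl.sum())
    if n_hl == 0:
        summary = OverlapSummary(threshold, 0, None, None)
    else:
        summary = OverlapSummary(
            threshold, n_hl,
            100.0 * float((hl & fut_hi).sum()) / n_hl,
            100.0 * float((hl & now_hi).sum()) / n_hl)
    return cat, summary
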