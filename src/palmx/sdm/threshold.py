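"""Binarisation of suitability surfaces into predicted current ranges.

The continuous suitability surface is cut at a threshold to define the
species' predicted current range.  The default rule maximises the true skill
statistic (sensitivity + specificity - 1) over presence vs background cells;
because TSS is piecewise constant in the threshold, ties over an interval of
equally optimal thresholds are broken at the interval midpoint.  The chosen
threshold and rule are recorded in the mask's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grid import Grid
from ..rasters import Raster


@dataclass
class RangeMask:
    """Binary current range plus its dispersal-buffered extension."""

    species_id: str
    grid: Grid
    current: np.ndarray            # boolean
    buffer_km: float = 0.0
    reachable: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=bool)
        if self.current.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if self.reachable is None:
            self.reachable = self.current.copy()
        self.reachable = np.asarray(self.reachable, dtype=bool)
        if self.buffer_km == 0 and (self.reachable != self.current).any():
            raise ValueError("buffer_km = 0 requires reachable == current")
        if (self.current & ~self.reachable).any():
            raise ValueError("current range must be a subset of reachable")

    @property
    def buffer_ring(self) -> np.ndarray:
        return self.reachable & ~self.current


def max_tss_threshold(presence_suit: np.ndarray,
                      background_suit: np.ndarray) -> tuple[float, float]:
    """Exhaustive scan for the TSS-maximising threshold.

    Candidate thresholds are the distinct observed suitability values (the
    rule is suitability >= threshold).  TSS is constant on each interval
    between consecutive distinct values; the returned threshold is the
    midpoint of the maximal optimal interval.  Returns (threshold, tss).
    """
    pres = np.asarray(presence_suit, dtype=float)
    bg = np.asarray(background_suit, dtype=float)
    values = np.unique(np.concatenate([pres, bg]))
    if values.size < 2:
        raise ValueError("degenerate surface: all candidate values equal")
    tss = np.array([
        (pres >= v).mean() + (bg < v).mean() - 1.0 for v in values
    ])
    best = tss.max()
    opt = np.flatnonzero(np.isclose(tss, best))
    # maximal contiguous run containing the first optimum
    first = opt[0]
    last = first
    while last + 1 < values.size and np.isclose(tss[last + 1], best):
        last += 1
    lower = values[first - 1] if first > 0 else values[0]
    return float(0.5 * (lower + values[last])), float(best)


def equal_sens_spec_threshold(presence_suit: np.ndarray,
                              background_suit: np.ndarray) -> float:
    pres = np.asarray(presence_suit, dtype=float)
    bg = np.asarray(background_suit, dtype=float)
    values = np.unique(np.concatenate([pres, bg]))
    if values.size < 2:
        raise ValueError("degenerate surface: all candidate values equal")
    gap = [abs((pres >= v).mean() - (bg < v).mean()) for v in values]
    return float(values[int(np.argmin(gap))])


def threshold_range(surface: Raster, presence_suit: np.ndarray,
                    background_suit: np.ndarray, rule: str = "max_tss",
                    tau: float | None = None,
                    species_id: str = "") -> RangeMask:
    """Cut a suitability surface into a binary predicted current range.

    ``presence_suit`` / ``background_suit`` are the suitability values at the
    occurrence and background cells used to calibrate the threshold.  Rules:
    ``max_tss`` (default), ``equal_sens_spec``, or ``fixed`` with ``tau``.
    """
    tss = None
    if rule == "fixed":
        if tau is None:
            raise ValueError("fixed rule requires tau")
        thr = float(tau)
    elif rule == "max_tss":
        thr, tss = max_tss_threshold(presence_suit, background_suit)
    elif rule == "equal_sens_spec":
        thr = equal_sens_spec_threshold(presence_suit, background_suit)
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    current = surface.mask & (np.nan_to_num(surface.values, nan=-np.inf) >= thr)
    prov = {"rule": rule, "threshold": thr}
    if tss is not None:
        prov["tss"] = tss
    prov.update(surface.provenance)
    sid = species_id or surface.provenance.get("species_id", "")
    return RangeMask(species_id=sid, grid=surface.grid, current=current,
                     buffer_km=0.0, provenance=prov)
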