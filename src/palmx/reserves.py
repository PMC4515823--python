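"""Protected-area retention of climatic suitability.

Each species' conserved suitability under a scenario is the cell-by-cell sum
of suitability times the fraction of the cell covered by the reserve
network, over the species' dispersal mask.  Comparing baseline and future
conserved suitability classifies the species as a PA loser, PA winner or
(within numerical noise) unchanged; the buffered mask admits immigration of
species into reserves under the 100-km dispersal scenario.  Raw sums are the
default; ``normalize=True`` divides by the summed suitability for a
range-size-independent retention score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sdm.threshold import RangeMask

PA_TIE_EPS = 1e-12


def conserved_suitability(suitability: np.ndarray, pa: np.ndarray,
                          mask: RangeMask, normalize: bool = False,
                          threshold: float | None = None) -> float:
    """Sum of suitability x protected fraction over the reachable mask.

    ``threshold`` switches to a presence-weighted variant (cells count their
    protected fraction only where suitability >= threshold) for sensitivity
    analysis; the continuous sum is the default statistic.
    """
    s = np.asarray(suitability, dtype=float)
    p = np.asarray(pa, dtype=float)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("protected fractions must lie in [0, 1]")
    m = mask.reachable & np.isfinite(s) & np.isfinite(p)
    if not m.any():
        return 0.0
    sv = s[m]
    if threshold is not None:
        score = float(((sv >= threshold) * p[m]).sum())
        denom = float((sv >= threshold).sum())
    else:
        score = float((sv * p[m]).sum())
        denom = float(sv.sum())
    if normalize:
        return score / denom if denom > 0 else 0.0
    return score


@dataclass
class PASummary:
    species_id: str
    scenario: dict
    conserved_baseline: float
    conserved_future: float

    @property
    def change(self) -> float:
        return self.conserved_future - self.conserved_baseline

    @property
    def pa_class(self) -> str:
        if self.change < -PA_TIE_EPS:
            return "pa_loser"
        if self.change > PA_TIE_EPS:
            return "pa_winner"
        return "pa_unchanged"

    def to_row(self) -> dict:
        return {"species_id": self.species_id, **self.scenario,
                "conserved_baseline": self.conserved_baseline,
                "conserved_future": self.conserved_future,
                "change": self.change, "pa_class": self.pa_class}


def pa_change(species_id: str, conserved_baseline: float,
              conserved_future: float, scenario: dict | None = None) -> PASummary:
    """Change in conserved suitability and its sign class for one species
    under one model combination (baseline and future must share the mask
    convention of the dispersal scenario)."""
    return PASummary(species_id=species_id, scenario=dict(scenario or {}),
                     conserved_baseline=float(conserved_baseline),
                     conserved_future=float(conserved_future))


def group_pa_proportions(df: pd.DataFrame,
                         by: tuple[str, ...] = ("period", "co2", "dispersal_km"),
                         ) -> pd.DataFrame:
    """Consensus PA loser/winner proportions (%) per group of scenarios.

    ``df`` holds one row per species x combination with a ``pa_class``
    column.  Classification happens per combination; the group proportion is
    the mean of the per-species loser/winner indicators across species and
    combinations (equivalently the mean over combinations of per-combination
    proportions), keeping the statistic-then-mean consensus order.
    """
    work = df.copy()
    work["is_loser"] = (work["pa_class"] == "pa_loser").astype(float)
    work["is_winner"] = (work["pa_class"] == "pa_winner").astype(float)
    out = (work.groupby(list(by), dropna=False)[["is_loser", "is_winner"]]
           .mean().mul(100.0).rename(columns={
               "is_loser": "pct_pa_losers", "is_winner": "pct_pa_winners"})
           .reset_index())
    return out
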