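"""Factorial forecast design: SDM x GCM x SRES x CO2 x period.

Ensemble climate-change forecasting propagates three nested sources of
uncertainty — the distribution-model algorithm, the circulation model that
produced the future climate fields, and the emission scenario driving it.
This module owns the bookkeeping: enumerating the complete factorial,
applying the CO2 water-use-efficiency rescaling to the water-balance
predictors, projecting every fitted model onto every climate set, and taking
consensus (arithmetic-mean) summaries across combinations.

The consensus order is fixed: the per-combination statistic is computed
FIRST, then averaged across (sdm, gcm, sres) for each period and CO2 flag.
The alternative order (average the suitability surfaces, then derive the
statistic) gives different winner/loser counts and is deliberately not
offered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASELINE = "baseline"
FUTURE_PERIODS = ("2020", "2050", "2080")
PERIODS = (BASELINE,) + FUTURE_PERIODS
CO2_FLAGS = ("minus", "plus")
ALGOS = ("maxent", "boosted_trees")


@dataclass(frozen=True, order=True)
class ScenarioKey:
    """One cell of the forecast factorial.

    The baseline period is canonical: it carries no GCM/SRES variation
    (``gcm = sres = None``) and, because the CO2 rescaling applies to future
    precipitation projections only, no CO2 variation either.
    """

    period: str
    gcm: str | None = None
    sres: str | None = None
    co2: str = "minus"
    sdm_algo: str | None = None

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}; expected one of {PERIODS}")
        if self.co2 not in CO2_FLAGS:
            raise ValueError(f"co2 must be one of {CO2_FLAGS}, got {self.co2!r}")
        if self.period == BASELINE:
            if self.gcm is not None or self.sres is not None:
                raise ValueError("baseline period admits no gcm/sres variation")
        else:
            if self.gcm is None or self.sres is None:
                raise ValueError(f"future period {self.period} requires gcm and sres")

    @property
    def is_baseline(self) -> bool:
        return self.period == BASELINE

    def climate_key(self) -> "ScenarioKey":
        """Drop the SDM axis (climate does not depend on the fitted model)."""
        return replace(self, sdm_algo=None)

    def with_algo(self, algo: str) -> "ScenarioKey":
        return replace(self, sdm_algo=algo)

    def label(self) -> str:
        parts = [self.period]
        if not self.is_baseline:
            parts += [self.gcm, self.sres]
        parts.append(f"co2-{self.co2}")
        if self.sdm_algo:
            parts.append(self.sdm_algo)
        return "_".join(parts)

    def to_dict(self) -> dict:
        return {
            "period": self.period, "gcm": self.gcm, "sres": self.sres,
            "co2": self.co2, "sdm_algo": self.sdm_algo,
        }


@dataclass(frozen=True)
class FactorialDesign:
    """Declared lists of GCM ids, SRES ids, future periods and CO2 flags."""

    gcms: tuple[str, ...]
    sres: tuple[str, ...]
    periods: tuple[str, ...] = FUTURE_PERIODS
    co2_flags: tuple[str, ...] = CO2_FLAGS
    algos: tuple[str, ...] = ALGOS

    def __post_init__(self) -> None:
        for p in self.periods:
            if p not in FUTURE_PERIODS:
                raise ValueError(f"future period {p!r} not in {FUTURE_PERIODS}")
        if not self.gcms or not self.sres:
            raise ValueError("design needs at least one GCM and one SRES")

    def climate_keys(self) -> list[ScenarioKey]:
        """Baseline plus every future (gcm, sres, period, co2) climate set."""
        keys = [ScenarioKey(BASELINE)]
        for co2, g, s, p in itertools.product(self.co2_flags, self.gcms,
                                              self.sres, self.periods):
            keys.append(ScenarioKey(p, g, s, co2))
        return keys

    def future_keys(self) -> list[ScenarioKey]:
        return [k for k in self.climate_keys() if not k.is_baseline]

    def combinations(self) -> list[tuple[str, str, str]]:
        """The (sdm, gcm, sres) combinations averaged over in consensus."""
        return list(itertools.product(self.algos, self.gcms, self.sres))


# ---------------------------------------------------------------------------
# CO2 precipitation rescaling

def rescale_precipitation(
    climate: "ClimateLayerSet",
    factor_per_period: Mapping[str, float] | None = None,
    transform: Callable[[np.ndarray, str], np.ndarray] | None = None,
) -> "ClimateLayerSet":
    """Apply the elevated-CO2 water-use-efficiency adjustment.

    Under elevated CO2, plants lose less water per unit carbon fixed, so a
    given rainfall behaves like more effective precipitation.  The default
    transform multiplies every water-balance-derived layer by a per-period
    factor and leaves temperature layers untouched; a custom ``transform``
    (array, period) -> array may replace it.  The returned set carries
    ``co2='plus'`` and records the transform parameters in provenance.
    """
    from .world import ClimateLayerSet  # local import to avoid a cycle

    key = climate.key
    if transform is None:
        if factor_per_period is None:
            raise ValueError("either factor_per_period or transform is required")
        if key.period not in factor_per_period:
            raise ValueError(
                f"no CO2 rescaling factor declared for period {key.period!r}"
            )
        f = float(factor_per_period[key.period])
        if f < 0:
            raise ValueError("CO2 rescaling factor must be nonnegative")
        transform = lambda arr, period: arr * f  # noqa: E731
        prov_extra = {"co2_transform": "multiplicative", "factor": f}
    else:
        prov_extra = {"co2_transform": getattr(transform, "__name__", "custom")}

    layers = {}
    for name, arr in climate.layers.items():
        if name in climate.water_balance_layers:
            layers[name] = transform(arr, key.period)
        else:
            layers[name] = arr.copy()
    new_key = replace(key, co2="plus")
    return ClimateLayerSet(
        grid=climate.grid, key=new_key, layers=layers,
        water_balance_layers=tuple(climate.water_balance_layers),
        provenance={**climate.provenance, **prov_extra},
    )


# ---------------------------------------------------------------------------
# Projection over the factorial

def run_scenarios(
    models: Mapping[str, Mapping[str, "SDMModel"]],
    climates: Mapping[ScenarioKey, "ClimateLayerSet"],
    keys: Iterable[ScenarioKey] | None = None,
) -> dict[str, dict[ScenarioKey, "Raster"]]:
    """Project every species' models onto every declared climate set.

    ``models`` maps species_id -> {algo -> fitted model}; ``climates`` maps
    climate-level ScenarioKeys (``sdm_algo is None``) to layer sets.  Returns
    ``{species_id: {full ScenarioKey (with sdm_algo): suitability Raster}}``.
    Every declared key must have a climate set and every species a model per
    algorithm; the factorial is completed or the call fails listing what is
    missing.  Results are independent of evaluation order.
    """
    from .sdm import predict_suitability

    if keys is None:
        keys = list(climates.keys())
    keys = [k.climate_key() for k in keys]
    missing = [k for k in keys if k not in climates]
    if missing:
        raise KeyError(
            "missing climate sets for ScenarioKeys: "
            + ", ".join(k.label() for k in sorted(missing))
        )
    out: dict[str, dict[ScenarioKey, "Raster"]] = {}
    for sid, per_algo in models.items():
        out[sid] = {}
        for algo, model in per_algo.items():
            for key in keys:
                surf = predict_suitability(model, climates[key])
                out[sid][key.with_algo(algo)] = surf
    return out


# ---------------------------------------------------------------------------
# Consensus

def consensus_mean(
    values: Sequence[float] | Sequence[np.ndarray],
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Arithmetic mean and sample sd (ddof=1) across model combinations.

    Accepts scalars or equally-shaped arrays (consensus surfaces are averaged
    cellwise).  A single combination returns sd 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape[0] == 0:
        raise ValueError("consensus over an empty set of combinations")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros_like(mean)
    if arr.ndim == 1:
        return float(mean), float(sd)
    return mean, sd


def consensus_table(
    df: pd.DataFrame,
    value_cols: Sequence[str],
    by: Sequence[str] = ("species_id", "period", "co2"),
    over: Sequence[str] = ("sdm_algo", "gcm", "sres"),
) -> pd.DataFrame:
    """Consensus mean +/- sd of per-combination statistics in long format.

    ``df`` holds one row per species x ScenarioKey with the statistic already
    computed per combination (statistic-then-mean order).  Averaging is
    grouped by ``by``; the ``over`` columns must jointly cover each group
    completely — period and CO2 flag are never averaged over.
    """
    for col in ("period", "co2"):
        if col in over:
            raise ValueError(f"{col} must never be averaged over")
    expected = None
    g = df.groupby(list(by), dropna=False)
    counts = g.size()
    expected = counts.iloc[0]
    if not (counts == expected).all():
        raise ValueError("unbalanced consensus groups: incomplete factorial")
    agg = g[list(value_cols)].agg(["mean", "std"])
    agg.columns = [f"{c}_{stat}" for c, stat in agg.columns]
    out = agg.reset_index()
    std_cols = [c for c in out.columns if c.endswith("_std")]
    out[std_cols] = out[std_cols].fillna(0.0)
    out["n_combinations"] = int(expected)
    return out
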