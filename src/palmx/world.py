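"""Synthetic study system with known ground truth.

The pipeline is exercised end-to-end on a virtual continent: smooth climate
fields that drift between periods, virtual species with Gaussian climate
niches, presence-only occurrence samples, growing clumped human-population
surfaces and a sparse reserve network.  Because every species' niche is known
exactly, each downstream stage has a parameter-recovery oracle.

Default design mirrors the real study system's shape: 40 species (27
rainforest, 11 open-habitat, 2 other), six climate predictors (three
temperature, three water-balance), a 3 pseudo-GCM x 3 pseudo-SRES x 3
future-period factorial, and warming/drying drift that grows with time.

Everything is deterministic given ``WorldConfig.seed``: each artifact draws
from its own named substream so generation order never matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import Grid
from .scenarios import (BASELINE, FUTURE_PERIODS, PERIODS, FactorialDesign,
                        ScenarioKey)

TEMP_LAYERS = ("temp_1", "temp_2", "temp_3")
WB_LAYERS = ("wb_1", "wb_2", "wb_3")
LAYER_NAMES = TEMP_LAYERS + WB_LAYERS

# per-layer (mean, spatial amplitude, noise sd) of the baseline fields
LAYER_SCALES: dict[str, tuple[float, float, float]] = {
    "temp_1": (24.0, 6.0, 0.15),
    "temp_2": (18.0, 5.0, 0.15),
    "temp_3": (30.0, 4.0, 0.15),
    "wb_1": (1000.0, 400.0, 10.0),
    "wb_2": (400.0, 150.0, 5.0),
    "wb_3": (80.0, 40.0, 2.0),
}

# substream tags
_CLIMATE, _OCC, _HPD, _PA, _NICHE = 1, 2, 3, 4, 5


class DegenerateNicheError(ValueError):
    """Raised when a niche assigns (numerically) zero weight to every cell."""


@dataclass(frozen=True)
class SpeciesSpec:
    species_id: str
    habitat_group: str
    niche_mean: tuple[float, ...]  # one value per predictor layer
    niche_sd: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.niche_mean) != len(LAYER_NAMES) or len(self.niche_sd) != len(LAYER_NAMES):
            raise ValueError("niche must specify one mean and sd per predictor")
        if any(s <= 0 for s in self.niche_sd):
            raise ValueError("niche_sd must be strictly positive")


@dataclass
class ClimateLayerSet:
    """Six predictor rasters for one scenario, as plain 2-D arrays."""

    grid: Grid
    key: ScenarioKey
    layers: dict[str, np.ndarray]
    water_balance_layers: tuple[str, ...] = WB_LAYERS
    provenance: dict = field(default_factory=dict)

    def matrix(self) -> np.ndarray:
        """Cells x predictors matrix in fixed layer order (row-major cells)."""
        return np.column_stack([self.layers[n].ravel() for n in LAYER_NAMES])

    def layer_names(self) -> tuple[str, ...]:
        return LAYER_NAMES


@dataclass
class WorldConfig:
    grid: Grid
    species: tuple[SpeciesSpec, ...]
    climate_trends: Mapping[tuple[str, str, str], Mapping[str, float]]
    design: FactorialDesign
    hpd_base: Mapping[str, float] = field(
        default_factory=lambda: {"mean": 50.0, "clumping": 1.2})
    hpd_growth: Mapping[str, float] = field(
        default_factory=lambda: {BASELINE: 1.0, "2020": 1.4, "2050": 2.0, "2080": 2.8})
    pa_fraction: float = 0.1
    n_occurrences: int = 300
    background_size: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pa_fraction <= 1.0:
            raise ValueError("pa_fraction must lie in [0, 1]")
        for (g, s, p), shifts in self.climate_trends.items():
            if g not in self.design.gcms or s not in self.design.sres \
                    or p not in self.design.periods:
                raise ValueError(f"climate trend for unknown scenario ({g}, {s}, {p})")
            unknown = set(shifts) - set(LAYER_NAMES)
            if unknown:
                raise ValueError(f"climate trend names unknown layers {sorted(unknown)}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def group_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sp in self.species:
            out[sp.habitat_group] = out.get(sp.habitat_group, 0) + 1
        return out


# ---------------------------------------------------------------------------
# default world construction


def default_trends(design: FactorialDesign,
                   temp_shift: Mapping[str, float] | None = None,
                   wb_fraction: Mapping[str, float] | None = None,
                   ) -> dict[tuple[str, str, str], dict[str, float]]:
    """Warming + drying drift growing with period, modulated per GCM/SRES.

    ``temp_shift`` is degrees of warming applied to every temperature layer
    per period; ``wb_fraction`` is the (negative) fractional change of each
    water-balance layer's spatial amplitude.  GCMs/SRES scale these by evenly
    spaced multipliers around 1 so the ensemble spreads without changing its
    central tendency.  Pass all-zero maps for a no-drift world.
    """
    if temp_shift is None:
        temp_shift = {"2020": 0.8, "2050": 1.8, "2080": 3.0}
    if wb_fraction is None:
        wb_fraction = {"2020": -0.06, "2050": -0.14, "2080": -0.25}

    def spread(names: tuple[str, ...]) -> dict[str, float]:
        n = len(names)
        if n == 1:
            return {names[0]: 1.0}
        return {nm: 0.8 + 0.4 * i / (n - 1) for i, nm in enumerate(names)}

    gmul, smul = spread(design.gcms), spread(design.sres)
    trends: dict[tuple[str, str, str], dict[str, float]] = {}
    for g in design.gcms:
        for s in design.sres:
            for p in design.periods:
                m = gmul[g] * smul[s]
                shifts = {}
                for nm in TEMP_LAYERS:
                    shifts[nm] = m * temp_shift[p]
                for nm in WB_LAYERS:
                    shifts[nm] = m * wb_fraction[p] * LAYER_SCALES[nm][1]
                trends[(g, s, p)] = shifts
    return trends


def draw_species(n_rainforest: int = 27, n_open: int = 11, n_other: int = 2,
                 seed: int = 0, niche_breadth: float = 0.45) -> tuple[SpeciesSpec, ...]:
    """Draw Gaussian niches inside the realised baseline climate envelope.

    Rainforest species center on the warm/wet side of each gradient,
    open-habitat species on the hot/dry side, 'other' anywhere.
    ``niche_breadth`` sets sigma as a fraction of each layer's spatial
    amplitude.
    """
    rng = np.random.default_rng([seed, _NICHE])
    specs = []
    groups = (["rainforest"] * n_rainforest + ["open-habitat"] * n_open
              + ["other"] * n_other)
    for i, group in enumerate(groups):
        mean, sd = [], []
        for nm in LAYER_NAMES:
            mu0, amp, _ = LAYER_SCALES[nm]
            if group == "rainforest":
                lo, hi = (0.1, 0.7) if nm in TEMP_LAYERS else (0.2, 0.9)
            elif group == "open-habitat":
                lo, hi = (0.3, 0.95) if nm in TEMP_LAYERS else (-0.9, 0.0)
            else:
                lo, hi = -0.8, 0.8
            mean.append(mu0 + amp * rng.uniform(lo, hi))
            sd.append(niche_breadth * amp * rng.uniform(0.8, 1.25))
        specs.append(SpeciesSpec(f"sp{i:03d}", group, tuple(mean), tuple(sd)))
    return tuple(specs)


def default_config(n_rows: int = 60, n_cols: int = 60, seed: int = 0,
                   n_gcm: int = 3, n_sres: int = 3,
                   zero_drift: bool = False,
                   n_occurrences: int = 300,
                   **overrides) -> WorldConfig:
    """The standard 40-species desk-scale world."""
    grid = Grid(n_rows, n_cols, cell_size_km=10.0)
    design = FactorialDesign(
        gcms=tuple(f"gcm{i+1}" for i in range(n_gcm)),
        sres=tuple(f"sres{i+1}" for i in range(n_sres)),
    )
    if zero_drift:
        trends = default_trends(design,
                                temp_shift={p: 0.0 for p in FUTURE_PERIODS},
                                wb_fraction={p: 0.0 for p in FUTURE_PERIODS})
    else:
        trends = default_trends(design)
    species = draw_species(seed=seed)
    return WorldConfig(grid=grid, species=species, climate_trends=trends,
                       design=design, seed=seed, n_occurrences=n_occurrences,
                       **overrides)


# ---------------------------------------------------------------------------
# field construction helpers


def _smooth_field(grid: Grid, rng: np.random.Generator, n_waves: int = 4) -> np.ndarray:
    """Sum of low-frequency sinusoids, normalised to roughly unit amplitude.

    Wavelengths span one half to two domain lengths, so fields vary smoothly
    enough for climate-like niche gradients yet differ between layers.
    """
    x, y = grid.cell_centers()
    lx = max(grid.n_cols, 2) * grid.cell_size_km
    ly = max(grid.n_rows, 2) * grid.cell_size_km
    out = np.zeros(grid.shape)
    weights = []
    for _ in range(n_waves):
        fx = rng.uniform(0.5, 2.0) / lx * rng.choice([-1.0, 1.0])
        fy = rng.uniform(0.5, 2.0) / ly * rng.choice([-1.0, 1.0])
        phase = rng.uniform(0, 2 * np.pi)
        w = rng.uniform(0.5, 1.0)
        out += w * np.sin(2 * np.pi * (fx * x + fy * y) + phase)
        weights.append(w)
    return out / np.sqrt(np.sum(np.square(weights)) / 2)


# ---------------------------------------------------------------------------
# generators


def generate_climate(config: WorldConfig, scenario: ScenarioKey) -> ClimateLayerSet:
    """Baseline gradients plus the configured drift for a future scenario.

    Baseline layers are seeded smooth gradients with additive noise; a future
    layer is the baseline layer plus the (spatially uniform) additive drift
    configured for its (gcm, sres, period).  The CO2 axis is handled later by
    :func:`palmx.scenarios.rescale_precipitation`, so climate generation
    always yields the ``minus`` flag.
    """
    scenario = scenario.climate_key()
    if not scenario.is_baseline:
        if (scenario.gcm not in config.design.gcms
                or scenario.sres not in config.design.sres
                or scenario.period not in config.design.periods):
            raise ValueError(f"scenario {scenario.label()} is not registered "
                             "in the world configuration")
    layers: dict[str, np.ndarray] = {}
    for j, nm in enumerate(LAYER_NAMES):
        rng = np.random.default_rng([config.seed, _CLIMATE, j])
        mu, amp, noise_sd = LAYER_SCALES[nm]
        base = mu + amp * _smooth_field(config.grid, rng)
        base += rng.normal(0.0, noise_sd, size=config.grid.shape)
        if not scenario.is_baseline:
            shift = config.climate_trends.get(
                (scenario.gcm, scenario.sres, scenario.period), {})
            base = base + float(shift.get(nm, 0.0))
        layers[nm] = base
    key = ScenarioKey(BASELINE) if scenario.is_baseline else \
        ScenarioKey(scenario.period, scenario.gcm, scenario.sres, "minus")
    return ClimateLayerSet(grid=config.grid, key=key, layers=layers,
                           provenance={"seed": config.seed,
                                       "scenario": key.to_dict()})


def true_suitability(spec: SpeciesSpec, climate: ClimateLayerSet) -> np.ndarray:
    """Ground-truth niche suitability: product of per-predictor Gaussians."""
    log_s = np.zeros(climate.grid.shape)
    for nm, mu, sd in zip(LAYER_NAMES, spec.niche_mean, spec.niche_sd):
        z = (climate.layers[nm] - mu) / sd
        log_s -= 0.5 * z * z
    return np.exp(log_s)


def sample_occurrences(spec: SpeciesSpec, climate: ClimateLayerSet,
                       n: int, seed: int) -> pd.DataFrame:
    """Presence-only records drawn with probability proportional to the
    true Gaussian-niche suitability; cells are drawn without replacement
    unless ``n`` exceeds the number of cells with positive weight.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = true_suitability(spec, climate).ravel()
    total = s.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise DegenerateNicheError(
            f"{spec.species_id}: niche assigns zero probability to every cell")
    p = s / total
    rng = np.random.default_rng([seed, _OCC])
    n_suitable = int((p > 0).sum())
    replace = n > n_suitable
    idx = rng.choice(p.size, size=n, replace=replace, p=p)
    rows, cols = np.unravel_index(idx, climate.grid.shape)
    x, y = climate.grid.cell_centers()
    return pd.DataFrame({
        "species_id": spec.species_id,
        "x": x[rows, cols],
        "y": y[rows, cols],
        "habitat_group": spec.habitat_group,
    })


def generate_hpd(config: WorldConfig, period: str) -> np.ndarray:
    """Clumped human-population-density surface for one period (people/km^2).

    The baseline is a log-normal-like field (exp of a smooth clumped field)
    rescaled to the configured mean; each later period multiplies the base
    field by its growth factor, so growth >= 1 gives cellwise monotone
    trajectories.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}")
    if period not in config.hpd_growth:
        raise ValueError(f"no HPD growth factor configured for {period!r}")
    rng = np.random.default_rng([config.seed, _HPD])
    f = _smooth_field(config.grid, rng, n_waves=6)
    f += rng.normal(0.0, 0.15, size=config.grid.shape)
    log_field = float(config.hpd_base.get("clumping", 1.2)) * f
    base = np.exp(log_field)
    base *= float(config.hpd_base["mean"]) / base.mean()
    return base * float(config.hpd_growth[period])


def generate_pa(config: WorldConfig) -> np.ndarray:
    """Sparse reserve network: per-cell protected fraction in {0, 1}.

    A smooth field thresholded at its (1 - pa_fraction) quantile yields a
    few contiguous reserves covering the target fraction of the grid.
    """
    if config.pa_fraction <= 0.0:
        return np.zeros(config.grid.shape)
    if config.pa_fraction >= 1.0:
        return np.ones(config.grid.shape)
    rng = np.random.default_rng([config.seed, _PA])
    f = _smooth_field(config.grid, rng, n_waves=6)
    f += rng.normal(0.0, 0.05, size=config.grid.shape)
    thresh = np.quantile(f, 1.0 - config.pa_fraction)
    return (f >= thresh).astype(float)
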