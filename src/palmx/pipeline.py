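"""End-to-end configured pipeline: simulate -> fit -> project -> expose ->
pressure -> reserves -> report.

The pipeline holds the factorial in memory (a desk-scale world is small) and
writes summary tables, report JSON and optional rasters into the configured
output directory.  Re-running with the same configuration and seed
reproduces every number exactly; every artifact carries provenance (scenario
lineage, seeds, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exposure as expo
from . import pressure, reserves
from .grid import Grid
from .rasters import Raster, read_raster, write_occurrences, write_raster
from .scenarios import (BASELINE, ScenarioKey, consensus_table,
                        rescale_precipitation, run_scenarios)
from .sdm import (build_dispersal_mask, fit_boosted_trees, fit_maxent,
                  threshold_range)
from .sdm.features import FeatureSpec
from .world import (ClimateLayerSet, LAYER_NAMES, WorldConfig, default_config,
                    generate_climate, generate_hpd, generate_pa,
                    sample_occurrences)

log = logging.getLogger("palmx")

_BACKGROUND_STREAM = 6


@dataclass
class RunConfig:
    """Everything one reproducible run needs, serialisable to YAML."""

    n_rows: int = 60
    n_cols: int = 60
    seed: int = 0
    n_gcm: int = 3
    n_sres: int = 3
    n_rainforest: int = 27
    n_open: int = 11
    n_other: int = 2
    zero_drift: bool = False
    # optional overrides of the drift magnitudes (per future period);
    # None keeps the generator defaults
    trend_temp_shift: dict | None = None
    trend_wb_fraction: dict | None = None
    n_occurrences: int = 300
    background_size: int = 10_000
    pa_fraction: float = 0.1
    hpd_mean: float = 50.0
    hpd_growth: dict = field(default_factory=lambda: {
        BASELINE: 1.0, "2020": 1.4, "2050": 2.0, "2080": 2.8})
    # SDM settings
    maxent_regularization: float = 0.01
    maxent_products: bool = False
    gbm_n_trees: int = 60
    gbm_depth: int = 2
    gbm_learning_rate: float = 0.1
    gbm_bag_fraction: float = 1.0
    threshold_rule: str = "max_tss"
    # scenario settings
    dispersal_km: tuple = (0.0, 100.0)
    co2_factors: dict = field(default_factory=lambda: {
        "2020": 1.05, "2050": 1.10, "2080": 1.15})
    # report thresholds
    con_hpd: float = pressure.CON_HPD
    high_loss_band: tuple = expo.HIGH_LOSS_BAND
    out_dir: str = "palmx_run"
    write_rasters: bool = False

    def validate(self) -> None:
        if min(self.n_rows, self.n_cols) < 10:
            raise ValueError("grid must be at least 10 x 10 cells")
        if self.n_occurrences < 5:
            raise ValueError("need at least 5 occurrences per species")
        for d in self.dispersal_km:
            if d < 0:
                raise ValueError("dispersal distances must be nonnegative")
        for p in ("2020", "2050", "2080"):
            if p not in self.co2_factors:
                raise ValueError(f"co2_factors must cover period {p}")
        if not 0 <= self.pa_fraction <= 1:
            raise ValueError("pa_fraction must lie in [0, 1]")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = asdict(self)
        d["dispersal_km"] = list(self.dispersal_km)
        d["high_loss_band"] = list(self.high_loss_band)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["dispersal_km"] = tuple(d.get("dispersal_km", (0.0, 100.0)))
        d["high_loss_band"] = tuple(d.get("high_loss_band", expo.HIGH_LOSS_BAND))
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output plumbing excluded)."""
        d = asdict(self)
        d["dispersal_km"] = list(self.dispersal_km)
        d["high_loss_band"] = list(self.high_loss_band)
        d.pop("out_dir")
        d.pop("write_rasters")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]

    def world_config(self) -> WorldConfig:
        cfg = default_config(
            n_rows=self.n_rows, n_cols=self.n_cols, seed=self.seed,
            n_gcm=self.n_gcm, n_sres=self.n_sres, zero_drift=self.zero_drift,
            n_occurrences=self.n_occurrences,
            background_size=self.background_size,
            pa_fraction=self.pa_fraction,
            hpd_base={"mean": self.hpd_mean, "clumping": 1.2},
            hpd_growth=dict(self.hpd_growth),
        )
        if (self.n_rainforest, self.n_open, self.n_other) != (27, 11, 2):
            from .world import draw_species
            cfg.species = draw_species(self.n_rainforest, self.n_open,
                                       self.n_other, seed=self.seed)
        if self.trend_temp_shift is not None or self.trend_wb_fraction is not None:
            from .world import default_trends
            cfg.climate_trends = default_trends(
                cfg.design, temp_shift=self.trend_temp_shift,
                wb_fraction=self.trend_wb_fraction)
        return cfg


@dataclass
class World:
    config: WorldConfig
    climates: dict            # climate-level ScenarioKey -> ClimateLayerSet
    occurrences: pd.DataFrame
    hpd: dict                 # period -> array
    pa: np.ndarray


@dataclass
class ReportBundle:
    config: RunConfig
    species_exposure: pd.DataFrame
    exposure_consensus: pd.DataFrame
    group_summary: pd.DataFrame
    weighted_hpd: pd.DataFrame
    weighted_hpd_consensus: pd.DataFrame
    pa_summary: pd.DataFrame
    pa_proportions: pd.DataFrame
    overlap: dict
    richness: dict            # group -> RichnessMaps (2080, +CO2 consensus)
    report: dict
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# stage: simulate

def simulate_world(config: RunConfig) -> World:
    """Materialise the synthetic study system for every declared scenario."""
    wc = config.world_config()
    climates: dict[ScenarioKey, ClimateLayerSet] = {}
    baseline = generate_climate(wc, ScenarioKey(BASELINE))
    climates[baseline.key] = baseline
    for key in wc.design.climate_keys():
        if key.is_baseline:
            continue
        if key.co2 == "minus":
            climates[key] = generate_climate(wc, key)
    for key in list(climates.keys()):
        if key.is_baseline or key.co2 != "minus":
            continue
        plus = rescale_precipitation(climates[key], config.co2_factors)
        climates[plus.key] = plus
    occ_frames = []
    for i, spec in enumerate(wc.species):
        occ_frames.append(sample_occurrences(
            spec, baseline, wc.n_occurrences, seed=wc.seed * 100_003 + i))
    occurrences = pd.concat(occ_frames, ignore_index=True)
    hpd = {p: generate_hpd(wc, p) for p in (BASELINE, "2020", "2050", "2080")}
    pa = generate_pa(wc)
    log.info("simulated world: %d species, %d climate sets, grid %s",
             wc.n_species, len(climates), wc.grid.shape)
    return World(config=wc, climates=climates, occurrences=occurrences,
                 hpd=hpd, pa=pa)


# ---------------------------------------------------------------------------
# stage: fit

def _background_cells(grid: Grid, size: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng([seed, _BACKGROUND_STREAM])
    n = grid.n_cells
    if size >= n:
        return np.arange(n)
    return rng.choice(n, size=size, replace=False)


def fit_models(config: RunConfig, world: World) -> dict:
    """Fit both SDM algorithms for every species on the baseline climate.

    Returns ``{species_id: {algo: model}}``.  The background is one seeded
    uniform sample of cells shared by all species (occurrence cells are
    added to the maxent universe inside the fitter).
    """
    baseline = world.climates[ScenarioKey(BASELINE)]
    X_all = baseline.matrix()
    bg_idx = _background_cells(world.config.grid, config.background_size,
                               world.config.seed)
    X_bg = X_all[bg_idx]
    models: dict[str, dict] = {}
    for spec in world.config.species:
        occ = world.occurrences[world.occurrences.species_id == spec.species_id]
        rows, cols = world.config.grid.cell_of_xy(occ.x.values, occ.y.values)
        cell_idx = rows * world.config.grid.n_cols + cols
        X_pres = X_all[cell_idx]
        meta = {"species_id": spec.species_id,
                "habitat_group": spec.habitat_group,
                "background_seed": world.config.seed}
        mx = fit_maxent(
            X_pres, X_bg, predictor_names=list(LAYER_NAMES),
            feature_spec=FeatureSpec(product=config.maxent_products),
            regularization=config.maxent_regularization, metadata=meta)
        gb = fit_boosted_trees(
            X_pres, X_bg, n_trees=config.gbm_n_trees, depth=config.gbm_depth,
            learning_rate=config.gbm_learning_rate,
            bag_fraction=config.gbm_bag_fraction,
            seed=world.config.seed, metadata=meta)
        models[spec.species_id] = {"maxent": mx, "boosted_trees": gb}
        log.info("fitted %s (maxent residual %.1e, gbm deviance %.1f -> %.1f)",
                 spec.species_id, mx.metadata["opt_residual"],
                 gb.train_deviance[0], gb.train_deviance[-1])
    return models


# ---------------------------------------------------------------------------
# stage: project + range masks

def project_all(models: dict, world: World) -> dict:
    """Suitability surfaces for every species x algo x climate scenario."""
    return run_scenarios(models, world.climates)


def derive_masks(config: RunConfig, world: World, models: dict,
                 surfaces: dict) -> dict:
    """Binary current ranges and dispersal masks per species x algo.

    Returns ``{species_id: {algo: {dispersal_km: RangeMask}}}``; the
    threshold is calibrated on occurrence vs background suitability of the
    baseline surface.
    """
    grid = world.config.grid
    bg_idx = _background_cells(grid, config.background_size, world.config.seed)
    masks: dict[str, dict] = {}
    for spec in world.config.species:
        occ = world.occurrences[world.occurrences.species_id == spec.species_id]
        rows, cols = grid.cell_of_xy(occ.x.values, occ.y.values)
        cell_idx = rows * grid.n_cols + cols
        masks[spec.species_id] = {}
        for algo in ("maxent", "boosted_trees"):
            base_key = ScenarioKey(BASELINE).with_algo(algo)
            surf = surfaces[spec.species_id][base_key]
            flat = surf.values.ravel()
            rmask = threshold_range(surf, flat[cell_idx], flat[bg_idx],
                                    rule=config.threshold_rule,
                                    species_id=spec.species_id)
            per_d = {}
            for d in config.dispersal_km:
                per_d[float(d)] = build_dispersal_mask(rmask, d)
            masks[spec.species_id][algo] = per_d
    return masks


# ---------------------------------------------------------------------------
# stage: exposure

def exposure_stage(config: RunConfig, world: World, surfaces: dict,
                   masks: dict) -> tuple[pd.DataFrame, dict]:
    """Per-combination winner/loser accounting for every species.

    Returns the long per-combination summary table and, for the final future
    period under +CO2, per-species consensus loser-fraction and range-
    fraction maps (for the community richness/overlap maps).
    """
    rows = []
    final_period = "2080"
    loser_frac: dict[str, np.ndarray] = {}
    range_frac: dict[str, np.ndarray] = {}
    shape = world.config.grid.shape
    group_of = {s.species_id: s.habitat_group for s in world.config.species}
    for sid, per_key in surfaces.items():
        loser_acc = np.zeros(shape)
        range_acc = np.zeros(shape)
        n_comb = 0
        for key, surf in per_key.items():
            if key.is_baseline:
                continue
            base = per_key[ScenarioKey(BASELINE).with_algo(key.sdm_algo)]
            delta = expo.delta_suitability(base, surf)
            for d in config.dispersal_km:
                mask = masks[sid][key.sdm_algo][float(d)]
                cats = expo.classify_exposure(delta, mask)
                summ = expo.summarize_species(cats, mask, scenario={
                    "habitat_group": group_of[sid],
                    "sdm_algo": key.sdm_algo, "gcm": key.gcm,
                    "sres": key.sres, "period": key.period,
                    "co2": key.co2, "dispersal_km": float(d)})
                rows.append(summ.to_row())
                if (d == 0.0 and key.period == final_period
                        and key.co2 == "plus"):
                    loser_acc += cats == expo.Category.LOCAL_LOSER
                    range_acc += mask.current
                    n_comb += 1
        if n_comb:
            loser_frac[sid] = loser_acc / n_comb
            range_frac[sid] = range_acc / n_comb
    df = pd.DataFrame(rows)
    return df, {"loser_frac": loser_frac, "range_frac": range_frac,
                "period": final_period, "co2": "plus"}


def community_maps(world: World, consensus: dict) -> dict:
    """Consensus richness / proportion-lost maps per habitat group."""
    lo, hi = expo.HIGH_LOSS_BAND
    out = {}
    group_of = {s.species_id: s.habitat_group for s in world.config.species}
    for group in ("all", "rainforest", "open-habitat"):
        sids = [sid for sid in consensus["loser_frac"]
                if group == "all" or group_of[sid] == group]
        if not sids:
            continue
        shape = world.config.grid.shape
        rich = np.zeros(shape)
        losers = np.zeros(shape)
        for sid in sids:
            rich += consensus["range_frac"][sid]
            losers += consensus["loser_frac"][sid]
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(rich > 0, losers / np.maximum(rich, 1e-300), np.nan)
        high = np.isfinite(prop) & (prop >= lo) & (prop <= hi)
        out[group] = expo.RichnessMaps(
            group=group, richness=rich, losers=losers,
            winners=np.zeros(shape), immigrant_winners=np.zeros(shape),
            proportion_lost=prop, high_loss=high,
            provenance={"period": consensus["period"], "co2": consensus["co2"]})
    return out


# ---------------------------------------------------------------------------
# stage: pressure

def pressure_stage(config: RunConfig, world: World, surfaces: dict,
                   masks: dict, richness: dict) -> tuple[pd.DataFrame, dict]:
    """Weighted-HPD trajectories and the climate-loss x HPD overlap."""
    rows = []
    for sid, per_key in surfaces.items():
        for key, surf in per_key.items():
            period = key.period
            hpd = world.hpd[period]
            for d in config.dispersal_km:
                mask = masks[sid][key.sdm_algo][float(d)]
                try:
                    w = pressure.weighted_hpd(surf.values, hpd, mask)
                except pressure.ZeroWeightError:
                    w = np.nan
                rows.append({
                    "species_id": sid, "sdm_algo": key.sdm_algo,
                    "gcm": key.gcm, "sres": key.sres, "period": period,
                    "co2": key.co2, "dispersal_km": float(d),
                    "weighted_hpd": w})
    df = pd.DataFrame(rows)

    overlaps = {}
    hpd_future = world.hpd["2080"]
    hpd_now = world.hpd[BASELINE]
    for group, maps in richness.items():
        footprint = maps.richness > 0
        cat, summary = pressure.threat_overlap(
            maps.high_loss, hpd_future, hpd_now, footprint,
            threshold=config.con_hpd)
        overlaps[group] = {"categories": cat, "summary": summary}
    return df, overlaps


# ---------------------------------------------------------------------------
# stage: reserves

def reserves_stage(config: RunConfig, world: World, surfaces: dict,
                   masks: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conserved-suitability change per species x combination x dispersal."""
    group_of = {s.species_id: s.habitat_group for s in world.config.species}
    rows = []
    for sid, per_key in surfaces.items():
        for key, surf in per_key.items():
            if key.is_baseline:
                continue
            base = per_key[ScenarioKey(BASELINE).with_algo(key.sdm_algo)]
            for d in config.dispersal_km:
                mask = masks[sid][key.sdm_algo][float(d)]
                cb = reserves.conserved_suitability(base.values, world.pa, mask)
                cf = reserves.conserved_suitability(surf.values, world.pa, mask)
                summ = reserves.pa_change(sid, cb, cf, scenario={
                    "habitat_group": group_of[sid],
                    "sdm_algo": key.sdm_algo, "gcm": key.gcm,
                    "sres": key.sres, "period": key.period, "co2": key.co2,
                    "dispersal_km": float(d)})
                rows.append(summ.to_row())
    df = pd.DataFrame(rows)
    props = []
    for group in ("all", "rainforest", "open-habitat"):
        sub = df if group == "all" else df[df.habitat_group == group]
        if len(sub) == 0:
            continue
        p = reserves.group_pa_proportions(sub)
        p.insert(0, "group", group)
        props.append(p)
    return df, pd.concat(props, ignore_index=True)


# ---------------------------------------------------------------------------
# stage: report

def _group_summary(consensus: pd.DataFrame, world: World) -> pd.DataFrame:
    """Group mean +/- sd (across species) of the species-consensus exposure
    percentages, for each period, CO2 flag and dispersal scenario."""
    group_of = {s.species_id: s.habitat_group for s in world.config.species}
    work = consensus.copy()
    work["habitat_group"] = work["species_id"].map(group_of)
    frames = []
    for group in ("all", "rainforest", "open-habitat"):
        sub = work if group == "all" else work[work.habitat_group == group]
        if len(sub) == 0:
            continue
        g = (sub.groupby(["period", "co2", "dispersal_km"])
             [["pct_loss_in_range_mean", "pct_overall_loss_mean"]]
             .agg(["mean", "std"]))
        g.columns = ["_".join(c) for c in g.columns]
        g = g.reset_index()
        g.insert(0, "group", group)
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage and write the report bundle to config.out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        world = simulate_world(config)
        stage = "fit"
        models = fit_models(config, world)
        stage = "project"
        surfaces = project_all(models, world)
        stage = "expose"
        masks = derive_masks(config, world, models, surfaces)
        exposure_df, consensus_maps = exposure_stage(config, world, surfaces,
                                                     masks)
        richness = community_maps(world, consensus_maps)
        stage = "pressure"
        hpd_df, overlaps = pressure_stage(config, world, surfaces, masks,
                                          richness)
        stage = "reserves"
        pa_df, pa_props = reserves_stage(config, world, surfaces, masks)
        stage = "report"
        bundle = _build_report(config, world, exposure_df, hpd_df, overlaps,
                               pa_df, pa_props, richness)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    _write_bundle(bundle, out)
    if config.write_rasters:
        _write_rasters(bundle, world, out)
    return bundle


def _build_report(config, world, exposure_df, hpd_df, overlaps, pa_df,
                  pa_props, richness) -> ReportBundle:
    exp_consensus = consensus_table(
        exposure_df, ["pct_loss_in_range", "pct_overall_loss"],
        by=("species_id", "period", "co2", "dispersal_km"))
    group_summary = _group_summary(exp_consensus, world)

    hpd_consensus = (hpd_df.groupby(
        ["species_id", "period", "co2", "dispersal_km"], dropna=False)
        ["weighted_hpd"].agg(["mean", "std"]).reset_index()
        .rename(columns={"mean": "weighted_hpd_mean",
                         "std": "weighted_hpd_sd"}))
    hpd_consensus["weighted_hpd_sd"] = hpd_consensus["weighted_hpd_sd"].fillna(0.0)

    overlap_out = {}
    for group, o in overlaps.items():
        s = o["summary"]
        overlap_out[group] = {
            "threshold": s.threshold,
            "n_high_loss_cells": s.n_high_loss_cells,
            "pct_high_loss_cells_over_threshold_future":
                s.pct_high_loss_cells_over_threshold_future,
            "pct_high_loss_cells_over_threshold_now":
                s.pct_high_loss_cells_over_threshold_now,
        }

    # share of species whose consensus weighted HPD (widest dispersal, +CO2,
    # final period) exceeds the high-pressure benchmark
    d_max = max(config.dispersal_km)
    final = hpd_consensus[(hpd_consensus.period == "2080")
                          & (hpd_consensus.co2 == "plus")
                          & (hpd_consensus.dispersal_km == d_max)]
    group_of = {s.species_id: s.habitat_group for s in world.config.species}
    pct_over = {}
    for group in ("all", "rainforest", "open-habitat"):
        sub = final if group == "all" else final[
            final.species_id.map(group_of) == group]
        if len(sub):
            pct_over[group] = float(
                100.0 * (sub.weighted_hpd_mean > config.con_hpd).mean())

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_species": world.config.n_species,
        "group_counts": world.config.group_counts(),
        "grid": world.config.grid.to_dict(),
        "group_summary_2080_plus": group_summary[
            (group_summary.period == "2080") & (group_summary.co2 == "plus")
        ].to_dict(orient="records"),
        "overlap": overlap_out,
        "pct_species_weighted_hpd_over_benchmark_2080_plus": pct_over,
        "pa_proportions_2080_plus": pa_props[
            (pa_props.period == "2080") & (pa_props.co2 == "plus")
        ].to_dict(orient="records"),
        "benchmarks": {"con_hpd": config.con_hpd,
                       "rwanda_hpd": pressure.RWANDA_HPD},
    }
    return ReportBundle(
        config=config, species_exposure=exposure_df,
        exposure_consensus=exp_consensus, group_summary=group_summary,
        weighted_hpd=hpd_df, weighted_hpd_consensus=hpd_consensus,
        pa_summary=pa_df, pa_proportions=pa_props, overlap=overlap_out,
        richness=richness, report=report)


def _round_df(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(10)


def _write_bundle(bundle: ReportBundle, out: Path) -> None:
    _round_df(bundle.species_exposure).to_csv(
        out / "species_exposure.csv", index=False)
    _round_df(bundle.exposure_consensus).to_csv(
        out / "exposure_consensus.csv", index=False)
    _round_df(bundle.group_summary).to_csv(
        out / "group_summary.csv", index=False)
    _round_df(bundle.weighted_hpd).to_csv(
        out / "weighted_hpd.csv", index=False)
    _round_df(bundle.weighted_hpd_consensus).to_csv(
        out / "weighted_hpd_consensus.csv", index=False)
    _round_df(bundle.pa_summary).to_csv(out / "pa_summary.csv", index=False)
    _round_df(bundle.pa_proportions).to_csv(
        out / "pa_proportions.csv", index=False)
    (out / "report.json").write_text(json.dumps(bundle.report, indent=1))


def _write_rasters(bundle: ReportBundle, world: World, out: Path) -> None:
    grid = world.config.grid
    for group, maps in bundle.richness.items():
        prov = {"group": group, **maps.provenance,
                "config_hash": bundle.config.config_hash()}
        for name in ("richness", "losers", "proportion_lost"):
            r = Raster(grid, getattr(maps, name),
                       name=f"{name}_{group}", provenance=prov)
            write_raster(r, out / "maps" / f"{name}_{group}.tif")
    write_raster(Raster(grid, world.pa, name="pa_coverage"),
                 out / "maps" / "pa_coverage.tif")
    for period, h in world.hpd.items():
        write_raster(Raster(grid, h, name=f"hpd_{period}"),
                     out / "maps" / f"hpd_{period}.tif")


# ---------------------------------------------------------------------------
# on-disk world for the staged CLI

def write_world(world: World, config: RunConfig, out: Path) -> None:
    out = Path(out)
    config.to_yaml(out / "config.yaml")
    for key, clim in world.climates.items():
        d = out / "climate" / key.label()
        for name, arr in clim.layers.items():
            write_raster(Raster(world.config.grid, arr, name=name,
                                provenance={"scenario": key.to_dict()}),
                         d / f"{name}.tif")
    write_occurrences(world.occurrences, out / "occurrences.csv")
    for period, h in world.hpd.items():
        write_raster(Raster(world.config.grid, h, name=f"hpd_{period}"),
                     out / "hpd" / f"hpd_{period}.tif")
    write_raster(Raster(world.config.grid, world.pa, name="pa"),
                 out / "pa.tif")


def load_world(run_dir: Path) -> tuple[RunConfig, World]:
    """Reload a simulated world directory, validating completeness.

    Missing climate rasters fail loudly with the offending ScenarioKeys.
    """
    run_dir = Path(run_dir)
    config = RunConfig.from_yaml(run_dir / "config.yaml")
    wc = config.world_config()
    climates = {}
    missing = []
    keys = [ScenarioKey(BASELINE)]
    for k in wc.design.climate_keys():
        if not k.is_baseline:
            keys.append(k)
    for key in keys:
        d = run_dir / "climate" / key.label()
        try:
            layers = {n: read_raster(d / f"{n}.tif").values
                      for n in LAYER_NAMES}
        except FileNotFoundError:
            missing.append(key)
            continue
        climates[key] = ClimateLayerSet(grid=wc.grid, key=key, layers=layers)
    if missing:
        raise FileNotFoundError(
            "missing climate rasters for ScenarioKeys: "
            + ", ".join(k.label() for k in missing))
    from .rasters import read_occurrences
    occurrences = read_occurrences(run_dir / "occurrences.csv")
    hpd = {p: read_raster(run_dir / "hpd" / f"hpd_{p}.tif").values
           for p in (BASELINE, "2020", "2050", "2080")}
    pa = read_raster(run_dir / "pa.tif").values
    world = World(config=wc, climates=climates, occurrences=occurrences,
                  hpd=hpd, pa=pa)
    return config, world
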