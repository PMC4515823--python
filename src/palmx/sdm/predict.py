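"""Projection of fitted SDMs onto climate layer sets, and model persistence."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.special import expit

from ..rasters import Raster
from ..world import ClimateLayerSet, LAYER_NAMES
from .gbm import BoostedTreesModel
from .maxent import MaxentModel


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def predict_suitability(model, climate: ClimateLayerSet) -> Raster:
    """Per-cell suitability in [0, 1] for one model under one climate set.

    Maxent yields the logistic output of the exponential model; boosted
    trees the inverse-logit of the additive score.  Nodata (NaN) in any
    predictor layer propagates to the output cell.
    """
    missing = [n for n in LAYER_NAMES if n not in climate.layers]
    if missing:
        raise KeyError(f"climate set lacks predictor layer(s): {missing}")
    X = climate.matrix()
    valid = np.isfinite(X).all(axis=1)
    out = np.full(X.shape[0], np.nan)
    if valid.any():
        Xv = X[valid]
        if isinstance(model, MaxentModel):
            F = model.transform.transform(Xv)
            eta = model.score(F) if model.lam.size else np.zeros(F.shape[0])
            out[valid] = _sigmoid(eta + model.intercept)
        elif isinstance(model, BoostedTreesModel):
            out[valid] = _sigmoid(model.score(Xv))
        else:
            raise TypeError(f"unknown model type {type(model).__name__}")
    values = out.reshape(climate.grid.shape)
    species = getattr(model, "metadata", {}).get("species_id", "")
    return Raster(climate.grid, values,
                  name=f"suitability_{species}_{climate.key.label()}",
                  provenance={"species_id": species,
                              "scenario": climate.key.to_dict(),
                              "algo": model.algo})


def save_model(model, path: str | Path) -> Path:
    """Persist a fitted model as JSON; reloaded predictions are bit-identical
    (floats round-trip exactly through repr-based JSON encoding)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(model.to_dict()))
    return path


def load_model(path: str | Path):
    d = json.loads(Path(path).read_text())
    if d["algo"] == "maxent":
        return MaxentModel.from_dict(d)
    if d["algo"] == "boosted_trees":
        return BoostedTreesModel.from_dict(d)
    raise ValueError(f"unknown model algo {d['algo']!r}")
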