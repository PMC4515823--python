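"""Predictor standardisation and feature expansion.

Predictors are z-scored against the fitting universe (background plus
presence cells) and the transform is stored in the model so projection onto
future climates re-applies exactly the same scaling.  Feature expansion
offers linear, quadratic and pairwise-product terms of the standardised
predictors; constant predictor columns are dropped with a warning rather
than poisoning the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FeatureSpec:
    linear: bool = True
    quadratic: bool = True
    product: bool = False

    def to_dict(self) -> dict:
        return {"linear": self.linear, "quadratic": self.quadratic,
                "product": self.product}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(**d)


@dataclass
class FeatureTransform:
    """Captured at fit time: column order, z-scoring, kept columns."""

    names: list[str] = field(default_factory=list)
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    kept: np.ndarray | None = None  # boolean over input columns
    spec: FeatureSpec = field(default_factory=FeatureSpec)

    def fit(self, X: np.ndarray, names: list[str] | None = None) -> "FeatureTransform":
        X = np.asarray(X, dtype=float)
        self.names = list(names) if names else [f"p{j}" for j in range(X.shape[1])]
        self.means = X.mean(axis=0)
        self.sds = X.std(axis=0)
        self.kept = self.sds > 0
        if not self.kept.all():
            dropped = [n for n, k in zip(self.names, self.kept) if not k]
            warnings.warn(f"dropping constant predictor column(s): {dropped}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Standardise then expand; rows with NaN stay NaN in every feature."""
        if self.means is None:
            raise RuntimeError("transform used before fit")
        X = np.asarray(X, dtype=float)
        sds = np.where(self.kept, self.sds, 1.0)
        Z = ((X - self.means) / sds)[:, self.kept]
        blocks = []
        if self.spec.linear:
            blocks.append(Z)
        if self.spec.quadratic:
            blocks.append(Z * Z)
        if self.spec.product:
            p = Z.shape[1]
            prods = [Z[:, j] * Z[:, k] for j in range(p) for k in range(j + 1, p)]
            if prods:
                blocks.append(np.column_stack(prods))
        if not blocks:
            return np.empty((X.shape[0], 0))
        return np.column_stack(blocks)

    def feature_names(self) -> list[str]:
        kept_names = [n for n, k in zip(self.names, self.kept) if k]
        out = []
        if self.spec.linear:
            out += kept_names
        if self.spec.quadratic:
            out += [f"{n}^2" for n in kept_names]
        if self.spec.product:
            out += [f"{a}*{b}" for i, a in enumerate(kept_names)
                    for b in kept_names[i + 1:]]
        return out

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "kept": self.kept.astype(int).tolist(),
            "spec": self.spec.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureTransform":
        t = cls(spec=FeatureSpec.from_dict(d["spec"]))
        t.names = list(d["names"])
        t.means = np.array(d["means"], dtype=float)
        t.sds = np.array(d["sds"], dtype=float)
        t.kept = np.array(d["kept"], dtype=bool)
        return t
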