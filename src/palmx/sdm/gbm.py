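"""Boosted regression trees on the binomial deviance.

A small stagewise gradient-boosting machine for presence (1) vs background
(0) labels: the model score starts at the base-rate log-odds and each stage
adds a shrunken depth-limited regression tree.  Splits are chosen by
exhaustively scanning candidate thresholds on every predictor and picking
the one that minimises the EXACT binomial deviance after assigning each
child its Newton-step constant — not a squared-error surrogate on pseudo-
residuals — so a brute-force threshold scan is a well-defined oracle for the
fitted tree.  When a predictor has more distinct values than ``max_bins``
the candidate set is thinned to quantile midpoints; below that cap every
midpoint between consecutive distinct values is scanned.

Split candidates are scored with each child at its clipped Newton-step
constant -sum(g)/sum(h) from the current margins (g = p - y, h = p(1-p)).
Final leaf constants use the same Newton step, additionally step-halved in
the rare case the full step fails to reduce the leaf's exact deviance, and
clipped to +/-4.  Because a leaf value
is only accepted when it does not increase the leaf deviance and the loss is
convex, the shrunken update cannot increase it either: training deviance is
non-increasing per stage (row subsampling, available via ``bag_fraction``,
defaults to 1.0 to keep that contract exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_LEAF_VALUE = 4.0
_EPS = 1e-12


def _deviance(y: np.ndarray, f: np.ndarray) -> float:
    """Total binomial deviance sum 2*log(1 + exp(-(2y-1) f))."""
    margins = np.where(y > 0.5, f, -f)
    return float(2.0 * np.logaddexp(0.0, -margins).sum())


@dataclass
class TreeNode:
    feature: int = -1          # -1 marks a leaf
    threshold: float = 0.0
    value: float = 0.0         # leaf constant (pre-shrinkage)
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.feature < 0:
            return np.full(X.shape[0], self.value)
        out = np.empty(X.shape[0])
        go_left = X[:, self.feature] <= self.threshold
        out[go_left] = self.left.predict(X[go_left])
        out[~go_left] = self.right.predict(X[~go_left])
        return out

    def to_dict(self) -> dict:
        if self.feature < 0:
            return {"value": self.value}
        return {"feature": self.feature, "threshold": self.threshold,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "feature" not in d:
            return cls(value=float(d["value"]))
        return cls(feature=int(d["feature"]), threshold=float(d["threshold"]),
                   left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]))


def _leaf_value(y: np.ndarray, f: np.ndarray) -> float:
    """Newton step for a constant added to the margins of one leaf,
    step-halved until it does not increase the leaf's exact deviance."""
    p = 1.0 / (1.0 + np.exp(-f))
    g = (p - y).sum()
    h = (p * (1.0 - p)).sum()
    c = float(np.clip(-g / (h + _EPS), -MAX_LEAF_VALUE, MAX_LEAF_VALUE))
    d0 = _deviance(y, f)
    for _ in range(20):
        if _deviance(y, f + c) <= d0 + 1e-12 or abs(c) < 1e-12:
            break
        c *= 0.5
    else:
        c = 0.0
    return c


def _candidate_thresholds(x: np.ndarray, max_bins: int) -> np.ndarray:
    """Midpoints between consecutive distinct values, quantile-thinned when
    there are more than ``max_bins`` distinct values."""
    u = np.unique(x)
    if u.size < 2:
        return np.empty(0)
    mids = 0.5 * (u[:-1] + u[1:])
    if mids.size > max_bins:
        pos = np.linspace(0, mids.size - 1, max_bins).round().astype(int)
        mids = mids[np.unique(pos)]
    return mids


def _newton_constant(g_sum, h_sum):
    return np.clip(-g_sum / (h_sum + _EPS), -MAX_LEAF_VALUE, MAX_LEAF_VALUE)


def _best_split(X: np.ndarray, y: np.ndarray, f: np.ndarray,
                max_bins: int, min_leaf: int) -> tuple[int, float, float] | None:
    """Exhaustive exact-deviance split search over all features.

    Each candidate split is scored by the EXACT binomial deviance after
    adding the (clipped) Newton-step constant of each child to its margins.
    Returns (feature, threshold, split deviance) for the best admissible
    split, or None when nothing beats the unsplit node.  Features are
    scanned in order and candidates ascending; the first minimum wins.
    """
    p = 1.0 / (1.0 + np.exp(-f))
    d_node = _deviance(y, f + _newton_constant((p - y).sum(),
                                               (p * (1 - p)).sum()))
    best: tuple[int, float, float] | None = None
    best_dev = d_node - 1e-10
    n = y.size
    sign = np.where(y > 0.5, 1.0, -1.0)
    for j in range(X.shape[1]):
        x = X[:, j]
        thresholds = _candidate_thresholds(x, max_bins)
        if thresholds.size == 0:
            continue
        order = np.argsort(x, kind="stable")
        xs, fs, ss = x[order], f[order], sign[order]
        ps = p[order]
        g = ps - y[order]
        h = ps * (1.0 - ps)
        G, H = np.cumsum(g), np.cumsum(h)
        m = np.searchsorted(xs, thresholds, side="right")  # left-child sizes
        ok = (m >= min_leaf) & (n - m >= min_leaf)
        if not ok.any():
            continue
        thresholds, m = thresholds[ok], m[ok]
        G_L, H_L = G[m - 1], H[m - 1]
        c_L = _newton_constant(G_L, H_L)
        c_R = _newton_constant(G[-1] - G_L, H[-1] - H_L)
        in_left = np.arange(n)[:, None] < m[None, :]
        margins = fs[:, None] + np.where(in_left, c_L[None, :], c_R[None, :])
        dev = 2.0 * np.logaddexp(0.0, -ss[:, None] * margins).sum(axis=0)
        k = int(np.argmin(dev))
        if dev[k] < best_dev:
            best_dev = float(dev[k])
            best = (j, float(thresholds[k]), best_dev)
    return best


def _grow(X: np.ndarray, y: np.ndarray, f: np.ndarray, depth: int,
          max_bins: int, min_leaf: int) -> TreeNode:
    if depth <= 0 or y.size < 2 * min_leaf or y.min() == y.max():
        return TreeNode(value=_leaf_value(y, f))
    split = _best_split(X, y, f, max_bins, min_leaf)
    if split is None:
        return TreeNode(value=_leaf_value(y, f))
    j, t, _ = split
    left = X[:, j] <= t
    return TreeNode(
        feature=j, threshold=t,
        left=_grow(X[left], y[left], f[left], depth - 1, max_bins, min_leaf),
        right=_grow(X[~left], y[~left], f[~left], depth - 1, max_bins, min_leaf),
    )


@dataclass
class BoostedTreesModel:
    algo: str
    trees: list[TreeNode]
    init_score: float
    learning_rate: float
    params: dict
    train_deviance: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Additive log-odds score at raw predictor rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        f = np.full(X.shape[0], self.init_score)
        for tree in self.trees:
            f += self.learning_rate * tree.predict(X)
        return f

    def to_dict(self) -> dict:
        return {
            "algo": self.algo,
            "trees": [t.to_dict() for t in self.trees],
            "init_score": self.init_score,
            "learning_rate": self.learning_rate,
            "params": self.params,
            "train_deviance": self.train_deviance,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedTreesModel":
        return cls(
            algo=d["algo"],
            trees=[TreeNode.from_dict(t) for t in d["trees"]],
            init_score=float(d["init_score"]),
            learning_rate=float(d["learning_rate"]),
            params=d.get("params", {}),
            train_deviance=list(d.get("train_deviance", [])),
            metadata=d.get("metadata", {}),
        )


def fit_boosted_trees(presence_X: np.ndarray, background_X: np.ndarray,
                      n_trees: int = 60, depth: int = 2,
                      learning_rate: float = 0.1, bag_fraction: float = 1.0,
                      seed: int = 0, max_bins: int = 64, min_leaf: int = 5,
                      metadata: dict | None = None) -> BoostedTreesModel:
    """Fit the boosted-trees SDM on raw predictor rows (no standardisation:
    trees are invariant to monotone rescaling of predictors)."""
    presence_X = np.atleast_2d(np.asarray(presence_X, dtype=float))
    background_X = np.atleast_2d(np.asarray(background_X, dtype=float))
    if presence_X.shape[0] == 0 or background_X.shape[0] == 0:
        raise ValueError("boosted trees require both presence and background rows")
    X = np.vstack([presence_X, background_X])
    y = np.concatenate([np.ones(presence_X.shape[0]),
                        np.zeros(background_X.shape[0])])
    base_rate = y.mean()
    init = float(np.log(base_rate / (1.0 - base_rate)))
    params = {"n_trees": n_trees, "depth": depth, "bag_fraction": bag_fraction,
              "max_bins": max_bins, "min_leaf": min_leaf, "seed": seed}
    model = BoostedTreesModel(algo="boosted_trees", trees=[], init_score=init,
                              learning_rate=learning_rate, params=params,
                              metadata=dict(metadata or {}))
    f = np.full(y.size, init)
    model.train_deviance.append(_deviance(y, f))
    if learning_rate == 0.0:
        return model  # constant model at the base-rate logit
    rng = np.random.default_rng(seed)
    for _ in range(n_trees):
        if bag_fraction < 1.0:
            m = max(2 * min_leaf, int(round(bag_fraction * y.size)))
            bag = rng.choice(y.size, size=m, replace=False)
        else:
            bag = slice(None)
        tree = _grow(X[bag], y[bag], f[bag], depth, max_bins, min_leaf)
        f += learning_rate * tree.predict(X)
        model.trees.append(tree)
        model.train_deviance.append(_deviance(y, f))
    return model
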