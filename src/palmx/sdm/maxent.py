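"""Maximum-entropy (Gibbs) presence/background model.

The model is the standard exponential ("Gibbs") distribution over the cells
of a background universe: choose feature weights lambda maximising the
entropy of the cell distribution subject to the feature expectations matching
the presence sample, which is equivalent to minimising the L1-regularised
negative log-likelihood

    L(lambda) = -mean_i lambda . f(x_i)  +  log Z(lambda)  +  beta ||lambda||_1

where i runs over presence records, Z sums exp(lambda . f(z)) over the
universe (background cells plus the presence cells themselves), and beta is
the regularisation weight.  The optimisation is convex; we solve it by
splitting lambda into positive and negative parts and running bound-
constrained L-BFGS, then verify first-order (subgradient) optimality.

Suitability is reported on the logistic output scale: sigmoid(H + eta(x) -
log Z) with H the entropy of the fitted Gibbs distribution, a monotone map
of the linear score eta into [0, 1] whose typical presence value sits near
0.5 for uninformative models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .features import FeatureSpec, FeatureTransform


class ConvergenceError(RuntimeError):
    """The optimiser failed to reach first-order optimality."""


@dataclass
class MaxentModel:
    algo: str
    transform: FeatureTransform
    lam: np.ndarray
    intercept: float  # H - log Z, captured at fit time
    regularization: float
    metadata: dict = field(default_factory=dict)

    def score(self, features: np.ndarray) -> np.ndarray:
        """Linear Gibbs score eta(x) = lambda . f(x) (on expanded features)."""
        return features @ self.lam

    def to_dict(self) -> dict:
        return {
            "algo": self.algo,
            "transform": self.transform.to_dict(),
            "lam": self.lam.tolist(),
            "intercept": self.intercept,
            "regularization": self.regularization,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentModel":
        return cls(
            algo=d["algo"],
            transform=FeatureTransform.from_dict(d["transform"]),
            lam=np.array(d["lam"], dtype=float),
            intercept=float(d["intercept"]),
            regularization=float(d["regularization"]),
            metadata=d.get("metadata", {}),
        )


def fit_gibbs(F_universe: np.ndarray, presence_idx: np.ndarray,
              regularization: float = 0.0, grad_tol: float = 1e-6,
              max_iter: int = 1000) -> tuple[np.ndarray, dict]:
    """Core solver on an explicit feature matrix.

    ``F_universe`` is (cells x features) for the whole universe;
    ``presence_idx`` indexes the presence rows within it.  Returns the weight
    vector and an info dict with the Gibbs log-probabilities and diagnostics.
    Raises :class:`ConvergenceError` if the subgradient optimality residual
    exceeds ``grad_tol`` — never fails silently.
    """
    F = np.asarray(F_universe, dtype=float)
    n, p = F.shape
    if len(presence_idx) < 1:
        raise ValueError("at least one presence record is required")
    beta = float(regularization)
    if beta < 0:
        raise ValueError("regularization must be nonnegative")
    f_emp = F[presence_idx].mean(axis=0)

    if p == 0:
        logq = np.full(n, -np.log(n))
        return np.empty(0), {"log_gibbs": logq, "opt_residual": 0.0, "n_iter": 0}

    def nll_grad(lam: np.ndarray) -> tuple[float, np.ndarray]:
        eta = F @ lam
        logZ = logsumexp(eta)
        q = np.exp(eta - logZ)
        val = -f_emp @ lam + logZ
        grad = -f_emp + q @ F
        return val, grad

    # lambda = a - b with a, b >= 0 turns the L1 term into a smooth bound-
    # constrained problem solvable by L-BFGS-B.
    def obj(ab: np.ndarray) -> tuple[float, np.ndarray]:
        a, b = ab[:p], ab[p:]
        val, g = nll_grad(a - b)
        val += beta * (a.sum() + b.sum())
        return val, np.concatenate([g + beta, -g + beta])

    def residual(lam: np.ndarray) -> float:
        # subgradient optimality: |g_j + beta sign(lam_j)| at active
        # coordinates, soft-thresholded |g_j| at zeros
        _, g = nll_grad(lam)
        r = np.where(lam > 0, np.abs(g + beta),
                     np.where(lam < 0, np.abs(g - beta),
                              np.maximum(np.abs(g) - beta, 0.0)))
        return float(np.max(r)) if p else 0.0

    x0 = np.zeros(2 * p)
    n_iter = 0
    lam = np.zeros(p)
    opt_residual = residual(lam)
    # restart from the current point if L-BFGS stops on its internal rule
    # before reaching the optimality tolerance
    for _ in range(4):
        res = minimize(obj, x0, jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * (2 * p),
                       options={"maxiter": max_iter, "ftol": 1e-15,
                                "gtol": 1e-12})
        n_iter += int(res.nit)
        lam = res.x[:p] - res.x[p:]
        opt_residual = residual(lam)
        if opt_residual <= grad_tol:
            break
        x0 = res.x
    res_nit = n_iter
    if opt_residual > grad_tol:
        raise ConvergenceError(
            f"maxent optimiser did not converge: optimality residual "
            f"{opt_residual:.3e} > {grad_tol:.0e} after {res_nit} iterations")
    eta = F @ lam
    logq = eta - logsumexp(eta)
    return lam, {"log_gibbs": logq, "opt_residual": opt_residual,
                 "n_iter": res_nit}


def fit_maxent(presence_X: np.ndarray, background_X: np.ndarray,
               predictor_names: list[str] | None = None,
               feature_spec: FeatureSpec = FeatureSpec(),
               regularization: float = 0.01,
               metadata: dict | None = None) -> MaxentModel:
    """Fit the maxent SDM on raw predictor rows.

    ``presence_X`` are predictor values at occurrence cells, ``background_X``
    at the sampled background cells.  Presence cells are appended to the
    background to form the Gibbs universe.  Standardisation and feature
    expansion are captured in the returned model for later projection.
    """
    presence_X = np.atleast_2d(np.asarray(presence_X, dtype=float))
    background_X = np.atleast_2d(np.asarray(background_X, dtype=float))
    if presence_X.shape[0] < 2:
        raise ValueError("maxent requires at least 2 occurrence records")
    universe_X = np.vstack([background_X, presence_X])
    transform = FeatureTransform(spec=feature_spec).fit(universe_X, predictor_names)
    F = transform.transform(universe_X)
    presence_idx = np.arange(background_X.shape[0], universe_X.shape[0])
    lam, info = fit_gibbs(F, presence_idx, regularization)

    logq = info["log_gibbs"]
    entropy = float(-(np.exp(logq) * logq).sum())
    # intercept folds the entropy and the training normaliser into the
    # logistic output: suitability(x) = sigmoid(eta(x) + intercept)
    eta = F @ lam if lam.size else np.zeros(F.shape[0])
    logZ = float(logsumexp(eta))
    md = dict(metadata or {})
    md.update({"n_presence": int(presence_X.shape[0]),
               "n_background": int(background_X.shape[0]),
               "entropy": entropy, "opt_residual": info["opt_residual"]})
    return MaxentModel(algo="maxent", transform=transform, lam=lam,
                       intercept=entropy - logZ, regularization=regularization,
                       metadata=md)


def gibbs_probabilities(model: MaxentModel, X: np.ndarray) -> np.ndarray:
    """Normalised Gibbs distribution over the given cells (sums to 1)."""
    F = model.transform.transform(np.atleast_2d(X))
    eta = model.score(F) if model.lam.size else np.zeros(F.shape[0])
    return np.exp(eta - logsumexp(eta))
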