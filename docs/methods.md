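# Methods

This note records the models, numerical choices and known limitations of
the pipeline, in the order the stages run.

## The synthetic study system

All analyses run on an abstract equal-area grid (default 60 × 60 cells of
10 km; cell (row, col) centers at origin + (col, row)·cell size, 0-based).
No geographic CRS mathematics enters the science modules; the raster I/O
layer carries grid metadata in JSON sidecars next to single-band TIFFs
(float32, nodata −9999).

**Climate.** Six predictor fields — three temperature-like (means 24/18/30,
spatial amplitudes 6/5/4 units) and three water-balance-like (means
1000/400/80, amplitudes 400/150/40) — are sums of four seeded low-frequency
sinusoids (wavelengths one half to two domain lengths) plus small Gaussian
noise. Future fields equal the baseline plus a spatially uniform additive
drift per (pseudo-GCM, pseudo-SRES, period): by default +0.8/+1.8/+3.0
units of warming on the temperature layers for 2020/2050/2080 and drying of
6/14/25 % of each water-balance layer's amplitude, modulated by evenly
spaced GCM/SRES multipliers in [0.8, 1.2] so the ensemble spreads without
moving its central tendency. The elevated-CO₂ variant multiplies the
water-balance layers of each future period by a configurable factor
(default 1.05/1.10/1.15) — an explicit placeholder for a physiological
water-use-efficiency rescaling whose exact functional form is a
configuration choice, recorded in output provenance.

**Species.** 40 virtual species in the study's group proportions (27
rainforest, 11 open-habitat, 2 other) carry Gaussian niches: suitability is
the product over predictors of exp(−(c−μ)²/2σ²). Rainforest niches center
on the cool/wet part of each gradient, open-habitat niches on the hot/dry
part, with σ ≈ 0.36–0.56 of each layer's spatial amplitude. Occurrences
are presence-only draws of cells with probability proportional to true
suitability, without replacement (emulating unique, deduplicated
collection records); 300 records per species by default.

**HPD and reserves.** Human population density is exp(clumping × smooth
field), rescaled to a 50 people/km² baseline mean and multiplied by a
per-period growth factor (1.4/2.0/2.8 by default), so growth ≥ 1 gives
cellwise monotone trajectories by construction. The reserve network
thresholds a smooth field at its (1 − target-fraction) quantile, producing
a few contiguous reserves covering 10 % of the grid by default.

Everything is deterministic given the world seed: each artifact draws from
its own named substream, so generation order never matters.

**What the generator does not emulate.** Real occurrence data carry spatial
sampling bias, georeferencing error and taxonomic noise; real climate
surfaces have topographic fine structure and spatially *non*-uniform change;
real HPD growth is spatially heterogeneous. Passing tests on this world
demonstrate that the machinery — estimators, accounting identities,
consensus arithmetic — is correct, not that any real flora has a particular
vulnerability.

## Maximum-entropy SDM

The model is the standard Gibbs/exponential distribution over a background
universe (a seeded uniform sample of up to 10 000 cells plus the occurrence
cells): minimise the L1-regularised negative log-likelihood
−mean λ·f(xᵢ) + log Z(λ) + β‖λ‖₁. Features are z-scored predictors plus
their squares (pairwise products optional, off by default; hinge features
are deliberately out of scope — the Gibbs/regularisation mechanics, not a
particular feature zoo, define the method). The transform is stored in the
model and re-applied at projection. β defaults to 0.01 on standardised
features. Optimisation splits λ into positive and negative parts and runs
bound-constrained L-BFGS, restarting from the incumbent if the solver's
internal rule stops before the subgradient optimality residual reaches
1e−6; failure to converge raises, never silently degrades. Constant
feature columns are dropped with a warning; with no informative features
the fit is the uniform distribution. Suitability is the logistic output
sigmoid(H + λ·f(x) − log Z) with H the fitted distribution's entropy — a
monotone map of the linear score into [0, 1].

## Boosted-trees SDM

A stagewise binomial-deviance GBM on presence (1) vs background (0): start
at the base-rate log-odds, add depth-limited trees shrunk by the learning
rate (defaults: 60 trees, depth 2, rate 0.1). Split selection scans every
candidate threshold on every predictor — all midpoints between distinct
values, quantile-thinned above 64 candidates per feature — and scores each
by the *exact* deviance after giving each child its clipped (±4)
Newton-step constant −Σg/Σh; this makes a brute-force scan a well-defined
oracle for the fitted tree. Final leaf constants use the same Newton step,
step-halved in the rare case the full step fails to reduce the leaf's exact
deviance; with convex loss this guarantees non-increasing training deviance
per stage. Row subsampling is available but off by default so that
guarantee is exact. A zero learning rate yields the base-rate constant
model.

## Range masks and dispersal

Suitability surfaces are binarised at the threshold maximising the true
skill statistic over occurrence vs background cells (TSS is piecewise
constant in the threshold; ties over an optimal interval break at its
midpoint). Fixed and equal-sensitivity-specificity rules are available;
the rule and threshold are recorded in provenance. The 100-km dispersal
mask adds every cell whose center lies within 100 km Euclidean distance of
the nearest current-range cell center, boundary inclusive, via the exact
distance transform (the 100-km buffer of one cell on a 10-km grid is the
317-cell closed disc of radius 10).

## Exposure, pressure, reserves

Δ-classification is sign-only; Δ = 0 cells are "unchanged" (exact
floating-point zero, with an optional dead-band ε defaulting to 0). The
net-loss statistic (losses minus buffer gains over range size) may be
negative and is never clamped, so group means remain faithful to the cell
accounting; on a small domain the 100-km ring dwarfs compact virtual
ranges and net expansion is the expected regime. Proportion-lost community
maps divide consensus loser counts by consensus richness (mean over model
combinations of each species' per-cell indicators); cells with zero
richness are nodata, and the high-loss flag covers the closed band
[0.8, 1.0].

Weighted HPD uses suitability-share weights normalised within the mask
(the only normalisation giving people/km² units); the statistic is
invariant to uniform weight rescaling and a zero total weight raises
rather than returning 0. The threat overlay restricts to the family range
footprint (union of current ranges), flags HPD above the benchmark
(default 50.14 people/km²; a 307 people/km² reference is carried for
report annotation only) now and in the future, and reports percentages
over high-loss cells only — undefined, not zero, when no high-loss cells
exist.

Conserved suitability is the raw sum of suitability × protected fraction
over the dispersal mask (an option normalises by summed suitability; a
thresholded presence variant exists for sensitivity analysis). Baseline
and future use the same mask per dispersal scenario, so the buffered mask
admits immigration into reserves. Species are PA-unchanged when |change| <
1e−12. Group proportions classify per model combination and then average
the indicators — equivalently, the mean over combinations of
per-combination proportions — keeping the statistic-then-mean order used
everywhere: consensus always averages a finished statistic over
SDM × GCM × SRES for one period and CO₂ flag, reporting the sample
standard deviation (ddof = 1) as spread, and never averages over period or
CO₂. The alternative order (average suitability, then classify) yields
different loser counts and is intentionally not offered.

## Experiment designs used in the tests

*Niche recovery.* The recovery oracle fits the maxent model to 300
presence cells of a virtual species on a 100 × 100 world and asks whether
the climate at the predicted suitability peak lies within 0.5σ of the true
niche mean on every predictor. For this experiment the niche must be
identifiable and the sample representative: means are anchored at the
climate of a real cell (an unrealised mean is unrecoverable in principle),
and σ equals one spatial amplitude per layer so the suitable pool
(≈500–4000 effective cells) far exceeds the 300 unique-cell draws —
without-replacement sampling from a pool comparable to n forces records
into niche tails and biases any estimator. The companion
centroid-convergence test likewise compares against the sampling law's
analytic expectation (the suitability-weighted landscape mean climate),
which differs from the niche mean exactly by the landscape's asymmetry
around it.

*Directional checks.* The zero-drift world (all drifts zero, CO₂ factors
1) must yield exactly no losers, no winners, no buffer gains and all
species PA-unchanged — and does, bitwise. The adverse-drift world shifts
every temperature layer by +40 units and every water-balance layer by −6
amplitudes in all periods, so each cell's every predictor moves beyond the
realised envelope away from every niche. Its species are all
interior-niche (rainforest-type): for a species whose niche sits on the
hot/dry edge of the envelope, a hot/dry drift does not pass through any
*observable* low-suitability space, and a piecewise-constant tree model
cannot distinguish the niche optimum from points beyond it — the premise
of a uniformly adverse drift is satisfiable only for niches interior to
the envelope in the drift direction. Under that design both algorithms
produce exactly 100 % loser cells and 100 % PA losers.

*Problem sizes.* The demonstration analysis uses the 40-species, 60 × 60,
2 × 3 × 3 × 3 × 2 design throughout (≈4 minutes on one CPU); oracle
comparisons run on 2–3-cell universes and 50-point 1-D datasets; geometry
oracles on grids up to 40 × 40. These sizes were chosen so every
verification is exhaustive or near-exhaustive at desk scale.

## Known limitations

- Spatially uniform drift cannot produce the geographic redistribution
  patterns (coastal concentration, regional contrasts) a real GCM ensemble
  would; community maps on the synthetic world are structurally plausible
  but geographically arbitrary.
- The CO₂ rescaling is a multiplicative placeholder; any
  physiologically derived transform can be plugged in and is recorded in
  provenance.
- Tree-model suitability is piecewise constant, so projections beyond the
  training envelope saturate at edge-leaf values; the maxent quadratic
  declines smoothly beyond the ridge. Ensemble disagreement between the
  two algorithms is largest in exactly those extrapolation regions.
- Background size, regularisation and boosting hyperparameters are
  configuration with sensible defaults, not tuned to any dataset.
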