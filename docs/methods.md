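# Methods

## Model

For *m* log-transformed PK parameters observed per subject *j* (n subjects)
and region *k* (K regions), the model is

    θ_ijk = α_i + X_ij' β_i + τ_ij + υ_ik + ε_ijk,

with m-dimensional multivariate-normal subject deviations
τ_j ~ MVN(0, Σ_subject), pooled region deviations υ_k ~ MVN(0, Σ_region)
for the subset of parameters flagged as pooled, and cell-level residuals
ε_jk ~ MVN(0, Σ_residual). Each covariance decomposes as
diag(σ)·R·diag(σ). The natural-log transform makes the parameters
positive by construction, makes additive effects proportional ones, and
approximately equalises variance across regions.

Binding and delivery parameters use per-region fixed effects instead of
pooled υ (reference region = alphabetically first, so α_i is the
reference-region intercept): their regional profiles are set by
neuroanatomy, not exchangeable draws from a common distribution. For the
1TC (m = 2) both parameters are fixed-effect, leaving an empty pooled
block, which the implementation supports.

The residual ε absorbs both region-within-subject biological variation and
NLS estimation error; the two are not separable at the parameter level,
which is also why the parameter-level simulations do not add a second layer
of NLS noise on top of generated parameters.

Assumptions: parameters approximately log-normal; NLS estimates
approximately unbiased for the underlying quantities; a covariance
structure shared by both groups (group-specific Σ is out of scope);
proportional covariate effects. Missing subject–region cells are dropped
listwise with a warning.

## Priors

* Intercepts α_i ~ Normal(log central value from the tracer profile, 0.25).
* Covariate effects (incl. the group difference) β ~ Normal(0, 0.1).
* Region fixed-effect offsets ~ Normal(0, 5) — proper but effectively flat.
* All hierarchy SDs ~ HalfNormal(0.3).
* Correlation matrices ~ LKJ(η = 2).

Only the intercept priors are informative; `perturb_intercept_priors`
implements the stress test of shifting every intercept prior mean by
±ln 2 ≈ 0.69 at random. All settings are plain dataclass fields,
YAML-serialisable and overridable.

## Inference: collapsed ensemble sampling

Conditional on the hyperparameters φ = (σ_subject, R_subject, σ_residual,
R_residual, σ_region, R_region), every remaining unknown enters linearly
with a Gaussian prior, so the whole linear block γ (intercepts, covariate
effects, region fixed effects, pooled region deviations) and the latent τ,
ε can be marginalised in closed form. The observation vector is Gaussian
with covariance B + U P U', where B is block-diagonal per subject with
blocks J_K ⊗ Σ_subject + I_K ⊗ Σ_residual, U the design of the linear
block and P its prior covariance. Rotating the region axis with a Helmert
basis block-diagonalises each subject block into (Σ_residual +
K·Σ_subject) on the subject-mean component and Σ_residual on the K−1
contrasts, and the Woodbury/determinant lemmas reduce the likelihood to a
handful of m×m inversions plus one q×q Cholesky (q = dim of the linear
block). All data dependence is precomputed once as small quadratic-form
tensors, so one likelihood evaluation costs microseconds and is batched
across ensemble walkers.

Only φ is sampled — 12–23 dimensions for the shipped models — using
emcee's affine-invariant ensemble with differential-evolution moves (80%
DEMove, 20% DESnookerMove), initialised in a 0.05-SD ball around the
collapsed-posterior mode found by L-BFGS-B with batched finite-difference
gradients. Correlation matrices are parameterised by unconstrained
canonical partial correlations through the C-vine construction (tanh
transform), under which the LKJ prior has a simple exact density including
the Jacobian; SDs are sampled on the log scale with the half-normal prior's
Jacobian included. A hard support box (|φ| < 12, log σ > −10) prevents
overflow; its prior mass is negligible.

For every retained draw of φ, the linear block is drawn exactly from its
conditional Gaussian N(m_φ, K_φ⁻¹) (Rao–Blackwellisation), so reported
posteriors for α, β, region effects and υ are exact mixtures over the
hyperparameter posterior. This yields the same posterior as sampling the
full non-centred hierarchical parameterisation, at a fraction of the cost.
Defaults: 64 walkers, 2000 steps with the first half discarded, thinned by
4. Determinism is guaranteed given (seed, walkers, steps, backend
version).

Diagnostics: split-Rhat and effective sample size are computed per quantity
treating walkers as chains (via arviz). Because ensemble walkers interact,
this Rhat is conservative; the convergence flag defaults to 1.05 rather
than the 1.01 used for independent HMC chains, and non-convergence warns
and flags the summary rather than failing. The ensemble sampler has no
divergence concept, so the divergence count is reported as 0 by contract.
The group-difference posterior itself is largely insensitive to residual
hyperparameter autocorrelation because it is reconstructed analytically per
draw.

## Kinetic forward models and NLS

Tissue curves are analytic convolutions of mono-/bi-exponential impulse
response functions with a piecewise-linear input (AIF or reference TAC)
forced through (0, 0); the per-segment antiderivative is exact, with a
series limit for rate constants below 1e-12. Micro-constant mappings: 2TC
(K1, VND, BPP, k4) → k2 = K1/VND, k3 = k4·BPP/VND (so VT = VND + BPP);
1TC k2 = K1/VT; SRTM k2 = R1·k2′, k2a = k2/(1+BPND). Frames are evaluated
at mid-times by default; a `frame_eval="average"` switch integrates each
frame with 5-point Gauss–Legendre quadrature instead (differences are
negligible at the shipped 20-frame, 90-min schedule).

NLS fits the direct parameterisation (VND and BPP rather than k2 and k3)
by bounded trust-region least squares from 5 Latin-hypercube start points
spaced uniformly in log-parameter space within conservative default bounds
(overridable); ties break toward the lowest objective, then the lowest
start index. Non-convergence from all starts and bound-pinned estimates
are flagged, not raised. Weights follow an approximate counts model:
frame variance ∝ C_f·exp(λ t_f)/Δ_f with λ = ln 2 / half-life (default
carbon-11, 20.4 min), activities floored at 5% of the curve peak,
weights = 1/variance normalised to mean one. This is a documented,
pluggable choice; the reference weighting scheme it emulates is not
restated in the literature it comes from, so the exact formula here is
this package's own. The identifiability diagnostic is the ratio of extreme
eigenvalue magnitudes of the Gauss–Newton variance–covariance matrix
σ̂²(JᵀWJ)⁻¹ after rescaling its columns to unit Euclidean norm, with 1e6
as the ill-conditioning threshold.

## Synthetic data

The tracer profiles in `pumba.profiles` are synthetic: plausible central
values, nine-region offset profiles, SD vectors and correlation matrices
for a well-behaved carbon-11 tracer under each kinetic model, with
subject-level delivery–binding correlations of 0.5 (1TC), 0.55 (SRTM) and
0.8 (2TC) — the range reported for fitted PET datasets. They are the
package's study conditions, not estimates from any empirical sample, so
simulation outcomes are compared against the generating values and
qualitative orderings, never against any published study's exact curves.

Parameter-mode generation draws θ = α + δ·1[binding, patient] + fixed
region offsets + τ + ε directly (region effects are fixed values per
named region, not redrawn). TAC-mode generation (2TC) pushes drawn true
parameters through the forward model and adds Gaussian frame noise whose
SD follows the weighting model's variance shape — so the NLS weights are
correctly specified under the generator — scaled to 5% average relative
noise at multiplier 1, with multipliers {0.5, 1, 2, 4} as study presets
and the truth table returned alongside for oracle comparisons. What the
generator does **not** emulate: non-Gaussian count statistics, motion and
scatter artefacts, AIF measurement error, age/sex effects (deliberately
absent), or NLS bias beyond what estimation from noisy TACs induces;
passing tests therefore demonstrate internal consistency of the method
under its own assumptions, not robustness to those real-data features.

Studies derive per-replicate seeds counter-style from the master seed
(`SeedSequence((master, replicate))`), recorded in a ledger so any
replicate regenerates independently.

## Evaluation

Power and false-positive rates are estimated by fitting a density to the
replicate distributions of the 95%-interval bounds and summing
P(lower bound > 0) and P(upper bound < 0). The default estimator is a
fixed-knot maximum-likelihood log-spline: log-density = cubic B-spline
(4–10 knots at sample quantiles, extended range ±3 SD) minus its
log-normaliser, fitted by L-BFGS-B on the convex ML objective with a 1e-4
ridge; it falls back to a Silverman-bandwidth Gaussian KDE and then to the
empirical proportion, each fallback logged. Study summaries report mean
estimate, bias, mean SE, between-replicate SD and the bias/SD ratio;
correlation recovery compares generating correlations with the mean and SD
of posterior means across replicates.

## Scaled-down study sizes

Verification runs (tests and `scripts/acceptance.py`) use 20 subjects per
group, nine regions, and 20–30 replicates per condition with a reduced
sampler budget (48 walkers × 1200 steps) for replicate fits — sizes chosen
so the full verification pipeline runs in minutes on a single core while
binomial tolerances on rates remain meaningful. The full-size designs (up
to 100 per group, 250–500 replicates, error multipliers 0.5–4) are
constructible through the same `make_study` interface.

## Known limitations

* The group-difference prior Normal(0, 0.1) shrinks estimates toward zero;
  at n = 20/group this produces a visible conservative bias in the mean
  estimate across replicates (the flip side of its lower SE and
  false-positive rate).
* Correlation hyperparameters mix more slowly than everything else; at the
  reduced sampler budget their walker-wise Rhat can sit above the flag
  threshold even though the (Rao–Blackwellised) group-difference posterior
  is stable.
* Balanced designs are the optimised path; heavily unbalanced region sets
  per subject work but fall back to per-group-size precomputations.
* Group-specific covariance matrices, non-normal outcome models and
  TAC-level Bayesian estimation are out of scope.
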