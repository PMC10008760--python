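# pumba

Multivariate hierarchical Bayesian analysis of PET pharmacokinetic
parameters.

## The problem

A PET study ends, conventionally, with one number per subject and region: a
binding parameter (BP_ND, BP_P or V_T) estimated from each time activity
curve (TAC) by nonlinear least squares (NLS), which is then compared between
groups with a t test or a linear mixed-effects (LME) model. Every other
estimated parameter — blood delivery (K1 or R1), the non-displaceable
distribution volume, dissociation rates — is thrown away, even though those
parameters are correlated with binding across subjects. Because PET samples
are small and expensive, that discarded shared information is statistical
power left on the table.

This package analyses **all** NLS-estimated parameters jointly. On the
natural-log scale, the parameters θ of subject *j* in region *k* are
modelled as

    θ_ijk = α_i + X_ij' β_i + τ_ij + υ_ik + ε_ijk

    (τ_1j … τ_mj)' ~ MVNormal(0, Σ_subject)
    (υ_1k … υ_mk)' ~ MVNormal(0, Σ_region)
    (ε_1jk … ε_mjk)' ~ MVNormal(0, Σ_residual)

with a global intercept α_i and covariate effects β_i per parameter *i*
(the group difference of interest is the group coefficient on the binding
parameter), multivariate-normal subject deviations τ, region deviations υ,
and residuals ε. Binding and blood-delivery parameters get per-region
*fixed* effects instead of pooled υ, because their regional heterogeneity
does not plausibly come from a common distribution. Priors are moderately
informative normals on the intercepts, zero-centred normals on covariate
effects, half-normals on hierarchy SDs and LKJ priors on correlation
matrices. When Σ_subject carries a strong delivery–binding correlation, the
conditional uncertainty of the binding parameter shrinks, and with it the
standard error of the group difference — without touching the TAC fits
themselves.

Inference collapses everything that is conditionally Gaussian (intercepts,
covariate and region effects, subject deviations, residuals) analytically,
samples only the scale/correlation hyperparameters with an ensemble MCMC
backend (emcee), and reconstructs the linear terms exactly per posterior
draw. See `docs/methods.md` for the derivation and its assumptions.

The package also ships everything needed to exercise the claim end to end
on synthetic data: 1TC/2TC/SRTM forward models with analytic convolution,
weighted multi-start NLS with a condition-number identifiability
diagnostic, generative study presets, the LME/t-test comparators, and
power/false-positive/bias evaluation with a log-spline density estimator
for credible-interval bounds.

## Worked example

Twenty patients and twenty controls, nine regions, 2TC parameters drawn
from the synthetic tracer profile with a true group difference of 0.1 on
log BP_P (a 10.5% difference) and a true subject-level delivery–binding
correlation of 0.8:

```python
from pumba import (GenerativeConfig, build_model, extract_group_difference,
                   generate_parameter_dataset, get_profile, spec_from_profile)

profile = get_profile("synthetic-2tc")
cfg = GenerativeConfig(profile=profile, delta=0.1, n_per_group=20, seed=42)
table = generate_parameter_dataset(cfg)
summary = build_model(spec_from_profile(profile), table).fit(seed=42)
d = extract_group_difference(summary)
```

Running `python examples/02_fit_pumba.py` (which does exactly this) prints:

```
group difference on logBPP (true 0.1): 0.123 (SE 0.032)
95% credible interval: [0.059, 0.185]
as a percent difference: 13.1%  (0.1 corresponds to 10.5%)

posterior subject-level correlations (these carry the shared information):
  cor_subject[logK1,logBPP]        +0.67 +- 0.08
  ...
```

The posterior mean of the group coefficient lands within one SE of the true
0.1; the delivery–binding correlation is recovered (0.67 ± 0.08 against a
true 0.8 at this sample size), and it is precisely that correlation that
pulls the group-difference SE below what LME achieves on the binding
parameter alone (`examples/03_compare_methods.py`: mean SE 0.051 for the
joint model vs 0.068 for LME on the same replicate datasets).

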