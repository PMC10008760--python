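"""Stress-test the intercept priors by randomly halving/doubling them.

Fits the same synthetic dataset with the default priors and with every
global intercept prior mean shifted by +-0.69 (= ln 2) at random, then
compares the posterior group differences.  The group-difference inference
should be essentially unchanged: only the intercept priors are informative,
and the data dominate them.
"""

from pumba import (
    GenerativeConfig,
    build_model,
    default_priors,
    extract_group_difference,
    generate_parameter_dataset,
    get_profile,
    perturb_intercept_priors,
    spec_from_profile,
)

profile = get_profile("synthetic-2tc")
cfg = GenerativeConfig(profile=profile, delta=0.1, n_per_group=20, seed=3)
table = generate_parameter_dataset(cfg)

for label, priors in [
    ("default priors", default_priors(profile)),
    ("perturbed +-0.69", perturb_intercept_priors(default_priors(profile), seed=1)),
]:
    spec = spec_from_profile(profile, priors=priors)
    s = build_model(spec, table).fit(seed=3)
    d = extract_group_difference(s)
    print(f"{label:18s}: group difference {d.estimate:.3f} (SE {d.se:.3f}), "
          f"CI [{d.ci_low:.3f}, {d.ci_high:.3f}]")

print("\nHalving or doubling every intercept prior's central value barely moves")
print("the group-difference posterior: the priors regularise, they do not drive.")
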