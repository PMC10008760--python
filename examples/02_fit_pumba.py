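"""Fit the multivariate hierarchical model to a synthetic parameter table.

Generates log-scale PK parameters for 20 patients and 20 controls across
nine regions (2TC profile, true group difference 0.1 on log BPP), fits the
joint model, and prints the posterior group difference and the estimated
subject-level correlations that the model exploits.
"""

from pumba import (
    GenerativeConfig,
    build_model,
    extract_group_difference,
    generate_parameter_dataset,
    get_profile,
    spec_from_profile,
)

profile = get_profile("synthetic-2tc")
cfg = GenerativeConfig(profile=profile, delta=0.1, n_per_group=20, seed=42)
table = generate_parameter_dataset(cfg)

model = build_model(spec_from_profile(profile), table)
summary = model.fit(seed=42)

d = extract_group_difference(summary)
print(f"group difference on logBPP (true 0.1): {d.estimate:.3f} (SE {d.se:.3f})")
print(f"95% credible interval: [{d.ci_low:.3f}, {d.ci_high:.3f}]")
print(f"as a percent difference: {d.percent:.1f}%  (0.1 corresponds to 10.5%)")
print(f"max split-Rhat: {summary.max_rhat:.3f} over {summary.n_chains} walkers\n")

print("posterior subject-level correlations (these carry the shared information):")
for q in summary.table.index:
    if q.startswith("cor_subject"):
        row = summary.table.loc[q]
        print(f"  {q:32s} {row['mean']:+.2f} +- {row['sd']:.2f}")
print("\nThe delivery-binding correlation (logK1, logBPP; true 0.8) is what lets")
print("the joint model sharpen the group-difference estimate beyond univariate LME.")
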