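"""Simulate noisy 2TC time activity curves and refit them by multi-start NLS.

Draws true parameters for a few subjects from the synthetic 2TC profile,
pushes them through the forward model with measurement noise, fits each
curve, and prints log-scale estimation error and the condition-number
identifiability diagnostic.  Condition numbers far below 1e6 indicate
well-identified fits.
"""

import numpy as np

from pumba import (
    GenerativeConfig,
    fit_nls,
    generate_tac_dataset,
    get_profile,
    make_synthetic_aif,
)

profile = get_profile("synthetic-2tc")
cfg = GenerativeConfig(profile=profile, delta=0.1, n_per_group=2, mode="tac",
                       error_multiplier=1.0, seed=1)
tacs, truth = generate_tac_dataset(cfg)
aif = make_synthetic_aif()

print(f"{'subject':8s} {'region':16s} {'logBPP true':>11s} {'logBPP fit':>11s} "
      f"{'cond number':>12s}")
errors = []
for tac, (_, row) in zip(tacs[:8], truth.iterrows()):
    fit = fit_nls(tac, "2tc", aif, seed=0)
    err = fit.estimates["logBPP"] - row["logBPP"]
    errors.append(err)
    print(f"{tac.subject:8s} {tac.region:16s} {row['logBPP']:11.3f} "
          f"{fit.estimates['logBPP']:11.3f} {fit.condition_number:12.1f}")

print(f"\nRMS log-binding estimation error over these fits: "
      f"{np.sqrt(np.mean(np.square(errors))):.3f}")
print("This NLS error is what the residual term of the hierarchical model absorbs.")
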