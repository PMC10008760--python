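"""Estimate power from the distribution of credible-interval bounds.

Simulates 95%-interval bounds for a hypothetical method whose lower bound is
Gaussian, estimates P(interval excludes zero) with the log-spline density
estimator, and compares with the exact Gaussian answer and the raw
empirical proportion.
"""

import numpy as np
from scipy.stats import norm

from pumba import estimate_power

rng = np.random.default_rng(0)
mu, sigma = 0.5, 0.4

for n in (40, 200, 10000):
    lows = rng.normal(mu, sigma, size=n)
    highs = lows + 2.0
    power, (upper, lower) = estimate_power(lows, highs)
    empirical = np.mean(lows > 0) + np.mean(highs < 0)
    print(f"n={n:6d}: density-based power {power:.3f}, empirical {empirical:.3f}, "
          f"exact {norm.cdf(mu / sigma):.3f}")

print("\nThe density-based estimate stabilises the empirical proportion at small")
print("replicate counts; all three converge as the number of replicates grows.")
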