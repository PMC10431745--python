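"""Group-level TFCE sign-flip inference on a 1-D accuracy time course.

Builds synthetic per-subject accuracy courses with an above-chance bump
between 200 and 300 ms, runs the max-TFCE sign-flip permutation test
against the 0.5 chance level, and prints which bins survive family-wise
correction.
"""

import numpy as np

import megscenes as m

rng = np.random.default_rng(0)
n_subjects, n_bins = 20, 50
times = 10.0 * np.arange(n_bins)

courses = rng.normal(0.5, 0.04, (n_subjects, n_bins))
courses[:, 20:30] += 0.08  # effect between 200 and 300 ms

config = m.InferenceConfig(n_permutations=1000, h0=0.5, seed=7)
result = m.signflip_permutation(courses, m.Adjacency.chain(n_bins), config)

sig = times[result.significant_mask]
print(f"max observed t: {result.observed_stat.max():.2f}")
print(f"smallest attainable p: {1 / (config.n_permutations + 1):.6f}")
print(f"significant bins (FWER < {config.alpha}): {sig.min():.0f}-{sig.max():.0f} ms")
print(f"corrected p at 250 ms: {result.p_corrected[25]:.4f}")
# The significant window should bracket the planted 200-300 ms effect;
# bins outside it fail the max-TFCE correction.
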