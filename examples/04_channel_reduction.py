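"""Rank channels, ablate the montage, and find the minimum channel count.

Channels are ranked once by gradient-boosting gain (how much
inter-subject variance each channel explains), then the lowest-ranked
channel is removed step by step with the forest retrained each time.
The minimum montage is the smallest channel count whose accuracy stays
within 1 percentage point of the full-montage benchmark.
"""

from eegauth import (
    CohortSpec, ModelParams, generate_cohort, min_channels_before_drop,
    run_authentication,
)

spec = CohortSpec(n_subjects=6, n_channels=8, duration=40.0, seed=0,
                  informative_channels=(0, 1, 2))
params = ModelParams(n_trees=50, max_depth=16, seed=0)
bundle = run_authentication(generate_cohort(spec), genuine_subject=0,
                            band="gamma", params=params, seed=0)

print("channel ranking (importance fractions):")
for label in bundle.ranking.order:
    print(f"  {label:5s} {bundle.ranking.importance_of(label):.3f}")

print("\nablation curve:")
for step in bundle.steps:
    print(f"  {step.n_channels} channels -> accuracy {step.accuracy:.3f}")

n_min = min_channels_before_drop(bundle.steps, bundle.benchmark_accuracy)
print(f"\nbenchmark (all 8 channels): {bundle.benchmark_accuracy:.3f}")
print(f"minimum montage within 1 point of benchmark: {n_min} channels")
print("The planted informative channels rank highest; accuracy holds up")
print("while noise channels are removed and collapses once the planted")
print("set itself is cut into (at this demo scale the curve also shows a")
print("few points of refit jitter, which the 1-point criterion picks up).")
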