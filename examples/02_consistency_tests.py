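"""Test whether color choices within each group are non-random.

For each odor the congruent and incongruent 36-color count vectors are
tested against uniformity with a Pearson chi-square; the combined
statistic (sum, df = 70) is the per-odor headline.  Significance is
flagged at the Bonferroni threshold alpha / (groups x odors).
"""

from chromodor import (
    GeneratorConfig,
    bonferroni_threshold,
    consistency_table,
    generate_dataset,
)

dataset = generate_dataset(GeneratorConfig(seed=1))  # full 6-group study
table = consistency_table(dataset, alpha=0.05)

m = len(dataset.groups) * len(dataset.odors)
print(f"family size m = {m}, per-test threshold = "
      f"{bonferroni_threshold(0.05, m):.6f}")
combined = table[table["component"] == "combined"]
print(combined.head(8).to_string(index=False))
frac = combined["significant_bonferroni"].mean()
print(f"\n{frac:.0%} of the {len(combined)} per-odor combined tests are "
      "significant after Bonferroni correction")
# With the default kappa = 0.5 profiles, most odors show strongly
# non-uniform choice patterns, as a consistent population should.
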