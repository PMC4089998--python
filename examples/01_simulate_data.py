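"""Generate a synthetic color-odor study and write it as CSV.

The generator plants a latent color-propensity profile per (group, odor):
`kappa` controls how spiky (consistent) the profiles are and `rho` how
much groups share them.  Each simulated participant picks 3 congruent and
3 incongruent colors per odor from the 36-color palette.
"""

from chromodor import GeneratorConfig, generate_dataset, write_responses

config = GeneratorConfig(
    groups={"dutch": 20, "german": 20, "us": 22},
    kappa=0.5,   # moderate within-group consistency
    rho=0.3,     # partial cross-group sharing
    seed=1,
)
dataset = generate_dataset(config)
write_responses(dataset, "responses.csv")

print(f"groups:        {dataset.groups}")
print(f"odors:         {len(dataset.odors)}")
print(f"participants:  {dataset.n_participants}")
print(f"rows written:  {len(dataset.records)}  (= participants x odors x 6 choices)")
# Every row is one color choice; a complete trial is 3 congruent + 3
# incongruent rows with disjoint colors, which read_responses re-validates.
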