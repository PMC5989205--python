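"""Simulate one carrier family: maternal diplotype, linked reads, plasma.

Builds a DMD-like carrier mother (deletion on one X haplotype), generates
barcoded linked-read observations at the study regime and one male-fetus
plasma draw, and prints what the dataset contains.
"""

import numpy as np

from hapdose import DrawSpec, FamilyConfig, SimParams, SVMutation, simulate_family
from hapdose.simulate import DMD_REGION

config = FamilyConfig(
    name="demo-family",
    mutation=SVMutation("deletion", 31_950_000, 32_090_000, "exons 49-52 deletion"),
    transmitted="wildtype",  # the fetus inherited the wild-type haplotype
    draws=(DrawSpec(fetal_fraction=0.0566, label="6wk"),),
)

dataset = simulate_family(config, SimParams(), seed=1)
d = dataset.diplotype
reads = dataset.reads
plasma = dataset.plasma[0]

print(f"region: {d.region.chrom}:{d.region.start}-{d.region.end} ({d.region.length/1e6:.1f} Mb)")
print(f"informative het SNPs: {d.n_snps}; mutation on haplotype {d.mutation_hap}")
print(f"linked-read observations: {reads.n_obs} from {len(np.unique(reads.barcode))} gems")
print(f"mean per-SNP read depth: {reads.n_obs / d.n_snps:.0f}x")
print(f"plasma draw: {plasma.n_snps} SNPs at {int(plasma.depth.mean())}x, "
      f"true fetal fraction {dataset.truth['fetal_fractions'][0]:.2%}")
# The observation depth approximates the targeted coverage; each gem mixes
# ~10 molecules, so phasing must resolve haplotypes statistically.
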