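"""Simulate an autotetraploid breeding study and inspect its design.

Builds the default study: 8 biparental families of 11 offspring descended
from 4 shared (grand)parents (n = 92 genotyped), with ~5,100 array SNPs on
12 pseudomolecules plus the unanchored groups "00"/"UN".
"""

import numpy as np

from tetrapanel import SimConfig
from tetrapanel.simulate import simulate_dataset

sim = simulate_dataset(SimConfig(seed=7))
g = sim.genotypes

print(f"samples: {g.n_samples} "
      f"({(sim.metadata['role'] == 'offspring').sum()} offspring + "
      f"{(sim.metadata['family'] == 'ancestor').sum()} ancestors)")
print(f"markers: {g.n_markers} on chromosomes "
      f"{sorted(set(sim.marker_map['chrom']), key=str)}")
print(f"missing calls: {np.isnan(g.dosages).mean():.2%}")

counts = np.array([np.sum(g.dosages == d) for d in range(5)], dtype=float)
print("dosage class frequencies (0..4):",
      np.round(counts / counts.sum(), 3))
# The five classes are the tetraploid allelic states AAAA..aaaa; a real
# array reports exactly these plus missing calls.

print("\ntrait summary (all samples):")
print(sim.phenotypes[["tuber_number", "tuber_weight_total",
                      "tuber_weight_avg", "audpc"]].describe().round(1))
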