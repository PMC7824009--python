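"""SNP filter chain and windowed LD pruning to target panel sizes.

Reproduces the marker-reduction arm of the pipeline: missingness filter
(<= 10 missing calls), probe-identity filter (>= 97%), MAF filter (>= 0.05),
diploidization, then per-pseudomolecule r^2 pruning (window 50 SNPs, step
10) bisected to hit requested panel sizes.
"""

from tetrapanel import SimConfig
from tetrapanel import io as tio
from tetrapanel import ldprune as lp
from tetrapanel.simulate import simulate_dataset

sim = simulate_dataset(SimConfig(seed=7))

g = sim.genotypes
print(f"input markers:          {g.n_markers}")
g = tio.filter_missingness(g, max_missing=10)
print(f"after missingness<=10:  {g.n_markers}")
g = tio.filter_identity(g, sim.identity, min_pident=97.0)
print(f"after identity>=97%:    {g.n_markers}")
g = tio.filter_maf(g, min_maf=0.05)
print(f"after MAF>=0.05:        {g.n_markers}")

dip = tio.diploidize(g)           # tetraploid dosages -> 0/1/2 codes
maf = tio.maf(g)                  # MAF on tetraploid dosages, for tie-breaks

for target in (500, 1500, 2000):
    thr, sub = lp.subset_for_target_size(dip, sim.marker_map, target,
                                         maf_for_ties=maf)
    spacing = lp.spacing_report(sub, sim.marker_map).dropna().mean()
    print(f"target {target:>4}: retained {sub.size:>4} at r2 <= {thr:.3f}, "
          f"mean inter-SNP spacing {spacing / 1e6:.2f} Mb")
# A smaller panel needs a stricter threshold and spreads the surviving
# markers further apart -- the mean spacing grows as the panel shrinks.
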