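"""Choose which clones of a large field population to genotype.

A field trial phenotypes thousands of clones, but only ~11 per family can
be genotyped at high throughput. The choice standardizes four traits, runs
a pooled PCA, takes the component dominated by the disease trait (AUDPC),
and picks clones at evenly spaced quantiles of that axis within each family
— an even spread of resistance phenotypes rather than a random draw.
"""

from tetrapanel import SimConfig
from tetrapanel import phenotypes as ph
from tetrapanel.simulate import simulate_population, simulate_traits

cfg = SimConfig(seed=13, offspring_per_family=120, loci_per_chrom=40,
                loci_per_unanchored=8, missing_rate=0.0,
                frac_high_missing=0.0)
genotypes, gmap, metadata, _ = simulate_population(cfg)
phenos, _ = simulate_traits(genotypes, metadata, cfg)
field = phenos[phenos["family"] != "ancestor"]
print(f"field population: {len(field)} clones in "
      f"{field['family'].nunique()} families")

chosen = ph.select_representatives(field, k_per_family=11,
                                   guide_trait="audpc")
print(f"selected for genotyping: {len(chosen)} clones "
      f"(11 x {field['family'].nunique()} families)")

sel = field[field["sample_id"].isin(chosen)]
print("\nAUDPC spread, family F1:")
print(f"  field   : {field[field.family == 'F1']['audpc'].min():.0f} .. "
      f"{field[field.family == 'F1']['audpc'].max():.0f}")
print(f"  selected: {sel[sel.family == 'F1']['audpc'].min():.0f} .. "
      f"{sel[sel.family == 'F1']['audpc'].max():.0f}")
# The selected 11 sit at even quantiles of the disease-dominated PCA axis,
# so the genotyped subset covers the bulk of the cross's resistance range
# instead of clustering near its mean.
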