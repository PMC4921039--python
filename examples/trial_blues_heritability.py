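"""Per-year trial mixed model: genotype BLUEs and broad-sense heritability.

Fits y_ijk = mu + G_i + S_j + B_k(j) + GS_ij + e_ijk by REML for one
trait-year (genotype fixed; location, block-in-location and G x location
random), extracts the genotype BLUEs that feed the association scan, and
computes per-location H^2 = s2_G / (s2_G + s2_e / r) on a genotype-mean
basis.
"""

import warnings

import canegwas as cg

warnings.simplefilter("ignore")

config = cg.SimConfig(seed=1)
markers, truth = cg.simulate_population(config)
phenos = cg.simulate_trials(markers, truth, config)

fit = cg.fit_trial_model(phenos, "CY", 1)
print("variance components (kg/plot)^2:")
for name, value in fit.variance_components.items():
    print(f"  {name:>10s} = {value:8.1f}")

blues = cg.compute_blues(fit).values[("CY", 1)]
t_ha = cg.convert_cy_units(blues.to_numpy())
print(f"BLUEs: {len(blues)} genotypes, "
      f"{t_ha.min():.1f} to {t_ha.max():.1f} t/ha "
      "(the phenotypic values used for GWAS)")

for loc in ("L1", "L2"):
    h = cg.compute_heritability(phenos, "CY", 1, loc)
    print(f"H2 at {loc}: {h.h2:.2f}  "
          f"(s2_G={h.sigma2_g:.0f}, s2_e={h.sigma2_e:.0f}, r={h.replicates:.0f})")
# High H2 means the trial data are precise enough for association mapping.

corr = cg.trait_correlations(cg.compute_blue_table(phenos))
print("between-year genetic correlations, cane yield:")
for a, b in ((0, 1), (1, 2), (0, 2)):
    print(f"  year {a} vs {b}: r = {corr.loc[('CY', a), ('CY', b)]:.2f}")
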