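"""Simulate a study-scale breeding panel and its field trials.

Builds the default synthetic panel — 88 clones in uneven full-sib
families, 1745 dominant presence/absence markers on 107 linkage groups,
two traits (cane yield in kg/plot, sugar content in %) measured in a
2-location x 3-block RCBD over 3 crop cycles — and prints what it made.
"""

import numpy as np

import canegwas as cg

config = cg.SimConfig(seed=1)
markers, truth = cg.simulate_population(config)
phenos = cg.simulate_trials(markers, truth, config)

freq = cg.presence_frequency(markers)
print(f"panel: {markers.n_genotypes} clones x {markers.n_markers} markers, "
      f"{truth.family_of.nunique()} families")
print(f"band frequencies span [{freq.min():.2f}, {freq.max():.2f}] "
      "(markers below 0.1 or above 0.9 would be MAF-filtered)")
print(f"planted QTL per trait: "
      f"{ {t: ids for t, ids in truth.qtl_markers.items()} }")
print(f"trial records: {len(phenos.records)} plots "
      f"(= 88 clones x 2 locations x 3 blocks x 3 years x 2 traits)")
cy = phenos.subset(trait="CY", year=1)["value"]
print(f"first-ratoon cane yield across plots: mean {cy.mean():.0f} kg/plot "
      f"(~{cg.convert_cy_units(cy.mean()):.0f} t/ha), sd {cy.std():.0f}")
# The truth object records which markers carry effects and how large they
# are, so downstream analyses can be scored against a known answer.
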