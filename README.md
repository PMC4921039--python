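# canegwas

Mixed-model genome-wide association mapping for breeding populations of
clonally propagated, polyploid crops genotyped with **dominant
presence/absence markers** (DArT, TRAP). The motivating setting is a
sugarcane selection panel: ~90 elite clones from crosses between the best
parents, phenotyped for cane yield (CY, kg plot⁻¹) and sugar content
(SC, %) in replicated trials at two locations over three successive crop
cycles (plant cane, first and second ratoon).

The package is used from Python (see `examples/`); a thin `canegwas`
command-line interface mirrors each stage and runs the whole pipeline
from a YAML config.

## What it computes

1. **Trial mixed model, per harvest year** (REML):

   `y_ijk = μ + G_i + S_j + B_k(j) + GS_ij + ε_ijk`

   with genotype `G_i` fixed and location `S_j`, block-within-location
   `B_k(j)` and genotype×location `GS_ij` random. Genotype **BLUEs**
   (not BLUPs, to avoid double shrinkage) are the phenotypic values for
   mapping. Broad-sense heritability per location on a genotype-mean
   basis: `H² = σ²_G / (σ²_G + σ²_ε / r)`.

2. **Dominant-marker QC**: band frequency `f`, MAF filter
   (`min(f, 1−f) ≥ 0.1`), duplicate-column detection.

3. **Diversity**: Dice dissimilarity `1 − 2a/(2a+b+c)` over shared band
   presences and a Saitou–Nei neighbor-joining tree (Newick export).

4. **Population structure**: one marker per linkage group (band
   frequency closest to 0.5), PCA with binomial `√(f(1−f))` scaling, and
   sequential **Tracy–Widom** tests (Patterson-style moment
   normalisation; the TW₁ distribution is evaluated as the Fredholm
   determinant of the Airy kernel) to pick the `k` significant axes. The
   standardised axis scores form the random-effect design `Q`.

5. **Association scan**: for every marker,

   `Y = Xβ + Qυ + e`,  `υ ~ N(0, σ²_u I_k)`,

   with the variance ratio `λ = σ²_u/σ²_e` profiled by exact REML
   through an eigenvalue decomposition (EMMA-style). By default λ is
   estimated once under the null model and reused per marker (EMMAX/P3D;
   `lambda_mode="exact"` re-profiles per marker). Wald test against
   `F(1, n−q)`; two-stage Benjamini–Hochberg FDR (candidates `q ≤ 0.05`,
   reported set `q ≤ 0.01`); Schweder–Spjøtvoll uniform-QQ diagnostics.

6. **Multi-QTL model**: stepwise-forward selection over the reported
   markers (entry by Wald `P < 0.01` given markers already retained, λ
   re-profiled at every step), yielding **allelic substitution effects**
   (ASE); CY effects are converted from kg plot⁻¹ to t ha⁻¹ using the
   48 m² plot (3 rows × 10 m × 1.6 m), i.e. ×10/48; a negative ASE means
   band *absence* is the favourable allele.

7. **Synthetic panels with known truth** (`simdata`): family-structured
   dominant markers from a Gaussian band-liability model with exact
   band-frequency conditioning, planted QTL with year-scaled effects,
   and multi-environment trial phenotypes with configurable variance
   components — the test bed for every statistical guarantee above.

## Worked example

`python examples/association_scan.py` simulates an 88-clone panel in
which one marker (here `M0912`) explains 25% of the BLUE variance, then
runs QC → trial model → structure → scan → multi-QTL:

```
planted QTL: M0912, allelic effect 2.00 trait units
scan: 1000 markers tested with k=3 structure axes; 2 candidates (q<=0.05), 1 reported (q<=0.01)
top associations:
           beta        se             p         q
M0912  2.224339  0.393913  2.067597e-07  0.000207
M0831  1.948569  0.446043  3.476827e-05  0.017384
M0814 -2.594616  0.705953  4.124660e-04  0.137489
QQ diagnostics: max |observed - expected| = 0.039 (near 0 under a well-calibrated null apart from the QTL)
multi-QTL model (ASE = trait change per band presence):
             ase        se         p favorable_allele
M0912   1.919252  0.379077  0.000002         presence
M0831   1.472348  0.406936  0.000503         presence
planted effect 2.00 vs estimated 1.92 +/- 0.38
```

The planted QTL is the top association by orders of magnitude, survives
the stringent FDR stage, and its joint-model ASE (1.92 ± 0.38) covers
the planted effect (2.00). The other examples walk through panel
simulation, the trial model/BLUEs/H², and diversity + structure; each
prints a line explaining what its numbers mean.

The same pipeline runs from the shell:

```bash
canegwas run --config config.yaml     # simulate -> ... -> multiqtl + manifest
canegwas scan --blues blues.tsv --genotypes geno.tsv --q q.tsv \
    --trait CY --year 0 --fdr 0.05 --report-fdr 0.01 --out out/
```

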