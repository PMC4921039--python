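# Methods

This note records the statistical models, the synthetic-data design, the
numerical choices and the known limitations of `canegwas`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Trial model and BLUEs

Each harvest year is analysed independently with

y_ijk = μ + G_i + S_j + B_k(j) + GS_ij + ε_ijk,

genotype fixed, the rest random with independent variances
(σ²_S, σ²_B, σ²_GS, σ²_ε). REML is computed on the profile scale: each
variance is parameterised as a log ratio γ_c = σ²_c/σ²_ε (non-negativity
by construction, so no boundary projection is needed), the residual
variance is profiled out analytically, and L-BFGS-B maximises the
restricted likelihood from three starts (γ = 0.1, 1, 10 for all
components), keeping the best optimum. Each likelihood evaluation uses
the Woodbury identity on the stacked random-effect design, so the cost
is O(n·r²) for r random-effect levels rather than O(n³). Ratios driven
to the lower bound (γ ≤ e⁻¹²) are reported as exactly zero. The
convergence tolerance is effectively machine precision on the
log-likelihood; the reported restricted likelihood follows the Harville
convention (includes the +½ log|X′X| term), which makes it directly
comparable with the eigenvalue form used by the scan.

The genotype design is cell-mean coded, so the fixed-effect estimates
are the BLUEs themselves; in a balanced complete design they coincide
with raw genotype means exactly (VX lies in the column space of X), a
property the tests assert to 1e-8. BLUEs, not BLUPs, feed the scan:
the scan applies its own mixed model, and shrinking twice would bias
effect estimates downward. Missing plots are handled by full likelihood
on the observed records; no imputation.

Heritability is computed per location-year from y = μ + block(random) +
genotype(random) + ε, as H² = σ²_G/(σ²_G + σ²_ε/r) with r the number of
blocks per genotype (harmonic mean if unbalanced). Whether block belongs
in this model is a design choice (kept here: it absorbs spatial
replicate effects that would otherwise inflate σ²_ε).

Trait utilities: SC% = 0.98·pol% − 0.28·brix%; cane yield converts from
kg plot⁻¹ to t ha⁻¹ via ×10/area with a default 48 m² plot
(3 rows × 10 m × 1.6 m inter-row spacing).

## Marker QC

For a dominant band with presence frequency f, MAF is operationalised as
min(f, 1−f); a marker is kept iff min(f, 1−f) ≥ 0.1, boundary inclusive
(with a 1e-12 slack so the boundary is symmetric in floating point:
1−0.9 < 0.1 by 2e-17). Missing calls are excluded from the frequency
denominator; markers over 20% missing are flagged. Duplicate detection
groups exactly identical call vectors (including the missing pattern); a
column and its complement are *not* grouped, because band phase is
unknowable for dominant markers.

## Diversity

Dice dissimilarity 1 − 2a/(2a+b+c) counts only band presences (a shared,
b/c private), over markers observed in both clones; shared absences are
uninformative for dominant data. A pair with no band observed in either
clone has an undefined index and raises an error rather than returning a
silent value. Neighbor joining follows Saitou–Nei (Q-criterion,
standard branch lengths); ties in Q are broken by the lexicographically
smallest sorted pair of node labels (internal nodes inherit their
smaller child label), making the output invariant to input permutation.
Negative branch-length estimates are clamped to zero with the deficit
moved to the sister branch so the joined pair distance is preserved; the
tree records how many clamps occurred. Trees are exported as Newick and
re-parsed with dendropy for path-length computations.

## Population structure

The PCA uses a marker subset independent of the scan's markers — one per
linkage group, choosing within each group the marker with band frequency
closest to 0.5 (the most informative dominant marker), exact ties broken
by a seeded draw — so the structure term cannot absorb QTL effects.
Columns are mean-imputed at f, centred, and scaled by √(f(1−f))
(binomial normalisation; plain centering available). Scores are the
projections U·s from the SVD of the standardised matrix, with a
deterministic sign convention (largest-magnitude loading positive).

Axis significance uses sequential Tracy–Widom tests with the
moment-based effective marker count

m̂ = (n′+1)·S₁² / ((n′−1)·S₂ − S₁²),  l = p′·λ₁/S₁,
μ = (√(m̂−1)+√n′)²/m̂,
σ = ((√(m̂−1)+√n′)/m̂)·(1/√(m̂−1)+1/√n′)^{1/3},

testing (l−μ)/σ against TW₁ at α = 0.05, decrementing the sample count
per tested axis, and stopping at the first non-significant axis. The
TW₁ CDF itself is computed numerically as the Fredholm determinant
F₁(s) = det(I − A_s) of the Airy kernel A_s(x,y) = Ai(x+y+s) on (0,∞),
discretised by 80-point Gauss–Legendre quadrature on [0, 20]; this
reproduces published percentiles (e.g. 0.9793 at the 95th) to ~1e-10,
and the test suite checks the 5% point against the published value. The
decision is invariant to rescaling the data (l, m̂ are scale-free).

The k retained score columns are centred and standardised to unit
variance (not eigenvalue-weighted), so a single shared variance
component σ²_u across axes is meaningful; with k = 0 the scan degrades
to ordinary least squares exactly.

## Association scan

Per marker, Y = Xβ + Qυ + e with X = [1, marker] and υ ~ N(0, σ²_u·I_k),
i.e. V = σ²_e(I + λ·QQ′), λ = σ²_u/σ²_e. The REML profile of λ is exact:
the restricted likelihood is written through the nonzero eigenvalues of
S·QQ′·S (S the OLS residual projector), obtained from the k×k Gram
matrix of SQ, so a profile costs O(nk²). The score equation is evaluated
on a 100-point grid over log λ ∈ [−10, 10]; every sign-change bracket is
refined by Brent root finding and the maximiser over stationary points,
boundary values and the λ→0 limit is kept. Oracle tests verify the
profile against a dense 10⁵-point full-matrix grid search.

By default the scan estimates λ once under the intercept-only null model
and holds it fixed for every marker (EMMAX/P3D). This is a deliberate
choice, not only a speed optimisation: REML operates on the residual
space of the fixed effects, so re-profiling λ per marker removes exactly
the structure contrast from the data whenever the tested marker is
collinear with a structure axis — λ̂ collapses to zero there and
confounded markers reach spurious significance. Simulation with a
two-family panel showed the per-marker variant inflating the
false-discovery rate several-fold while the null-model variant stayed
calibrated; `lambda_mode="exact"` remains available for panels without
marker–structure collinearity, and the single-marker `fit_marker` API
profiles λ exactly. Each marker is tested on its complete cases (≥ 10,
non-constant) with a two-sided Wald test of β against F(1, n−2).

Multiple testing: Benjamini–Hochberg step-up q-values per trait-year
family (years are analysed independently). Two stages: candidates at
q ≤ 0.05; a pruned reported set at q ≤ 0.01. QQ diagnostics plot sorted
p-values against (i−0.5)/m.

## Multi-QTL model

Candidates (the scan's reported set) are ordered by scan p-value and
added one at a time to a joint mixed model that keeps Qυ throughout,
re-profiling λ after every design change. A candidate is retained iff
the Wald p-value of its coefficient given the markers already retained
is below the (liberal) entry threshold 0.01; candidates linearly
dependent on the retained design (residual norm ≤ 1e-8 relative) are
skipped as collinear. One forward pass, no backward elimination; earlier
entries are not re-tested. The final coefficients are the allelic
substitution effects; cane-yield ASEs are reported in t ha⁻¹ (×10/48)
and negative ASEs flagged absence-favourable. The few missing calls a
selected marker may have are mean-imputed at its band frequency, since
the joint model needs a complete design.

## Synthetic data

The generator emulates the study conditions: 88 clones in 30 full-sib
families of uneven size (one ~12-clone and one ~6-clone elite progeny
plus many 2–3-clone crosses), 1745 dominant markers with band
frequencies uniform on [0.1, 0.9] assigned round-robin to 107 linkage
groups, 2 locations × 3 blocks (RCBD) × 3 crop cycles, and two traits.

**Markers.** Bands come from a Gaussian liability: per marker, each
family receives a shared deviate and each clone an individual deviate
(shares w and 1−w, default w = 0.55), and the round(p·n) highest-liability
clones carry the band. Conditioning on the carrier count pins every
realised band frequency to its target — an explicit design decision: at
n = 88 unconditioned Bernoulli draws would routinely push realised
frequencies outside the configured range, and with few families a
parental-configuration model quantises band frequencies onto a coarse
lattice that starves the frequency-stratified PCA sample of structured
markers. The family share w was calibrated so the leading PCA axis of a
default panel explains ≈7.5% of marker variance — the subtle structure
an elite panel shows (full-sib band co-segregation is further diluted in
a highly polyploid genome, where a band reports "at least one copy"
across many homo(eo)logous alleles); w = 0.55 corresponds to a full-sib
band correlation around 0.4. Under this default a study-scale panel
yields 2–3 Tracy–Widom-significant axes depending on the draw.

**Phenotypes.** One plot record per genotype × location × block × year ×
trait:

value = μ_year + Σ_m x_m·β_m·ω_year + family + individual + g×year
        + location + block(location) + g×location + residual,

each random term drawn from its configured variance. Year-to-year
genetic correlation arises from the shared QTL + polygenic part against
the year-specific g×year term. Default variance components and effect
sizes were set from the study system's printed summaries: CY year means
229/361/408 kg plot⁻¹ (≈48/75/85 t ha⁻¹) and SC 9.2/10.6/10.9%, CVs
near 0.1–0.2, per-location H² in the 0.3–0.84 band, between-year genetic
correlations in the 0.4–0.8 band, and multi-QTL allelic effects of a few
t ha⁻¹ (CY) and a few tenths of a percent (SC). An optional missing
fraction deletes plots at random.

**Scenario helpers.** `heritability_config(h2)` solves σ²_ε for a target
H² at r blocks with purely polygenic genetics. `null_scenario_config()`
builds the calibration panel: two families, no QTL, family deviate = 25%
of genetic variance — moderate, kinship-like confounding of the kind the
PCA correction is designed for, rather than two discretely diverged
subpopulations (under strong discrete confounding with a single noisy
1-df structure contrast, *any* PCA-based correction under-corrects; see
Limitations). `power_scenario(r2)` plants one QTL whose effect is solved
from its realised band frequency to explain an exact share of the BLUE
variance; the QTL band is population-segregating (carriers uniform, not
family-structured) so the scenario measures detection power for an
effect of known size rather than convolving it with kinship confounding,
which the calibration scenario characterises separately.

**What the generator does not emulate.** No chromosome-level meiosis or
LD decay (markers are exchangeable within the family covariance), no
allele dosage, no aneuploidy, no spatial field trend, no half-sib
pedigree links across families. Passing tests therefore demonstrate the
statistical machinery under family-type covariance and exact frequency
control, not robustness to LD structure or dosage effects in real
panels.

## Verified guarantees

The acceptance tests compute, at realistic sizes: REML oracle agreement
(20 instances vs a 10⁵-point grid), OLS degeneration to 1e-8,
null-scan calibration (mean KS over 20 two-family panels) with BH
false-discovery control, ≥80% detection of a 25%-variance QTL over 50
replicates with ~nominal 2-SE ASE coverage, balanced-design BLUE
identity to 1e-8, mean H² recovery within ±0.1 at targets 0.3/0.6/0.8,
exact NJ additivity on random additive trees, Tracy–Widom size ≤10% on
pure-noise panels, and the 48 kg plot⁻¹ → 10 t ha⁻¹ conversion. Under
the global null, BH's any-rejection rate equals the nominal α (Simes'
identity), so the FDP check is asserted as consistency with the nominal
rate (one-sided binomial) rather than a sample mean strictly below a
boundary it sits on.

## Numerical choices and degenerate inputs

- Variance ratios live on a log scale in [e⁻¹², e⁸]; bound-pinned
  ratios are reported as zero. Rank-deficient fixed designs raise a
  named error rather than silently dropping columns.
- The scan's perfect-fit edge (se = 0) reports p = 0 with an infinite
  Wald statistic rather than dividing by zero.
- Q entirely inside the fixed-effect column space (e.g. k = 0, or a
  marker identical to the single axis) degrades to OLS explicitly.
- All simulation randomness flows from `numpy.random.default_rng`
  seeded per scenario; identical seeds give byte-identical pipeline
  outputs (manifest included; no timestamps are written).

## Problem sizes

The test suite and the acceptance script run the pipeline at the study's
own scale (88 × 1745; 1000–2000 markers in the Monte-Carlos) with
replicate counts of 20–50 per scenario and 200 for the Tracy–Widom size
check — enough replicates that each Monte-Carlo mean is estimated to a
few percent, which the assertions' tolerances reflect.

## Limitations

- Under strong *discrete* population splits the structure variance is a
  1-df quantity; its REML estimate is noisy and the scan under-corrects
  in replicates where the realised contrast is large. This is inherent
  to modelling structure with a handful of PCA axes, and is why the
  calibration scenario (and the intended use) is subtle, kinship-like
  structure. A marker-based kinship matrix (GRM) alternative is out of
  scope for this version.
- The per-marker exact-REML mode loses FDR control when markers are
  collinear with structure axes (see Association scan); it is kept as an
  option because it is slightly more powerful when no such collinearity
  exists.
- Dominant 0/1 calls discard dosage; effects are per band presence.
- Location variance in a 2-location trial has a single degree of
  freedom: its REML estimate is upward-biased under truncation at zero
  and cannot be recovered accurately — the BLUEs (the quantity carried
  forward) are unaffected in balanced designs.
- The entry rule of the multi-QTL model is forward-only; markers that
  become non-significant after later additions are reported with their
  final joint-model p-values but not removed.
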