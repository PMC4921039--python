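"""Synthetic breeding-panel generator with known truth.

Emulates the data layout of a sugarcane selection panel: ~88 clones in
full-sib families of uneven size (a couple of large elite-parent progenies
plus many small crosses), ~1745 dominant presence/absence markers with band
frequencies in [0.1, 0.9], and multi-environment trials in a randomized
complete-block design (2 locations x 3 blocks) repeated over 3 crop cycles.

Markers are simulated conditional on their target band frequency through
a Gaussian band liability: per marker, each family receives a shared
deviate and each clone an individual deviate, and the round(p * n)
clones with the highest liability carry the band.  Conditioning on the
carrier count pins every realised band frequency to its target, while
the family share of the liability gives bands the within-family
co-segregation the population-structure analysis must detect; the share
is calibrated so the leading PCA axis of a default panel explains ~7.5%
of marker variance, the subtle structure typical of an elite breeding
pool (band co-segregation of full sibs is further diluted in a highly
polyploid genome, where a band reports "at least one copy" across many
homo(eo)logous alleles).

Phenotypes decompose as

    value = mu_year + sum_m x_m beta_m(year) + family + individual
            + genotype x year + location + block(location) + G x E + residual

with every random term drawn from its configured variance.  Year-to-year
genetic correlation arises from the shared QTL/polygenic part against the
year-specific genotype x year term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import MarkerMatrix
from .pheno import PhenotypeTable

__all__ = [
    "VarianceComponents",
    "TraitSim",
    "SimConfig",
    "SimTruth",
    "simulate_population",
    "simulate_trials",
    "heritability_config",
    "null_scenario_config",
    "power_scenario",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class VarianceComponents:
    """Variances of the simulated random terms, in squared trait units."""

    location: float = 0.0        # sigma2_S
    block: float = 0.0           # sigma2_B, blocks nested in locations
    gxe: float = 0.0             # sigma2_GS, genotype x location
    residual: float = 1.0        # sigma2_eps, plot error
    family: float = 0.0          # shared polygenic deviate per family
    individual: float = 0.0      # individual polygenic deviate
    genotype_year: float = 0.0   # year-specific genetic deviate

    def validate(self, trait: str) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ConfigurationError(
                    f"variance_components.{name} for trait {trait!r} is "
                    f"negative ({v})")


@dataclass(frozen=True)
class TraitSim:
    """Per-trait simulation settings.

    ``year_means`` gives the trait mean per crop cycle; ``qtl_effects`` the
    base allelic effects of the planted QTL (trait units per band
    presence); ``year_scale`` multiplies the effects per year.
    """

    name: str
    year_means: tuple
    qtl_effects: tuple
    year_scale: tuple
    variance: VarianceComponents


def _default_traits() -> dict:
    # Cane yield in kg per plot (a 48 m2 plot; ~4.8 kg/plot per t/ha).
    cy = TraitSim(
        name="CY",
        year_means=(229.0, 361.0, 408.0),
        qtl_effects=(40.0, -40.0, 30.0, -25.0, 25.0),
        year_scale=(0.8, 1.0, 1.2),
        variance=VarianceComponents(location=400.0, block=150.0, gxe=350.0,
                                    residual=4400.0, family=400.0,
                                    individual=500.0, genotype_year=900.0),
    )
    # Sugar content in %.
    sc = TraitSim(
        name="SC",
        year_means=(9.22, 10.62, 10.88),
        qtl_effects=(0.5, -0.45, 0.4, -0.35, 0.3),
        year_scale=(0.8, 1.0, 1.2),
        variance=VarianceComponents(location=0.15, block=0.05, gxe=0.08,
                                    residual=0.9, family=0.06,
                                    individual=0.08, genotype_year=0.2),
    )
    return {"CY": cy, "SC": sc}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic breeding panel and its trials."""

    n_genotypes: int = 88
    n_families: int = 30
    n_markers: int = 1745
    n_linkage_groups: int = 107
    band_freq_range: tuple = (0.1, 0.9)
    qtl_per_trait: int = 5
    n_locations: int = 2
    n_blocks: int = 3
    n_years: int = 3
    seed: int = 0
    traits: dict = field(default_factory=_default_traits)
    family_sizes: tuple | None = None
    missing_fraction: float = 0.0
    #: share of the latent band liability carried by the family deviate;
    #: controls how strongly bands co-segregate within full-sib families.
    #: The default reproduces the subtle structure of an elite panel
    #: (leading PCA axis explaining ~7.5% of marker variance at the
    #: default panel dimensions).
    family_band_correlation: float = 0.55

    def validate(self) -> None:
        for name in ("n_genotypes", "n_families", "n_markers",
                     "n_linkage_groups", "n_locations", "n_blocks",
                     "n_years"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        lo, hi = self.band_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(
                f"band_freq_range must lie within (0, 1), got {self.band_freq_range}")
        if self.qtl_per_trait < 0:
            raise ConfigurationError("qtl_per_trait must be >= 0")
        if self.qtl_per_trait > self.n_markers:
            raise ConfigurationError(
                "qtl_per_trait exceeds n_markers: planted QTL must be a "
                "subset of simulated markers")
        if self.n_families > self.n_genotypes:
            raise ConfigurationError("n_families exceeds n_genotypes")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigurationError("missing_fraction must be in [0, 1)")
        if not 0.0 <= self.family_band_correlation < 1.0:
            raise ConfigurationError(
                "family_band_correlation must be in [0, 1)")
        for trait, ts in self.traits.items():
            ts.variance.validate(trait)
            for attr in ("year_means", "year_scale"):
                if len(getattr(ts, attr)) < self.n_years:
                    raise ConfigurationError(
                        f"traits[{trait!r}].{attr} shorter than n_years")
            if len(ts.qtl_effects) < self.qtl_per_trait:
                raise ConfigurationError(
                    f"traits[{trait!r}].qtl_effects shorter than qtl_per_trait")
        if self.family_sizes is not None:
            if sum(self.family_sizes) != self.n_genotypes:
                raise ConfigurationError(
                    "family_sizes must sum to n_genotypes")


@dataclass
class SimTruth:
    """Ground truth of a simulated panel, for recovery tests."""

    qtl_markers: dict                 # trait -> list of marker ids
    qtl_effects: dict                 # (trait, year) -> effects (trait units)
    family_of: pd.Series              # genotype id -> family id
    variance_components: dict         # trait -> VarianceComponents
    band_frequency: pd.Series         # marker id -> target band frequency

    def validate_against(self, markers: MarkerMatrix) -> None:
        for trait, ids in self.qtl_markers.items():
            unknown = [i for i in ids if i not in markers.marker_ids]
            if unknown:
                raise ValueError(
                    f"truth references unknown markers for {trait!r}: {unknown}")


def _family_sizes(config: SimConfig, rng) -> np.ndarray:
    """Uneven family sizes: two large elite-parent progenies, rest small."""
    if config.family_sizes is not None:
        return np.asarray(config.family_sizes, dtype=int)
    n, f = config.n_genotypes, config.n_families
    sizes = np.ones(f, dtype=int)
    rest = n - f
    if f >= 3 and rest > 6:
        big = min(rest // 3, 11)
        sizes[0] += big
        sizes[1] += min(rest - big, max(big // 2, 1))
        rest -= big + int(sizes[1] - 1)
    # spread the remainder round-robin over the small families
    i = 2 if f >= 3 else 0
    order = np.arange(f)
    while rest > 0:
        sizes[order[i % f]] += 1
        i += 1
        rest -= 1
    return sizes


def simulate_population(config: SimConfig):
    """Simulate a family-structured dominant-marker panel.

    Returns the marker matrix and a :class:`SimTruth` with the planted QTL,
    their per-year effects, the family assignment and the target band
    frequencies.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sizes = _family_sizes(config, rng)
    fam_labels = np.repeat([f"F{i + 1:02d}" for i in range(len(sizes))], sizes)
    genotype_ids = [f"G{i + 1:03d}" for i in range(config.n_genotypes)]
    family_of = pd.Series(fam_labels, index=genotype_ids, name="family")

    lo, hi = config.band_freq_range
    freqs = rng.uniform(lo, hi, size=config.n_markers)
    n_fam = len(sizes)
    fam_index = np.repeat(np.arange(n_fam), sizes)

    # Band liability: family deviate + individual deviate; the round(p*n)
    # genotypes with the highest liability carry the band.  This pins each
    # realised band frequency to its target while giving bands the
    # within-family co-segregation (correlation ~ family_band_correlation)
    # the structure analysis must detect.
    w = config.family_band_correlation
    n = config.n_genotypes
    calls = np.zeros((n, config.n_markers))
    for j, p in enumerate(freqs):
        u_fam = rng.normal(size=n_fam)
        liability = np.sqrt(w) * u_fam[fam_index] \
            + np.sqrt(1.0 - w) * rng.normal(size=n)
        c = min(max(int(round(p * n)), 1), n - 1)
        carriers = np.argpartition(-liability, c - 1)[:c]
        calls[carriers, j] = 1.0

    marker_ids = [f"M{j + 1:04d}" for j in range(config.n_markers)]
    groups = [f"LG{(j % config.n_linkage_groups) + 1:03d}"
              for j in range(config.n_markers)]
    meta = pd.DataFrame({"source": "DArT", "linkage_group": groups},
                        index=marker_ids)
    matrix = MarkerMatrix(pd.DataFrame(calls, index=genotype_ids,
                                       columns=marker_ids), meta)

    # plant QTL among mid-frequency markers so they survive the MAF filter
    band = pd.Series(freqs, index=marker_ids, name="band_frequency")
    eligible = band[(band >= 0.2) & (band <= 0.8)].index.to_numpy()
    if eligible.size < config.qtl_per_trait * len(config.traits):
        eligible = band.index.to_numpy()
    qtl_markers = {}
    qtl_effects = {}
    for trait, ts in config.traits.items():
        picked = rng.choice(eligible, size=config.qtl_per_trait,
                            replace=False)
        qtl_markers[trait] = [str(m) for m in picked]
        base = np.asarray(ts.qtl_effects[: config.qtl_per_trait], dtype=float)
        for yi in range(config.n_years):
            qtl_effects[(trait, yi)] = base * ts.year_scale[yi]

    truth = SimTruth(
        qtl_markers=qtl_markers, qtl_effects=qtl_effects,
        family_of=family_of,
        variance_components={t: ts.variance for t, ts in config.traits.items()},
        band_frequency=band,
    )
    return matrix, truth


def simulate_trials(markers: MarkerMatrix, truth: SimTruth,
                    config: SimConfig, seed: int | None = None,
                    return_effects: bool = False):
    """Simulate multi-environment trial phenotypes for a panel.

    One record per genotype x location x block x year x trait; the balanced
    record count is n_genotypes x n_locations x n_blocks x n_years x
    n_traits, reduced at random by ``config.missing_fraction``.
    Deterministic given the seed (defaults to ``config.seed + 1``).
    """
    config.validate()
    truth.validate_against(markers)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    geno = list(markers.genotype_ids)
    n = len(geno)
    fam = truth.family_of.reindex(geno)
    if fam.isna().any():
        raise ValueError("truth families do not cover all genotypes")
    fam_codes, fam_levels = pd.factorize(fam)
    locs = [f"L{i + 1}" for i in range(config.n_locations)]
    blocks = [f"B{i + 1}" for i in range(config.n_blocks)]
    years = list(range(config.n_years))

    rows = []
    effects_log = {}
    for trait, ts in config.traits.items():
        vc = ts.variance
        qtl_ids = truth.qtl_markers.get(trait, [])
        Xq = markers.calls[qtl_ids].to_numpy(dtype=float) if qtl_ids \
            else np.zeros((n, 0))
        fam_dev = rng.normal(0.0, np.sqrt(vc.family), size=len(fam_levels))
        ind_dev = rng.normal(0.0, np.sqrt(vc.individual), size=n)
        g_shared = fam_dev[fam_codes] + ind_dev
        for yi, year in enumerate(years):
            beta = truth.qtl_effects.get((trait, yi),
                                         np.zeros(Xq.shape[1]))
            g_qtl = Xq @ beta
            g_year = rng.normal(0.0, np.sqrt(vc.genotype_year), size=n)
            genetic = g_qtl + g_shared + g_year
            loc_eff = rng.normal(0.0, np.sqrt(vc.location),
                                 size=config.n_locations)
            blk_eff = rng.normal(0.0, np.sqrt(vc.block),
                                 size=(config.n_locations, config.n_blocks))
            gxe_eff = rng.normal(0.0, np.sqrt(vc.gxe),
                                 size=(n, config.n_locations))
            resid = rng.normal(0.0, np.sqrt(vc.residual),
                               size=(n, config.n_locations, config.n_blocks))
            mu = ts.year_means[yi]
            for li, lc in enumerate(locs):
                for bi, bk in enumerate(blocks):
                    vals = (mu + genetic + loc_eff[li] + blk_eff[li, bi]
                            + gxe_eff[:, li] + resid[:, li, bi])
                    for gi, g in enumerate(geno):
                        rows.append((g, lc, bk, year, trait, vals[gi]))
            effects_log[(trait, year)] = {
                "genetic": pd.Series(genetic, index=geno),
                "qtl": pd.Series(g_qtl, index=geno),
                "shared": pd.Series(g_shared, index=geno),
                "location": loc_eff, "block": blk_eff,
                "gxe": gxe_eff, "residual": resid,
            }

    table = pd.DataFrame(rows, columns=["genotype", "location", "block",
                                        "year", "trait", "value"])
    if config.missing_fraction > 0:
        keep = rng.random(len(table)) >= config.missing_fraction
        table = table[keep].reset_index(drop=True)
    out = PhenotypeTable(table)
    if return_effects:
        return out, effects_log
    return out


def heritability_config(h2: float, sigma2_g: float = 4.0, n_blocks: int = 3,
                        n_genotypes: int = 88, seed: int = 0,
                        sigma2_block: float = 0.2) -> SimConfig:
    """Single-location, single-year config planted at a target H^2.

    The genetic variance is purely polygenic (individual deviates, no QTL)
    and the residual variance solves H^2 = s2_g / (s2_g + s2_e / r) for
    r = n_blocks.
    """
    if not 0.0 < h2 < 1.0:
        raise ConfigurationError("h2 must be in (0, 1)")
    sigma2_e = sigma2_g * n_blocks * (1.0 - h2) / h2
    trait = TraitSim(
        name="Y", year_means=(10.0,), qtl_effects=(), year_scale=(1.0,),
        variance=VarianceComponents(block=sigma2_block, residual=sigma2_e,
                                    individual=sigma2_g),
    )
    return SimConfig(n_genotypes=n_genotypes, n_families=n_genotypes,
                     n_markers=10, n_linkage_groups=10, qtl_per_trait=0,
                     n_locations=1, n_blocks=n_blocks, n_years=1, seed=seed,
                     traits={"Y": trait})


def null_scenario_config(seed: int = 0, n_genotypes: int = 88,
                         n_markers: int = 2000, n_families: int = 2,
                         family_variance: float = 0.5,
                         individual_variance: float = 1.5,
                         residual: float = 3.0) -> SimConfig:
    """Global-null panel with planted family structure and no QTL.

    Defaults give a two-family panel whose shared family deviate accounts
    for a quarter of the genetic variance — moderate, kinship-like
    structure of the kind PCA correction is designed for (and elite
    breeding panels show), rather than two discretely diverged
    subpopulations.  Used for scan calibration checks.
    """
    trait = TraitSim(
        name="Y", year_means=(10.0,), qtl_effects=(), year_scale=(1.0,),
        variance=VarianceComponents(block=0.2, residual=residual,
                                    family=family_variance,
                                    individual=individual_variance),
    )
    return SimConfig(n_genotypes=n_genotypes, n_families=n_families,
                     n_markers=n_markers, n_linkage_groups=107,
                     qtl_per_trait=0, n_locations=1, n_blocks=3, n_years=1,
                     seed=seed, traits={"Y": trait})


def power_scenario(seed: int = 0, r2: float = 0.25, n_genotypes: int = 88,
                   n_markers: int = 1000, n_families: int = 30):
    """Panel with one planted QTL explaining ``r2`` of the BLUE variance.

    The QTL is planted on an unstructured band (carriers drawn uniformly
    across the panel at frequency 0.5, not co-segregating with families):
    the scenario isolates the scan's detection power for a marker effect
    of known size, whereas a family-co-segregating causal band convolves
    power with kinship confounding — partial absorption by the structure
    term and inflated effect-estimator variance — which the calibration
    scenario characterises separately.  The allelic effect is solved from
    the realised band frequency so that beta^2 f(1-f) equals
    r2 / (1 - r2) times the remaining BLUE variance (polygenic + BLUE
    error).  Returns (markers, truth, phenotypes, config); the single
    trait is named "Y".
    """
    if not 0.0 < r2 < 1.0:
        raise ConfigurationError("r2 must be in (0, 1)")
    vc = VarianceComponents(block=0.2, residual=3.0, family=0.5,
                            individual=1.5)
    trait = TraitSim(name="Y", year_means=(10.0,), qtl_effects=(1.0,),
                     year_scale=(1.0,), variance=vc)
    n_blocks = 3
    config = SimConfig(n_genotypes=n_genotypes, n_families=n_families,
                       n_markers=n_markers, n_linkage_groups=107,
                       qtl_per_trait=1, n_locations=1, n_blocks=n_blocks,
                       n_years=1, seed=seed, traits={"Y": trait})
    markers, truth = simulate_population(config)
    qtl = truth.qtl_markers["Y"][0]
    rng = np.random.default_rng(config.seed + 7)
    col = np.zeros(n_genotypes)
    col[rng.choice(n_genotypes, size=n_genotypes // 2, replace=False)] = 1.0
    markers.calls[qtl] = col
    f = markers.calls[qtl].mean()
    var_rest = vc.family + vc.individual + vc.residual / n_blocks
    beta = np.sqrt(r2 / (1.0 - r2) * var_rest / (f * (1.0 - f)))
    truth.qtl_effects[("Y", 0)] = np.array([beta])
    phenos = simulate_trials(markers, truth, config)
    return markers, truth, phenos, config
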