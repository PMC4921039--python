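"""Field-trial phenotype analysis.

Each harvest year is analysed independently with the trial mixed model

    y_ijk = mu + G_i + S_j + B_k(j) + GS_ij + e_ijk

where the genotype effect ``G_i`` is fixed and location ``S_j``, block
within location ``B_k(j)`` and genotype-by-location ``GS_ij`` are random.
Genotype BLUEs from this model are the phenotypic values carried into the
association scan (BLUEs rather than BLUPs, so that genetic values are not
shrunk twice once the scan itself applies a mixed model).  Broad-sense
heritability is computed per location on a genotype-mean basis as

    H^2 = sigma2_G / (sigma2_G + sigma2_e / r)

with ``r`` the number of replicates.  Trait utilities cover the sugar
content formula SC% = 0.98 pol% - 0.28 brix% and the conversion of cane
yield from kg per plot to t per hectare.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._linmix import reml_variance_ratios

__all__ = [
    "PhenotypeTable",
    "TrialModelFit",
    "BlueTable",
    "HeritabilityEstimate",
    "fit_trial_model",
    "compute_blues",
    "compute_blue_table",
    "compute_heritability",
    "sc_from_brix_pol",
    "convert_cy_units",
    "trait_correlations",
    "DEFAULT_PLOT_AREA_M2",
]

#: default plot area: 3 rows x 10 m long x 1.6 m inter-row spacing
DEFAULT_PLOT_AREA_M2 = 3 * 10 * 1.6

_COLUMNS = ["genotype", "location", "block", "year", "trait", "value"]


@dataclass
class PhenotypeTable:
    """Plot-level trait observations.

    One record per (genotype, location, block, year, trait); block ids are
    nested within locations.  Values are in trait units (kg per plot for
    cane yield, % for sugar content).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        self.records = self.records[_COLUMNS].reset_index(drop=True)
        key = ["genotype", "location", "block", "year", "trait"]
        if self.records.duplicated(key).any():
            dup = self.records[self.records.duplicated(key)].iloc[0]
            raise ValueError(f"duplicate plot record: {dup[key].to_dict()}")

    def subset(self, trait=None, year=None, location=None) -> pd.DataFrame:
        df = self.records
        if trait is not None:
            df = df[df["trait"] == trait]
        if year is not None:
            df = df[df["year"] == year]
        if location is not None:
            df = df[df["location"] == location]
        return df

    @property
    def traits(self) -> list:
        return sorted(self.records["trait"].unique())

    @property
    def years(self) -> list:
        return sorted(self.records["year"].unique())

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class TrialModelFit:
    """REML fit of the per-year trial model for one trait."""

    trait: str
    year: object
    mu: float
    genotype_effects: pd.Series        # centred fixed effects G_i
    blues: pd.Series                   # mu + G_i (original trait scale)
    blue_se: pd.Series
    variance_components: dict          # sigma2_S, sigma2_B, sigma2_GS, sigma2_eps
    loglik: float
    converged: bool
    dropped_terms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("negative variance component")


@dataclass
class BlueTable:
    """Per-genotype BLUEs, columns indexed by (trait, year)."""

    values: pd.DataFrame
    se: pd.DataFrame | None = None

    @property
    def genotype_ids(self) -> pd.Index:
        return self.values.index

    def column(self, trait, year) -> pd.Series:
        return self.values[(trait, year)]

    def to_tsv(self, path) -> None:
        flat = self.values.copy()
        flat.columns = [f"{t}:{y}" for t, y in flat.columns]
        flat.index.name = "genotype"
        flat.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "BlueTable":
        flat = pd.read_csv(path, sep="\t", index_col=0)
        cols = [tuple(c.split(":", 1)) for c in flat.columns]
        # years written as integers round-trip as integers
        cols = [(t, int(y) if y.lstrip("-").isdigit() else y) for t, y in cols]
        flat.columns = pd.MultiIndex.from_tuples(cols, names=["trait", "year"])
        return cls(flat)


@dataclass
class HeritabilityEstimate:
    trait: str
    year: object
    location: object
    sigma2_g: float
    sigma2_e: float
    replicates: float
    h2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"H2 out of [0, 1]: {self.h2}")


def _indicator(labels) -> tuple[np.ndarray, list]:
    labels = pd.Series(labels).astype(str)
    levels = sorted(labels.unique())
    Z = (labels.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    return Z, levels


def fit_trial_model(data: PhenotypeTable, trait, year) -> TrialModelFit:
    """Fit the per-year trial mixed model for one trait by REML.

    With a single location the location and genotype-by-location terms are
    dropped (recorded in ``dropped_terms``) and a warning is issued.
    """
    df = data.subset(trait=trait, year=year)
    if df.empty:
        raise ValueError(f"no records for trait={trait!r}, year={year!r}")
    genotypes = sorted(df["genotype"].astype(str).unique())
    if len(genotypes) < 2:
        raise ValueError("trial model needs at least 2 genotypes")
    X, _ = _indicator(df["genotype"])          # cell-mean coding: BLUE_i = beta_i
    y = df["value"].to_numpy(dtype=float)

    loc = df["location"].astype(str)
    blk = loc + "/" + df["block"].astype(str)  # blocks nested in locations
    gxl = df["genotype"].astype(str) + "/" + loc
    dropped = []
    names = []
    Z_blocks = []
    if loc.nunique() >= 2:
        for nm, lab in (("sigma2_S", loc), ("sigma2_B", blk), ("sigma2_GS", gxl)):
            Z, _ = _indicator(lab)
            Z_blocks.append(Z)
            names.append(nm)
    else:
        warnings.warn("single location: dropping location and G x location "
                      "terms", stacklevel=2)
        dropped = ["sigma2_S", "sigma2_GS"]
        Z, _ = _indicator(blk)
        Z_blocks.append(Z)
        names.append("sigma2_B")

    fit = reml_variance_ratios(y, X, Z_blocks)
    if not fit.converged:
        warnings.warn(f"trial model for {trait}/{year} did not converge",
                      stacklevel=2)
    comps = {nm: float(g * fit.sigma2_e) for nm, g in zip(names, fit.ratios)}
    for nm in dropped:
        comps[nm] = float("nan")
    comps["sigma2_eps"] = float(fit.sigma2_e)

    blues = pd.Series(fit.beta, index=genotypes, name="blue")
    mu = float(blues.mean())
    comps_clean = {k: (0.0 if np.isnan(v) else v) for k, v in comps.items()}
    return TrialModelFit(
        trait=trait, year=year, mu=mu,
        genotype_effects=blues - mu, blues=blues,
        blue_se=pd.Series(fit.se, index=genotypes, name="se"),
        variance_components=comps_clean, loglik=fit.loglik,
        converged=fit.converged, dropped_terms=dropped,
    )


def compute_blues(fit: TrialModelFit) -> BlueTable:
    """Genotype BLUEs (mu + G_i) for one trait-year, with standard errors."""
    if not fit.converged:
        raise ValueError("cannot extract BLUEs from a non-converged fit")
    cols = pd.MultiIndex.from_tuples([(fit.trait, fit.year)],
                                     names=["trait", "year"])
    vals = pd.DataFrame({cols[0]: fit.blues})
    ses = pd.DataFrame({cols[0]: fit.blue_se})
    vals.columns = cols
    ses.columns = cols
    return BlueTable(vals, ses)


def compute_blue_table(data: PhenotypeTable) -> BlueTable:
    """BLUEs for every trait-year combination present in the data."""
    pieces = []
    ses = []
    for trait in data.traits:
        for year in sorted(data.subset(trait=trait)["year"].unique()):
            bt = compute_blues(fit_trial_model(data, trait, year))
            pieces.append(bt.values)
            ses.append(bt.se)
    values = pd.concat(pieces, axis=1)
    return BlueTable(values, pd.concat(ses, axis=1))


def compute_heritability(data: PhenotypeTable, trait, year,
                         location) -> HeritabilityEstimate:
    """Broad-sense heritability on a genotype-mean basis for one location.

    Model per location-year: y = mu + block (random) + genotype (random) + e,
    estimated by REML; r is the number of blocks per genotype (harmonic mean
    when unbalanced).
    """
    df = data.subset(trait=trait, year=year, location=location)
    if df.empty:
        raise ValueError(f"no records for {trait}/{year}/{location}")
    reps = df.groupby("genotype")["value"].count()
    r = stats.hmean(reps)
    if r < 2:
        raise ValueError("heritability needs >= 2 replicates per genotype")
    y = df["value"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    Zb, _ = _indicator(df["block"])
    Zg, _ = _indicator(df["genotype"])
    fit = reml_variance_ratios(y, X, [Zb, Zg])
    sigma2_b, sigma2_g = (float(g * fit.sigma2_e) for g in fit.ratios)
    sigma2_e = float(fit.sigma2_e)
    h2 = sigma2_g / (sigma2_g + sigma2_e / r) if sigma2_g + sigma2_e > 0 else 0.0
    return HeritabilityEstimate(trait=trait, year=year, location=location,
                                sigma2_g=sigma2_g, sigma2_e=sigma2_e,
                                replicates=float(r), h2=float(h2))


def sc_from_brix_pol(pol_pct, brix_pct):
    """Sugar content (%) from Pol and Brix readings: 0.98 pol - 0.28 brix."""
    pol = np.asarray(pol_pct, dtype=float)
    brix = np.asarray(brix_pct, dtype=float)
    if (pol < 0).any() or (brix < 0).any():
        raise ValueError("pol and brix percentages must be non-negative")
    out = 0.98 * pol - 0.28 * brix
    return float(out) if out.ndim == 0 else out


def convert_cy_units(kg_per_plot, plot_area_m2: float = DEFAULT_PLOT_AREA_M2):
    """Convert cane yield from kg per plot to t per hectare.

    t/ha = kg/plot * 10 / plot_area_m2; the default 48 m2 plot is
    3 rows x 10 m at 1.6 m inter-row spacing.
    """
    if plot_area_m2 <= 0:
        raise ValueError(f"plot area must be positive, got {plot_area_m2}")
    x = np.asarray(kg_per_plot, dtype=float)
    if (x < 0).any():
        raise ValueError("cane yield must be non-negative")
    out = x * 10.0 / plot_area_m2
    return float(out) if out.ndim == 0 else out


def trait_correlations(blues: BlueTable) -> pd.DataFrame:
    """Pairwise Pearson correlations of genotype means across trait-years.

    Computed on genotypes present in both columns of each pair; a
    zero-variance column yields NaN entries and a warning rather than a
    silent zero.
    """
    vals = blues.values
    if vals.dropna(how="any").shape[0] < 3:
        raise ValueError("need >= 3 genotypes in common for correlations")
    sd = vals.std()
    if (sd == 0).any():
        flat = [f"{t}:{y}" for t, y in vals.columns[sd == 0]]
        warnings.warn(f"zero-variance columns give undefined correlations: "
                      f"{flat}", stacklevel=2)
    return vals.corr(method="pearson")
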