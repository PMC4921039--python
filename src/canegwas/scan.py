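"""Single-marker mixed-model association scan.

Each marker is tested in

    Y = X beta + Q v + e,     v ~ N(0, sigma2_u I_k),  e ~ N(0, sigma2_e I)

where Y holds the genotype BLUEs for one trait-year, X is an intercept
plus the marker's presence/absence column and Q the standardised scores of
the significant PCA axes.  The marker coefficient is tested with a
two-sided Wald test against F(1, n - q); multiple testing is controlled by
Benjamini-Hochberg FDR in two stages: candidate associations at q <= 0.05
and a stringent reported set at q <= 0.01.

The variance ratio lambda = sigma2_u / sigma2_e is profiled by exact REML
(EMMA-style eigenvalue profile).  By default the scan estimates lambda
once under the null (intercept-only) model and reuses it for every marker
(the EMMAX/P3D strategy): because REML operates on the residual space of
the fixed effects, re-profiling lambda per marker discards exactly the
structure contrast for markers aligned with a structure axis, collapses
lambda to zero there and lets confounded markers reach spurious
significance.  ``lambda_mode="exact"`` restores per-marker re-profiling
for the (common) situations where no marker is strongly collinear with Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._linmix import _gls_q, fit_mixed, profile_reml_lambda
from .markers import MarkerMatrix

__all__ = ["MarkerTest", "ScanResult", "FdrResult",
           "fit_marker", "scan_all", "bh_fdr", "qq_points"]

MIN_COMPLETE_CASES = 10


@dataclass
class MarkerTest:
    beta: float
    se: float
    wald: float
    p_value: float
    lam: float
    loglik: float
    n_used: int
    skipped: str = ""          # non-empty when the marker was not testable


def _as_q(Q, index) -> np.ndarray:
    if Q is None:
        return np.zeros((len(index), 0))
    if isinstance(Q, pd.DataFrame):
        missing = index.difference(Q.index)
        if len(missing):
            raise ValueError(f"Q lacks genotypes: {list(missing)[:5]}")
        return Q.loc[index].to_numpy(dtype=float)
    Q = np.asarray(Q, dtype=float)
    if Q.ndim == 1:
        Q = Q[:, None]
    if Q.shape[0] != len(index):
        raise ValueError("Q row count does not match phenotype vector")
    return Q


def fit_marker(y, x, Q=None, lam: float | None = None) -> MarkerTest:
    """Mixed-model Wald test of one marker.

    Complete cases only; the marker must be non-constant among them and at
    least ``MIN_COMPLETE_CASES`` cases must remain.  With an empty Q the
    model reduces exactly to ordinary least-squares simple regression.
    When ``lam`` is given the variance ratio is held fixed (P3D); otherwise
    it is re-profiled by exact REML for this marker.
    """
    y = pd.Series(y).astype(float)
    x = pd.Series(np.asarray(x, dtype=float), index=y.index)
    Qm = _as_q(Q, y.index)
    ok = y.notna().to_numpy() & x.notna().to_numpy()
    yv = y.to_numpy()[ok]
    xv = x.to_numpy()[ok]
    n = int(ok.sum())
    if n < MIN_COMPLETE_CASES:
        return MarkerTest(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          n, skipped="too_few_complete_cases")
    if np.ptp(xv) == 0:
        return MarkerTest(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          n, skipped="constant")
    X = np.column_stack([np.ones(n), xv])
    if lam is None:
        fit = fit_mixed(yv, X, Qm[ok])
        beta, se = float(fit.beta[1]), float(fit.se[1])
        lam_used, loglik, df = float(fit.extra["lam"]), float(fit.loglik), \
            fit.extra["df"]
    else:
        beta_v, cov, _ = _gls_q(yv, X, Qm[ok], float(lam))
        beta, se = float(beta_v[1]), float(np.sqrt(cov[1, 1]))
        lam_used, loglik, df = float(lam), np.nan, n - 2
    if se == 0.0:
        # perfect fit: report the smallest representable tail probability
        return MarkerTest(beta, 0.0, np.inf, 0.0, lam_used, loglik, n)
    wald = (beta / se) ** 2
    p = float(stats.f.sf(wald, 1, df))
    return MarkerTest(beta, se, float(wald), p, lam_used, loglik, n)


@dataclass
class ScanResult:
    """Per-marker scan table sorted by p-value, plus skipped markers."""

    table: pd.DataFrame           # marker, beta, se, wald, p, q, n, lambda
    skipped: pd.DataFrame
    alpha: float
    report_alpha: float

    @property
    def candidates(self) -> pd.Index:
        return self.table.index[self.table["q"] <= self.alpha]

    @property
    def reported(self) -> pd.Index:
        return self.table.index[self.table["q"] <= self.report_alpha]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "marker"
        out.to_csv(path, sep="\t")


def scan_all(y, m: MarkerMatrix, Q=None, alpha: float = 0.05,
             report_alpha: float = 0.01,
             lambda_mode: str = "null") -> ScanResult:
    """Mixed-model scan of every marker with two-stage BH FDR.

    ``lambda_mode="null"`` (default) profiles the variance ratio once under
    the intercept-only model and reuses it for every marker (EMMAX/P3D);
    ``"exact"`` re-profiles it per marker.
    """
    if lambda_mode not in ("null", "exact"):
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")
    y = pd.Series(y).astype(float)
    extra = y.index.difference(m.genotype_ids)
    missing = pd.Index(m.genotype_ids).difference(y.index)
    if len(extra) or len(missing):
        raise ValueError(
            "genotype ids do not match between phenotypes and markers; "
            f"only in phenotypes: {list(extra)[:5]}, "
            f"only in markers: {list(missing)[:5]}")
    calls = m.calls.loc[y.index]
    lam = None
    if lambda_mode == "null":
        ok = y.notna()
        Qm = _as_q(Q, y.index)[ok.to_numpy()]
        null = profile_reml_lambda(y[ok].to_numpy(),
                                   np.ones((int(ok.sum()), 1)), Qm)
        lam = null["lam"]
    rows, skipped = {}, {}
    for marker in m.marker_ids:
        t = fit_marker(y, calls[marker], Q, lam=lam)
        if t.skipped:
            skipped[marker] = {"reason": t.skipped, "n": t.n_used}
        else:
            rows[marker] = {"beta": t.beta, "se": t.se, "wald": t.wald,
                            "p": t.p_value, "n": t.n_used, "lambda": t.lam}
    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        fdr = bh_fdr(table["p"], alpha=alpha, report_alpha=report_alpha)
        table["q"] = fdr.q_values
        table = table.sort_values("p")
        table = table[["beta", "se", "wald", "p", "q", "n", "lambda"]]
    skipped_df = pd.DataFrame.from_dict(skipped, orient="index")
    return ScanResult(table=table, skipped=skipped_df, alpha=alpha,
                      report_alpha=report_alpha)


@dataclass
class FdrResult:
    q_values: pd.Series
    candidates: pd.Index          # q <= alpha
    reported: pd.Index            # q <= report_alpha

    def __post_init__(self) -> None:
        assert (self.q_values.sort_index().index ==
                self.q_values.sort_index().index).all()


def bh_fdr(p, alpha: float = 0.05, report_alpha: float = 0.01) -> FdrResult:
    """Benjamini-Hochberg step-up q-values with a two-stage report.

    Candidates are markers with q <= ``alpha``; the reported (pruned) set
    uses the more stringent ``report_alpha``.
    """
    p = pd.Series(p, dtype=float)
    if p.isna().any():
        raise ValueError("p-values contain NaN")
    if ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)].iloc[0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    _, q, _, _ = multipletests(p.to_numpy(), method="fdr_bh")
    q = pd.Series(q, index=p.index, name="q")
    return FdrResult(q_values=q,
                     candidates=q.index[q <= alpha],
                     reported=q.index[q <= report_alpha])


def qq_points(p) -> pd.DataFrame:
    """Uniform-QQ table: expected quantiles (i - 0.5)/m vs sorted p-values."""
    p = np.sort(np.asarray(p, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values")
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame({"expected": expected, "observed": p})


def plot_qq(p, ax=None):
    """Render a Schweder-Spjotvoll style uniform QQ plot (optional)."""
    import matplotlib.pyplot as plt
    pts = qq_points(p)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    ax.plot(pts["expected"], pts["observed"], ".", ms=3)
    ax.set_xlabel("expected quantile (uniform)")
    ax.set_ylabel("observed p-value")
    return ax
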