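"""Stepwise-forward multi-QTL model over scan-significant markers.

Markers that survived the stringent FDR stage of the scan enter a single
joint mixed model one at a time, in order of their scan p-value.  The
random structure term Q v is retained throughout and the variance ratio is
re-profiled after every change of the fixed design.  A candidate is kept
iff the Wald p-value of its coefficient, given the markers already
retained, is below the (deliberately liberal) entry threshold of 0.01;
candidates linearly dependent on the retained design are skipped.  Forward
selection only, no backward elimination: earlier entries are not re-tested
after later additions.

The coefficient of a retained marker in the final joint model is its
allelic substitution effect (ASE): the expected trait change associated
with band presence.  A negative ASE means band *absence* is the favourable
allele.  Cane-yield effects are converted from kg per plot to t per
hectare for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._linmix import fit_mixed
from .markers import MarkerMatrix
from .pheno import DEFAULT_PLOT_AREA_M2, convert_cy_units
from .scan import ScanResult, _as_q

__all__ = ["MultiQTLModel", "forward_select", "report_ase"]

_COLLINEAR_TOL = 1e-8


@dataclass
class MultiQTLModel:
    """Final joint model after one forward pass."""

    selected: list                      # marker ids in entry order
    ase: pd.Series                      # joint-model coefficients, trait units
    se: pd.Series
    p_values: pd.Series                 # Wald p in the final joint model
    entry_p: float
    sigma2_e: float
    sigma2_u: float
    lam: float
    n: int
    skipped: dict = field(default_factory=dict)   # marker -> reason
    intercept: float = float("nan")


def _joint_fit(yv, cols, Qm):
    X = np.column_stack([np.ones(len(yv))] + cols)
    return fit_mixed(yv, X, Qm)


def forward_select(y, candidates, m: MarkerMatrix, Q=None,
                   entry_p: float = 0.01, order_by=None) -> MultiQTLModel:
    """One forward pass over ``candidates``, ordered by scan p-value.

    ``order_by`` may be a :class:`ScanResult` or a Series of p-values; when
    omitted the candidates are taken in the order given.
    """
    y = pd.Series(y).astype(float)
    ok = y.notna()
    y = y[ok]
    Qm = _as_q(Q, y.index)
    candidates = [str(c) for c in candidates]
    unknown = [c for c in candidates if c not in m.marker_ids]
    if unknown:
        raise ValueError(f"candidates not in marker matrix: {unknown[:5]}")
    if order_by is not None:
        p = order_by.table["p"] if isinstance(order_by, ScanResult) else \
            pd.Series(order_by, dtype=float)
        candidates = sorted(candidates,
                            key=lambda c: (p.get(c, np.inf), c))
    calls = m.calls.loc[y.index]
    yv = y.to_numpy()

    selected: list[str] = []
    cols: list[np.ndarray] = []
    skipped: dict[str, str] = {}
    for cand in candidates:
        x = calls[cand].to_numpy(dtype=float)
        if np.isnan(x).any():
            # joint model needs a complete design; mean-impute the few
            # missing calls at the marker's band frequency
            x = np.where(np.isnan(x), np.nanmean(x), x)
        design = np.column_stack([np.ones(len(yv))] + cols)
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        resid = x - design @ coef
        if np.linalg.norm(resid) <= _COLLINEAR_TOL * max(np.linalg.norm(x), 1.0):
            skipped[cand] = "collinear"
            continue
        fit = _joint_fit(yv, cols + [x], Qm)
        j = len(cols) + 1                      # candidate coefficient index
        se = fit.se[j]
        if se == 0:
            p_cand = 0.0
        else:
            wald = (fit.beta[j] / se) ** 2
            p_cand = float(stats.f.sf(wald, 1, fit.extra["df"]))
        if p_cand < entry_p:
            selected.append(cand)
            cols.append(x)
        else:
            skipped[cand] = f"entry_p>={entry_p}"

    final = _joint_fit(yv, cols, Qm)
    idx = pd.Index(selected, name="marker")
    beta = pd.Series(final.beta[1:], index=idx, name="ase")
    se = pd.Series(final.se[1:], index=idx, name="se")
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (beta / se) ** 2
    pvals = pd.Series(stats.f.sf(wald.to_numpy(), 1, final.extra["df"]),
                      index=idx, name="p")
    lam = float(final.extra["lam"])
    return MultiQTLModel(
        selected=selected, ase=beta, se=se, p_values=pvals, entry_p=entry_p,
        sigma2_e=float(final.sigma2_e), sigma2_u=float(lam * final.sigma2_e),
        lam=lam, n=len(yv), skipped=skipped, intercept=float(final.beta[0]),
    )


def report_ase(model: MultiQTLModel, units: str,
               plot_area_m2: float = DEFAULT_PLOT_AREA_M2) -> pd.DataFrame:
    """ASE report table in publication units.

    ``units`` is the unit of the response: ``"kg_per_plot"`` (cane yield;
    effects are converted to t/ha) or ``"percent"`` (sugar content;
    reported as-is).  Negative effects are annotated as absence-favourable.
    """
    if units == "kg_per_plot":
        factor = convert_cy_units(1.0, plot_area_m2)
        out_units = "t/ha"
    elif units == "percent":
        factor = 1.0
        out_units = "%"
    else:
        raise ValueError(f"unknown trait units {units!r}; expected "
                         "'kg_per_plot' or 'percent'")
    ase = model.ase * factor
    favorable = pd.Series(
        np.where(ase < 0, "absence", np.where(ase > 0, "presence", "")),
        index=ase.index,
    )
    return pd.DataFrame({
        "ase": ase,
        "se": model.se * abs(factor),
        "units": out_units,
        "p": model.p_values,
        "favorable_allele": favorable,
    })
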