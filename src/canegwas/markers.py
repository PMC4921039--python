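"""Dominant-marker matrices and quality control.

Presence/absence ("band") markers such as DArT and TRAP are scored 1 when a
band is observed for a clone and 0 otherwise; dosage is unobservable in a
highly polyploid genome, so every downstream computation works on the binary
calls only.  This module holds the genotype x marker container, band-frequency
computation, minor-allele-frequency filtering and duplicate-column detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "presence_frequency",
    "filter_maf",
    "find_duplicate_markers",
]

#: fraction of missing calls above which a marker is flagged as low quality
MISSING_FLAG_THRESHOLD = 0.20


@dataclass
class MarkerMatrix:
    """Genotypes x markers presence/absence calls.

    Parameters
    ----------
    calls
        DataFrame indexed by genotype id with one column per marker id.
        Values are 0.0, 1.0 or NaN (missing call).
    metadata
        Optional per-marker metadata indexed by marker id.  Recognised
        columns: ``source`` ("DArT" or "TRAP"), ``linkage_group`` and
        ``homology_group`` labels used for stratified sampling.
    """

    calls: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            raise ValueError("duplicate genotype ids in marker matrix")
        if self.calls.columns.has_duplicates:
            raise ValueError("duplicate marker ids in marker matrix")
        values = self.calls.to_numpy(dtype=float)
        bad = ~(np.isnan(values) | (values == 0.0) | (values == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary call {values[i, j]!r} at genotype "
                f"{self.calls.index[i]!r}, marker {self.calls.columns[j]!r}"
            )
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=self.calls.columns)
        else:
            self.metadata = self.metadata.reindex(self.calls.columns)

    # -- basic properties -------------------------------------------------
    @property
    def genotype_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_genotypes(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def values(self) -> np.ndarray:
        """Calls as a float array with NaN for missing."""
        return self.calls.to_numpy(dtype=float)

    def subset(self, marker_ids) -> "MarkerMatrix":
        """Matrix restricted to ``marker_ids`` (order preserved as given)."""
        return MarkerMatrix(self.calls.loc[:, list(marker_ids)],
                            self.metadata.loc[list(marker_ids)])

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path, metadata_path=None) -> None:
        """Write calls (and optionally metadata) as TSV; missing coded NA."""
        out = self.calls.copy()
        out.index.name = "genotype"
        out.to_csv(path, sep="\t", na_rep="NA")
        if metadata_path is not None:
            meta = self.metadata.copy()
            meta.index.name = "marker"
            meta.to_csv(metadata_path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, metadata_path=None) -> "MarkerMatrix":
        """Read a genotype x marker TSV (header row of marker ids, first
        column genotype ids, missing coded ``NA``)."""
        calls = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        calls = calls.rename_axis(index=None)
        meta = pd.DataFrame()
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", index_col=0,
                               na_values=["NA"]).rename_axis(index=None)
        return cls(calls, meta)


def presence_frequency(m: MarkerMatrix) -> pd.Series:
    """Band-presence frequency per marker.

    ``f = (#ones) / (#non-missing)``; markers with no non-missing call get
    NaN and trigger a warning — they carry no information and must be
    excluded before analysis.
    """
    x = m.values()
    n_obs = np.sum(~np.isnan(x), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(x, axis=0) / n_obs
    freq = np.where(n_obs == 0, np.nan, freq)
    if (n_obs == 0).any():
        dead = list(m.marker_ids[n_obs == 0])
        warnings.warn(f"markers with all calls missing: {dead}", stacklevel=2)
    return pd.Series(freq, index=m.marker_ids, name="presence_frequency")


def filter_maf(m: MarkerMatrix, threshold: float = 0.1):
    """MAF filter for dominant markers.

    For a binary band the minor-allele frequency is operationalised as
    ``min(f, 1 - f)`` of the band frequency ``f``.  A marker is kept iff
    ``min(f, 1 - f) >= threshold`` (boundary inclusive).  Markers whose calls
    are all missing are always excluded.  Markers with more than
    ``MISSING_FLAG_THRESHOLD`` missing calls are kept but flagged.

    Returns
    -------
    kept : MarkerMatrix
    excluded : pd.DataFrame indexed by excluded marker id with a ``reason``
        column ("maf<threshold" or "all_missing") and the frequency.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in (0, 0.5], got {threshold}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        freq = presence_frequency(m)
    maf = np.minimum(freq, 1.0 - freq)
    # boundary is inclusive and symmetric: f = 0.9 must fare as f = 0.1
    keep = maf >= threshold - 1e-12
    keep &= ~freq.isna()
    reasons = pd.Series("", index=m.marker_ids, dtype=object)
    reasons[freq.isna()] = "all_missing"
    reasons[(~keep) & (~freq.isna())] = f"maf<{threshold}"
    excluded = pd.DataFrame(
        {"reason": reasons[~keep], "presence_frequency": freq[~keep]}
    )
    x = m.values()
    miss_frac = np.mean(np.isnan(x), axis=0)
    flagged = m.marker_ids[(miss_frac > MISSING_FLAG_THRESHOLD) & keep.to_numpy()]
    if len(flagged):
        warnings.warn(
            f"{len(flagged)} markers kept with >{MISSING_FLAG_THRESHOLD:.0%} "
            "missing calls", stacklevel=2,
        )
    kept = m.subset(m.marker_ids[keep.to_numpy()])
    return kept, excluded


def find_duplicate_markers(m: MarkerMatrix) -> list[list[str]]:
    """Groups (size >= 2) of markers with identical call vectors.

    Equality is exact over the full call vector including the missing
    pattern.  A column and its complement are *not* grouped: band phase is
    unknowable for dominant markers, so complementary patterns cannot be
    asserted to tag the same locus.
    """
    groups: dict[tuple, list[str]] = {}
    x = m.values()
    for j, marker in enumerate(m.marker_ids):
        col = x[:, j]
        key = tuple(-1 if np.isnan(v) else int(v) for v in col)
        groups.setdefault(key, []).append(str(marker))
    return [g for g in groups.values() if len(g) >= 2]
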