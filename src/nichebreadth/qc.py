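"""Occurrence-record quality control: deduplication and climatic outlier
screening.

Two per-species, per-variable outlier screens are provided, mirroring the
screens used for point-locality climate data in distribution-modelling
practice:

* **reverse jackknife** — a gap test on the sorted values: a value is
  suspect when it is separated from the body of the data by a gap larger
  than a sample-size-dependent critical value
  ``C = (0.95 * sqrt(n) + 0.2) * range / 50``.  Suited to larger samples
  with roughly normal values.
* **1.5 x IQR fences** — values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` with
  ``k = 1.5``.  Recommended for small samples (conventionally N < 20).

``apply_qc`` selects the method per species by sample size (IQR below a
threshold, reverse jackknife above), screens each requested bioclimatic
variable independently, and removes a record flagged on any variable.  Every
decision is recorded in a :class:`QCReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import BIOCLIM_VARS

__all__ = [
    "QCReport",
    "deduplicate",
    "iqr_outliers",
    "reverse_jackknife_outliers",
    "apply_qc",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["row", "species", "status", "method", "variable", "value", "threshold"]


@dataclass
class QCReport:
    """Per-record QC outcome.

    ``records`` has one row per *decision*: every input row appears at least
    once (status ``kept``, ``duplicate`` or ``outlier``); outlier rows carry
    the method, the offending variable, its value and the threshold it
    violated (a record flagged on several variables appears once per flag).
    """

    records: pd.DataFrame
    summary: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int((self.records.drop_duplicates("row")["status"] == "kept").sum())

    @property
    def n_removed(self) -> int:
        uniq = self.records.drop_duplicates("row")
        return int((uniq["status"] != "kept").sum())

    def to_csv(self, path: str) -> None:
        self.records.to_csv(path, index=False)


def deduplicate(
    records: pd.DataFrame, precision: int = 4
) -> tuple[pd.DataFrame, QCReport]:
    """Collapse records identical in (species, lon, lat) after rounding.

    Coordinates are snapped to a grid of cell size ``10**-precision`` degrees
    (~11 m at the default 4) by flooring; records of one species falling in
    the same cell collapse to the first occurrence in table order.
    Deduplication is within species: different species at the same
    coordinates are all kept.
    """
    scale = 10.0 ** precision
    key = pd.DataFrame(
        {
            "species": records["species"],
            "lon_r": np.floor(records["lon"] * scale),
            "lat_r": np.floor(records["lat"] * scale),
        }
    )
    dup = key.duplicated(keep="first")
    kept = records.loc[~dup]
    rep = pd.DataFrame(
        {
            "row": records.index,
            "species": records["species"],
            "status": np.where(dup, "duplicate", "kept"),
            "method": pd.NA,
            "variable": pd.NA,
            "value": pd.NA,
            "threshold": pd.NA,
        }
    )
    report = QCReport(
        rep,
        {
            "n_in": len(records),
            "n_kept": int((~dup).sum()),
            "n_duplicates": int(dup.sum()),
            "precision": precision,
        },
    )
    return kept, report


def iqr_outliers(values, k: float = 1.5) -> set[int]:
    """Positional indices of values outside the Tukey fences.

    Quartiles use linear interpolation between order statistics (numpy's
    default, the "type 7" convention).  Values exactly on a fence are kept.
    Fewer than 4 values: nothing is flagged and a warning is logged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        logger.warning("iqr_outliers: n=%d < 4, no screening applied", v.size)
        return set()
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return set(np.flatnonzero((v < lo) | (v > hi)).tolist())


def iqr_fences(values, k: float = 1.5) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    return q1 - k * (q3 - q1), q3 + k * (q3 - q1)


def reverse_jackknife_outliers(values) -> set[int]:
    """Positional indices flagged by the reverse-jackknife gap test.

    Sort ascending and compute the critical gap
    ``C = (0.95 * sqrt(n) + 0.2) * (max - min) / 50``.  Walking inward from
    each end toward the median, any gap between consecutive sorted values
    exceeding C cuts off everything outside it (toward that extreme).  The
    test is invariant under adding a constant to all values.  Needs n >= 5
    and a positive range; otherwise nothing is flagged and a warning is
    logged.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 5:
        logger.warning("reverse_jackknife: n=%d < 5, no screening applied", n)
        return set()
    rng_ = float(v.max() - v.min())
    if rng_ <= 0:
        logger.warning("reverse_jackknife: zero range, no screening applied")
        return set()
    c = (0.95 * np.sqrt(n) + 0.2) * rng_ / 50.0
    order = np.argsort(v, kind="stable")
    sv = v[order]
    gaps = np.diff(sv)
    mid = n // 2
    flagged_sorted: set[int] = set()
    # lower tail: outermost offending gap below the median cuts off 0..i
    lower = np.flatnonzero(gaps[:mid] > c)
    if lower.size:
        flagged_sorted.update(range(0, lower.max() + 1))
    upper = np.flatnonzero(gaps[mid:] > c)
    if upper.size:
        flagged_sorted.update(range(mid + upper.min() + 1, n))
    return {int(order[i]) for i in flagged_sorted}


def reverse_jackknife_critical(values) -> float:
    v = np.asarray(values, dtype=float)
    return (0.95 * np.sqrt(v.size) + 0.2) * float(v.max() - v.min()) / 50.0


def apply_qc(
    records: pd.DataFrame,
    variables: list[str] | None = None,
    threshold_n: int = 20,
    method: str = "auto",
    iqr_k: float = 1.5,
    by_region: bool = True,
    species_bounds: dict[str, tuple[float, float, float, float]] | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Screen climatic outliers per species (x region) and variable.

    Parameters
    ----------
    records:
        Occurrence table (see the occurrence CSV schema).
    variables:
        Bioclim columns to screen; default all six.
    threshold_n:
        With ``method="auto"``, groups with fewer records than this use the
        IQR screen, larger groups the reverse jackknife.
    method:
        ``"auto"`` (sample-size selector), ``"iqr"`` or ``"jackknife"`` to
        force one screen for every group.
    by_region:
        Group per species x region when a ``region`` column is present.
    species_bounds:
        Optional ``species -> (lon_min, lon_max, lat_min, lat_max)`` plausible
        range boxes; records outside their species' box are removed first
        (status ``out_of_range``).

    Returns the kept records and a :class:`QCReport`; a record flagged on
    any variable is removed.
    """
    variables = list(variables) if variables is not None else list(BIOCLIM_VARS)
    unknown = [v for v in variables if v not in records.columns]
    if unknown:
        raise ValueError(f"unknown variable(s): {unknown}")
    if method not in ("auto", "iqr", "jackknife"):
        raise ValueError(f"unknown method {method!r}")

    decisions: list[dict] = []
    removed = pd.Series(False, index=records.index)

    if species_bounds:
        for sp, (lon0, lon1, lat0, lat1) in species_bounds.items():
            mask = (records["species"] == sp) & ~(
                records["lon"].between(lon0, lon1)
                & records["lat"].between(lat0, lat1)
            )
            for row in records.index[mask]:
                decisions.append(
                    dict(row=row, species=sp, status="out_of_range", method="bounds",
                         variable=pd.NA, value=pd.NA, threshold=pd.NA)
                )
            removed |= mask

    group_cols = ["species"]
    if by_region and "region" in records.columns:
        group_cols.append("region")

    for _, grp in records.loc[~removed].groupby(group_cols, sort=False):
        n = len(grp)
        use = method
        if method == "auto":
            use = "iqr" if n < threshold_n else "jackknife"
        for var in variables:
            vals = grp[var].to_numpy(dtype=float)
            if use == "iqr":
                flags = iqr_outliers(vals, k=iqr_k)
                lo, hi = iqr_fences(vals, k=iqr_k) if n >= 4 else (np.nan, np.nan)
                thr = f"[{lo:.4g}, {hi:.4g}]" if n >= 4 else pd.NA
            else:
                flags = reverse_jackknife_outliers(vals)
                thr = f"gap>{reverse_jackknife_critical(vals):.4g}" if n >= 5 else pd.NA
            for pos in sorted(flags):
                row = grp.index[pos]
                removed.loc[row] = True
                decisions.append(
                    dict(row=row, species=grp["species"].iloc[0], status="outlier",
                         method=use, variable=var,
                         value=float(vals[pos]), threshold=thr)
                )

    for row in records.index[~removed]:
        decisions.append(
            dict(row=row, species=records.loc[row, "species"], status="kept",
                 method=pd.NA, variable=pd.NA, value=pd.NA, threshold=pd.NA)
        )
    rep_df = pd.DataFrame(decisions, columns=REPORT_COLUMNS)
    kept = records.loc[~removed]
    report = QCReport(
        rep_df,
        {
            "n_in": len(records),
            "n_kept": len(kept),
            "n_removed": int(removed.sum()),
            "method": method,
            "threshold_n": threshold_n,
            "variables": variables,
            "jackknife_critical_formula": "(0.95*sqrt(n)+0.2)*range/50",
        },
    )
    return kept, report
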