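"""Species-level climatic niche breadth, position and decomposition statistics.

A "locality" is one occurrence record (one ~1 km^2 grid cell).  For a set of
localities of one species (optionally restricted to one region):

* **TNB** (temperature niche breadth, degC): max Bio5 - min Bio6 across
  localities — the full range of temperatures the species experiences,
  combining seasonal extremes within sites and differences among sites.
* **PNB** (precipitation niche breadth, mm): two indices — the range of
  annual precipitation (max Bio12 - min Bio12, spatial heterogeneity only)
  and max Bio16 - min Bio17 (wettest-quarter maximum minus driest-quarter
  minimum, combining spatial and seasonal variability).
* **Niche position**: mean Bio1 (degC) and mean Bio12 (mm).
* **Within-locality breadths** (TNB_WL, PNB_WL): the mean across localities
  of the local seasonal range, Bio5 - Bio6 and Bio16 - Bio17.
* **Within/species ratios** (TNBR_WL-S, PNBR_WL-S): within-locality breadth
  divided by the species(-region) breadth, computed per region and averaged
  (unweighted) across a species' occupied regions.  Near 1 means seasonality
  at single sites, not geography, generates the species' breadth.
* **Niche position variances** (TNPV degC^2, PNPV mm^2): the variance across
  localities of per-locality climatic midpoints — (Bio5+Bio6)/2 for
  temperature, (Bio16+Bio17)/2 for precipitation — an among-locality
  (spatial) variability measure.

``summarize`` produces one row per species x region plus one pooled
species-level row (region label ``"global"``) per species.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "tnb",
    "pnb_annual",
    "pnb_wetdry",
    "positions",
    "within_locality_breadths",
    "breadth_ratios",
    "position_variances",
    "summarize",
    "SUMMARY_COLUMNS",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "species", "region", "n_localities",
    "temp_position", "precip_position",
    "tnb", "pnb_annual", "pnb_wetdry",
    "tnb_wl", "pnb_wl",
    "tnbr_wl_s", "pnbr_wl_s",
    "tnpv", "pnpv",
]


def _require_records(records: pd.DataFrame) -> None:
    if len(records) == 0:
        raise ValueError("no occurrence records")


def tnb(records: pd.DataFrame) -> float:
    """Temperature niche breadth: max Bio5 - min Bio6 (degC)."""
    _require_records(records)
    return float(records["bio5"].max() - records["bio6"].min())


def pnb_annual(records: pd.DataFrame) -> float:
    """Annual-precipitation niche breadth: max Bio12 - min Bio12 (mm)."""
    _require_records(records)
    return float(records["bio12"].max() - records["bio12"].min())


def pnb_wetdry(records: pd.DataFrame) -> float:
    """Wet/dry-quarter precipitation niche breadth: max Bio16 - min Bio17 (mm)."""
    _require_records(records)
    return float(records["bio16"].max() - records["bio17"].min())


def positions(records: pd.DataFrame) -> tuple[float, float]:
    """Niche positions: (mean Bio1 in degC, mean Bio12 in mm)."""
    _require_records(records)
    return float(records["bio1"].mean()), float(records["bio12"].mean())


def within_locality_breadths(records: pd.DataFrame) -> tuple[float, float]:
    """Mean per-locality seasonal ranges: (mean Bio5-Bio6, mean Bio16-Bio17)."""
    _require_records(records)
    t = float((records["bio5"] - records["bio6"]).mean())
    p = float((records["bio16"] - records["bio17"]).mean())
    return t, p


def breadth_ratios(
    regional: Iterable[tuple[float, float, float, float]]
) -> tuple[float, float]:
    """Mean within-to-species breadth ratios over occupied regions.

    ``regional`` yields per-region tuples ``(tnb_wl, tnb, pnb_wl, pnb)``.
    Each region contributes ``tnb_wl / tnb`` and ``pnb_wl / pnb``; the
    species value is the unweighted mean across regions.  A zero regional
    breadth (single locality with zero seasonal range) gives ratio 1 by
    convention, with a warning.
    """
    t_ratios, p_ratios = [], []
    for tnb_wl_r, tnb_r, pnb_wl_r, pnb_r in regional:
        t_ratios.append(_safe_ratio(tnb_wl_r, tnb_r, "TNB"))
        p_ratios.append(_safe_ratio(pnb_wl_r, pnb_r, "PNB"))
    if not t_ratios:
        raise ValueError("no regional breadths supplied")
    return float(np.mean(t_ratios)), float(np.mean(p_ratios))


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den <= 0:
        logger.warning("%s breadth is 0; within/species ratio defined as 1", what)
        return 1.0
    return num / den


def position_variances(
    records: pd.DataFrame, mode: str = "locality"
) -> tuple[float, float]:
    """Variances of climatic midpoints: (TNPV degC^2, PNPV mm^2).

    Midpoints are (Bio5+Bio6)/2 and (Bio16+Bio17)/2 per locality.  With
    ``mode="locality"`` (default) the sample variance (n-1 denominator) is
    taken across localities; with ``mode="region"`` across per-region mean
    midpoints (degenerate for single-region species).  A single unit gives
    variance 0 by convention.
    """
    _require_records(records)
    t_mid = (records["bio5"] + records["bio6"]) / 2.0
    p_mid = (records["bio16"] + records["bio17"]) / 2.0
    if mode == "region":
        if "region" not in records.columns:
            raise ValueError("mode='region' requires a region column")
        t_mid = t_mid.groupby(records["region"]).mean()
        p_mid = p_mid.groupby(records["region"]).mean()
    elif mode != "locality":
        raise ValueError(f"unknown midpoint-variance mode {mode!r}")
    if len(t_mid) < 2:
        return 0.0, 0.0
    return float(t_mid.var(ddof=1)), float(p_mid.var(ddof=1))


def _group_stats(grp: pd.DataFrame, pnb_index: str, variance_mode: str) -> dict:
    t_pos, p_pos = positions(grp)
    t_wl, p_wl = within_locality_breadths(grp)
    tnpv, pnpv = position_variances(grp, mode=variance_mode)
    return {
        "n_localities": len(grp),
        "temp_position": t_pos,
        "precip_position": p_pos,
        "tnb": tnb(grp),
        "pnb_annual": pnb_annual(grp),
        "pnb_wetdry": pnb_wetdry(grp),
        "tnb_wl": t_wl,
        "pnb_wl": p_wl,
        "tnpv": tnpv,
        "pnpv": pnpv,
    }


def summarize(
    records: pd.DataFrame,
    by_region: bool = True,
    ratio_denominator: str = "regional",
    pnb_index: str = "wetdry",
    variance_mode: str = "locality",
) -> pd.DataFrame:
    """All niche statistics, one row per species x region plus a pooled row.

    Parameters
    ----------
    records:
        QC'd occurrence table.
    by_region:
        Split multi-region species into per-region rows (requires a
        ``region`` column); the pooled row (region ``"global"``) always uses
        all of a species' points.
    ratio_denominator:
        ``"regional"`` (default): within/species ratios are computed per
        region and averaged across regions — in the pooled row too, which
        therefore reports the mean of the regional ratios.  ``"species"``:
        ratios use the pooled species-level breadth instead (sensitivity
        analysis).
    pnb_index:
        Which precipitation breadth the ratio denominators use: ``"wetdry"``
        (default; matches PNB_WL's Bio16/Bio17 basis) or ``"annual"``.
    variance_mode:
        Midpoint-variance mode (see :func:`position_variances`).
    """
    _require_records(records)
    if ratio_denominator not in ("regional", "species"):
        raise ValueError(f"unknown ratio_denominator {ratio_denominator!r}")
    if pnb_index not in ("wetdry", "annual"):
        raise ValueError(f"unknown pnb_index {pnb_index!r}")
    split = by_region and "region" in records.columns
    pnb_col = "pnb_wetdry" if pnb_index == "wetdry" else "pnb_annual"

    rows: list[dict] = []
    for sp, sp_grp in records.groupby("species", sort=True):
        regional_rows: list[dict] = []
        if split:
            for region, r_grp in sp_grp.groupby("region", sort=True):
                row = {"species": sp, "region": region}
                row.update(_group_stats(r_grp, pnb_index, variance_mode))
                regional_rows.append(row)
        else:
            row = {"species": sp, "region": "all"}
            row.update(_group_stats(sp_grp, pnb_index, variance_mode))
            regional_rows.append(row)

        for row in regional_rows:
            if ratio_denominator == "regional":
                t_r, p_r = breadth_ratios(
                    [(row["tnb_wl"], row["tnb"], row["pnb_wl"], row[pnb_col])]
                )
            else:
                pooled_tnb = tnb(sp_grp)
                pooled_pnb = (
                    pnb_wetdry(sp_grp) if pnb_index == "wetdry" else pnb_annual(sp_grp)
                )
                t_r, p_r = breadth_ratios(
                    [(row["tnb_wl"], pooled_tnb, row["pnb_wl"], pooled_pnb)]
                )
            row["tnbr_wl_s"] = t_r
            row["pnbr_wl_s"] = p_r

        pooled = {"species": sp, "region": "global"}
        pooled.update(_group_stats(sp_grp, pnb_index, variance_mode))
        # species-level ratio: mean of the per-region ratios
        pooled["tnbr_wl_s"] = float(np.mean([r["tnbr_wl_s"] for r in regional_rows]))
        pooled["pnbr_wl_s"] = float(np.mean([r["pnbr_wl_s"] for r in regional_rows]))

        if split:
            rows.extend(regional_rows)
        rows.append(pooled)

    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return out
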