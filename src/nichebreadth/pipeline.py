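"""End-to-end analysis pipeline: simulate/ingest -> QC -> metrics -> PGLS suites.

The pipeline produces three result tables:

1. **breadth-position suite** — PGLS regressions of niche breadth on niche
   position (TNB on mean Bio1, PNB on mean Bio12) and of TNB on PNB, fitted
   within each region and globally.
2. **ratio summary** — per region and globally: N, mean and range of the
   within-to-species breadth ratios (TNBR_WL-S, PNBR_WL-S).
3. **decomposition suite** — PGLS regressions of species breadth on the
   within-locality breadths, the ratios, and the niche position variances.

Regional fits use the per-region summaries of each species (a multi-region
species contributes a row per region, restricted to its points there);
global fits use one pooled species-level row per species.  Strata with fewer
than 4 species are skipped with a warning.  Everything is deterministic
given the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import summarize
from .phylo import Phylogeny, normalize_label, read_newick_file, write_newick
from .pgls import fit_pgls_lambda
from .qc import apply_qc, deduplicate
from .synthetic import (
    ClimateFieldParams,
    read_occurrences,
    simulate_occurrences,
    simulate_yule_tree,
    write_occurrences,
)

__all__ = [
    "AnalysisConfig",
    "run_breadth_position_suite",
    "run_ratio_summary",
    "run_decomposition_suite",
    "run_all",
]

logger = logging.getLogger(__name__)

MIN_STRATUM_N = 4

FIT_COLUMNS = [
    "model", "region", "n", "lambda", "r2", "p", "slope", "intercept",
    "pnb_index", "converged", "degenerate",
]

BREADTH_POSITION_MODELS = [
    ("TNB~Bio1", "tnb", "temp_position"),
    ("PNB~Bio12", "PNB", "precip_position"),
    ("TNB~PNB", "tnb", "PNB"),
]

DECOMPOSITION_MODELS = [
    ("TNB~TNB_WL", "tnb", "tnb_wl"),
    ("PNB~PNB_WL", "PNB", "pnb_wl"),
    ("TNB~TNBR_WL-S", "tnb", "tnbr_wl_s"),
    ("PNB~PNBR_WL-S", "PNB", "pnbr_wl_s"),
    ("TNB~TNPV", "tnb", "tnpv"),
    ("PNB~PNPV", "PNB", "pnpv"),
]


def _strata(summaries: pd.DataFrame) -> list[tuple[str, pd.DataFrame]]:
    """Regional strata (species x region rows) plus the Global stratum
    (pooled species-level rows)."""
    out = []
    for region in sorted(r for r in summaries["region"].unique() if r != "global"):
        out.append((region, summaries[summaries["region"] == region]))
    out.append(("Global", summaries[summaries["region"] == "global"]))
    return out


def _resolve(df: pd.DataFrame, col: str, pnb_index: str) -> pd.Series:
    if col == "PNB":
        col = "pnb_wetdry" if pnb_index == "wetdry" else "pnb_annual"
    return pd.Series(df[col].to_numpy(dtype=float), index=df["species"].map(normalize_label))


def _run_suite(
    models: list[tuple[str, str, str]],
    summaries: pd.DataFrame,
    tree: Phylogeny,
    pnb_index: str,
) -> pd.DataFrame:
    rows = []
    for region, stratum in _strata(summaries):
        n = len(stratum)
        if n < MIN_STRATUM_N:
            logger.warning(
                "stratum %s has %d species (< %d); skipped", region, n, MIN_STRATUM_N
            )
            continue
        for model, ycol, xcol in models:
            y = _resolve(stratum, ycol, pnb_index)
            x = _resolve(stratum, xcol, pnb_index)
            if float(np.ptp(x.to_numpy())) == 0.0:
                logger.warning(
                    "model %s in %s: constant predictor; fit skipped as degenerate",
                    model, region,
                )
                rows.append(dict(
                    model=model, region=region, n=n, **{"lambda": np.nan},
                    r2=np.nan, p=np.nan, slope=np.nan, intercept=np.nan,
                    pnb_index=pnb_index, converged=False, degenerate=True,
                ))
                continue
            fit = fit_pgls_lambda(y, x, tree)
            rows.append(dict(
                model=model, region=region, n=fit.n, **{"lambda": fit.lambda_hat},
                r2=fit.r2, p=fit.p_slope, slope=fit.slope, intercept=fit.intercept,
                pnb_index=pnb_index, converged=fit.converged,
                degenerate=fit.degenerate,
            ))
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def run_breadth_position_suite(
    summaries: pd.DataFrame, tree: Phylogeny, pnb_index: str = "wetdry"
) -> pd.DataFrame:
    """PGLS of breadth on position and TNB on PNB, per region and globally."""
    return _run_suite(BREADTH_POSITION_MODELS, summaries, tree, pnb_index)


def run_decomposition_suite(
    summaries: pd.DataFrame, tree: Phylogeny, pnb_index: str = "wetdry"
) -> pd.DataFrame:
    """PGLS of species breadth on within-locality breadths, ratios and
    position variances, per region and globally."""
    return _run_suite(DECOMPOSITION_MODELS, summaries, tree, pnb_index)


def run_ratio_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """N, mean and range of the within-to-species breadth ratios per stratum."""
    rows = []
    for region, stratum in _strata(summaries):
        rows.append(
            {
                "region": region,
                "n": len(stratum),
                "tnbr_mean": stratum["tnbr_wl_s"].mean(),
                "tnbr_min": stratum["tnbr_wl_s"].min(),
                "tnbr_max": stratum["tnbr_wl_s"].max(),
                "pnbr_mean": stratum["pnbr_wl_s"].mean(),
                "pnbr_min": stratum["pnbr_wl_s"].min(),
                "pnbr_max": stratum["pnbr_wl_s"].max(),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run.

    Either ``occurrences``/``tree`` paths (ingest mode) or ``simulate=True``
    with ``sim_params`` (simulation mode).  All outputs land in ``outdir``.
    """

    outdir: str = "nichebreadth_out"
    seed: int = 0
    force: bool = False
    # inputs
    simulate: bool = True
    occurrences: str | None = None
    tree: str | None = None
    sim_params: ClimateFieldParams = field(default_factory=ClimateFieldParams)
    # QC
    dedup_precision: int = 4
    qc_variables: list[str] | None = None
    qc_threshold_n: int = 20
    qc_method: str = "auto"
    temp_scale: float = 1.0
    # metrics / suites
    by_region: bool = True
    ratio_denominator: str = "regional"
    pnb_index: str = "wetdry"
    variance_mode: str = "locality"

    @classmethod
    def from_file(cls, path: str) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("sim_params", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("locality_range", "seasonal_amplitude_range",
                        "range_spread_range", "precip_base_range",
                        "wet_dry_fraction_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "regions" in sim:
                sim["regions"] = tuple(tuple(r) for r in sim["regions"])
            cfg.sim_params = ClimateFieldParams(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_all(config: AnalysisConfig) -> Path:
    """Run the full pipeline and write all artifacts to ``config.outdir``.

    Outputs: ``manifest.json`` (config echo, seed, version, row counts,
    warnings), ``occurrences.csv`` (simulated input, simulation mode only),
    ``tree.nwk``, ``qc_report.csv``, ``niche_summaries.csv``,
    ``breadth_position_fits.csv``, ``ratio_summary.csv``,
    ``decomposition_fits.csv`` and ``pipeline.log``.

    Refuses to overwrite an existing non-empty output directory unless
    ``config.force`` is set.  Any stage failure aborts with the stage name.
    """
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not config.force:
            raise FileExistsError(
                f"output directory {outdir} exists and is not empty; "
                "pass force=True (--force) to overwrite"
            )
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(outdir / "pipeline.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    pkg_logger = logging.getLogger("nichebreadth")
    pkg_logger.addHandler(log_handler)
    warnings_seen: list[str] = []

    class _Collect(logging.Handler):
        def emit(self, rec: logging.LogRecord) -> None:
            if rec.levelno >= logging.WARNING:
                warnings_seen.append(rec.getMessage())

    collector = _Collect()
    pkg_logger.addHandler(collector)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                logger.info("stage %s: start", name)
                try:
                    return fn(*a, **kw)
                except Exception as exc:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            return wrapped
        return deco

    try:
        # ---- ingest / simulate -------------------------------------------
        @stage("input")
        def _input():
            if config.simulate:
                params = dataclasses.replace(config.sim_params, seed=config.seed)
                records, truth = simulate_occurrences(params)
                n_sp = records["species"].nunique()
                tree = simulate_yule_tree(n_sp, seed=config.seed + 1)
                # synthetic species names already match tree tip labels
                write_occurrences(records, str(outdir / "occurrences.csv"))
                (outdir / "sim_truth.json").write_text(truth.to_json())
            else:
                if not config.occurrences or not config.tree:
                    raise FileNotFoundError(
                        "ingest mode needs both occurrences and tree paths"
                    )
                for p in (config.occurrences, config.tree):
                    if not Path(p).exists():
                        raise FileNotFoundError(f"input file not found: {p}")
                records = read_occurrences(
                    config.occurrences, temp_scale=config.temp_scale
                )
                records["species"] = records["species"].map(normalize_label)
                tree = read_newick_file(config.tree)
            (outdir / "tree.nwk").write_text(write_newick(tree) + "\n")
            return records, tree

        records, tree = _input()
        manifest["stages"]["input"] = {"n_records": len(records),
                                       "n_species": int(records["species"].nunique()),
                                       "n_tips": tree.n_tips}

        # ---- QC -----------------------------------------------------------
        @stage("qc")
        def _qc():
            deduped, dedup_report = deduplicate(records, config.dedup_precision)
            kept, qc_report = apply_qc(
                deduped,
                variables=config.qc_variables,
                threshold_n=config.qc_threshold_n,
                method=config.qc_method,
                by_region=config.by_region,
            )
            full = pd.concat(
                [dedup_report.records[dedup_report.records["status"] == "duplicate"],
                 qc_report.records],
                ignore_index=True,
            )
            full.to_csv(outdir / "qc_report.csv", index=False)
            summary = {**dedup_report.summary, **qc_report.summary}
            (outdir / "qc_summary.json").write_text(json.dumps(summary, indent=2))
            return kept, summary

        kept, qc_summary = _qc()
        manifest["stages"]["qc"] = {"n_kept": len(kept),
                                    "n_removed": qc_summary["n_in"] - len(kept)}

        # ---- metrics -------------------------------------------------------
        @stage("metrics")
        def _metrics():
            summaries = summarize(
                kept,
                by_region=config.by_region,
                ratio_denominator=config.ratio_denominator,
                pnb_index=config.pnb_index,
                variance_mode=config.variance_mode,
            )
            summaries.to_csv(outdir / "niche_summaries.csv", index=False)
            return summaries

        summaries = _metrics()
        manifest["stages"]["metrics"] = {
            "n_rows": len(summaries),
            "n_species": int((summaries["region"] == "global").sum()),
        }

        # ---- PGLS suites ---------------------------------------------------
        @stage("pgls")
        def _suites():
            t1 = run_breadth_position_suite(summaries, tree, config.pnb_index)
            t2 = run_ratio_summary(summaries)
            t3 = run_decomposition_suite(summaries, tree, config.pnb_index)
            t1.to_csv(outdir / "breadth_position_fits.csv", index=False)
            t2.to_csv(outdir / "ratio_summary.csv", index=False)
            t3.to_csv(outdir / "decomposition_fits.csv", index=False)
            return t1, t2, t3

        t1, t2, t3 = _suites()
        manifest["stages"]["pgls"] = {
            "breadth_position_fits": len(t1),
            "ratio_summary_rows": len(t2),
            "decomposition_fits": len(t3),
        }

        manifest["warnings"] = warnings_seen
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    finally:
        pkg_logger.removeHandler(log_handler)
        pkg_logger.removeHandler(collector)
        log_handler.close()
    return outdir
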