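"""Synthetic phylogenies, traits and occurrence/climate tables with known truth.

Real occurrence compilations for widespread lizard clades are built from
museum and GBIF-style point records joined to bioclimatic rasters.  This
module produces structurally equivalent synthetic inputs in which every
quantity the downstream analysis estimates is known exactly:

* pure-birth (Yule) phylogenies,
* Brownian-motion tip traits with a chosen Pagel lambda (for estimator
  recovery experiments),
* occurrence tables where the within-locality (seasonal) and among-locality
  (spatial-gradient) components of climatic variation are set independently,
  so the within- vs among-locality decomposition has a known answer.

Climate construction per locality: a latitude-dependent mean temperature m
(the among-locality component), a seasonal half-amplitude a (the
within-locality component) giving Bio5 = m + a and Bio6 = m - a, and Bio1
drawn near m and clamped into [Bio6, Bio5].  Annual precipitation Bio12 comes
from a spatial field; the wettest-quarter share w and driest-quarter share d
satisfy d <= w and w + d <= 1 so that 0 <= Bio17 <= Bio16 and
Bio16 + Bio17 <= Bio12 (the wettest plus driest quarters cannot exceed the
annual total) always hold.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .phylo import Phylogeny, PhyloCovariance, lambda_transform, vcv

__all__ = [
    "ClimateFieldParams",
    "SimTruth",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_regression_dataset",
    "simulate_occurrences",
    "seasonality_dominant_params",
    "gradient_dominant_params",
    "OCCURRENCE_COLUMNS",
    "BIOCLIM_VARS",
]

BIOCLIM_VARS = ["bio1", "bio5", "bio6", "bio12", "bio16", "bio17"]
OCCURRENCE_COLUMNS = ["species", "lon", "lat", "region"] + BIOCLIM_VARS

#: Longitude bands standing in for the continental regions a widespread
#: Old-World lizard clade occupies (no polygon data needed downstream).
DEFAULT_REGIONS: tuple[tuple[str, float, float], ...] = (
    ("Africa", -20.0, 52.0),
    ("Asia", 52.0, 110.0),
    ("Oceania", 110.0, 180.0),
)


def simulate_yule_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """Simulate a pure-birth tree with ``n_tips`` labelled tips.

    Waiting times between speciation events are Exponential(k * birth_rate)
    with k the current number of lineages; the lineage that splits is chosen
    uniformly.  A final Exponential(n * birth_rate) interval is appended so
    terminal branches have positive length.  Tips are labelled ``sp0001`` ...
    in left-to-right order.  Deterministic given ``seed``.
    """
    if n_tips < 2:
        raise ValueError(f"need at least 2 tips, got {n_tips}")
    rng = np.random.default_rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    t = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active: list[tuple[dendropy.Node, float]] = [(c1, t), (c2, t)]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.edge.length = t - born
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        active.append((a, t))
        active.append((b, t))
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for node, born in active:
        node.edge.length = t - born
    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = taxon_ns.new_taxon(f"sp{i:0{width}d}")
        leaf.taxon = taxon
    return Phylogeny(tree)


def _mvn_from_cov(rng: np.random.Generator, cov: np.ndarray) -> np.ndarray:
    """Sample N(0, cov) via Cholesky with an eigenvalue fallback."""
    z = rng.standard_normal(cov.shape[0])
    try:
        L = np.linalg.cholesky(cov)
        return L @ z
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh(cov)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("covariance matrix is not positive semi-definite")
        return Q @ (np.sqrt(np.clip(w, 0.0, None)) * z)


def simulate_bm_traits(
    tree,
    lam: float,
    sigma2: float,
    root_value: float = 0.0,
    seed: int = 0,
    *,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Brownian-motion tip traits with phylogenetic signal ``lam``.

    Tip values are multivariate normal with mean ``root_value`` and
    covariance ``sigma2 * lambda_transform(vcv(tree), lam)``.  ``sigma2 = 0``
    degenerates to all tips equal to the root value.  ``tree`` may be a
    :class:`~nichebreadth.phylo.Phylogeny` or a precomputed
    :class:`~nichebreadth.phylo.PhyloCovariance` (cheaper in replicated
    experiments).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    if rng is None:
        rng = np.random.default_rng(seed)
    base = tree if isinstance(tree, PhyloCovariance) else vcv(tree)
    cov = lambda_transform(base, lam)
    if sigma2 == 0.0:
        vals = np.full(cov.n, float(root_value))
    else:
        vals = root_value + _mvn_from_cov(rng, sigma2 * cov.matrix)
    return pd.Series(vals, index=list(cov.taxa))


@dataclass
class SimTruth:
    """Ground truth recorded by a generator, exactly as used."""

    # regression simulations
    lam: float | None = None
    slope: float | None = None
    intercept: float | None = None
    sigma2: float | None = None
    # occurrence simulations: per-species records
    species: dict[str, dict] = field(default_factory=dict)
    outlier_rows: list[int] = field(default_factory=list)
    duplicate_rows: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def simulate_regression_dataset(
    tree,
    slope: float,
    intercept: float,
    lam: float,
    sigma2: float,
    seed: int,
    *,
    x_sigma2: float = 1.0,
) -> tuple[pd.Series, pd.Series, SimTruth]:
    """Simulate (x, y) tip data with y = intercept + slope * x + eps.

    The predictor evolves by plain Brownian motion (lambda = 1, rate
    ``x_sigma2``); the residual has phylogenetic signal ``lam`` and rate
    ``sigma2``.  Independent RNG streams are used for x and eps so changing
    the residual model never changes the predictor.  ``tree`` may be a
    Phylogeny or a precomputed PhyloCovariance.
    """
    ss = np.random.SeedSequence(seed)
    rng_x, rng_e = (np.random.default_rng(s) for s in ss.spawn(2))
    base = tree if isinstance(tree, PhyloCovariance) else vcv(tree)
    x = simulate_bm_traits(base, 1.0, x_sigma2, 0.0, rng=rng_x)
    eps = simulate_bm_traits(base, lam, sigma2, 0.0, rng=rng_e)
    y = intercept + slope * x + eps
    truth = SimTruth(lam=lam, slope=slope, intercept=intercept, sigma2=sigma2)
    return x, y, truth


@dataclass
class ClimateFieldParams:
    """Parameters of the synthetic occurrence/climate generator.

    Defaults emulate a ~100-species Old-World lizard compilation: locality
    counts span 2-3082 with a heavy upper tail, mean annual temperature falls
    off with latitude, seasonal temperature range per locality varies from
    near-tropical (~4 degC full range) to strongly seasonal (~36 degC), and
    annual precipitation spans arid to everwet.

    Attributes
    ----------
    n_species:
        Number of species to generate.
    locality_range:
        (min, max) locality count per species.
    locality_distribution:
        ``"loguniform"``: counts log-uniform on ``locality_range`` (arithmetic
        mean ~420 for the default range).  ``"lognormal"``: truncated
        log-normal (median ~60), whose mean ~240 matches typical GBIF-style
        compilations more closely.
    regions:
        (name, lon_min, lon_max) disjoint longitude bands.
    spatial_gradient_temp:
        degC of mean-temperature decline per degree of absolute latitude
        (among-locality component); ~0.6 is realistic for near-surface
        annual means.
    seasonal_amplitude_range:
        (min, max) degC for the per-species seasonal half-amplitude
        (Bio5 - Bio6)/2 (within-locality component).
    range_spread_range:
        (min, max) degrees for the SD of locality scatter around a species'
        range center; controls among-locality variance jointly with the
        gradients.
    precip_base_range:
        (min, max) mm for species-level annual precipitation.
    spatial_gradient_precip:
        mm of Bio12 change per degree latitude within a range.
    wet_dry_fraction_range:
        (min, max) of the wettest-quarter share w of Bio12; the driest-quarter
        share is drawn in [0, min(w, 1 - w)].
    amplitude_latitude_weight:
        In [0, 1]: how strongly a species' seasonal amplitude tracks the
        absolute latitude of its range center (0 = amplitudes independent
        of latitude, the default; 1 = fully determined by latitude).
        Positive values emulate the real-world increase of temperature
        seasonality toward the poles, which induces a negative
        breadth-position relationship downstream.
    amplitude_jitter:
        Relative SD of the per-locality seasonal half-amplitude around the
        species mean amplitude (dimensionless; 0 makes seasonality uniform
        across a range).
    noise_sd_temp, noise_sd_precip:
        Measurement-style noise SDs (degC, mm).
    outlier_fraction, outlier_sd_multiplier:
        Fraction of extra records per species injected with all-variable
        shifts of ``multiplier`` x the species' among-locality SD (for QC
        experiments); 0 disables.
    duplicate_fraction:
        Fraction of records duplicated exactly (for dedup experiments).
    seed:
        RNG seed; generation is fully deterministic given params + seed.
    """

    n_species: int = 100
    locality_range: tuple[int, int] = (2, 3082)
    locality_distribution: str = "loguniform"
    regions: tuple[tuple[str, float, float], ...] = DEFAULT_REGIONS
    spatial_gradient_temp: float = 0.6
    seasonal_amplitude_range: tuple[float, float] = (2.0, 18.0)
    range_spread_range: tuple[float, float] = (0.5, 8.0)
    precip_base_range: tuple[float, float] = (200.0, 2500.0)
    spatial_gradient_precip: float = 15.0
    wet_dry_fraction_range: tuple[float, float] = (0.35, 0.6)
    amplitude_latitude_weight: float = 0.0
    amplitude_jitter: float = 0.1
    noise_sd_temp: float = 0.5
    noise_sd_precip: float = 30.0
    outlier_fraction: float = 0.0
    outlier_sd_multiplier: float = 10.0
    duplicate_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "locality_range",
            "seasonal_amplitude_range",
            "range_spread_range",
            "precip_base_range",
            "wet_dry_fraction_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        if self.locality_range[0] < 1:
            raise ValueError("locality_range: minimum count must be >= 1")
        wlo, whi = self.wet_dry_fraction_range
        if not (0.0 < wlo and whi < 1.0):
            raise ValueError("wet_dry_fraction_range must lie inside (0, 1)")
        if self.seasonal_amplitude_range[0] < 0:
            raise ValueError("seasonal_amplitude_range: amplitudes must be >= 0")
        if self.locality_distribution not in ("loguniform", "lognormal"):
            raise ValueError(
                f"unknown locality_distribution {self.locality_distribution!r}"
            )
        if not (0.0 <= self.amplitude_latitude_weight <= 1.0):
            raise ValueError("amplitude_latitude_weight must be in [0, 1]")
        if not (0.0 <= self.outlier_fraction < 1.0):
            raise ValueError("outlier_fraction must be in [0, 1)")
        if not (0.0 <= self.duplicate_fraction < 1.0):
            raise ValueError("duplicate_fraction must be in [0, 1)")
        for name, lo, hi in self.regions:
            if lo >= hi:
                raise ValueError(f"region {name}: empty longitude band")


def seasonality_dominant_params(
    n_species: int = 60, seed: int = 0
) -> ClimateFieldParams:
    """Preset: within-locality (seasonal) variation dominates.

    Large, nearly uniform seasonal amplitudes over a quiet spatial field;
    downstream, mean TNBR_WL-S approaches 1 and breadth is generated by
    seasonality at single sites.
    """
    return ClimateFieldParams(
        n_species=n_species,
        seed=seed,
        locality_range=(10, 100),
        seasonal_amplitude_range=(12.0, 16.0),
        spatial_gradient_temp=0.05,
        range_spread_range=(0.3, 1.0),
        spatial_gradient_precip=2.0,
        amplitude_jitter=0.01,
        noise_sd_temp=0.1,
    )


def gradient_dominant_params(
    n_species: int = 60, seed: int = 0
) -> ClimateFieldParams:
    """Preset: among-locality (spatial-gradient) variation dominates.

    Weak-to-moderate seasonality over wide ranges on a steep latitudinal
    gradient; downstream, mean TNBR_WL-S is small (geography generates the
    breadth) while species still differ enough in seasonal amplitude that
    the within-locality contribution to total breadth remains identifiable.
    """
    return ClimateFieldParams(
        n_species=n_species,
        seed=seed,
        locality_range=(10, 100),
        seasonal_amplitude_range=(1.0, 8.0),
        spatial_gradient_temp=1.2,
        range_spread_range=(7.0, 9.0),
        spatial_gradient_precip=40.0,
    )


def _draw_locality_counts(
    rng: np.random.Generator, params: ClimateFieldParams
) -> np.ndarray:
    lo, hi = params.locality_range
    if lo == hi:
        return np.full(params.n_species, lo)
    if params.locality_distribution == "loguniform":
        u = rng.uniform(np.log(lo), np.log(hi), params.n_species)
        return np.maximum(lo, np.exp(u).astype(int))
    # truncated log-normal, median ~60 localities for the default range
    mu, sd = np.log(60.0), 1.7
    out = np.empty(params.n_species, dtype=int)
    for i in range(params.n_species):
        while True:
            v = int(np.exp(rng.normal(mu, sd)))
            if lo <= v <= hi:
                out[i] = v
                break
    return out


def simulate_occurrences(
    params: ClimateFieldParams,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate an occurrence table with known decomposition structure.

    Returns
    -------
    records:
        DataFrame with columns ``species, lon, lat, region, bio1, bio5,
        bio6, bio12, bio16, bio17``; every row satisfies
        ``bio6 <= bio1 <= bio5`` and ``0 <= bio17 <= bio16 <= bio12``.
    truth:
        Per-species ground truth (range center, seasonal amplitude, spatial
        variance components, region) plus the row indices of any injected
        outliers and duplicates.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    counts = _draw_locality_counts(rng, params)
    bands = list(params.regions)
    widths = np.array([hi - lo for _, lo, hi in bands], dtype=float)
    band_p = widths / widths.sum()

    frames: list[pd.DataFrame] = []
    truth = SimTruth()
    row0 = 0
    width = max(4, len(str(params.n_species)))
    for si in range(params.n_species):
        sp = f"sp{si + 1:0{width}d}"
        n_loc = int(counts[si])
        b = int(rng.choice(len(bands), p=band_p))
        name, lon_lo, lon_hi = bands[b]
        spread = float(rng.uniform(*params.range_spread_range))
        center_lon = float(rng.uniform(lon_lo + spread, lon_hi - spread)) \
            if lon_hi - lon_lo > 2 * spread else float(rng.uniform(lon_lo, lon_hi))
        center_lat = float(rng.uniform(-40.0, 40.0))
        a_lo, a_hi = params.seasonal_amplitude_range
        amp_rand = float(rng.uniform(a_lo, a_hi))
        amp_lat = a_lo + (a_hi - a_lo) * min(abs(center_lat), 40.0) / 40.0
        w_lat = params.amplitude_latitude_weight
        amp = (1.0 - w_lat) * amp_rand + w_lat * amp_lat
        p_base = float(
            np.exp(rng.uniform(*np.log(np.asarray(params.precip_base_range))))
        )

        lat = np.clip(rng.normal(center_lat, spread, n_loc), -60.0, 60.0)
        lon = np.clip(rng.normal(center_lon, spread, n_loc), -180.0, 180.0)
        # among-locality component: latitude gradient + smooth site noise
        m = 28.0 - params.spatial_gradient_temp * np.abs(lat) + rng.normal(
            0.0, params.noise_sd_temp, n_loc
        )
        # within-locality component: per-locality seasonal half-amplitude
        a = np.maximum(
            0.1, amp * (1.0 + rng.normal(0.0, params.amplitude_jitter, n_loc))
        )
        bio5 = m + a
        bio6 = m - a
        bio1 = np.clip(m + rng.normal(0.0, params.noise_sd_temp, n_loc), bio6, bio5)

        bio12 = np.maximum(
            10.0,
            p_base
            + params.spatial_gradient_precip * (lat - center_lat)
            + rng.normal(0.0, params.noise_sd_precip, n_loc),
        )
        w = rng.uniform(*params.wet_dry_fraction_range, n_loc)
        d = rng.uniform(0.0, np.minimum(w, 1.0 - w))
        bio16 = w * bio12
        bio17 = d * bio12

        df = pd.DataFrame(
            {
                "species": sp,
                "lon": lon,
                "lat": lat,
                "region": _region_of(lon, bands),
                "bio1": bio1,
                "bio5": bio5,
                "bio6": bio6,
                "bio12": bio12,
                "bio16": bio16,
                "bio17": bio17,
            }
        )

        n_out = int(round(params.outlier_fraction * n_loc))
        if n_out:
            out = _make_outliers(rng, df, n_out, params.outlier_sd_multiplier)
            truth.outlier_rows.extend(range(row0 + len(df), row0 + len(df) + n_out))
            df = pd.concat([df, out], ignore_index=True)
        truth.species[sp] = {
            "region": name,
            "center_lat": center_lat,
            "center_lon": center_lon,
            "seasonal_amplitude": amp,
            "range_spread": spread,
            "precip_base": p_base,
            "n_localities": n_loc,
        }
        frames.append(df)
        row0 += len(df)

    records = pd.concat(frames, ignore_index=True)

    n_dup = int(round(params.duplicate_fraction * len(records)))
    if n_dup:
        dup_idx = rng.choice(len(records), n_dup, replace=False)
        dups = records.iloc[dup_idx].copy()
        truth.duplicate_rows = list(range(len(records), len(records) + n_dup))
        records = pd.concat([records, dups], ignore_index=True)

    return records, truth


def _region_of(lon: np.ndarray, bands) -> np.ndarray:
    """Band containing each longitude; spillover goes to the nearest band."""
    lon = np.asarray(lon, dtype=float)
    dist = np.stack(
        [np.maximum.reduce([lo - lon, lon - hi, np.zeros_like(lon)])
         for _, lo, hi in bands]
    )
    names = np.array([name for name, _, _ in bands], dtype=object)
    return names[np.argmin(dist, axis=0)]


def _make_outliers(
    rng: np.random.Generator, df: pd.DataFrame, n_out: int, multiplier: float
) -> pd.DataFrame:
    """Copies of random clean records shifted far out in climate space.

    Temperature variables are shifted together (preserving
    bio6 <= bio1 <= bio5) by ``multiplier`` x the species' among-locality SD
    of bio1; precipitation variables are scaled together by a factor putting
    bio12 ``multiplier`` SDs above its mean, preserving the quarter ordering.
    """
    base = df.iloc[rng.choice(len(df), n_out, replace=True)].copy()
    sd_t = max(float(df["bio1"].std(ddof=0)), 0.5)
    sd_p = max(float(df["bio12"].std(ddof=0)), 20.0)
    sign = rng.choice([-1.0, 1.0], n_out)
    dt = sign * multiplier * sd_t
    for c in ("bio1", "bio5", "bio6"):
        base[c] = base[c].to_numpy() + dt
    target = float(df["bio12"].mean()) + multiplier * sd_p
    factor = target / base["bio12"].to_numpy()
    for c in ("bio12", "bio16", "bio17"):
        base[c] = base[c].to_numpy() * factor
    return base.reset_index(drop=True)


def write_occurrences(records: pd.DataFrame, path: str) -> None:
    """Write an occurrence table as CSV with a fixed column order and
    float formatting, so identical inputs produce byte-identical files."""
    records.to_csv(path, index=False, columns=OCCURRENCE_COLUMNS, float_format="%.6f")


def read_occurrences(path: str, temp_scale: float = 1.0) -> pd.DataFrame:
    """Read an occurrence CSV.

    ``temp_scale=10`` divides the temperature columns by 10 on read, for
    rasters that store temperature as degC x 10.
    """
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns and c != "region"]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    if temp_scale != 1.0:
        for c in ("bio1", "bio5", "bio6"):
            df[c] = df[c] / temp_scale
    return df
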