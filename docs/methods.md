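# Methods

## The scientific problem

A species' climatic niche breadth — the range of temperature and
precipitation conditions across its occupied localities — can be generated
in two ways: by seasonal variation experienced *within* each locality, or by
climatic differences *among* the localities a species occupies.
Distinguishing the two, and asking how breadth relates to niche position
(is a warm-climate species' thermal niche narrower?), requires species-level
statistics built from point occurrences joined to bioclimatic variables, and
cross-species regressions that account for shared ancestry.  This package
implements that full chain: occurrence quality control, niche
breadth/position/decomposition statistics, and phylogenetic generalized
least squares (PGLS) under the Pagel λ model, together with a synthetic-data
generator in which the decomposition has a known ground truth.

## Niche statistics

For one species (optionally restricted to one region), with each occurrence
record one "locality" (~1 km² cell):

* TNB = max Bio5 − min Bio6 (°C); PNB_annual = max Bio12 − min Bio12 (mm);
  PNB_wetdry = max Bio16 − min Bio17 (mm).
* Positions: mean Bio1 (°C), mean Bio12 (mm).
* Within-locality breadths TNB_WL, PNB_WL: means across localities of
  Bio5 − Bio6 and Bio16 − Bio17.
* Ratios TNBR_WL-S, PNBR_WL-S: within-locality breadth over the
  species(-region) breadth, computed per region and averaged (unweighted)
  over a species' occupied regions.  The precipitation denominator is
  PNB_wetdry by default, because PNB_WL is defined from Bio16 − Bio17;
  `pnb_index="annual"` switches it.  The regional denominator is the default
  (`ratio_denominator="regional"`); the pooled species-level denominator is
  available for sensitivity analysis and can only make ratios smaller.
* Position variances TNPV, PNPV: sample variances (n−1) of the per-locality
  midpoints (Bio5+Bio6)/2 and (Bio16+Bio17)/2.  Variance across localities
  is the default; `variance_mode="region"` computes it across per-region
  mean midpoints instead (that reading is degenerate for single-region
  species, which is why it is not the default).  n = 1 gives variance 0; a
  zero breadth denominator gives ratio 1, both by convention and logged.

Identities that hold by construction and are enforced in tests: TNB ≥
TNB_WL, PNB_wetdry ≥ PNB_WL (hence ratios in (0, 1]); all breadths and
variances are permutation-invariant in locality order and invariant under
adding a constant to all temperatures (resp. precipitations).

## Occurrence QC

Deduplication snaps coordinates to a 10⁻ᵖ-degree grid by flooring (default
p = 4, ~11 m) and collapses records of one species in the same cell; this
"same cell" semantics is deliberate — IEEE round-half-even on floats would
split coordinates that belong to one raster cell.

Two per-species, per-variable outlier screens:

* **1.5×IQR fences** (small samples): flag values outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by linear interpolation (type 7);
  values on a fence are kept.  Needs n ≥ 4.
* **Reverse jackknife** (large samples): with critical gap
  C = (0.95·√n + 0.2)·range/50, walking inward from each end of the sorted
  values toward the median, a gap exceeding C cuts off everything outside
  it.  Needs n ≥ 5 and positive range.  The exact constant in the deployed
  GIS tool this emulates is undocumented; the formula used is recorded in
  every QC summary.  This screen is aggressive near the small-sample
  boundary — a species with ~20–30 irregular localities can lose many
  records — which is exactly why the sample-size selector exists.

`apply_qc` chooses the screen per species (×region) by sample size (IQR
below N = 20, jackknife above, both forceable), screens the six bioclim
variables independently, and removes a record flagged on any variable.
Screening variables, threshold, and per-record decisions are all surfaced in
the QC report.

## PGLS under the Pagel λ model

With V the phylogenetic variance–covariance matrix (V[i,j] = root depth of
the MRCA of tips i, j) and V_λ its off-diagonal entries multiplied by λ:

    y = Xβ + ε,  ε ~ N(0, σ²·V_λ),  λ ∈ [0, 1]

λ is profiled by maximum likelihood: for fixed λ, β̂ and σ̂² have closed-form
GLS/ML solutions computed by Cholesky whitening (V is never inverted
explicitly), and the profile log-likelihood is maximized by bounded scalar
search (tolerance 1e−6) run on the full interval and three overlapping
subintervals, with both endpoints always evaluated — the reported optimum
therefore dominates λ = 0 and λ = 1 by construction.  Branch lengths are
used as-is apart from the λ rescaling (κ = δ = 1 implicitly).  λ is bounded
to [0, 1] because larger values can break positive-definiteness.

Summaries follow standard PGLS conventions: r² = 1 − RSS/TSS in the
whitened space with a GLS intercept-only null under the same V_λ; the slope
p-value is a two-sided t test with the unbiased residual variance
RSS_w/(n−2) and df = n − 2.  ML (not REML) throughout.  A σ̂² floor of
1e−12 keeps the likelihood finite on perfect fits (flagged `degenerate`).
Species missing either variable are dropped pairwise and the tree re-pruned
per model.  On ultrametric-free trees nothing changes: only V matters.
Rescaling all branch lengths by c changes σ̂² by 1/c and nothing else (a
tested invariance).

Independent oracles used in the test suite: explicit dense-inverse GLS
algebra, classical OLS on identity/star covariance, statsmodels GLS at
fixed V, a brute-force λ grid (step 1e−4), and R's `nlme::gls` +
`ape::corPagel` (agreement to ~6 significant digits on λ, coefficients,
log-likelihood, and p on a 30-tip fixture).

## Synthetic data generator

The generator emulates a GBIF/VertNet-style occurrence compilation for a
widespread Old-World lizard clade without any GIS machinery.  Per species:
a region (one of three longitude bands standing in for Africa/Asia/Oceania),
a range center and scatter SD (0.5–8°), a locality count, a seasonal
half-amplitude a (so Bio5 = m + a, Bio6 = m − a), and a precipitation base.
The among-locality temperature component comes from a latitudinal lapse of
mean temperature (default 0.6 °C per degree of |latitude|, a realistic
near-surface value) plus site noise; the within-locality component is the
seasonal amplitude (default species range 2–18 °C half-amplitude, i.e.
4–36 °C full seasonal range, spanning tropical to strongly seasonal
climates), jittered 10% across a species' localities.  By default a
species' amplitude is drawn independently of its latitude;
`amplitude_latitude_weight` in (0, 1] makes amplitude track the |latitude|
of the range center, emulating the real-world poleward increase of
temperature seasonality — under that coupling warm-position species have
narrow thermal niches, and the pipeline demonstrably recovers the induced
negative breadth–position slope.  Precipitation shares
satisfy d ≤ w and w + d ≤ 1 so 0 ≤ Bio17 ≤ Bio16 and Bio16 + Bio17 ≤ Bio12
always hold (wettest plus driest quarter cannot exceed the annual total —
real bioclim data obeys this even though it need not be stated anywhere).

Locality counts: default log-uniform on [2, 3082] (the empirical range of
such compilations).  Note the arithmetic mean of that distribution is ≈ 420;
compilations whose mean is nearer ~240 are better matched by the truncated
log-normal option (median 60, σ_log = 1.7), provided as
`locality_distribution="lognormal"`.

Two presets pin the decomposition's ground truth at its extremes:
`seasonality_dominant_params` (large near-uniform amplitudes, quiet spatial
field → mean TNBR_WL-S ≈ 0.97) and `gradient_dominant_params` (weak
seasonality, wide ranges on a steep gradient → ≈ 0.24; amplitudes still
vary across species so the within-locality contribution stays
identifiable in regressions).  Contamination for
QC experiments is injected as whole-record climate shifts of k× the
species' among-locality SD (temperature additive, precipitation
multiplicative, preserving all record invariants), with injected row
indices recorded in the truth sidecar.

What the generator does **not** emulate: spatial autocorrelation beyond a
linear gradient, coastlines/elevation, covariance between temperature and
precipitation fields, taxonomic or sampling bias, and real raster
discretization.  Passing tests therefore demonstrate correctness of the
statistics and estimators under the stated model, not robustness to every
pathology of real occurrence data.

Trait simulation draws tip values from N(root, σ²·V_λ) via Cholesky (with
an eigen-decomposition fallback near singularity), using independent seed
streams for predictor and residual so the predictor is invariant to the
residual model.  Yule trees use exponential waiting times with a final
extra interval so terminal branches are positive; everything is
deterministic given the seed.

## Pipeline and problem sizes

`run_all` chains input (simulate or ingest) → dedup → outlier screen →
niche summaries → three result tables (breadth~position fits, ratio
summary, decomposition fits), with a JSON manifest recording config, seed,
version, per-stage counts and warnings.  Strata with fewer than 4 species
are skipped with a warning.  Regional fits use per-region summaries;
global fits use pooled per-species summaries (one row per species).

Default experiment sizes were chosen to make the statistical checks sharp
while staying desk-scale: the bundled example runs 100 species with ≤ 500
localities each (seconds); estimator-recovery experiments use 200-tip trees
with 200 replicates per (λ, slope) cell, giving Monte-Carlo SEs of ~0.005
on mean slopes; the λ grid oracle uses 50-tip problems at grid step 1e−4.

## Known limitations

* The reverse-jackknife screen is a deterministic gap test; it has no
  false-positive-rate guarantee and can decimate species with irregular
  multimodal climate distributions just above the method-selection
  threshold.
* λ̂ at the ML optimum frequently sits exactly on an endpoint (0 or 1) in
  small samples; no confidence interval on λ is reported.
* r² in GLS is not uniquely defined; the whitened-space definition used
  here matches common PGLS summaries but other conventions exist.
* The pooled "global" stratum treats a multi-region species as one unit
  with all points pooled; alternatives (e.g. averaging regional summaries)
  are not implemented.
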