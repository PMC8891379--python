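# Methods

## Data model

The analytical panel is the 16 EPA priority PAHs, each carried with its
method limit of detection (LOD) and quantification (LOQ) in µg/kg, a
toxicity equivalency factor (TEF), and inert GC-MS selected-ion
metadata. The packaged registry encodes the survey's validated method
limits; the LOQ/LOD ratio is 3.0–3.13 for every congener (unusual — the
common conventions are 3.3× and 10× — but the constants are used as
published, without reinterpretation). Concentrations are stored in
µg/kg throughout; the risk equations convert to mg/kg explicitly at the
model boundary.

A measurement is either a numeric value or a *censored* non-detect
(`nd` / `<LOD`, case-insensitive). Censored cells carry no number until
imputation replaces them with a deterministic surrogate — LOD/2 by
default, matching the survey's stated rule for computing means;
zero/LOD/LOQ substitutions are provided as the standard lower/upper
sensitivity bounds. Imputation is idempotent and cell-local, so it is
independent of record order.

## Group summaries and the overall row

Per product type, the summary reports mean/SD/min/max of each congener
and of two per-sample derived scores: the full-panel sum (ΣPAH16,
"Total") and the EU regulatory PAH4 sum. The *overall* block aggregates
across product types as the **unweighted mean of group means**, with
overall extrema taken as extrema of the group extrema. This convention
is chosen because it reproduces the published study-level values exactly
(total PAHs 3.73, PAH4 0.72, BaP 0.29 µg/kg at two decimals, the latter
with all-censored group means entered at LOD/2 = 0.11); per-sample
pooling cannot be validated without the undeposited raw data. A
published group mean whose min and max are both non-detects is treated
as the half-LOD surrogate leaking into the table (it always equals
LOD/2) and flagged all-censored.

Internal consistency of the published tables is checked by a
reconstruction oracle: for each product type the sum of the 16 imputed
congener means re-derives the published Total within 0.04 µg/kg and
PAH4 within 0.02 µg/kg, the rounding slack of two-decimal means. One
side effect worth knowing: the highest group's reconstructed PAH4 mean
is exactly 1.00 µg/kg (published: 0.98), i.e. *at* the EU limit, so
synthetic data regenerated around the published means is borderline for
that one group under a strict-inequality compliance rule.

The across-group comparison is the classical one-way fixed-effects
ANOVA, implemented from its sums of squares (two groups reduce to the
equal-variance t test, F = t²). All-identical data returns F = 0, p = 1
by convention. Note the published per-congener p-values cannot be
reproduced without the raw samples — and are, in fact, inconsistent
with the published group means and SDs, which imply a strongly
significant group effect for the Total (the synthetic replica gives
F ≈ 57); the suite therefore checks the test's *calibration* (type-I
error 0.05 ± 0.02 on 1000 null replicates) rather than any published
p-value.

## Risk chain

* **BEC** (BaP-equivalent concentration): Σᵢ Cᵢ·TEFᵢ, with per-congener
  contribution shares. Default TEF set is Nisbet & LaGoy
  (BaP = DhA = 1; BaA = BbF = BkF = IP = 0.1; A = Ch = BgP = 0.01;
  others 0.001); the survey's own TEF table is in unavailable
  supplementary material, so the field-standard scheme is shipped and
  every value is overridable. Under it, BaP contributes ~71% of the
  BEC and DhA ~12% — the survey's figure names BaP and BkF as the two
  dominant contributors, which implies a different (unpublished) TEF
  set; this qualitative discrepancy is reported, not resolved.
* **EDI**: C·IR·EF·ED / (BW·AT) in mg/(kg bw·day).
* **ILCR**: two conventions. `dose_consistent` (default) is
  EDI(BEC)·SF — the slope factor multiplies a true daily dose.
  `study_verbatim` reproduces the survey's printed formula
  BEC·EF·ED·SF/(BW·AT), which omits the intake rate IR and is
  dimensionally a risk per unit concentration; it is retained for
  fidelity and comparison. Zones: < 10⁻⁶ safe; up to 10⁻⁴
  intermediate; up to 10⁻³ threshold exceeded; above that significant
  danger (boundary values fall in the less alarming zone). The JECFA
  flag triggers strictly above 10⁻⁵ mg/kg bw/day (10 ng/kg bw/day) of
  BaP intake.

### Exposure parameters

BW = 70 kg and SF = 7.3 (mg/kg/day)⁻¹ are the survey's stated values
(the adult body weight is kept verbatim even though the consumers are
infants — a documented oddity of the source analysis, and conservative
in neither direction since IR is calibrated jointly, see below). IR,
EF, ED and AT are cited by the survey to external references without
numbers. They are therefore shipped as a documented default
configuration whose *combined ingestion factor*

    IR·EF·ED / (BW·AT) = 1.86e-4 per day

is back-calculated from the survey's own EDI table: the ratio of the
median EDI to the mean concentration is constant across all twelve
detected congeners (1.81–1.89 ×10⁻⁴/day). The default splits this as
IR = 0.01302 kg/day with EF = 365 d/y, ED = 1 y, AT = 365 d; only the
product matters and every entry is overridable in
`data/default_exposure.yaml`.

## Monte Carlo uncertainty analysis

Each iteration draws all inputs (per-congener concentrations and
IR/EF/ED/BW/AT/SF), evaluates the chain, and reports empirical
percentiles (order statistics with linear interpolation; default 10⁴
iterations, percentiles 5/50/75/95, fixed seed 20220217). Negative
concentration draws truncate to zero; explicit truncation bounds use
rejection sampling. Supported families: point, normal, lognormal
(log-space, median + P95/P50 ratio, or moment parameterizations),
uniform, triangular.

The default configuration puts the uncertainty on the ingestion factor
— IR lognormal with a 95th/50th percentile ratio of 1.5 — and leaves
concentrations at their study means. The ratio is back-calculated from
the survey's EDI table, whose 95%/50% ratio is essentially constant
(1.48–1.54) across congeners with concentration CVs from 0.33 to 1.0.
That constancy is only possible if concentration variability did not
enter the published simulation (pyrene's concentration CV alone would
force a ratio ≥ 1.7), so the default emulates an exposure-factor-only
simulation; lognormal or zero-truncated-normal concentration specs
built from any summary's mean/SD remain one call away
(`concentration_specs(..., family="lognormal")`) for genuine
sensitivity work, and shift the 95th-percentile ILCR from ~8.3×10⁻⁷ to
~1.05×10⁻⁶. Under the default the EDI percentile table reproduces the
survey's printed values to ~1% (e.g. pyrene 8.35×10⁻⁸ vs 8.37×10⁻⁸ at
the median).

The survey's printed 95th-percentile ILCR (7.03×10⁻¹⁰) is not
derivable from any printed inputs — it sits three orders of magnitude
below BEC×SF×(any plausible intake factor) — and is treated as
non-reproducible; the package's claim is the zone classification
(safe, < 10⁻⁶), not that digit string.

## Synthetic data generator

The generator emulates the survey design: 9 product types × 2 brands ×
2 duplicates (n = 4 per group, exposed as a parameter since the survey
reports only the total of 36), drawing each cell from a zero-truncated
normal at the published group (mean, SD) and recording draws below the
congener's LOD as non-detects. The truncated-normal parent location is
solved per cell so the *truncated* mean equals the target exactly;
naive clipping would bias cells with mean ≲ 2 SD above zero by up to
~2 standard errors at n = 500. The parent scale is the target SD, so
heavily truncated cells are slightly under-dispersed (exact two-moment
matching is impossible anyway for the one published cell with CV > 1,
wheat-based IP at 0.12 ± 0.13). A moment-matched lognormal family is
available as a robustness alternative. Congeners flagged all-censored
for a group are always generated as non-detects.

What the generator does *not* emulate: brand effects (labels are
recorded but carry no distributional difference, mirroring the survey,
which found none), between-congener correlation within a sample,
measurement error below the LOD, and the fact that the published means
were themselves computed with half-LOD substitution (regenerating from
them and re-substituting double-counts the surrogate slightly for
heavily censored cells). Passing recovery tests therefore show that
the *pipeline* is correct and calibrated on data with the survey's
marginal structure — not that real baby-food PAH data is truncated
normal. Calibration: at the study scale, ~96% of detected group-mean
cells land within 2 SE of their targets across 200 replicate seeds; at
n = 500 per group (uncensored) every cell recovers within 3 SE.

## Clustering

Variables (16 congeners + Total + PAH4) are clustered on their
group-mean profiles across the 9 product types: rows standardized to
zero mean/unit variance (toggleable; correlation distance is affine
invariant, so this only matters for the heat-map colors), distance
d = 1 − r (not 1 − |r|, matching the ClustVis convention of the source
analysis), average linkage via scipy's UPGMA. The test suite holds the
implementation to a brute-force average-linkage oracle exhaustively for
2–6 leaves (cophenetic-matrix equality). Congeners undetected in every
group have constant half-LOD profiles, carry no correlation signal, and
are dropped with a warning. At k = 3 the BbF/BaP/PAH4 trio lands in one
cluster, in qualitative agreement with the survey's heat map; full
memberships depend on preprocessing choices the survey does not state
and are reported rather than asserted.

## Numerical and testing choices

* Percentile estimator: linear interpolation (numpy default); stable at
  10⁴ draws.
* Ties in rankings and group extremes resolve to panel/table order
  (stable sorts); linkage tie-breaking follows scipy's deterministic
  ordering (ties have measure zero on continuous distance data).
* Single-sample groups report SD 0; all-identical ANOVA input returns
  F = 0, p = 1; an empty BEC map returns 0 with contributions flagged
  undefined.
* Problem sizes in the routine runs — 10⁴ Monte Carlo iterations,
  1000 ANOVA null replicates, 200 generator calibration seeds, n = 500
  recovery groups — were chosen as the smallest sizes at which the
  corresponding Monte Carlo standard errors are comfortably inside the
  asserted tolerances.
* Floating-point: constant-profile detection and symmetry checks use
  small absolute tolerances (1e-12) rather than exact equality.
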