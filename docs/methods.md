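# Methods

## Scope and model

`dustrisk` implements a deterministic USEPA multi-pathway dose/risk
layer (oral, dermal, inhalation exposure to arsenic in settled dust)
and a Monte Carlo layer that propagates the uncertainty of exactly two
inputs — the dust arsenic concentration (AsC) and body weight (BW) —
through those formulas, stratified by four receptor age groups. All
other exposure factors are treated as constants, matching the design of
the Araró field study the default configuration encodes. Risk metrics:
hazard quotient HQ = ADD/RfD, hazard index HI = Σ HQ over pathways,
carcinogenic dose cADD = ADD·AT/cAT, carcinogenic risk CR and its sum
aCR.

## Parameters, units, defaults

The default configuration (`default_araro_config`) carries, per age
group: AsC mean 15.6 mg/kg with SD 5.94 and observed range 5.94–42.53
mg/kg; EF 350 d/y; ED 3.51/8.82/15.88/42.94 y; BW means
16.31/33.8/60.91/72.67 kg with population ranges 10–39, 14–95.7,
25.9–158.4 and 45–194.2 kg; AT 1,229/3,087/5,558/15,029 d (= ED·EF
within rounding, enforced by a validator); dust ingestion rates
100/100/30/30 mg/d; inhalation rates 9.5/12/15.75/14.67 m³/d;
PEF 1.36×10⁹ m³/kg; skin areas 760/1,080/1,840/1,935 cm²; AF 0.5
mg/cm²; ABS 0.03; CF 10⁻⁶ kg/mg. Toxicity: oral RfD 3×10⁻⁴ mg/kg/day,
oral slope factor 1.5 (mg/kg/day)⁻¹, HQ limit 1, CR limit 10⁻⁵.

Three defaults are package decisions where the source tables are
silent or internally inconsistent:

- **cAT = 25,550 d** (70 y × 365). With this lifetime averaging time
  the published oral cancer risks follow from the published oral doses
  under CR = cADD/SF to within rounding, so it is adopted as the value
  the study effectively used.
- **EV = 1 event/day** — the standard residential default for the
  dermal formula, which needs an event frequency the parameter table
  does not list.
- **Inhalation HQ denominator = 1.5×10⁻⁵ mg/kg/day.** The published
  inhalation hazard quotients equal the published inhalation doses
  divided by 1.5×10⁻⁵ (the USEPA inhalation reference value for
  arsenic) in all four age groups, not by the 3×10⁻⁴ shown in the
  dose table's screening column. The package therefore keeps two
  inhalation criteria: `RfD_inhalation` (1.5×10⁻⁵, divides HQ) and
  `RfD_inhalation_screen` (3×10⁻⁴, flags raw doses). Dermal doses are
  likewise screened at 1.23×10⁻⁴ but their HQ divides by 3×10⁻⁴,
  which is what the published dermal quotients imply.

The parameter table also lists a "dermal contact factor" DFS = 362.4
mg·y/kg/day that no formula consumes; it is stored as inert metadata.
The concentration mean is configurable: the parameter table says 15.6,
the survey text 15.21 ± 5.94 (median 12.33); which one drove the
published simulation is not stated, and the default follows the table.

The carcinogenic-risk convention is configurable. The published tables
follow CR = cADD/SF (division), which inverts conventional USEPA
practice (multiplication); `cr_convention="printed"` (default)
reproduces the tables, `"standard"` gives the conventional product.
With SF = 1.5 the two differ by ×2.25.

## Distributions and simulation

- AsC ~ lognormal by method of moments: σ² = ln(1+(sd/mean)²),
  μ = ln(mean) − σ²/2; truncated to the observed sample range
  [5.94, 42.53] mg/kg.
- BW is published as mean + range only. The range is read as the
  central 99% interval of the underlying lognormal:
  σ = (ln hi − ln lo)/(2·z₀.₉₉₅), μ matches the arithmetic mean, and
  draws are truncated to [lo, hi]. The 99% coverage is a package
  choice (configurable via `bw_range_coverage`): the ranges look like
  near-extremes of a national anthropometric survey, and no BW spread
  is published. Results are insensitive to moderate coverage changes
  because the dose depends on 1/BW mostly through its median.
- Truncation is enforced by rejection sampling with redraws (bounded
  retries; infeasible bounds raise). Percentiles use numpy's
  linear-interpolation convention.
- Each of the 10,000 scenarios (default; `n_iterations` configurable)
  draws one (AsC, BW) pair per age group, shared by the three pathways,
  making HI and aCR genuine within-scenario sums. Age groups use
  independent child streams spawned from the configured seed
  (default 20,180,000 — arbitrary); identical configs are bit-identical.
- Sensitivity: squared Spearman rank correlations of each varying input
  with the output, normalised to sum to one. On the default
  configuration the oral dose splits roughly 70% AsC / 30% BW.

## Synthetic data

The generator emulates the field inputs: a survey over A hectares has
n = floor(2.26·A^0.31) samples (the Mexican sampling-norm formula;
11,400 ha → 40), true concentrations drawn from a specified lognormal,
multiplied by a constant recovery factor (default 117%, the instrument's
quality-control accuracy) and unit-mean multiplicative lognormal noise
with the instrument CV (0.75%); values under the 4 mg/kg limit of
detection are flagged, and substitution policies (half-LOD, LOD, drop)
are provided. The model deliberately omits spatial autocorrelation,
source heterogeneity and sieving physics — synthetic samples are
exchangeable, so tests passing on them say nothing about spatial
structure in real surveys, only about the statistical pipeline.

## Verification

The test suite checks three layers: (1) exact/hand-computed values for
every formula (e.g., the preschooler oral dose at the mean
concentration, 9.56×10⁻⁵ mg/kg/day); (2) a deterministic consistency
chain across the published tables — mean HQ from mean ADD within 1%
(oral) or printed precision (inhalation), oral CR from oral ADD within
10%; (3) stochastic reproduction of the published oral and inhalation
medians/means at 10,000 scenarios within ±20%, plus distribution-free
invariants (linearity in concentration, inverse body-weight scaling,
median factorisation of lognormal ratios at three bootstrap standard
errors, Jensen mean inflation, collapse to point estimates under
degenerate inputs, seed determinism, moment-fit parameter recovery,
closed-form truncated-tail exceedance). Observed agreement of the
simulated medians with the published ones is a few percent across
seeds.

## Known limitations

- **Dermal pathway.** The published dermal doses are irreproducible
  from the dermal formula with the published parameters (discrepancy
  ~1.5–8× across age groups under any single constant factor); the
  package computes the formula as written and excludes dermal cells
  (and HI/aCR levels dominated by them) from numeric reproduction. The
  test suite asserts the mismatch itself so a silent change in either
  side is caught.
- Published inhalation cancer risks are ~8× below what the oral slope
  factor predicts; the slope factor actually used is unstated. The
  package applies SF = 1.5 to all pathways unless per-pathway overrides
  are configured.
- The published exceedance of the 22 mg/kg soil regulation (13.51%) is
  not an integer fraction of 40 samples; the denominator is unclear, so
  the screening utility is validated against the closed-form lognormal
  tail instead.
- One-dimensional Monte Carlo only: variability and uncertainty are not
  separated, and no Latin-hypercube option is provided.
- No bioaccessibility adjustment, single contaminant, no GIS/spatial
  output.
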