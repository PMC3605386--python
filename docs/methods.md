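# Methods

This note records the models implemented in `fscshape`, the conventions
and tunables that affect results, what the synthetic data does and does
not emulate, and the numerical choices made where the procedure is
genuinely underdetermined.

## Signal model and scope

All analyses assume a *linear* FSC acquisition scale quantised to 1024
integer channels (0–1023), as on a BD FacsCalibur. No gating (debris or
doublet exclusion) is applied anywhere: the indicators are computed on
the full event stream, and binning clamps out-of-range events into the
edge channels rather than dropping them (the clamp count is reported as
a QC field, `n_clamped`). Fluorescence channels, compensation and
logicle/arcsinh transforms are out of scope; sample annotations such as
density fraction, antibody label or flow rate are carried as opaque
metadata only.

Kurtosis and PCD are computed from the raw event values; SphI is
defined on the binned channel histogram, because it is intrinsically a
histogram-peak procedure. This means kurtosis/PCD are unaffected by the
1-channel quantisation while SphI operates at channel resolution.

## Moment indicators

Excess kurtosis offers the three standard small-sample estimators
(`g2`, `G2`, `b2`, as defined in the README); the package default is
`G2`, matching the type-2 convention of R's `e1071::kurtosis` and of
SPSS/SAS, so that values are comparable with cytometry work processed
through those tools. All three agree to O(1/n); the choice matters only
for small samples, far below typical acquisition sizes (10⁴–5·10⁴
events).

PCD uses the n−1 standard deviation by default (`ddof=1`), again the
common statistical-software convention; the population form is
available via `ddof=0`. Both indicators are location- and
scale-invariant (up to floating-point error), which the test suite
asserts as a property.

Degenerate inputs (zero variance, fewer events than the estimator's
minimum n) raise a dedicated error rather than returning NaN.

## SphI: splitting procedure and conventions

The published description of the Spherical Index leaves several
details open (smoothing, what counts as a detectable mode, tie-breaks,
median convention for binned data, behaviour on monomodal input). The
implementation fixes them as follows; every knob is exposed in
`SphIConfig` and logged with results, because they change the value:

1. **Smoothing** — centred moving window of 9 channels with reflected
   ends. Internally an integer moving *sum* is used instead of a float
   moving average: all downstream decisions (peak positions,
   prominences relative to the global maximum, inter-mode minima) are
   invariant to the positive scale factor, and exact int64 arithmetic
   makes plateau and tie handling bit-reproducible. 9 channels is wide
   enough to suppress single-channel shot noise at 10⁴–5·10⁴ events
   without merging modes ~30 channels apart.
2. **Mode detection** — local maxima of the smoothed counts with
   topographic prominence exceeding 5% of the global smoothed maximum
   (`min_prominence_fraction`); the two most prominent qualify, ties
   broken toward the lower channel. The same criterion defines
   `classify_modality`, so "bimodal" and "SphI defined" coincide under
   the default policy.
3. **Provisional split** — minimum of the smoothed counts strictly
   between the two mode channels (lowest channel on ties).
4. **Part modes** — argmax of the *raw* counts on each side of the
   split (lowest channel on ties); the split channel itself belongs to
   the lower side.
5. **Final cutoff** — arithmetic mean of the two part modes, kept
   fractional; events in the channel equal to ⌊cutoff⌋ belong to the
   lower part.
6. **Part medians** — lower-median convention for binned data: the
   smallest channel whose cumulative count reaches half the part's
   total. This reproduces integer part medians such as 148/60.
7. **SphI** = upper median / lower median.

Monomodal histograms follow `monomodal_policy`: the default leaves SphI
undefined (`None`) — a monomodal distribution has no second part to
take a ratio of — while `fixed_cutoff` splits at a configured channel
regardless (e.g. channel 101), the convention used when a fixed
reference cutoff is calibrated per instrument. Both are implemented
because practice varies; the adaptive procedure is the default. SphI is
refused below 1000 total events (`min_events`): with fewer events the
raw-count modes are noise-dominated.

A lower part median of 0 would make the ratio undefined; this (and an
empty part under a fixed cutoff) returns `None` rather than raising.

## Synthetic data

The generators emulate the *shape* of erythrocyte FSC data, not the
optics:

- **Acquisitions** are two-component Gaussian mixtures on the channel
  scale, clipped (not rejected) at [0, 1023]. Gaussian components are a
  modelling choice — the real orientation-mode shapes are not
  documented — chosen because only the mono/bimodal geometry matters to
  the indicators. Defaults: modes 60/148 (the canonical strongly
  bimodal configuration), σ = 10, equal weights, 50 000 events, the
  size of a standard low-flow-rate acquisition.
- **Osmolarity series**: 10 subjects × osmolarities
  {259, 285, 300, 315, 335} mosmol/kg (50 samples), with mode
  separation affine in osmolarity from 12 channels (near-spherical at
  259) to 88 channels (strongly biconcave at 335, the Figure-like
  60/148 separation), mixture centre at channel 104, σ = 14, and
  Gaussian per-subject offsets on separation (SD 3) and centre (SD 5).
  Only monotonicity of the separation map is load-bearing; the affine
  form is the simplest monotone choice.
- **Cohorts** are drawn from exactly the random-intercept model the
  variance-component analysis fits, so parameter recovery is a
  well-posed check. Defaults: 10 subjects × 3 visits (days −1, 3, 7).

What passing tests on this material shows: the indicator pipeline,
split procedure and mixed-model machinery are correct on data with the
assumed structure. What it cannot show: behaviour under real-world
features absent from the generator — asymmetric or heavy-tailed
orientation modes, debris/doublet contamination, channel saturation
spikes, drift within an acquisition, or instrument-to-instrument
channel shifts.

### Indicator-agreement grid

The kurtosis–SphI agreement check uses a random mixture grid with mode
separation ~U(25, 110) channels, a common per-sample mode width
~U(9, 12), and near-equal weights ~U(0.42, 0.58) (60 samples × 20 000
events). Rationale: across erythrocyte samples the dominant axis of
variation is bimodality (how far the orientation modes are apart),
while the per-mode optical width is largely instrument-determined; a
grid in which width varies as strongly and independently as separation
would decouple kurtosis (a function of separation/width) from SphI (a
function of separation alone) and describe a different population than
FSC samples. On this grid the Spearman correlation is stably around
−0.95, and its sign and strength do not depend on the seed.

## Variance components and tests

- The random-intercept model is fitted by **maximum likelihood** (not
  REML), via `statsmodels` `MixedLM`; ML is the convention this
  analysis follows, and its (a−1)/a shrinkage of the between-subject
  variance at a = 10 subjects is visible in parameter-recovery
  simulations (≈ −5 to −9% on σ_b) — a property of the estimator, not a
  bug. Balanced and unbalanced designs are accepted; a singular fit
  (σ̂_b → 0) reports `r_ratio = inf` instead of raising.
- **Harris r** is the *variance* ratio σ²_within/σ²_between by default:
  back-calculation from published descriptive tables of this analysis
  type matches the variance ratio, and the accompanying captions
  describe it as an intra- to inter-individual *variance* ratio. The SD
  ratio is available via `ratio_scale="sd"` for compatibility with the
  original 1970s formulation.
- **SEM** = σ̂_ε/√(number of subjects), i.e. the intra-individual *SD*
  over √n. Formula texts sometimes write "variance" here, but only the
  SD form reproduces the standard reported values (0.12 → 0.04 at
  n = 10), so the SD form is implemented.
- **Friedman test**: SciPy's tie-corrected statistic for ≥ 3
  conditions; for exactly 2 conditions (which SciPy refuses) the same
  tie-corrected rank formula is computed directly, where it coincides
  with the two-sided sign-test chi-square. Fully tied blocks yield
  χ² = 0, p = 1 rather than NaN. Pairwise comparisons are two-sided
  Wilcoxon signed-rank tests with **Bonferroni** adjustment (raw
  p × number of pairs, capped at 1); the published analyses do not name
  their adjustment, so the most conservative standard choice is the
  default and Holm is available.
- **Spearman ρ** uses average ranks for ties; constant input raises
  (the correlation is undefined), and the 3×3 indicator-agreement
  matrix is ordered (SphI, PCD, kurtosis) with p-values attached as
  DataFrame attrs.

## Problem sizes

Simulation-backed tests use the sizes stated above (50 000-event
acquisitions for worked-example and direction checks, 20 000 events for
grid samples, 500 replicate cohorts of 10 × 3 for parameter recovery);
these are the study-like sizes at which the statistical properties are
both meaningful and quick to compute.

## Known limitations

- The FCS reader is minimal by design: list-mode data, one datatype per
  file (F/D/I with 8/16/32/64-bit integers), pure little- or big-endian
  byte orders, no analysis segment, no multi-dataset files
  (`$NEXTDATA` ignored). It is sufficient for FacsCalibur-style linear
  FSC data and for fixtures written by the package's own FCS 3.0
  writer.
- SphI's mode detection, like any mode estimator, is noise-sensitive
  near the mono/bimodal boundary; the prominence threshold trades false
  second modes against missed shallow ones, and results near the
  boundary should be interpreted together with kurtosis (which is
  continuous through it).
- The mixed model has a single random intercept; visit-level fixed
  effects, heteroscedastic residuals and multi-level designs are out of
  scope.
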