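# Methods

This note documents the models, numerical choices and open design decisions
behind `neurostates`, and what the synthetic-data validation does and does
not establish.

## Data model

A `Recording` is a channels × time matrix with a sampling rate, ordered
channel labels and subject metadata.  Internally everything is stored
channels × time; the segmentation algorithm receives time × channels through
an explicit transposition (`rec.data.T`).  Sample indexing is 0-based with
half-open intervals: boundary index `b` means the state change occurs
between samples `b − 1` and `b`, and the sample at `b` belongs to the new
state.

Block downsampling averages non-overlapping blocks of `block` consecutive
samples (default 100, turning 512 Hz into 5.12 Hz, one sample per ~195 ms).
A trailing partial block is dropped so every output sample is an
equal-weight mean; we do not resample to exactly 200 ms.  Downsampling is
linear, which the test suite checks numerically.

Group labels outside {younger, older} are coerced to `unknown` and excluded
from group contrasts.

## Greedy state boundary search

Each timepoint is a spatial pattern over `C` channels.  Patterns are
z-scored across channels once up front; Pearson correlation is invariant to
this per-pattern affine transform, so nothing else changes, and no
additional z-scoring of channels over time is applied (the correlation
already centers and scales each pattern).

The fit score of a segmentation is the mean Pearson correlation between
every timepoint's pattern and the mean pattern (*state template*) of its
state, where templates are means of the z-scored patterns.  With z-scored
patterns this has a closed form: the summed correlation of a state's
timepoints with their template equals `‖S‖ / √C`, `S` being the sum of the
state's z-scored patterns.  Candidate placements are therefore scored from
cumulative sums in O(C) each; the full greedy fit to `k_max` states costs
O(k_max · T · C) and handles a 2,503-sample, 32-channel recording with
`k_max = 488` in a few seconds on one CPU.

Per iteration one new boundary is placed at the location that maximizes the
fit score (earliest location wins ties, making output deterministic).  The
variant that splits one state into three by placing two boundaries at once
is exposed (`double_split=True`) but off by default: single placement is the
canonical procedure, and with pair placements the attained state counts may
skip values.  After each placement, a fine-tuning pass repeatedly offers
every boundary a ±1-sample shift, accepting only strict improvements of the
global fit (zero-gain moves would allow drift); among equal improvements
the earlier position wins.  Whether fine-tuning is interleaved with every
placement or applied only at the end is not uniquely determined by the
published descriptions; we interleave, which is the stronger variant.

Splitting a state can never lower the fit score (triangle inequality on
`‖S‖`), so the fit curve is non-decreasing in `k`; this is a tested
invariant.

### t-distance and model selection

The t-distance of a segmentation is an independent two-sample Student t
with pooled variance comparing two pools of pattern correlations: all
unordered timepoint pairs inside one state versus all pairs spanning two
*temporally adjacent* states.  Length-1 states contribute no within pairs.
The pooled (rather than Welch) flavor was chosen for simplicity and is
validated against a brute-force oracle built from the full correlation
matrix with explicit pair masks; if both pools are constant the statistic is
returned as ±inf in the direction of the mean difference.  The curve over
`k` is computed from 2-D prefix sums of the T × T correlation matrix, O(k)
per candidate after an O(T²) setup.

Slow signal drifts (periods of hundreds of seconds) produce strong
anti-correlations between distant timepoints, which makes the t-distance
enormous for two- to four-state solutions.  The synthetic generator
reproduces this with a single sinusoid of period equal to the recording
length added with random per-channel signs; with drift amplitude several
times the pattern scale, the unconstrained t-distance argmax collapses below
5 states while the true structure remains recoverable.  Model selection
therefore takes the *first peak* of the curve (a `k` whose t-distance
exceeds both neighbors) at or above `k_min = 15`; if no such peak exists the
argmax over `k ≥ k_min` is returned with a warning flag.  The default
`k_max` is the floor of the recording duration in seconds (e.g. 489 for a
489-s movie); an explicit integer can override it.

## Alignment statistics

Boundary trains are smoothed with a unit-peak Gaussian kernel (SD 2 samples
≈ 400 ms at 5.12 Hz, truncated at ±4 SD).  Unit-peak normalization is
cosmetic — Pearson correlation is scale invariant — but fixed for
reproducibility.  The group reference for a subject is the pointwise mean
of all *other* subjects' smoothed timelines; averaging smoothed timelines
versus smoothing an averaged boundary train are identical up to one kernel
application by linearity of convolution, and we keep the single code path.

The null distribution shuffles the order of the subject's state durations
(uniformly, with replacement across the 1,000 replicates), re-derives
boundaries from the cumulative permuted durations, smooths and correlates.
Zero-variance correlations (flat reference or degenerate shuffle) return 0
with a warning rather than raising so cohort loops survive degenerate
cases.

`r_max` places the subject's boundary count on the reference's highest
local maxima — plateau tops count once, at their midpoint, which matters
for behavioral press densities whose 2-s counting windows create flat-topped
plateaus — with a minimum separation of 2 samples, falling back to the
highest unused values under the same constraint when there are fewer
maxima.  The adjusted match `(r_raw − null_mean) / r_max` is 0 in
expectation for unrelated boundaries (verified by a 200-subject
calibration), positive for shared boundaries, and declines monotonically
with boundary jitter.

Behavioral densities subtract 0.9 s from each press (response-time
correction) and count, at every sample of the neural grid, the fraction of
subjects with at least one corrected press within ±1 s.  The window is
centered on the timepoint; the published procedure does not state the
centering, and a symmetric window matches the symmetric uncertainty left
after the RT correction.  Corrected presses before time zero are clipped to
zero with a warning.

## Boundary distinctiveness

For each boundary with full windows inside the recording, every pattern in
the `h` samples before the boundary is correlated with every pattern in the
`h` samples after it (`h` = 2 s rounded to the nearest sample count; the
boundary sample itself lies in the post window).  The per-boundary means
are aggregated by the median (correlation distributions are skewed), and
the same procedure at state midpoints — `floor((start + end) / 2)`, with
states shorter than `2h` skipped so baseline windows never straddle a
boundary — provides the baseline.  The median is used at both aggregation
steps ("same procedure" symmetry).  `delta` = boundary median − midstate
median; negative delta means boundaries are more distinct than mid-state
periods.  Edge-excluded boundaries and short states are counted in the
result.

The within-event similarity test computes the mean pattern correlation over
all timepoint pairs inside the same (behaviorally defined) event and
compares it to the same statistic after duration-preserving shuffles of the
event order; `p` is the fraction of null values at least as large as the
observed.

## Memory statistics

Summary-statistic t tests use the pooled-variance two-sample t with
`df = n1 + n2 − 2` and Cohen's d against the pooled SD; these reproduce the
bundled worked-example table to input-rounding precision.  The 2 × 2 mixed
ANOVA uses classical weighted sums of squares (between-subject error =
subjects within groups; within-subject error for the condition and
interaction terms) with partial eta squared per effect, and matches
`pingouin.mixed_anova` exactly on unbalanced random data in the tests.

The moderation regression is `y ~ 1 + x + group + x:group` with group coded
0 (older) / 1 (younger) and `x` uncentered; the coding is recorded in the
output because the interaction's interpretation depends on it.  The
bootstrap resamples subjects with replacement *stratified by group* — at
n = 26/28, unstratified resampling occasionally produces single-group
replicates and singular designs.  Replicates whose normal-equations matrix
is numerically singular are dropped and counted; more than 10% dropped is
an error.  Coefficients are reported as OLS point estimates, bootstrap
medians (B = 5,000 by default) and percentile 95% CIs; the whole-model F
compares against the intercept-only model.  Whether the published analysis
stratified its bootstrap or which coding it used is not stated; our choices
are reported alongside the results rather than presented as the only
possibility.

## Synthetic data

The generator emulates cleaned, downsampled recordings, not raw EEG: no
1/f background, oscillations, artifacts or sensor geometry.  State patterns
are drawn independently per state (no Markov structure), which matches the
stable-pattern model the segmentation assumes and keeps ground truth
unambiguous — but it also makes states *much* more separable than in real
data, where successive states are correlated.  Passing tests therefore
establish correctness and calibration of the machinery, not effect sizes
transferable to real recordings: synthetic adjusted-match means (~0.8) and
distinctiveness deltas (~−0.8) are an order of magnitude larger than the
~0.2 and ~−0.01 seen in practice.

Defaults mirror the study conditions: 28 younger + 26 older subjects,
2,503 samples × 32 channels at 5.12 Hz, 18 shared states (minimum length 3
samples), per-subject boundary jitter SD 1 sample, 10% idiosyncratic
boundary replacements, pattern scale 1.0 with noise SD 0.5 ("moderate"
SNR), drift off unless the pathology is the object of study (amplitude 4 ×
pattern scale there).  Press logs use a 0.9-s mean response lag (SD 0.3 s,
truncated at zero), 70% hit probability and one false alarm per minute.
Memory couples `proportion_internal` to distinctiveness with slope −1.5 and
noise SD 0.04 around an intercept of 0.87, plus a +0.035 younger-group
offset — values on the scale of real recall data.  Inside the pipeline the
coupling uses each subject's delta *relative to the cohort mean*, which
keeps proportions inside the unit interval whatever the absolute
distinctiveness scale of a synthetic cohort; slope estimates are unaffected
by centering the predictor.

Boundary-recovery scoring matches planted and estimated boundaries by
minimum-cost one-to-one assignment within a tolerance (Hungarian
algorithm), verified against exhaustive enumeration on small sets.

## Problem sizes used in validation

Unit and acceptance tests run cohorts at 512 samples (100 s at 5.12 Hz)
with 32 channels, where one subject segments in ~0.2 s; the acceptance
script additionally runs the full 54-subject cohort at 2,503 samples.
Calibration suites use 200 subjects × 1,000 shuffles; regression recovery
uses 20 cohorts of 54 subjects at B = 5,000.  These sizes make the whole
validation run in a few minutes on a single CPU while keeping every
statistic at the defaults described above.

## Known limitations

- The exact t-distance variant (pooled vs Welch; treatment of immediate
  temporal neighbors in the adjacent-state pool) is a documented choice,
  validated against our own oracle, not against an external reference
  implementation.
- `r_max` is a constructive lower bound on the true maximum attainable
  correlation (boundaries on the reference's highest separated maxima); a
  subject could in principle exceed it on adversarial references, though
  the `r_raw ≤ r_max` invariant holds across all tested cohorts.
- The CLI covers single-subject and cohort workflows but not distributed
  execution; subject loops run serially.
- Group labels are binary (younger/older); continuous age is out of scope.
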