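# Methods

This note documents the models, conventions, and numerical choices behind
`pbspike`, and what the synthetic-data tests do and do not establish about
real recordings.

## Detection model

All spike-train inference runs on trial-aligned PSTHs with half-open bins
`[edge, edge + bin_width)`; a spike exactly on a boundary is counted once,
in the bin to its right.  The default bin width is **0.1 s**, chosen so the
500 ms after-discharge criterion is exactly 5 bins; any bin width that
divides the criterion is accepted, and `ad_min_duration` is snapped to a
whole number of bins (with a logged warning if snapping changed it).

**Baseline band.**  The baseline rate statistics pool the individual bin
counts of the 5 s pre-stimulus window across trials — the same window the
suppression test uses, so there is a single baseline definition.  The
default band is the normal approximation `mean ± z(0.995)·sd` on the
pooled counts (converted to Hz, lower bound floored at 0); a
`poisson_exact` mode uses the 0.5th/99.5th Poisson quantiles of the mean
bin count instead.  At the low per-bin counts typical of these neurons
(~0.5 counts/bin) the Poisson quantile is quantized and skew-shifted above
the normal band, so the two modes are *not* numerically interchangeable;
what they share, and what the test suite asserts, is behavior: both hold
the per-bin false-positive rate of the band at or below 2% on homogeneous
Poisson trains, and their upper bands agree within 10% once expected
counts reach ~25 per bin.  Because the band is built from the spread of
single-trial bin counts but is applied to the across-trial *mean* rate,
the criterion is conservative — appropriate for the large evoked effects
it is meant to flag.

**Response and after-discharge.**  A unit is excited if any in-stimulus
bin's mean rate exceeds the band.  The after-discharge duration is the
length of the maximal run of consecutive supra-band bins *starting at the
first post-offset bin* — a discharge is continuity of the evoked response,
so no leading gap is allowed, and interior gap tolerance defaults to 0
bins (configurable).  Runs shorter than 500 ms score a duration of 0 in
results (the raw run length is kept in diagnostics), so non-AD responsive
units enter population duration statistics at 0.  Scanning continues
until the rate returns below the band or the aligned window ends; the
aligned window must extend at least the rebound-scan window (default
10 s) past offset.

**Suppression and rebound.**  Suppression is a two-tailed paired t-test
(per-trial pre-stimulus vs. in-stimulus rates, ≥ 3 trials) at α = 0.05,
with the label additionally requiring a mean rate decrease so an excited
unit can never be called suppressed.  Zero-variance differences with a
nonzero mean are reported as p = 0 with a degeneracy warning.  A
suppressed unit is scanned for rebound with the same run rule but no
minimum duration; sub-bin rebounds are undetectable by construction.
Suppression takes precedence in classification, and suppressed units
contribute an after-discharge duration of 0.

## Response magnitudes

Mechanical magnitude is `(evoked − spontaneous) / force-integral` by
default.  "Normalized to spontaneous rate" could also be read as a ratio;
subtraction is the default because a sizeable fraction of these neurons
(11–25%) have zero spontaneous rate, for which a ratio needs an arbitrary
floor.  Ratio mode is available with a 0.1 Hz floor (one spike per 10 s),
logged whenever it engages, and every output row records its mode.
Evoked rate is the mean over the full 3 s stimulus, not the peak bin.
Thermal magnitude defaults to the rate ratio against the baseline mean (a
non-responder scores ~1); a silent baseline engages the floor and sets a
degeneracy flag.  Spontaneous rate is counted over quiet intervals that
exclude stimulus windows plus their 10 s post-offset pads.

## Behavioral estimators

The up-down threshold uses the staircase convention `10^(Xf + k·δ)/10^4`
grams with `Xf` the final filament on the `log10(10^4·g)` scale and `δ`
the mean log-step of the ladder.  The coefficient `k` is obtained by
maximizing the likelihood of the classical normal (probit) tolerance
model with its scale fixed at one log-step over the observed
(filament, response) pairs — the same constrained model from which the
traditional coefficient table was computed; on a uniformly log-spaced
ladder the minimal O→X series gives k = −0.5 exactly, matching the
tabulated value, and the estimate is monotone in the response pattern.
Computing `k` rather than shipping a transcribed table avoids
transcription risk and handles every pattern, including ones absent from
the table; an independent grid-search likelihood implementation serves as
the oracle in tests.  All-response sequences pin to the ladder minimum,
all-non-response to the maximum, and estimates are clipped to the ladder
range.  Default ladders are log-spaced von Frey sets covering 0.4–26 g
(face) and 2–60 g (hind paw); the exact filament set is configurable.
Sequences outside 6–20 stimuli warn (10–12 is typical).

Grimace scores are the arithmetic mean over all non-missing
image × action-unit cells (4 units — orbital tightening, nose-cheek
bulge, whisker tightening, ear position — each 0/1/2); Hargreaves
latency is the mean of the (typically five) trials.

## Group statistics

Mann-Whitney U is reported as `min(U_a, U_b)` with midranks for ties;
the p-value is exact for combined n ≤ 20 without ties, otherwise a
tie-corrected normal approximation with continuity correction.  Median
CIs default to the distribution-free order-statistic interval (largest
symmetric order-statistic pair whose binomial tails stay within 2.5%
each, hence conservative; nominal coverage 96.5% at n = 15); for n < 6
no 95% interval exists and the data range is returned with a warning; a
seeded percentile bootstrap is the alternative, and the method used is
always recorded.  The two-tailed binomial test uses the
minimum-likelihood convention (doubling available).  Chi-square on 2×2
tables applies Yates correction by default (small expected cells are
typical here) and warns when an expected cell is below 5.  Cohen's d is
the absolute standardized mean difference with (n−1)-weighted pooling —
it cannot be derived from medians, so it is only computed from raw data.

## Synthetic-data generator

Spikes are drawn from an inhomogeneous Poisson process with
piecewise-constant rate, sampled exactly by exponential inter-arrivals
restarted at each breakpoint (exact by memorylessness; no thinning).
Stimulus protocol: 3 s stimuli, 5 repetitions per modality/site, default
inter-stimulus interval 16 s — above the 8 s experimental floor and long
enough that successive 5 s-pre + 13 s-post analysis windows never
overlap — automatically extended when simulated after-discharges exceed
3 s.  After-discharges are rectangular by default (constant `ad_rate` for
`ad_duration`, so true duration is sharply defined for recovery tests)
with an exponential-decay option (time constant `ad_duration/3`).

Population presets encode the study conditions: `sham_like` (AD incidence
0.136, silent fraction 0.11, OFF-cell fraction 3/22, spontaneous-rate
median 1.595 Hz) and `cci_like` (0.512, 0.25, 11/43, 1.912 Hz).
Spontaneous rates of non-silent units are lognormal around the preset
median (σ = 0.8 on the log scale) clipped at 5 Hz, matching the observed
0–5 Hz range.  The AD flag is drawn first at its marginal incidence;
OFF-cells are drawn from the non-AD remainder at
`off_cell_fraction/(1 − ad_incidence)` so both marginals hold exactly and
ADs belong to excited units.  Default evoked/AD/rebound rates (60 Hz
against ≤ 5 Hz baselines) put detection in the high signal-to-noise
regime the recovery claims are stated for.  AD durations default to
uniform 0.5–3 s and rebound durations to uniform 1–3 s (the observed
rebound medians are 1–3 s).

Behavioral sequences come from a latent logistic psychometric function in
log10 force with slope 10 per decade (steep, as in behaving animals);
responses follow the staircase rules, stop 4 stimuli after the first
reversal, cap at 12 stimuli, and stop after 3 pinned responses at a
ladder end.

**What the generator does not emulate:** spike-sorting errors and
waveform drift, non-Poisson firing statistics (bursting, refractoriness,
serial correlation), adaptation across the 5 repetitions, correlated
noise across simultaneously recorded neurons, anesthesia-depth
fluctuations, and behavioral lapses or sensitization.  Passing recovery
tests therefore establishes that the detectors are correct and calibrated
for the assumed point-process model, not that they are robust to every
departure real recordings exhibit; the conservative band construction is
the main safeguard there.

## Problem sizes and reproducibility

Everything stochastic is seeded; a single master seed fans out to stage
seeds through `numpy.random.SeedSequence` (all below 2^31).  The test
suite exercises recovery at 200–500 seeds per condition, specificity on
1000 null neurons, the group contrast over 200 paired replicates, up-down
recovery over 2000 simulated animals, and CI coverage over 10^4
replicates.  `scripts/acceptance.py` re-runs the same computations at
100 paired population replicates, 150 seeds per AD duration, 500 null
neurons, and 1000 simulated animals — sizes at which every reported
fraction has a standard error well below the differences of interest —
and completes in well under a minute on one CPU.

## Known limitations

- The baseline band treats bin counts as exchangeable across the 5 s
  baseline; slow drifts within a session widen the empirical sd and make
  the criterion more conservative, not anticonservative.
- AD durations are quantized to the bin width; sub-bin events are
  invisible and boundary bins can shift an estimate by one bin.
- The paired t-test on 5 trials has limited power; weak suppression will
  be missed (direction-gating also means borderline two-tailed p-values
  with a rate increase are never labelled suppressed).
- Order-statistic CIs are conservative at small n and undefined below
  n = 6, where the data range is substituted with a warning.
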