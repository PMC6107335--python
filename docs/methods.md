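# Methods

This note documents the models, rules and numerical choices behind
`crchain`: what each analysis computes, what the synthetic generator does
and does not emulate, and where genuinely open design decisions were made.

## Conventions

Time is in milliseconds with t = 0 at CS onset; sampling is 1 kHz;
windows are half-open `[a, b)`; eyelid position is in millimeters with
closure positive, full closure calibrated to 6.0 mm and the pre-CS
baseline mean at 0. Behavioral records span [−200, 2300) ms; spike
records span [−1500, 2300) ms so that the full baseline-normalization
window is available. Peak and crossing ties resolve to the earliest
sample, everywhere.

## Trace processing

Raw readouts are scaled so the test-US full closure reads 6.0 mm, then
baseline-subtracted. Smoothing is Savitzky–Golay; the window/order are
not dictated by the measurement model, so the defaults — 21 samples
(21 ms), order 3 — were chosen to suppress sensor noise (detector
resolution ±0.1 mm) while leaving CR rise times (~50–200 ms) essentially
untouched; both are configurable. Velocity uses `numpy.gradient` with
`edge_order=2` (central differences interior, one-sided second-order at
the ends), followed by the same filter.

Trial screening discards whole trials, never segments: (1) upward
movement exceeding the 0.3 mm CR criterion (strict inequality, relative
to the zeroed baseline) during the 200 ms before CS onset or the
half-open [0, 100) ms from CS onset; (2) position below −0.5 mm at any
time before US onset (paired trials) or from trial start to 500 ms after
CS offset (CS-alone trials). On contralateral sessions both eyes are
screened and either can trigger exclusion.

## CR detection and decomposition

A deflection is a CR when it reaches 0.3 mm — 5% of full closure. The
**two-step onset**: step 1 scans backward from the criterion crossing for
the departure point, the first sample below
`baseline + max(2·(pre-CS noise SD), 0.01 mm)` that stays below for at
least 5 ms; step 2 back-projects the line through the departure point and
the criterion crossing onto the baseline level. The step-1 constants are
configurable; the 2-SD rule makes the threshold noise-adaptive, and the
0.01 mm floor keeps it defined on noise-free input. On a linear rise the
back-projection is exact; when no departure precedes the crossing the
onset falls back to the latency-to-criterion with a flag.

Multi-CR trials are decomposed by local maxima with **prominence
≥ 0.5 mm** (interpreted in millimeters, the trace unit, consistent with
the 0.3 mm criterion). Later-CR onsets are the position minimum between
consecutive peaks. CS-alone trials are analyzed over the full record
(up to four CRs fit in the window); paired trials are truncated at the
delivered US, with the second-CR peak constrained to within 100 ms of the
scheduled US₂. When US truncation clips a genuine second peak's
prominence, the windowed rule takes over: the maximum over
[US₂ − 100, US₂) counts as the second CR provided it re-rises by at least
the criterion above the inter-CR minimum, so the first CR's decay tail is
never double-counted. Trials whose first-CR onset falls at/after CS
offset use the windowed delayed/absent estimate (first amplitude =
maximum over [0, CS offset + 200); second = maximum over
[CS offset + 200, CS offset + 800)); if that window shows no first CR,
no later events are emitted — by construction the decomposition never
reports a second CR without a first — and any residual activity flags the
trial for review. With a single prominent peak, the same 200–800 ms
post-offset window is searched for a distinct rebound using local maxima
with prominence at the 0.3 mm criterion (a bare windowed maximum would
turn large first-CR tails into false seconds); such trials are flagged.

The **squint gate** — max over [400, US₂) minus min over [US₂ − 300, US₂)
must reach 1 mm — qualifies a trial for second-CR analysis. It is
evaluated only on trials with a detected first CR: its purpose is to
reject trials where a sustained squint after the first response makes the
second undetectable, and a flat no-CR trace (which would fail the literal
inequality) presents no such ambiguity.

**Contralateral trials**: the right-eye amplitude is the overall maximum
minus the maximum during the CS, suppressing sympathetic co-movement of
the right eyelid during the left-eye CR; the corrected amplitude must
reach 0.3 mm.

## Sequence statistics

Second-CR probability is the fraction of first-CR trials that also carry
a second CR; zero denominators yield NaN with a flag, never 0.
Extinction curves split a session into eight contiguous near-equal
portions, remainder to the earliest portions.

The **conditional probability** of a second CR uses seven first-CR
amplitude bins by default — {<0.3 (non-CR), 0.3–1, 1–2, 2–3, 3–4, 4–5,
≥5} mm, matching the six degrees of freedom of the chi-square the
analysis reports. CIs are percentile bootstrap (2.5/97.5), 2000
replicates, resampling trials *within* each bin (resampling a Bernoulli
indicator with replacement is drawn as a binomial for speed; the two are
identical in distribution). The chi-square uses the standard contingency
routine on the per-bin present/absent table; empty bins are dropped with
df reduced.

**Timing co-variation** pairs any two timing measures of successive CRs
on trials where both amplitudes exceed a threshold. The inclusion
threshold is 2 mm by default with 3 mm available — both thresholds appear
in the source procedures and the choice is a config switch. Outliers
beyond 3 SD from the mean in either coordinate are removed before the
Pearson correlation (standard t-approximation p-values).
Normalized-profile **fraction times** invert each CR profile (normalized
by its peak) at 0.005 fraction steps with linear interpolation, first
crossing on non-monotone profiles.

The **shuffle null** permutes the first-CR timings across trials (2000
permutations, sampling without replacement) and pools the recomputed
inter-CR intervals. The test statistic is the two-sample KS statistic
between the true intervals and the pool. Its asymptotic p-value is
severely conservative here — the true sample is itself one permutation
and is embedded in the pool (measured type-I error 0.00 at α = 0.05) —
so the reported p is permutation-calibrated: the rank of the true
statistic among the per-permutation statistics, exact under the
independence null by exchangeability. Measured calibration: type-I error
0.03–0.07 at α = 0.05 (200 replicates, 100 trials), power ≈ 1 against
the chained generator with 20 ms interval jitter.

**CS2 transfer** compares, per session, second-CR probability on CS1
trials with first CR above 3 mm, on CS2-alone trials above the same gate,
and on CS2-alone trials without a first CR. CS1 trials on which US₁ was
delivered are excluded from the first group: the analysis truncates at
the US, so those trials cannot express a second CR, and in the closed
loop the online contingency keeps them out of the supra-gate group. The
across-session Pearson correlation between the CS1 and CS2 group
probabilities indexes whether sequence expression travels with the first
response rather than with the training cue. The session-inclusion rule
for the necessity analysis (second-CR probability > 40%) uses the
second-CR probability as defined above.

## Purkinje-cell analysis

Instantaneous rate is the inverse inter-spike interval (piecewise
constant between simple spikes, zero outside the spike span, 1/ISI in Hz)
convolved with a Gaussian kernel of 20 ms SD. At the record edges the
kernel is renormalized to unit mass inside the window, avoiding
artificial edge dips. Spike times are at 1 ms resolution; coincident
rounded spikes are merged (refractoriness implies one spike per
millisecond). Trains with fewer than two simple spikes yield a flagged
zero series. Rates are normalized by the mean over the 1500 ms pre-CS
baseline of the same trial.

Measured calibration: for Bernoulli-per-millisecond (Poisson at the
recording resolution) trains at 20/50/100 Hz over 100 s, the
time-averaged estimate is within 2% of the realized spike-count rate —
the realized rate, not the nominal λ, is the right comparator because at
100 s and 20 Hz the Poisson fluctuation of the count itself is ~2.2% SD.
Fifty-trial averaged normalized baselines sit at 1.00 ± 0.03.

**Unit verification**: a PC requires complex spikes plus a
post-complex-spike pause in the complex-spike-triggered simple-spike
average — rate below 50% of the pre-event rate for ≥ 8 consecutive ms
within 20 ms (the source criterion is qualitative; these constants are
configurable). An eyelid PC additionally shows a complex spike within
(0, 10] ms after at least 50% of US deliveries.

**Grouping**: trials with the keyed CR are sorted by onset or amplitude
and split into three equal subgroups (remainder to the earliest); non-CR
trials form their own group, whose size is not controlled. Second-CR
keys consider only trials with a first CR above 3 mm. Where the source
narrative mentions both "three groups (non-CR, early, late)" and "three
equal subgroups", the implementation keeps non-CR + three CR subgroups
and displays the extremes.

**Averages and separation**: pointwise mean across trials with 95% CI as
mean ± 1.96·SEM (bootstrap percentile is available); CI non-overlap at a
time point is the separation criterion; behavioral and neural averages
are truncated at the delivered US. **Onset alignment** shifts each CR
trial so its onset maps to 0; non-CR trials receive a pseudo-onset drawn
(seeded) from the empirical CR-onset distribution. The pre-onset
decrease metric is the aligned average at time 0 exactly (a 10 ms window
variant is a trivial change and gave indistinguishable values on
synthetic data).

## The synthetic generator

The generator defines the study conditions the tests run under. It
emulates: the block structure (12 blocks of 1 CS-alone + 8 paired; CS2
test sessions of 108 trials at a 60/25/15 CS1/CS2-paired/CS2-alone mix,
largest-remainder apportionment), the amplitude contingency evaluated on
the clean first-CR profile at the US₁ time, US-evoked full-closure
unconditioned responses, chained second/third CRs (third and later only
where no US truncates the sequence; cross-eye chaining and no third CRs
in the contralateral protocol), sympathetic right-eye co-movement (gain
0.05), optional planted screening violations, and eyelid-PC spike trains.

The CR waveform is a quarter-sine rise to the peak followed by an
exponential decay. A strict sigmoid rise was considered and rejected:
with zero slope at onset the clean signal departs quadratically, and
under 0.05 mm noise the onset of small CRs is not localizable to 10 ms by
*any* linear back-projection — the information is absent from the trace.
A quarter-sine keeps peak-equals-amplitude and smoothness at the peak
while giving the movement a definite initial velocity, which is also the
more realistic kinematics for ballistic eyelid closures.

Defaults (placeholders in the documented sense — the source experiments
publish no numerical onset/amplitude distributions): first-CR presence
0.9; onset ~ N(300, 55²) ms truncated to [10, 450]; amplitude
~ N(3.5, 1.2²) mm truncated to [0, 6]; rise 190 ms (CRs peak near the
US₁ time, so the contingency is live); decay constant 250 ms; chain
probability = 0.85 · min(prev amplitude / 3 mm, 1); amplitude ratio 0.7
with 15% multiplicative jitter; interval jitter SD 30 ms; trace noise SD
0.05 mm (half the stated detector resolution). The onset-to-onset chain
interval adapts to the protocol (CS duration + gap − rise − mean onset)
so the next CR peaks at the trained US₂/US_R time; an explicit value
overrides. In chained mode the next onset is
`gain · previous onset + interval + jitter`; in independent mode the
reference onset is redrawn, erasing the trial-by-trial dependence while
preserving the marginal timing distribution. A `cs1`-bound variant
generates later CRs only on CS1-cued trials, the alternative hypothesis
the CS2-transfer analysis must reject.

A next CR is planted only if its amplitude exceeds `0.6 + 0.2 · previous`
mm and its peak lies ≥ 300 ms before the record end: a chained bump below
the 0.5 mm prominence resolution (riding on the previous decay tail) or
clipped at the edge is not a distinct CR under the counting rule, so
planting one would make planted-event recovery ill-posed rather than
harder. Each trial records its ground truth: nominal onsets/amplitudes
plus the realized peak time/amplitude of each bump on the clean summed
trace (superposition shifts peaks by a few ms).

With the default 55 ms onset spread, the chained-mode correlation between
first- and second-CR onsets exceeds 0.8 for interval jitter up to ~5% of
the chain interval (the default 30 ms); larger jitter-to-spread ratios
lower the correlation as basic variance arithmetic dictates.

The PC model: simple spikes are Bernoulli per 1 ms bin at
`baseline · (1 − dip_depth · CR profile shifted earlier by dip_lead)`
clipped at zero (baseline 70 Hz, 0.15 per mm, lead 50 ms); one complex
spike 3 ms after each delivered US, followed by a 15 ms simple-spike
pause. Determinism: all randomness flows from one `SeedSequence` per
session with per-trial and per-unit spawned substreams; identical
configuration and seed reproduce a session exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no learning dynamics within or across sessions
(acquisition/extinction schedules must be imposed parametrically), no
biomechanical eyelid model or EMG-like noise structure (noise is white
and additive; real detector noise may be correlated), no slow baseline
drift or blink artifacts beyond the planted screening violations, single
CR waveform family, and PC rate dips that are exact linear functions of
the planted profile rather than of a latent motor command.

## Problem sizes

The test and acceptance runs use: 504 trials for noise-free recovery and
~500 for noisy recovery; 200 replicates × 100 trials × 2000 permutations
for shuffle-null type-I error and 100 for power; 500 replicates at
50 trials/bin × 6 bins for bootstrap coverage; 100 s spike trains per
rate for estimator calibration; one 108-trial session × 16 units for the
alignment analyses; and 16 CS2 test sessions per generative mode for the
transfer discrimination. These sizes give Monte-Carlo error comfortably
inside each asserted band.

## Known limitations

* The delayed/absent first-CR estimate and the single-peak second-CR
  search are heuristics for genuinely ambiguous trials; both flag their
  outcomes rather than deciding silently.
* The squint gate still excludes trials whose first CR is small
  (< 1 mm range over the gate windows), slightly depleting the lowest
  occupied amplitude bins of the conditional-probability table.
* The permutation-calibrated shuffle p is exact only under full
  exchangeability; heteroscedastic timing noise across trials would make
  it approximate.
* CI non-overlap is a conservative separation criterion; it is used for
  fidelity to the analysis it reproduces, not as an optimal test.
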