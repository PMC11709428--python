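# Methods

`dendrosync` simulates and analyses fiber-photometry recordings of the GnRH
neuron dendron in freely behaving mice, together with coupled luteinizing
hormone (LH) measurements from serial tail-tip blood samples.  The package
has two halves that validate each other: a generator that renders
two-channel photometry with known ground truth, and an analysis pipeline
that must recover the generating parameters blind.

## Signal model

The calcium-dependent channel is modelled as

    F465(t) = B(t) · (1 + b(t) + s(t) + u(t) + m(t)) + ε(t)

where `B(t) = F0·[(1−d) + d·exp(−t/τ)]` is single-exponential photobleaching
(default τ = 6 h, depth d = 20%, F0 = 300 a.u.), `b` is low-amplitude
clustered baseline activity, `s` the dendron synchronization episodes
(dSEs), `u` the proestrus surge (zero in other profiles), `m` brief biphasic
motion artifacts (2/h, 5% fractional amplitude, shared with the reference
channel so isosbestic subtraction can cancel them), and `ε` white sensor
noise (0.3 ΔF/F percentage points per 10 Hz sample).  The 405 nm reference
channel carries the same bleaching curve (scaled to 40% of F0) and the same
fractional motion artifacts, but no calcium signal.  Scheduled acquisition
(5 s on / 10 s off) zero-masks the off windows and emits an explicit mask.

### dSE waveform

Only three summary measures of the episode waveform are available: the rise
and decay widths at half maximum measured separately on each limb
(30 s and 102 s in males; 31 s and 81 s in females) and the total duration
(658 s males, 463 s females).  The kernel family is a half-Gaussian rise
joined at the peak to a two-exponential decay.  The rise sigma follows from
the half-max-to-peak width; the two decay time constants are solved
numerically (with a fixed slow-tail fraction of 0.45) so that the decay
crosses one half at the decay FWHM and 5% of the peak at the offset implied
by the total duration, which is defined as the 5%-of-peak
crossing-to-crossing extent.  An infeasible triple raises a configuration
error.  The absolute episode amplitude is not reported anywhere; the default
of 20 ΔF/F% is an explicit free parameter, and only amplitude *ratios*
(baseline activity at 11% of the dSE amplitude in males, 8.5% in females)
are calibrated quantities.

### Inter-episode intervals

Intervals are gamma-distributed with the shape pinned by the printed sample
skewness (2/√k, so k ≈ 2.07 for the male skewness of 1.39) and the mean set
per stage: 93.3 min (male), 70.2 (metestrus), 46.2 (diestrus), 38.8
(proestrus), 151.0 (estrus).  Draws below the smallest observed interval
(3.9 min) are resampled.  No upper truncation is applied: numerical
integration shows that a gamma truncated to the observed male range can
never exceed skewness ≈ 1.11 whatever its shape, so hard-truncating would
contradict the very statistic the shape is calibrated to; the observed
maximum (346.6 min) is instead consistent with an untruncated gamma, which
exceeds it in only ~0.5% of draws.

### Baseline clusters

Low-amplitude micro-events are laid out in clusters whose durations are
gamma-distributed (shape 8) around the stage mean (22.5 min in males), with
inter-cluster gaps uniform in 8–25 min — at least 8 min so that the
analysis-side 420 s separation rule can resolve cluster boundaries.  Within
a cluster, raised-cosine micro-events (40 s width, ±8 s jitter) occur at the
intra-cluster frequency (default 0.012 Hz, the middle of the reported
0.006–0.018 Hz band).  Clusters avoid the dSE footprint
[peak − 120 s, peak + 660 s]: during an episode the micro-activity is
swamped by the episode itself, and the event-kinetics measurement needs an
uncontaminated local baseline and decay tail.

### Proestrus surge

The surge envelope's rising and falling limbs are monotone PCHIP curves
through the anchors the timing statistics define: onset 4.0 h before
lights-off (σ = 0.75 h per animal), peak 5.9 h after onset, return to
baseline 12.6 h after onset, incline/decline half-maximum widths 3.1/4.7 h,
peak amplitude uniform in 20–40 ΔF/F%.  Because the onset of the real
recordings was itself *defined* by a 5-percentage-point detection rule, the
ground-truth onset is defined the same way: the clean envelope crosses
5 pp exactly at the nominal onset, with a sub-detection foot extending
30 min earlier.  A zero-mean multiplicative oscillation (depth 0.5) with
trough-to-trough periods drawn from a normal(78, 20) min distribution
clipped to 32–150 min rides on the envelope; modelling it as symmetric
about the envelope (rather than as dips below it) keeps the 5 pp crossing
of the rendered signal unbiased around the nominal onset.  dSE generation
halts for 5 h starting at the envelope peak, emulating the episode arrest
around the surge plateau.

### LH secretion

Latent LH = basal (0.3 ng/mL) + one pulse per dSE + a surge term.  Each
pulse is a difference of exponentials whose rise constant is solved so the
pulse peaks exactly `peak_lag_min` after its dSE peak (5.0 min male,
6.1 min female) and clears with an 8-min half-life; the 1.5 ng/mL amplitude
makes pulses unambiguous at 5–10 min bleeding.  The surge term is driven by
the *slow* envelope (a 90-min moving mean of the rendered surge component,
so the ~78-min crests do not propagate into LH) through a desensitizing
pituitary gain: a sigmoid in cumulative normalized calcium exposure with
midpoint 1.6 exposure-hours past the exposure reached at the envelope peak
and width 0.15.  The gain scale is calibrated numerically so the latent
surge peaks at exactly 9.3 ng/mL; the same gain multiplies post-surge
pulses, so LH returns to basal hours before the calcium envelope offset, as
observed.  Samples are latent values times lognormal assay noise (CV 8.2%)
floored at the 0.04 ng/mL assay sensitivity.

## Analysis pipeline

**Preprocessing.**  Scheduled traces are first collapsed to one sample per
on/off cycle (window means at window centres; gaps are never interpolated).
Reference subtraction fits the 405 channel to the 465 channel by least
squares, subtracts the fitted reference and re-adds its mean ("scaled"
mode; the literal direct subtraction is available behind a flag).  The
photobleaching baseline a·exp(−t/τ) + c is fitted to 60-s block medians by
quantile (pinball) regression at the 0.15 quantile, then refined by least
squares on baseline blocks after asymmetrically clipping elevated blocks —
calcium transients and the surge are strictly positive excursions, and on
proestrus the surge occupies half the recording, which defeats symmetric
robust losses.  ΔF/F = (F − F_baseline)/F_baseline × 100.

**Event detection.**  Local-maxima search on a 10-s moving mean with
minimum prominence 5 pp, minimum separation 180 s, and a maximum width at
half prominence of 600 s (which rejects slow ultradian crests).  The local
baseline per event is the median of [peak − 600 s, peak − 120 s] excluding
other events' footprints.  Rise/decay FWHM are interpolated half-max
crossings on the 10-s smoothed trace; the 5%-of-amplitude extent is
measured on a 30-s smoothed copy because the decay tail is nearly flat at
the 5% level and noise there converts directly into crossing-time error.
Crossings not found before the adjacent event or within 1200 s flag the
event truncated and its affected measures null.

**Interval statistics.**  Bias-uncorrected sample moments (Fisher–Pearson
g1; both Pearson and excess kurtosis are reported because both conventions
appear in practice), Shapiro–Wilk normality, and a 10-min right-open
histogram in percent.  Stage comparisons use Kruskal–Wallis with hand-rolled
Dunn post-hoc z tests (pooled midranks, tie correction), reported unadjusted
and Bonferroni-adjusted.

**Surge extraction.**  A 30-min centred moving mean with shrinking edge
windows (MATLAB `movmean` convention).  Onset is the earliest time the
smoothed trace exceeds the baseline-epoch (first 2 h) median by more than
5 pp; a literal running-maximum variant is retained behind a flag but can
only fire on a discontinuous rise, since on a continuous one each sample
exceeds the running maximum infinitesimally.  Peak is the highest smoothed
value after onset; offset is where the elevation has decayed by 90%
(baseline + 10% of the excursion — a literal 0.9 × baseline sits below
pre-surge levels and is unreachable).  Incline/decline FWHM are interpolated
half-excursion crossings.  In the pipeline the smoother runs on a
pulse-excised copy of the trace (detected episodes replaced by linear
interpolation): smoothed episode bumps are ~2 pp tall and otherwise bias
the onset late.  Oscillations are segmented as troughs of the smoothed trace
between onset and offset (prominence ≥ 2 pp, separation ≥ 20 min), each
consecutive pair defining one trough-to-trough duration.  The surge trace
is then subtracted pointwise, and episode detection runs on the residual.

**Residual clustering.**  Samples in [peak − 60 s, peak + 360 s] around
every detected episode are excised (overlaps merge).  Residual peaks are
local maxima of the 10-s smoothed residual above the median of non-excluded
samples plus a threshold, with 30 s minimum separation.  The printed
5%-above-baseline threshold presumes episode amplitudes large enough that
baseline events (5–12% of the episode amplitude) clear it; at the
generator's free 20 ΔF/F% episode scale the micro-events sit near 2.2 pp,
so the pipeline's synthetic-scale configuration uses a 1 pp threshold while
the library default stays at the printed 5 pp.  Peaks more than 420 s after
their predecessor start a new cluster (exactly 420 s stays in-cluster);
single-peak clusters have no defined duration and are excluded from the
duration/frequency summaries.

**LH analysis.**  A sample is a pulse peak when it exceeds both neighbours
and the minimum of the preceding window (two nominal sampling intervals, at
least 10 min) by 6 × assay CV times that minimum; the minimum of noisy
samples is biased low, so the multiple is conservative.  Each detected LH
pulse is attributed to the latest unused preceding dSE within 20 min —
when two episodes fall minutes apart their LH pulses merge, and the merged
peak belongs to the later episode.  Matching is order-preserving.  Surge
concordance estimates the LH surge onset (first sample above twice the
pre-onset median) and return-to-basal (first post-peak sample below
basal + 10% of the LH excursion), placing both crossings at the midpoint of
the bracketing sample pair (midpoint imputation for interval-censored
times), and reports the onset and offset differences against the calcium
surge.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses consume: episode
waveform summaries, right-skewed interval distributions per stage, clustered
baseline micro-activity, the surge envelope with ultradian oscillations and
episode arrest, LH pulse lags and the surge LH profile, photobleaching,
shared motion artifacts, sensor and assay noise, and both acquisition modes.
It does not emulate hemodynamic or pH artifacts, slow drifts that are not
exponential, animal-to-animal waveform variability beyond amplitude jitter,
behavioural covariates, or any within-episode fine structure — so passing
recovery tests demonstrate that the pipeline implements its rules correctly
at realistic signal-to-noise, not that those rules are optimal for every
artifact real recordings can contain.

## Problem sizes and numerical choices

Recovery checks use five 24-h male traces, five 6-h diestrus traces, six
4-h pulse-bleeding traces per sex with 5-min LH sampling, and ten 24-h
proestrus traces with 3-h LH sampling over 18 h — enough to hold the
recovered means well inside their tolerance bands while a full suite run
stays in the minutes range.  Two statistics remain intrinsically noisy at
these sizes and are reported as such: the pooled interval mean over five
24-h windows carries a −3…−5% length-censoring bias plus a ±8% standard
error, and the pooled sample skewness of ~150 gamma intervals has a
standard deviation of ≈ 0.35, so individual seed sets scatter widely around
the calibrated 1.39.  All randomness flows from one seed through named
child generators (intervals, amplitudes, clusters, surge, motion, two noise
channels, LH assay), making every output bit-reproducible.  Tie-breaks and
degenerate inputs: all-identical samples give Kruskal–Wallis p = 1; an
all-zero reference channel falls back to direct subtraction with a warning;
a non-convergent bleach fit falls back to a constant low-quantile baseline;
surge detection requires at least 12 h of data and returns none rather than
guessing.

## Known limitations

The onset-to-peak recovery inherits a small late bias (~10–20 min) from the
oscillation phase at the detection crossing; the sparse-sampling LH lag
carries up to half a sampling interval of quantization; cluster spans
measured peak-to-peak understate the generating cluster duration by about
one micro-event spacing; and the 5%-extent duration measure is sensitive to
local-baseline errors because the calibrated decay tail is nearly flat at
that level — the measurement-side smoothing and baseline-exclusion choices
above exist to keep that sensitivity in check.
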