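# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `stepnet`: a pipeline for normative scoring of spatiotemporal
ERP peaks (STEPs), trial-to-trial ERP variability (ERPv), behavioral
performance measures and group-discrimination statistics, together with the
synthetic task-evoked EEG cohort generator that makes every stage testable
without access to clinical recordings.

## The analysis model

### STEP extraction and normative percentile scoring

The core procedure treats a subject's condition-average ERP as a smooth
scalp field evolving in time and reduces it to a small set of salient
spatiotemporal peaks:

1. **Band filtering.** The condition average is filtered into three
   overlapping physiological bands — delta 0.5–4 Hz, theta 3–8 Hz, alpha
   7–13 Hz — with a least-squares linear-phase FIR (101 taps at 250 Hz,
   2.5 Hz transition bands) applied forward and reverse (`filtfilt`), so the
   net phase is zero and peak times are not displaced. Because the filter is
   linear, filtering the average equals averaging filtered epochs; the
   implementation filters the average, which is two orders of magnitude
   cheaper at identical output.
2. **Scalp gridding.** Each time slice is interpolated onto a 32 × 32 grid
   over the unit disc (azimuthal-equidistant projection of the 64-channel
   cap, nose up) with an exact thin-plate-spline interpolant; nodes outside
   the disc are masked. "High resolution" is not quantified anywhere
   authoritative; 32 × 32 puts ≈ 0.065 disc radii between nodes, several
   times finer than the inter-electrode spacing.
3. **Peak parcellation.** STEPs are the strict local extrema of the
   (x, y, t) volume in a 3 × 3 × 3 neighborhood, post-stimulus, with
   |amplitude| ≥ 1 μV (a config value suppressing noise extrema after
   filtering). Exact plateaus — e.g. a noiseless bump centered between two
   grid nodes — yield one STEP per connected equal-valued plateau. Each peak
   carries its half-amplitude surround: the 26-connected, same-sign region
   with at least half the peak's absolute amplitude. The 15 most salient
   peaks per condition × band are kept.
4. **Clustering.** Reference subjects' STEPs (one band × condition at a
   time) are agglomerated under the capped metric
   `max(|Δt|/100 ms, Δs/0.5 radii)` with polarity mismatches forbidden,
   average linkage, cut at 1. A cluster is a *main STEP* iff ≥ 70% of the
   subjects contribute at least one member (a subject counts once — its
   STEP nearest the centroid). Average linkage was chosen over complete
   linkage after observing that detected peak locations jitter by more than
   any reasonable pairwise cap, which shatters true clusters under complete
   linkage; under average linkage the caps constrain typical, not worst-case,
   pairs. The spatial cap of 0.5 radii reflects the measured spread of
   detected peak locations for one underlying component.
5. **Matching and scoring.** A subject's STEPs are assigned to main STEPs
   greedily by ascending normalized distance √((Δt/σt)² + (Δs/σs)²), σ being
   the cluster dispersions floored at (25 ms, 0.1 radii); a candidate must
   share the template's polarity and lie within windows of 2× the cluster
   dispersion, floored at (100 ms, 0.3 radii). The floors are deliberately
   wide: a clinically delayed peak (+50–60 ms) must remain inside the
   window, otherwise pathology silently becomes "unmatched" rather than a
   low/high score. Matched amplitude (signed, μV — no rectification, so a
   shallower negativity scores higher) and latency (ms from onset) are
   converted to mid-rank percentiles against the reference distribution:
   `100 × (#{ref < x} + ½ #{ref = x}) / n`. Unmatched templates produce no
   percentile and are excluded from group statistics, with the match rate
   reported.

The reference group holds, per main STEP and attribute, the sorted values of
its 120 members (templates matched by fewer than half the members are
dropped). Scoring a reference member against its own group yields, by
construction of the mid-rank formula, percentiles uniform on [0, 100] — the
calibration property the acceptance suite verifies.

### ERP variability

ERPv is the trial-by-trial standard error (n−1 SD over trials, divided by
√n) of the amplitude at every post-stimulus sample and electrode, averaged
over all of them: one scalar per subject × condition, computed on broadband
cleaned epochs outside the band-filtered STEP flow. Valid trials are correct
responses (response conditions), correct inhibitions (NoGo), or all
artifact-free trials (Frequent/Novel). The raw score is in μV; since no
authoritative unit exists for the published 0–1-range values, a normalized
variant divides by the RMS of the condition-average post-stimulus ERP and
is the score used for group discrimination. Neural consistency is
1 − normalized ERPv. Group comparisons of ERPv therefore assert directions
and separability, never published magnitudes.

### Preprocessing

Cleaning order: bad-electrode detection → blink ICA → epoch rejection (the
order is not fixed by any authority; rejecting epochs last avoids discarding
epochs whose only defect was a removable blink).

- *Bad electrodes*: more than 5% of samples outside ±100 μV ("extensive" is
  unquantified; 5% is the package's choice), or correlation with the mean of
  the 4 nearest neighbors below 0.05. The correlation threshold is
  deliberately permissive: single-trial EEG is noise-dominated, and with
  channel-independent sensor noise even healthy channels correlate only
  weakly with their neighbor average — the rule is meant to catch channels
  sharing *nothing* with the scalp. Flagged channels are interpolated from
  their nearest good neighbors (inverse-distance weights).
- *Blink removal*: FastICA on concatenated epochs (20 components);
  components whose time course correlates |r| > 0.7 with the ocular proxy
  (mean of the two most anterior channels — no dedicated EOG channel is
  simulated) are subtracted, at most 2. An unconverged unmixing is still
  used; a failed decomposition passes data through with a logged warning.
- *Epoch rejection*: an epoch is dropped iff any sample exceeds ±100 μV or
  lies more than 7 per-channel SDs from the per-channel mean, statistics
  pooled over all epochs of the same condition; the epoch is judged on its
  worst channel.

### Statistics

Per score: a two-level mixed (split-plot) ANOVA with group
(healthy/patient) between subjects and visit (1/2) within subjects,
reporting the between-group F, its degrees of freedom and unadjusted p
(Benjamini–Hochberg available behind a flag, off by default, matching
standard per-score clinical ERP reporting); Levene's test on absolute
deviations from group means, with Welch's t (summary-statistic form, with
Welch–Satterthwaite df) reported when Levene is significant; Cohen's d on
subject-mean scores with pooled n−1 SD, signed patient − healthy; ROC
analysis with patients as positives, AUC by the tie-corrected rank
(Mann–Whitney) formulation, oriented to ≥ 0.5, and the Youden-optimal
operating point; test–retest reliability as ICC(A,1) — two-way model,
absolute agreement, single measurement (no model is named anywhere
authoritative; absolute agreement is the conservative choice for a score
meant to be comparable across visits). The ROC observation unit is the
subject × visit score. Subjects missing a visit are deleted listwise from
the ANOVA. The mixed ANOVA and ICC are computed via pingouin; the test
suite checks both against hand-coded sums-of-squares and variance-component
oracles, and AUC against exhaustive pair counting.

## The synthetic cohort generator

The generator is first-class, tested code. Its defaults are the study
conditions: an auditory oddball of 600 tones (80% Frequent at 2 kHz, 10%
Target at 1 kHz, 10% Novel with per-trial random frequency; one tone per
1.5 s; epochs −200…+1200 ms), a Go/NoGo task of 300 tones (80/20, ISI
uniform on 1000–2000 ms; epochs −200…+800 ms), 64 channels at 250 Hz,
30 healthy + 9 patient subjects, two visits with identical subject-level
parameters and fresh trial noise (which is what makes test–retest
reliability positive), and behavioral defaults equal to the published group
summaries (e.g. patient oddball RT 570.68 ± 119.31 ms). The ambiguous
phrase relating the 1000–2000 ms ISI range to an additional "jitter of
100–50 ms" is resolved by implementing the uniform range only.

**Components.** Four planted components with canonical topographies and
latencies: N100 (−, fronto-central, 100 ms), P200 (+, central, 200 ms),
N2 (−, frontal, 250 ms, NoGo only), P3a (+, fronto-central, 300 ms,
Novel/NoGo). Each is amplitude × spatial kernel (isotropic Gaussian over
disc positions) × temporal kernel. The temporal kernel is a Gaussian
envelope; components whose nominal band lies above delta additionally carry
a cosine at the band's center frequency (5.5 Hz for N100/P200, 10 Hz for
N2), making each component band-limited to its own band. A pure Gaussian
bump concentrates its energy at DC regardless of the component's nominal
band, which floods the delta-band grid with early-component leakage and
makes the per-band extraction scientifically meaningless; band-limited
kernels are what per-band scoring presupposes. Amplitudes default to
N100/P200 4 μV, N2 3 μV, P3a 8 μV — the novelty P3a is canonically the
dominant slow deflection of the novelty response, roughly twice the early
components in grand averages.

**Noise and variability.** Per-trial amplitude jitter (1 μV SD), latency
jitter (20 ms SD), additive white sensor noise (6 μV SD;
1/f-shaped noise available behind a flag), and stereotyped biphasic 300-ms
blink transients (120 μV at a virtual ocular site above the nose, decaying
with scalp distance, Poisson-arriving at 4/min) on frontal channels.
Between subjects, component amplitudes/latencies vary by their stated SDs
and the noise/jitter SDs by lognormal factors (15–20%), so discrimination
metrics are not degenerate.

**The patient effect.** Patients differ by the planted group effect:
P3a latency +50 ms, P3a amplitude ×0.7, and a 1.5× *trial-jitter* factor
that scales all trial-level stochasticity — component jitter *and* sensor
noise. The last point is a deliberate interpretation: with flat sensor noise
common to both groups, scaling only the component jitter changes the
single-trial SD by under 2% (the kernels occupy a small fraction of the
epoch), and elevated trial-to-trial variability in *every* condition — the
phenomenon ERPv measures — is precisely an elevated neural-noise effect.
Behavioral patient defaults (slower, more variable RTs; more misses; NoGo
commission rate as published) are separate parameters, so zeroing the EEG
group effect leaves EEG scores exchangeable between groups.

**Seed policy.** One master seed; every subject × visit × task × stream
(signal/noise/blinks/behavior) derives its generator from
`numpy.random.SeedSequence(master, spawn_key=...)`. Cohorts are lazy: a
recording is materialized on demand and reproduced bit-identically, so the
full default cohort (which would occupy ≈ 8 GiB eagerly) never has to fit
in memory.

**What the generator does not emulate.** No head-model forward physics, no
spatially correlated background EEG (sensor noise is channel-independent),
no muscle or line-noise artifacts, no habituation/sequential effects, no
age or sex dependence of the signals (demographics are metadata only), no
speed–accuracy trade-off. Consequently, passing tests demonstrate that the
pipeline recovers planted effects under idealized noise — not that it would
behave identically on clinical EEG, where neighbor-correlation thresholds,
ICA component counts and the 1 μV extraction floor would need re-tuning
against real recordings.

## Problem sizes of the verification experiments

The planted-effect recovery experiment uses a shared 120-member normative
reference (60 Novel epochs per member — the per-session Novel count of the
default oddball) and 20 replicate cohorts of 30 + 9 subjects × 2 visits.
Because epochs are statistically independent in the generator, each
replicate simulates exactly the condition subsets the analysis consumes:
60 Novel epochs per subject × visit for P3a scoring (delta band), and
48/12-trial condition subsets per task for ERPv; this is distributionally
identical to subsetting full task runs. Null calibration of the statistics
layer runs 500 score-level simulations (39 subjects × 2 visits, no group
difference). The percentile-calibration check builds a 120-member reference
at the STEP level (generator-drawn peak attributes), exercising the
cluster → match → percentile machinery directly; the full-EEG reference
path is exercised at 120 members in the recovery experiment and at smaller
sizes in unit tests. The STEP-extraction oracle check runs 200 random
smooth 16 × 16 × 50 volumes against an exhaustive neighborhood scan.

## Numerical and degenerate-input conventions

Half-open time windows `[start, end)`; epoch sample 0 at −200 ms; latencies
in ms from stimulus onset. Sample SD (n−1) throughout, including the RT
outlier rule, which is single-pass: mean and SD computed once on the full
list, no re-iteration, nothing excluded when SD = 0. Percent-correct
denominators are all trials of the condition; NoGo correctness means a
withheld response. A recording is valid iff overall percent correct ≥ 65%.
RT outlier statistics are computed per subject × visit × condition. Ties in
percentile scoring take mid-rank. Zero-variance inputs raise (`ICC`,
normalization by a zero-RMS ERP) or short-circuit (Levene/ANOVA on
identical values → statistic 0). EDF I/O quantizes to 16 bits over a
symmetric range covering the recording; intermediate pipeline stages
therefore exchange float arrays and only the interchange format quantizes.

## Known limitations

- The matcher's similarity metric and normalization are package choices
  (declared above, configurable); the original proprietary matcher is not
  disclosed, so only its documented behavior — polarity, time/space
  windows, percentile conversion — is reproduced.
- Published score magnitudes (ERPv values, percentile-score tables) are not
  reproduction targets: the clinical EEG is private, so verification rests
  on calibration properties, planted-effect recovery and direction patterns.
- Per-band extraction treats bands independently; a peak appearing in two
  overlapping bands is scored in both.
- The EDF writer covers the subset of EDF+ needed here (uniform sampling
  rate, one data record per second, no annotations).
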