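# Methods

## The paradigm and its timeline

One experiment is a single absolute clock in seconds: a 5-min rest epoch,
then three 10-min linear-chamber sessions — empty-empty (`EE`), first
social-object (`fSO`), second social-object (`sSO`, sides swapped).  All
intervals are half-open `[start, end)`; tracking runs at 30 frames/s in
chamber coordinates (x ∈ [0, 45] cm along the corridor, y ∈ [0, 10] cm).
Six per-session targets exist for trial bookkeeping (left/right empty in
EE, social/object in each S-O session); for responsiveness classification
the contexts are pooled: empty bouts over both EE sides, social and object
bouts over both S-O sessions, and center-zone bins over all three sessions.

## Behavioral events

Sniffing is a nose-position band: nose x within 3 cm of a face, across the
full corridor width (the face band, not a radial disc; radial distance to
the face center is used only for the object proximity profile).  In-zone
and center membership use the **midpoint of nose and tail base** (not the
tracked body-center point), against the 9-cm band and the middle of the
five 9-cm sections (`[18, 27)` cm).  Frame runs become intervals
`[t_first, t_last + 1/fps)`.

Validity filtering is a single forward scan: drop bouts shorter than the
minimum duration, then drop bouts whose gap from the previously *retained*
bout is below the minimum gap (sniffing: 1 s / 2 s; in-zone and center:
0.5 s / 0.5 s; proximal/distal: duration ≥ 1 s only).  The scan is
idempotent by construction.  Frames whose required part falls below a 0.9
likelihood are filled by last-observation-carried-forward; no other gap
model is applied.

## Unit classification and inclusion

Putative excitatory (pExc) units need half-valley width strictly above 200
and peak-to-valley ratio strictly above 1.4; putative inhibitory strictly
below both.  Discordant or exactly-on-threshold feature pairs are
*unclassified* and excluded — the rule defines only the two concordant
cells of the 2×2.  The half-valley-width threshold is applied to the stored
feature value as-is; its printed unit is treated as a label on the feature
scale, not converted.  Cluster quality requires isolation distance > 25 and
L-ratio < 0.1 (strict).  The rate filter requires a mean rate ≥ 0.5 Hz
(inclusive) over the 30-min chamber epoch; rest-period rate comparisons
bypass it.  If any of the six targets lacks a valid sniffing or in-zone
trial, the whole experiment's units are excluded.

## Responsiveness calling (auROC + permutation)

Instantaneous rates are spike counts in consecutive 0.5-s bins cut from
each valid bout's start; a trailing remainder < 0.5 s is discarded so bins
are identically sized.  The ROC compares the sniffing-rate and
center-rate distributions by sweeping a threshold across the pooled
[min, max] range in 100 steps, plotting P(sniff > thr) against
P(center > thr), closing the curve at (0,0) and (1,1), and integrating by
trapezoids.  The sweep agrees with the exhaustive rank-statistic AUC (ties
counted ½) within 0.01 on continuous data — that agreement is the
contract, and a test enforces it.

The null re-partitions the pooled bins into groups of the original sizes
(label permutation), 1000 times; a unit is responsive iff its observed
auROC is strictly above the 99.5% or strictly below the 0.5% quantile of
the shuffled distribution (quantiles by linear interpolation).  Fewer than
40 bins (20 s) in either context → `insufficient_data`.  The shuffle loop
is vectorised as a selection-matrix product over the precomputed
rate-vs-threshold indicator matrix, which is why 10,000-unit calibration
runs fit in a test suite.  Under the null the two-tailed call rate is the
nominal 1% (Monte-Carlo checked).

Spike density functions use 250-ms bins from −1.5 to +3 s around sniff
onsets, averaged over trials; for group averages each unit is normalized by
the joint maximum across its three target SDFs, so cross-target amplitude
relations survive.  z-scores are (FR_T − µ_C)/σ_C with µ_C, σ_C the mean
and sample SD of the center bins; trial consistency is the percentage of
per-trial z-scores matching the unit's direction (z = 0 counts against).

## Decoding

A linear SVM (C = 1, no feature standardisation — mirroring the default of
the common reference routine) decodes the session's class pair from trial
rates (spikes in a valid sniffing trial / trial duration).  Each repetition
samples 10 trials per class without replacement; leave-one-out holds out
the i-th trial of each class, trains on the remaining 18, tests the 2
held-out trials; 100 repetitions give the mean accuracy.  Pseudo-population
ensembles sample units and, per unit, 10 trials per class independently;
the i-th sampled trials concatenate into one feature vector (units come
from different experiments, so pairing is by sampling index).  The shuffle
control permutes class labels over the repetition's 20 selected trials,
i.e. re-partitions them into two balanced pseudo-groups — every fold still
trains on 9 + 9, which keeps the control unbiased at 50% (an unbalanced
per-fold shuffle would push leave-one-out systematically below chance).
Decision values exactly 0 count as incorrect, deterministically.  "Correct
neurons" are single units with mean accuracy strictly above 55%.

## Firing-rate dynamics

Windows of 3 s advance in 1-s steps from the epoch start; the k-th window
is truncated at the epoch end and its rate uses the actual window length,
so a 30-min epoch yields exactly 1800 rates (window sizes 0.5–5 s are
supported).  Sigma is the **sample** SD (n−1) of the series; range is
max − min.  Per-session statistics use the windows whose start lies in the
session.  Normalized-rate histograms divide by the series maximum and bin
over [0, 1] in 0.1 steps, the top bin right-closed.  The σ-vs-mean contrast
fits OLS of log10 σ on log10 mean per group and applies the
slope-comparison test below.  Maximum Δ firing rate compares each in-zone
rate (spike count / total valid in-zone duration) with the center-zone
rate; the normalized form divides each difference by the corresponding sum
and is bounded in [0, 1].

## Bursts

Burst spikes participate in at least one ISI ≤ threshold (default 10 ms,
sweep 5–30 ms, comparisons inclusive); chains count every member.  ISI
histograms use 1-ms bins up to 200 ms (1 ms resolves the few-ms structure
the analysis cares about), normalized by the count of *all* ISIs.  Epoch
restriction precedes ISI formation, so no ISI crosses the rest/chamber
boundary.  Burst elimination removes all burst-participating spikes, tonic
elimination removes exactly the complement; the outputs always partition
the train, and downstream analyses accept either output unchanged.

## Intrinsic properties

From 500-ms current steps (−300…400 pA by 50 pA): AP threshold is the
membrane potential at the last upward crossing of dV/dt = 5 mV/ms
preceding each peak (central differences, linear interpolation; peaks are
local maxima above 0 mV); amplitude and AHP are the positive and negative
excursions from that threshold (AHP searched within 20 ms after the peak,
stopping at the next peak); FWHM is the interpolated width at threshold +
amplitude/2.  Input resistance is |steady-state − baseline| / 100 pA with
the steady state averaged over the final 100 ms of the −100 pA step.  The
sweep simulator combines a single-exponential RC subthreshold response
with stereotyped triangular APs whose rise/fall times are solved so the
analytic half-height width equals the requested FWHM; spike times follow a
linear F–I gain with mild adaptation, and an optional doublet probability
adds 8-ms ISI bursts.  Extraction recovers threshold, amplitude, and input
resistance within 2% across a parameter grid (tested).

## Slope / elevation comparison

For two groups, the slope test uses t = (b₁ − b₂)/SE with the residual
variance pooled over the two separate fits and df = n₁ + n₂ − 4.  If the
slopes are homogeneous at α = 0.05, a common-slope model tests elevation:
t = [(ȳ₁ − ȳ₂) − b_c(x̄₁ − x̄₂)] / SE, df = n₁ + n₂ − 3.  A test verifies
the slope t against an OLS group×x interaction fit.  Other group tests
(Mann-Whitney, RM-ANOVA, Friedman, Fisher) are delegated to standard
statistical routines by the caller; the pipeline emits the counts and 2×2
tables they need rather than re-deriving them.

## The synthetic-data generator

**Trajectory.** A bounded random walk with dwell states: the body center
alternates between the two faces (dwells of 2–4 s at 2.8–3.8 cm from the
face, travel at 8–12 cm/s, occasional 0.8–1.6 s center pauses).  Body
parts sit at fixed offsets from the heading (nose 2 cm ahead, tail base
2 cm behind, ears ±1 cm laterally); lateral position is an AR(1) wander
around the corridor midline.  Tracking likelihood is fixed at 1.0, with an
optional Gaussian-jitter flag.  Trajectories are redrawn (bounded number
of attempts) until every target accrues ≥ 20 s of valid sniffing; failure
names the offending target.  When a social target is present its nose
jitters just inside the face, so proximal (< 2.5 cm) interactions occur
naturally during dwells.

**Spikes.** A thinned homogeneous Poisson process: the rate is the rest
rate during the rest epoch, the baseline rate in the chamber, and baseline
× gain while the nose occupies a target's sniffing zone (gain > 1
increasing, < 1 decreasing).  Thinning makes expected counts exact:
rate × duration over any zone-constant span.  Bursts are inserted post
hoc — each spike spawns 1–2 extra spikes at the 5-ms intra-burst interval
with probability `burst_propensity` — which multiplies the expected count
by 1 + 1.5 × propensity; the rate-calibration checks therefore run at
propensity 0.

**Population structure.** Baseline rates are lognormal (median 2 Hz,
log-SD 0.4, floor 0.8 Hz so most units clear the 0.5 Hz filter); the
population is partitioned into social (20%), object (10%), and empty (10%)
neurons plus an unmodulated remainder, with 30% of modulated units
decreasing (gain 1/g); the default gain is 3.  The KO preset scales the WT
values: resting rate × 1.3, burst propensity × 0.5, social-neuron fraction
× 0.6 — chosen as plausible contrast magnitudes for exercising the
analyses, not as measured values.  About 6% of units are drawn as pInh and
a fixed waveform/quality distribution keeps the rest comfortably inside
the QC cuts.

**What the generator does not emulate**: real rodent kinematics, tracking
dropouts and identity swaps, non-Poisson spike-count variability
(over-dispersion, slow drifts), waveform shape, or any genotype difference
in σ at exactly equal mean rate — a thinned-Poisson train's variability is
tied to its rate, so the σ-scaled population contrast is checked on
constructed (mean, σ) points instead.  Passing tests therefore demonstrate
the correctness and calibration of the procedures, not their behaviour
under real-data pathologies.

## Determinism and seeds

Every stochastic step takes a `numpy` Generator or integer seed.  Each
unit's spike train and each unit's shuffle stream derive from
`(experiment seed, unit index)` sequence seeds, so results are reproducible
under any execution order.  Identical (config, seed) reproduces on-disk
bytes exactly; floats are written with `%.17g` and read back with
round-trip parsing.

## Problem sizes used in the checks

The acceptance script simulates 50 units (shuffled-decoding control at
ensemble sizes 1/5/10/20 × 100 repetitions) and 100 units (classification
+ trial consistency at 1000 shuffles).  The test suite additionally runs a
10,000-unit permutation-null calibration at 60/80 bins per context, a
200-unit recovery of a planted 20% social fraction, a 1000-pair
ROC-vs-rank oracle sweep, and a 3×3×3 intrinsic parameter grid — sizes
chosen so each suite completes in seconds to a couple of minutes while
keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

- The object proximity profile uses the face-center point; targets deep in
  a side chamber are not modeled.
- Head orientation is not used to gate sniffing; a nose inside the band
  while facing away still counts.
- `sigma_vs_mean_regression` compares exactly two groups; more groups get
  per-group fits only.
- The SVM configuration is fixed to a linear kernel with C = 1 (both
  configurable) — no kernel or box-constraint tuning.
- Burst detection is the ISI-threshold rule only; no Poisson-surprise or
  MaxInterval detectors.
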