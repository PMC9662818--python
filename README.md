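# socialchamber

Single-unit and behavioral analysis of the **linear-chamber social-interaction
test**, the paradigm used to compare medial-prefrontal-cortex (mPFC) firing in
wild-type and IRSp53/*Baiap2*-knockout mice during social and non-social
target approach.

A subject mouse rests for 5 min, then explores a 45 × 10 cm corridor for
three 10-min sessions: both end chambers empty (E-E), then a social
conspecific and an inanimate object (first S-O), then the same targets with
sides swapped (second S-O).  Pose tracks (DeepLabCut-style CSVs) and sorted
spike trains go in; out come behavioral events, cell-type and quality
filters, target-responsive neuron calls, decoding accuracies, firing-rate
dynamics, and burst statistics.  A synthetic-data generator reproduces the
paradigm end to end, so the whole pipeline runs and is tested without any
recordings.

## What it computes

- **behavior** — sniffing bouts (nose ≤ 3 cm from a chamber face), in-zone
  bouts (nose/tail-base midpoint ≤ 9 cm), the center zone (middle 9-cm
  section), proximal/distal interactions (nose-to-target distance < 2.5 cm /
  2.5–10 cm), distance moved; validity filters (sniffing ≥ 1 s with ≥ 2 s
  between trials; in-zone/center ≥ 0.5 s / ≥ 0.5 s).
- **unitqc** — putative excitatory/inhibitory split from half-valley width
  (> 200 / < 200) and peak-to-valley ratio (> 1.4 / < 1.4), cluster quality
  (isolation distance > 25, L-ratio < 0.1), ≥ 0.5 Hz mean-rate filter over
  the 30-min chamber epoch, and exclusion of experiments missing valid
  trials for any of the six targets.
- **encoding** — instantaneous rates in 0.5-s bins; auROC between
  target-sniffing and center-zone rate distributions via a 100-step
  threshold sweep; a neuron is *target-responsive* when its auROC falls
  outside the 0.5%/99.5% quantiles of 1000 label-shuffled auROCs (auROC
  > 0.5 increasing, < 0.5 decreasing; < 40 bins in either context →
  insufficient data).  Also spike density functions (250-ms bins, −1.5 to
  +3 s around sniff onset), z = (FR_T − µ_C)/σ_C, and trial-to-trial
  consistency.
- **decoding** — linear-SVM decoding of left-vs-right (E-E) or
  social-vs-object (S-O) from trial firing rates: 10 trials per class,
  leave-one-out over paired trials, 100 repetitions; pseudo-population
  ensembles combine independently sampled trials across units;
  label-shuffle controls sit at the 50% chance level.
- **dynamics** — instantaneous rate in 3-s windows stepped by 1 s (1800
  windows per 30-min epoch), firing-rate range (max − min), sigma (1 SD of
  the series), normalized-rate histograms, log σ vs log mean regression
  with a slope/elevation comparison test, and the maximum Δ firing rate
  between the two in-zones and the center zone (plus its normalized form
  |(FR_I − FR_C)/(FR_I + FR_C)|).
- **bursts** — ISI histograms (≤ 200 ms), burst proportion (spikes in ISIs
  ≤ 10 ms; threshold sweep 5–30 ms), rest vs chamber comparison, and
  burst/tonic spike-elimination transforms for re-running the analyses on
  partial trains.
- **intrinsic** — current-clamp sweeps (−300…400 pA in 50-pA, 500-ms steps):
  F–I curve, AP threshold at the first 5 mV/ms upward dV/dt crossing,
  amplitude, AHP, FWHM, input resistance from the −100 pA step, and burst
  proportion per current.
- **synthdata / pipeline** — the trajectory + thinned-Poisson spike
  generator with WT/KO presets, and orchestration with deterministic
  seeding, per-stage TSV outputs, and a content-hashed manifest.

## Worked example

```python
import numpy as np
from socialchamber import synthdata, pipeline, encoding, decoding, dynamics, bursts

config = synthdata.SimulationConfig(n_units=20, ko_fraction=0.5,
                                    social_neuron_fraction=0.4)
bundle = synthdata.simulate_experiment(config, seed=7)
events = pipeline.extract_events(bundle)

u = bundle.units[0]
center = events.pooled_center()
sniff = events.pooled_sniff("social")
res = encoding.classify_target_neuron(u.spikes, sniff, center,
                                      seed=np.random.default_rng([7, 0]))
series = dynamics.instantaneous_rates(u.spikes, bundle.layout.chamber_epoch)
s = dynamics.summarize_dynamics(series, bundle.layout.chamber_epoch)
```

prints, for the first unit and a 10-unit pseudo-population:

```
u000 (KO): auROC = 0.840, null 99% band = (0.454, 0.543) -> responsive, increasing
mean rate 3.44 Hz, range 12.00 Hz, sigma 1.865 Hz
burst proportion: rest 28.6%, chamber 27.5%
ensemble of 10: social-vs-object accuracy 96.7% (shuffled control 51.8%)
```

The unit's firing-rate distribution during social sniffing is well separated
from its center-zone distribution (auROC 0.84, far above the shuffled null's
99% band), so it is called an increasing social neuron.  Its sigma and range
summarize how widely the 3-s-window rate fluctuates over the 30-min test.
The ensemble decodes social vs object nearly perfectly while the
label-shuffled control stays at chance — the signature of genuine
target information in the trial rates.

The same analyses are scriptable from a shell:

```bash
socialchamber simulate --n-units 20 --seed 7 --out exp/
socialchamber detect-events --experiment exp/ --out out/
socialchamber run-all --seed 7 --n-units 20 --out out/
```

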