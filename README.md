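# cinda

Analysis pipeline for **identified striatal cholinergic interneurons
(CINs)** and **dopamine fiber photometry** recorded while rats perform a
probabilistic two-choice ("bandit") reward task — plus a seeded synthetic-
session generator that provides ground truth for every stage.

Striatal CINs are the presumed substrate of the classic "tonically active
neuron" (TAN), whose brief cue-evoked pause has long been thought to
coincide with dopamine reward-prediction-error (RPE) pulses. Testing that
idea requires a specific chain of analyses: positively identifying CINs by
optogenetic tagging, quantifying their tonic firing statistics (including
during slow-wave sleep), timing cue-evoked burst–pause–rebound components
with shuffle-test statistics, processing dLight photometry into dF/F, and
relating both signals to a trial-by-trial reward-expectation model. This
package implements that chain as a tested, reusable library with a CLI.

## What it computes

- **Optotagging** (`cinda.optotagging`) — a unit is ChAT+/Chrimson-tagged
  when, for at least one pulse condition, its first-spike latency after
  laser onset is significantly shorter than after random times (one-sided
  rank-sum, *p* < 0.01), it spikes within 15 ms of onset on ≥ 25 % of
  pulses, and the laser-evoked waveform correlates with the spontaneous
  waveform at *r* > 0.9. Simultaneously tagged units are screened for
  duplicates by ±1 ms coincidence.
- **Unit metrics** (`cinda.unit_metrics`) — mean rate, ISI CV, fraction of
  time inside ISIs > 2 s, postspike suppression (first autocorrelogram bin
  above half its mean), waveform FWHM and peak-to-valley, and a
  configurable CIN-enrichment screen.
- **Sleep state** (`cinda.sleep_state`) — SWS epochs from the ECoG
  band-power statistic
  `k = P(0.5–8)/P(20–60) − P(0.5–4)/P(8–12)`, threshold 3, epochs < 30 s
  discarded.
- **Peri-event statistics** (`cinda.event_stats`) — PETHs in 10 ms bins
  sliding by 5 ms over a 3 s window; per-bin up/down significance against
  a shuffle null (10,000 pseudo-event alignments by default); response
  onset/offset/duration; contra-vs-ipsi selectivity index; sensory-vs-
  motor classification of burst/pause/rebound components by comparing
  Go-cue-aligned and movement-aligned response amplitudes.
- **Photometry** (`cinda.photometry`) — demultiplexing of the 10 kHz
  time-division detector trace (10 ms frames, 4 ms on / 6 ms off),
  least-squares rescaling of the 405 nm control to the 470 nm signal,
  `dF/F = (470 − 405_fit)/405_fit` at 250 Hz, 5-point median filter,
  z-scoring, and the same event-aligned shuffle statistics as for spikes.
- **Value model** (`cinda.value_model`) — reward expectation as a beta
  distribution with decaying pseudo-counts
  `α ← γα + r`, `β ← γβ + (1 − r)`, trial value `V = α/(α+β)` (the
  pre-outcome prediction); γ fitted per session by maximizing the negative
  correlation between V and log initiation latency; value terciles; OLS
  value/RPE regressions of firing rates or dF/F (epoch default:
  100–250 ms after Side In on rewarded trials, two-tailed F-test,
  α = 0.05).
- **Synthetic sessions** (`cinda.synth`) — bandit behavior (35–45-trial
  blocks, 10/50/90 % reward probabilities, 0.5–1.5 s hold, value-coupled
  latencies), inhomogeneous gamma-renewal spike trains with cue- or
  movement-locked kernels and RPE-scaled gains, laser-evoked spiking,
  state-switching ECoG, and two-channel photometry with bleaching and
  shared motion artifacts. Every generator is a pure function of
  (spec, seed) and stores its ground truth.

## Worked example

Simulate a session with four units (two CIN-like, laser-responsive, with
Go-cue burst–pause kernels and an RPE-scaled reward response; two
non-responsive), then run the full pipeline:

```sh
cinda simulate --seed 7 --out demo --n-trials 300 --n-units 4 --n-tagged 2
printf 'peth:\n  n_shuffles: 2000\n  correction: pointwise\n' > cfg.yaml
cinda run demo --config cfg.yaml --seed 1 --out demo_out
cinda report demo_out
```

prints

```
session synth-7
tagged units: 2/4 (u0, u1); duplicate pairs flagged: 0
SWS: 0 epoch(s), 0 s total
CIN-enrichment filter: 2/4 pass
peri-event stats: 4/4 units with significant modulation; onsets written for 40 unit x event x direction cells
value model: gamma* = 0.68; RPE-consistent units (neg. slope, p<0.05): 2/4
```

Exactly the two laser-responsive units are tagged and pass the enrichment
screen, and the fitted value-decay γ* = 0.68 recovers the generating value
(0.7). The per-unit onset table (`demo_out/onsets.csv`) shows the
recovered Go-cue response timing for unit u0 — burst onset at 30 ms and
pause onset at 95 ms, matching the injected kernel onsets (30 ms and
85 ms; pause detection lags by up to one bin because edge bins straddle
the rate step):

```
unit  event   direction  onset  offset  duration
u0    go_cue  up         0.030  0.085   0.065
u0    go_cue  down       0.095  0.165   0.080
```

and `demo_out/regressions.csv` shows the reward-cue regressions: both
CIN-like units carry significant negative value slopes (RPE-consistent),
the non-responsive units do not.

## Layout

```
src/cinda/
  core_io.py      session data model, CSV/HDF5 formats, validation, config
  synth.py        synthetic-session generators + ground truth
  optotagging.py  tagging criteria and duplicate detection
  unit_metrics.py firing/waveform metrics and the CIN-enrichment screen
  sleep_state.py  k-statistic SWS detection
  event_stats.py  PETHs, shuffle significance, onsets, selectivity
  photometry.py   demultiplexing, dF/F, aligned significance
  value_model.py  beta value model, gamma fitting, RPE regressions
  pipeline.py     stage orchestration, manifest, summary report
  cli.py          `cinda` command-line interface
```
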