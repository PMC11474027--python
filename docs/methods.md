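# Methods

This note documents the models, statistics and numerical choices behind
`cinda`, and what the synthetic-session benchmarks do and do not show
about real recordings.

## Conventions

All times are seconds as floats on a single session clock starting at 0.
Every binned window is half-open, `[a, b)`. With window `[t0, t1)`, bin
width `w` and step `s`, bin *i* covers `[t0 + i·s, t0 + i·s + w)` and the
number of bins is `floor((t1 − t0 − w)/s) + 1` (599 bins for a 3 s window
at 10 ms / 5 ms). Sessions are plain directories of CSV files (HDF5 only
for the two high-rate continuous signals), written at ≥ 9 significant
digits so that write → load round-trips are lossless at analysis
precision.

## Shuffle-test significance

A unit's peri-event rate in each bin is compared with a null distribution
built from pseudo-event alignments: each of `n_shuffles` draws places the
same number of events uniformly at random anywhere in the session that
the full analysis window fits, and contributes the mean windowed rate
across those pseudo-events. Because placements are uniform, every bin of
a pseudo-PETH has the same marginal distribution, so one sample per
shuffle serves the whole map; this matches the classical construction of
comparing each time point to a single session-derived shuffle
distribution, and makes large calibration runs cheap.

Decision thresholds (two-tailed throughout, so `up` and `down` are
mutually exclusive):

- **bonferroni** (default): per-tail probability `(α/2)/n_bins`. Because
  empirical quantiles cannot resolve such tails (0.005/2/599 ≈ 4×10⁻⁶
  needs millions of shuffles), the tail is modeled from the null
  sample's moments. A plain Gaussian is visibly anti-conservative here —
  the null (a mean of per-trial counts) is right-skewed, and at 4.5 σ the
  skewness inflates the true upper tail several-fold — so the threshold
  uses a Cornish–Fisher third-moment correction,
  `z′ = z + g₁(z² − 1)/6` with `g₁` the null-sample skewness. Measured
  familywise error on 200 null sessions at nominal α = 0.005 is 0 – 2 %.
- **pointwise**: raw shuffle quantiles at α per tail, no correction.
- **maxstat**: the null distribution of the across-bin extremum of full
  pseudo-PETHs (expensive; quadratic in window size).

An `empirical` tail mode raises "insufficient shuffles" when
`n_shuffles < 1/α_tail` rather than silently returning the sample
extremum.

**A bound worth knowing:** a *decrease* can only be flagged if the lower
threshold is positive. With ~300 trials, 10 ms bins and a ~6 Hz baseline
the null SD of a bin's mean rate is ~1.4 Hz, so a 4.5 σ Bonferroni
threshold sits below zero and *no pause, however complete, can reach
significance in that mode at these sizes*. Pause/onset timing analyses
therefore run in pointwise mode (α = 0.005 per tail), which flags a full
pause at ≈ 3.4 σ; burst timing is insensitive to this choice. Onset is
reported as the center of the first significant bin after the event;
because edge bins straddle the rate step, detected pause onsets lag the
true step by up to one bin (5–10 ms), which bounds the recovery error
seen in the benchmarks.

## Optotagging

Criteria per unit: (i) one-sided Wilcoxon rank-sum (evoked first-spike
latencies shorter than latencies after random times; matched null sample
size by default) with *p* < 0.01 in at least one pulse condition, (ii)
spikes within 15 ms of onset on ≥ 25 % of that condition's pulses, and
(iii) Pearson *r* > 0.9 between the laser-evoked (< 10 ms) and
spontaneous mean waveforms. The session model retains only mean
waveforms, so the evoked mean waveform is stored per unit
(`units/<id>.evoked.csv`); the generator writes it as the spontaneous
waveform plus small independent noise, and classification refuses to tag
when it is missing while evoked spikes exist. Conditions with fewer than
10 pulses are recorded as untested. Pulse trains default to 40 pulses per
width × frequency condition; with substantially fewer, chance spikes at
a ~6 Hz baseline (P(spike ≤ 15 ms) ≈ 9 %) start crossing the 25 %
reliability bar in some of the 12 conditions, degrading specificity.
Duplicate detection flags pairs of tagged units whose ±1 ms zero-lag
coincidence (relative to the sparser train) exceeds 0.5 and recommends
dropping the lower-amplitude unit — a concrete stand-in for manual
cross-correlogram inspection.

## Unit metrics

Mean rate, ISI CV and the fraction of time inside ISIs > 2 s are computed
over the whole session or restricted to state intervals (CV defaults to
SWS when epochs exist). Postspike suppression is the first 1 ms
autocorrelogram bin (lags up to 200 ms, raw pair counts) exceeding half
the mean bin count. Waveform FWHM uses linear interpolation at the
half-minimum of the deepest trough on the largest-amplitude channel. The
CIN-enrichment screen is a configurable box — rate ∈ [2, 10] Hz,
CV ≤ 1.9, suppression ≥ 40 ms, width ≥ 0.3 ms — intended as an
*enrichment* filter for untagged units, not ground truth.

## Sleep-state detection

Frames of 10 s advancing by 5 s; within each frame a Hann-tapered Welch
periodogram (5 s segments, 0.2 Hz resolution) gives band powers as the
PSD *integrated* over the band (under this convention white noise yields
k = 7.5/40 − 3.5/4 = −0.6875). Frames with k > 3 mark putative SWS;
single sub-threshold frames inside a run are bridged; epochs shorter than
30 s are discarded. Note the k statistic is deliberately *not* a delta
detector: a lone delta-band oscillation inflates both ratios and is
subtracted away (that is the artifact-correction term's job); k rises
when delta power comes with spindle-band (8–12 Hz) elevation and
suppressed 20–60 Hz activity, as in real SWS.

## Photometry

Each 10 ms frame yields one channel value: the mean over the interior of
the 4 ms on-window, discarding 0.5 ms transitions at each edge. The two
LEDs alternate frames, so each channel is natively ~50 Hz; both are
linearly interpolated onto a shared uniform 250 Hz grid and dF/F is
computed there (the demuxed rate is *below* 250 Hz, so a literal
"compute dF/F, then downsample to 250 Hz" order would be an upsample;
interpolating the channels first onto the output grid is the faithful
equivalent). The 405 nm control is rescaled to the 470 nm signal by least
squares (slope + intercept by default; slope-only available), then
`dF/F = (470 − 405_fit)/405_fit`, a 5-point median filter, and z-scoring
over the whole session. Because bleaching and motion enter both channels
multiplicatively, an exact affine relation between channels gives
identically zero dF/F, and the control fit strictly reduces shared-motion
variance. Aligned significance reuses the shuffle machinery on 250 Hz
samples. Kernel amplitude recovery from trial-averaged pre-z-score dF/F
runs ~10 % low because 50 Hz channel sampling plus interpolation smooths
the sharp transient peak; this bias is amplitude-independent.

## Trial-value model

`α ← γα + r`, `β ← γβ + (1 − r)` after each outcome, from a Beta(1, 1)
prior; the reported V is the *pre-outcome* posterior mean (the
prediction, switchable to post-outcome). At γ = 1 this reduces exactly to
the Laplace running mean `(α₀ + Σr)/(α₀ + β₀ + t)`. γ is fitted on a
grid (0.50–1.00, step 0.01) by minimizing the Pearson correlation
between V and log initiation latency (most negative r wins; ties go to
the smallest γ). Terciles are assigned by within-session V rank with
ties broken by trial order. Value/RPE regressions are ordinary least
squares of a per-trial signal on V — per PETH bin with Bonferroni
correction, or on an epoch mean (default 100–250 ms after Side In,
rewarded trials) with a two-tailed F-test at α = 0.05; for a single
regressor this p-value is computed via the equivalent t-test. A constant
signal returns slope 0 with p = 1 by convention; zero variance in V
(e.g. a single block) is an error, not a silent zero.

## Synthetic sessions

The generator reproduces the task as specified: block lengths uniform on
{35…45}, per-side reward probabilities drawn independently from
{0.1, 0.5, 0.9}, hold period uniform on [0.5, 1.5] s, reaction times
log-normal with median 161 ms. Choices are probability-matched on
per-side decaying-beta values (the analyses do not depend on the choice
rule). Initiation latency is `exp(a − b·V + ε)` with ε ~ N(0, σ²),
defaults a = 0.7, b = 1.5, σ = 0.5 — log-normal latencies spanning
roughly 0.3–3 s with the engaged/unengaged split near 1 s. Inter-trial
intervals are uniform on [2, 6] s.

Spike trains are inhomogeneous gamma renewal processes built by time
rescaling: unit-mean Gamma(shape) ISIs in operational time
`Λ(t) = ∫ rate`, so the rate tracks the kernel-modulated profile and
ISI CV → 1/√shape. Kernels multiply the rate by a gain over
`[ref + onset, ref + onset + duration)` with `ref` the aligning event
(cue-locked) or Center Out (movement-locked); the gain deviation is
scaled by `1 + rpe_scale·(outcome − V)` and optionally by a contraversive
direction factor. One consequence of the renewal model: regularity and
postspike suppression are one knob, so a unit cannot have both CV ≈ 1
and ≥ 40 ms suppression like some real CINs; synthetic CIN-like units
use shape 4–6 (CV 0.35–0.5, suppression 45–75 ms). ECoG is spectrally
shaped Gaussian noise per wake/SWS segment (1/f backbone; SWS adds
~12× delta amplitude, spindle-band elevation, gamma suppression, and a
5× overall amplitude). Photometry transients are event-locked
exponentials (peak = amplitude, τ = 200 ms) entering the 470 channel
multiplicatively on top of a shared bleaching trend (exponential to a
floor) and low-pass motion noise, multiplexed into a 10 kHz detector
trace with per-sample noise.

What passing these benchmarks does **not** show about real data: spike
sorting quality, non-renewal firing (bursting CINs), non-multiplicative
photometry artifacts (hemodynamics, fiber bending), ECoG
non-stationarity within states, and any behavioral structure beyond the
value-latency coupling are all outside the generator; results on real
sessions depend on those assumptions holding approximately.

## Benchmark problem sizes

The packaged calibration runs use 200-trial null sessions (200 seeds,
2,000 shuffles) for shuffle calibration; 300-trial sessions over 20 seeds
for onset recovery; 40-pulse-per-condition schedules with 60 responsive
and 1,000 non-responsive unit draws for tagging; 1,000-trial sessions
over 25 seeds for γ recovery; 500 null and 100 slope replicates for the
regression calibration; 400–500-trial sessions for photometry amplitude
recovery; and 30-minute ECoG sessions for SWS IoU. These sizes put each
Monte-Carlo standard error well below the tolerance being checked while
keeping the whole suite inside a couple of minutes.
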