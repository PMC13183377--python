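# Methods

## The detection problem

An egg-collection device samples one fly's output as eggs per 4-h food
well, six wells per day, for about a week: a record of ~42 small
integers. Three features make rhythmicity assessment hard at this scale:
(i) ~6 samples per circadian cycle, (ii) Poisson-scale counting noise on
means of a few eggs, and (iii) a systematic decline of egg output over
the experiment. The pipeline treats a rhythmic fly's record as a
periodic signal corrupted by strong individual noise riding on a
decreasing trend, and an arrhythmic fly's record as trend plus noise
only.

## Pipeline

**Detrending.** The trend estimate T(i) is a centred 6-point moving
average of the counts; the detrended series is D(i) = E(i)/T(i).
Conventions (fixed, pinned by tests):

* The even window is centred with 3 points left / 2 right of the focal
  bin. The window spans exactly one day, so a 24-h periodic component
  integrates out of T and survives in D.
* Edge bins use the truncated window rather than being dropped: records
  are only 36–48 points long and discarding 5 of them measurably hurts
  the period estimate.
* Where T(i) = 0 (a full day without eggs) D(i) is missing (NaN), never
  infinite; all downstream stages operate on (time, value) pairs and
  simply omit missing bins. Division keeps the detrended series
  dimensionless with mean ≈ 1, so flies with different fecundities are
  directly comparable and averaging is not dominated by strong layers.

**Averaging.** Per-bin mean of the detrended series over flies, with a
per-bin contributor count; truncated (dead-fly) records contribute while
they have data. Averaging assumes the periodic component is shared
across the cohort (light-synchronized before release into constant
darkness) while noise is individual, which is what makes a rhythm that
is invisible per fly detectable in the average.

**Spectral estimation.** Classical variance-normalized Lomb-Scargle
power, evaluated with the phase-shift (tau) form; it equals the variance
reduction of an unweighted least-squares sinusoid fit divided by twice
the sample variance (n−1 denominator), so E[P] ≈ 1 under white noise and
the power is invariant to value offset/positive scaling and to time
translation. A brute-force least-squares oracle pins this equality to
<1e-9 relative in the tests. The period grid runs from 8 h (Nyquist for
4-h bins) to 48 h, uniform in frequency with step 1/(10·span) — 10×
oversampling so peak positions are not grid-quantized. At a degenerate
frequency (e.g. exactly Nyquist on a perfectly regular grid) one basis
vector collapses to numerical zero; its 0/0 power term is dropped, which
is what a rank-revealing least-squares fit does.

**Significance.** Non-parametric: permute, recompute the maximum power
over the grid, repeat R = 1000 times; the level-α line is the
ceil((1−α)(R+1))-th order statistic of the shuffle maxima, so under
exchangeability the exceedance probability is (R+1−k)/(R+1) ≈ α — the
exact permutation-test convention. Two lines are drawn, at 0.05 and
0.01. What is permuted matters: shuffling the *detrended* values is
anticonservative (measured type-I error ~0.16–0.20 at the 0.05 line)
because the divide-by-moving-average filter colors the noise spectrum
while a shuffle whitens it. The pipeline therefore permutes each fly's
*raw counts* and recomputes the full statistic — detrend, average,
max power — per shuffle, restoring calibration (measured 0.050/0.008 at
nominal 0.05/0.01 over 2000 null records). The generic
`significance_lines` function still applies a plain value permutation
for arbitrary user series; the pipeline entry points use the count-level
scheme.

**Peaks and classification.** A peak is a local maximum of the power
curve whose prominence is at least 1/3 of the maximum in-window power: a
"second peak" must be comparable to the dominant one to count. At a
smaller prominence cutoff the exactly-one-peak rules below reject most
genuinely rhythmic cohorts because of sampling-noise side bumps; at 1/3
a pure-noise periodogram still shows two or more (non-significant)
in-window peaks in ~60% of series, so spurious double peaks remain an
expected null phenomenon rather than evidence of complex rhythms.
Decision rules (both window bounds inclusive, strong > weak >
arrhythmic):

* **Genotype**: strong iff the average periodogram has exactly one peak
  in [16, 32] h and its power exceeds the 0.05 line; otherwise
  arrhythmic. There is no weak class at genotype level.
* **Individual**: strong by the genotype rule on the fly's own
  periodogram (with its own count-shuffle lines); else weak iff exactly
  one peak in [18, 32] h with power above the cutoff; else arrhythmic.

The weak-power cutoff is configured as a *fraction of the maximum
attainable power* (n−1)/2 — by default 0.2, i.e. the peak sinusoid must
explain more than 20% of the detrended series' variance (≈ power 4.1 for
42 bins). Read as a raw power on the variance-normalized scale, 0.2
would be vacuous (pure-noise maxima are 3–7) and the weak category
degenerates into a coin flip that can *decrease* with increasing true
modulation; on the variance-share scale the rhythmic fraction is an
approximately monotone function of modulation depth.

**Period and uncertainty.** The reported period is the highest in-window
peak's grid period; the quoted uncertainty is the half-width of the peak
at half its prominence mapped to hours (a resolution-style width, chosen
as a convention because reported uncertainties of this kind rarely state
their method). Exact power ties break to the smaller period, flagged.

## Synthetic egg records

No generative model of fly egg-laying is established; the generator is
an explicit stand-in with the structure the pipeline assumes. Counts are
Poisson draws with per-bin mean equal to the integral of

λ(t) = B·exp(−t/τ)·[1 + m·g(2π((t − φ − δ) mod P)/P)]

with g a zero-mean unit-peak von Mises bump (its κ→0 limit is a cosine;
min g ≥ −1 keeps the rate non-negative for m ≤ 1). Per fly, the baseline
B is lognormal with mean `baseline_rate` and CV `fly_cv`, and the phase
offset δ is Normal(0, `phase_jitter_h`). Defaults, chosen once as a
realistic device cohort:

| parameter | default | units | rationale |
|---|---|---|---|
| `baseline_rate` | 1.0 | eggs/h | ~4 eggs/bin at t=0; counts span 0–10 like real wells |
| `trend_tau` | 120 | h | clear decline over one week (≈4× drop) |
| `period_h` | 24 | h | wild-type circadian period |
| `phase_h` | 10 | h after lights-on | egg deposition peaks at the end of the day |
| `mod_depth` | 0.5 | — | a detectable but individually noisy rhythm |
| `concentration` | 2 | — | a few-hour-wide evening bump, not a pure cosine |
| `fly_cv` | 0.3 | — | strong layer-to-layer fecundity differences |
| `phase_jitter_h` | 1.5 | h | imperfect synchrony between flies |
| `n_days`, `bins_per_day` | 7, 6 | — | one device run; 4-h wells |
| `ld_days` | 2 | days | light-dark entrainment before constant darkness |

`generate_population` forces `mod_depth = 0` for a chosen fraction of
flies to emulate mixed cohorts. Records are deterministic given
(seed, fly index); identical inputs give byte-identical CSVs.

What the generator does **not** emulate: mating-status effects, substrate
choice, mortality (an experiment loses ~20% of flies; truncated records
are *accepted* by the averaging code but not generated by default),
inter-bin correlation beyond the trend (real decisions to lay may
cluster), and any entrainment response to the collection schedule.
Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes from data of the assumed form — not that real egg
records satisfy those assumptions.

The connectome fixture generator plays the analogous role for the
connectivity analysis: it realizes a requested cluster-level topology
(strength class or exact directed synapse total per cluster pair) as a
neuPrint-style per-neuron-pair edge list, with synthetic body ids. The
bundled example topology encodes the known clock/oviposition wiring
(E1↔oviIN, E3↔pC1b only, E2 isolated from the oviposition side,
oviIN→LPN 135 vs LPN→oviIN 16); it is synthetic and stands in for real
hemibrain query results, which the tests never download.

## Open choices made here

* **Segment**: periodograms are computed on the full record by default;
  `segment="dd"` restricts to constant-darkness bins. The full record
  uses all information; the DD restriction isolates free-running rhythm.
* **Randomization target**: raw counts, not detrended values (above).
* **Strength classes** are applied to per-neuron-pair summed synapse
  counts (neuPrint connection-table semantics), not individual synapses.
* **Uncertainty convention**: half-width at half prominence (above).
* **DOT export** is write-only; GraphML and JSON round-trip through the
  package's own reader.

## Problem sizes and numerical budget

Study-scale checks run at: 2000 null records × 1000 shuffles for
calibration; 50 replicate cohorts of 20 flies for period recovery (at
24 h and 20.6 h true periods); 200 random series for oracle equivalence;
300 null records for peak-multiplicity morphology. The shuffle
max-power computation is vectorized (one matrix product per record
across all shuffles), so the full test suite runs in ~2 minutes and the
acceptance script in ~1 minute on a single CPU.

## Limitations

* The permutation null assumes counts are exchangeable after trend
  removal; slow nonstationarities other than a smooth decline (e.g.
  abrupt fecundity loss) are not covered and make the test mildly
  conservative (shuffles of a trended record are overdispersed relative
  to its local noise).
* With ~6 samples per cycle the screen cannot distinguish waveform
  shape, and periods near the 8-h Nyquist limit are unreliable.
* Individual-level calls on 42-point records have limited power; the
  weak category trades specificity for sensitivity and its rate on pure
  noise is ~20%, which is why cohort-level inference rests on the
  averaged periodogram.
* Period uncertainties are peak widths, not confidence intervals.
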