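# ovirhythm

Detection of circadian rhythmicity in *Drosophila* egg-laying records, plus
connectivity analysis of the clock/oviposition neural circuit.

Egg-laying is one of the hardest fly behaviors to score for circadian
rhythmicity: a semi-automated collection device yields only ~6 counts per
cycle (one 4-h food well at a time), the counts are small integers (typically
0–10 eggs), output declines steadily as a mated female ages, and the decision
to lay an egg is influenced by much more than the clock. A single fly's
record often does not look rhythmic at all even when a rhythm is present.
`ovirhythm` implements an analysis pipeline built for exactly this regime,
together with a synthetic record generator that emulates the device's output,
so every stage of the pipeline can be validated without any experimental
data. It is intended for chronobiologists analyzing sparse behavioral count
series and for anyone who needs a calibrated permutation-tested Lomb-Scargle
screen for short, trending, low-count time series.

## The method

For each fly with count series *E(i)* (six 4-h bins per day over *N* days):

1. **Detrend.** A 6-point moving average *T(i)* estimates the declining
   trend (the window spans exactly one day, so a 24-h rhythm does not leak
   into it); the detrended series is the pointwise ratio *D(i) = E(i)/T(i)*.
   Bins where *T(i) = 0* are treated as missing.
2. **Average.** The detrended series of all flies of a genotype are averaged
   bin by bin. The circadian component is shared across flies while the
   noise is individual, so averaging raises the signal-to-noise ratio.
3. **Lomb-Scargle periodogram.** Normalized power on a period grid from 8 h
   (the Nyquist period of 4-h sampling) to 48 h, oversampled 10× relative to
   1/(record span):

   P(ω) = 1/(2s²) · [ (Σᵢ yᵢ cos ω(tᵢ−τ))² / Σᵢ cos² ω(tᵢ−τ)
                    + (Σᵢ yᵢ sin ω(tᵢ−τ))² / Σᵢ sin² ω(tᵢ−τ) ],

   with mean-centred values *y*, sample variance *s²*, and the usual phase
   shift tan 2ωτ = Σ sin 2ωtᵢ / Σ cos 2ωtᵢ. This equals the variance
   reduction of a least-squares sinusoid fit divided by 2s², is exact for
   uneven or gappy sampling, and gives expected power ≈ 1 under white noise.
4. **Randomization significance.** Each fly's raw counts are permuted
   (times fixed), the whole statistic — detrend, average, max power over the
   grid — is recomputed per shuffle, and the 0.05/0.01 significance lines are
   the upper quantiles of the 1000 shuffle maxima. Recomputing the full
   statistic keeps the test calibrated: on pure-noise records the 0.05 line
   is exceeded 5% of the time.
5. **Classification.** A genotype is **strongly rhythmic** if its average
   periodogram has exactly one peak between 16 and 32 h and that peak is
   above the 0.05 line; otherwise arrhythmic. An individual fly is strong by
   the same rule on its own periodogram, else **weakly rhythmic** if it has
   exactly one peak between 18 and 32 h whose power exceeds the configured
   cutoff (by default 20% of the maximum attainable power, i.e. the peak
   explains >20% of the series variance), else arrhythmic. The reported
   period is the peak period; its uncertainty is the half-width of the peak
   at half prominence.

The connectome module classifies neuPrint-style connection tables by synapse
count (≤2 weak — excluded as reconstruction-error-prone, 3–9 intermediate,
>9 strong), extracts the bipartite network between clock-neuron clusters
(with the LNd/5th-sLNv evening cells split into E1/E2/E3 subgroups) and
oviposition-circuit clusters (oviDN, oviEN, oviIN, pC1a–e, U, G), and
summarizes per-pair directionality. `popstats` adds the 'N−1' chi-squared
test for comparing proportions of rhythmic flies and pooled-SD Cohen's d for
period comparisons.

## Worked example

```python
from ovirhythm import (AnalysisConfig, GenParams, generate_population,
                       run_genotype_analysis)

params = GenParams(period_h=24.0, mod_depth=0.5, seed=7)
records = generate_population(params, n_flies=20, frac_arrhythmic=0.3)
result = run_genotype_analysis(records, AnalysisConfig(seed=1))

call = result.genotype_call
print(f"genotype call : {call.label}")
print(f"period        : {call.period_h:.2f} +/- {call.uncertainty_h:.2f} h")
print(f"peak power    : {call.peak_power:.2f} "
      f"(0.05 line at {result.genotype_periodogram.sig_lines[0.05]:.2f})")
print(f"individuals   : {result.n_rhythmic}/{result.n_total} rhythmic")
```

prints

```
genotype call : strong
period        : 24.06 +/- 1.50 h
peak power    : 13.31 (0.05 line at 7.55)
individuals   : 9/20 rhythmic
```

A cohort of 20 simulated flies (30% of them arrhythmic, all others carrying
a 24-h rhythm at 50% modulation depth) is recognized as strongly rhythmic at
the genotype level: the averaged periodogram has a single 16–32 h peak at
24.06 h whose power (13.31) clears the randomization 0.05 line (7.55). Only
9 of the 20 flies are individually rhythmic — the averaging step is what
makes the population rhythm detectable.

The same pipeline is available from the shell:

```bash
ovirhythm simulate --out records.csv --seed 7 --n-flies 20 --frac-arrhythmic 0.3
ovirhythm analyze --in records.csv --seed 1 --out-dir report/
ovirhythm nullstudy --n-series 1000 --seed 3 --out calibration.json
ovirhythm connectome --edges edges.csv --out network.graphml
```

The numbered scripts under `analysis/` run the full study on synthetic
cohorts (simulation → rhythmicity screen → null calibration → connectome
network) and write their tables under `results/`.

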