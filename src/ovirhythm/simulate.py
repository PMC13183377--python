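"""Synthetic egg-record generator.

No generative model for fly egg-laying is established in the literature;
the one implemented here is an explicit stand-in with the statistical
structure the analysis pipeline assumes: an inhomogeneous Poisson count
process whose rate combines

* an exponentially decaying baseline (mated females lay fewer eggs as
  the experiment progresses),
* a smooth unimodal circadian bump peaking once per cycle (egg
  deposition peaks at the end of the day), and
* per-fly heterogeneity: a lognormal baseline and a normal phase offset,

so the counts are discrete, low, noisy and trending -- the features that
make rhythmicity assessment of real records hard.

The per-bin expected count is the integral over the bin of

    lambda(t) = B_i * exp(-t / trend_tau)
                * (1 + mod_depth * g((t - phase_h - delta_i) mod period_h))

where ``g`` is a zero-mean, unit-peak von Mises bump with sharpness
``concentration`` (``concentration = 0`` degenerates to a pure cosine),
``B_i`` is the fly's lognormal baseline with coefficient of variation
``fly_cv`` and mean ``baseline_rate``, and ``delta_i ~ N(0, phase_jitter_h)``.
Counts are Poisson draws, independent across bins given the rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .records import EggRecord

__all__ = ["GenParams", "generate_fly", "generate_population", "light_labels"]


class ParameterError(ValueError):
    """Raised when a generative parameter is out of range."""


@dataclass(frozen=True)
class GenParams:
    """Parameters of the synthetic egg-laying population.

    baseline_rate : expected eggs per hour at t=0 (> 0)
    trend_tau     : decay time constant, hours (> 0; ``inf`` = no trend)
    period_h      : circadian period, hours (> 0)
    phase_h       : peak time within the cycle, hours after lights-on
    mod_depth     : relative modulation amplitude in [0, 1]; 0 = arrhythmic
    concentration : von Mises sharpness of the circadian bump (>= 0)
    fly_cv        : coefficient of variation of the per-fly baseline (>= 0)
    phase_jitter_h: SD of per-fly phase offsets, hours (>= 0)
    n_days        : record length in days (>= 1)
    bins_per_day  : food wells per day (device default 6, i.e. 4-h bins)
    ld_days       : initial days under the light-dark cycle before DD
    seed          : RNG seed; (seed, fly_index) fully determine a record
    """

    baseline_rate: float = 1.0
    trend_tau: float = 120.0
    period_h: float = 24.0
    phase_h: float = 10.0
    mod_depth: float = 0.5
    concentration: float = 2.0
    fly_cv: float = 0.3
    phase_jitter_h: float = 1.5
    n_days: int = 7
    bins_per_day: int = 6
    ld_days: int = 2
    seed: int = 0

    def validate(self) -> None:
        checks = [
            ("baseline_rate", self.baseline_rate > 0),
            ("trend_tau", self.trend_tau > 0),
            ("period_h", self.period_h > 0),
            ("mod_depth", 0.0 <= self.mod_depth <= 1.0),
            ("concentration", self.concentration >= 0),
            ("fly_cv", self.fly_cv >= 0),
            ("phase_jitter_h", self.phase_jitter_h >= 0),
            ("n_days", self.n_days >= 1),
            ("bins_per_day", self.bins_per_day >= 1),
            ("ld_days", self.ld_days >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ParameterError(f"invalid GenParams field: {name}={getattr(self, name)!r}")

    @property
    def bin_width_h(self) -> float:
        return 24.0 / self.bins_per_day


def _bump(theta: np.ndarray, kappa: float) -> np.ndarray:
    """Zero-mean, unit-peak periodic bump of the cycle angle ``theta``.

    For kappa > 0 this is the von Mises kernel exp(kappa*cos(theta))
    recentred to zero cycle-mean and rescaled to peak value 1; its
    kappa -> 0 limit is cos(theta), which is used directly for tiny kappa.
    The minimum is always >= -1, so 1 + mod_depth * g stays non-negative
    for mod_depth <= 1.
    """
    if kappa < 1e-8:
        return np.cos(theta)
    mean = np.i0(kappa)
    peak = math.exp(kappa)
    return (np.exp(kappa * np.cos(theta)) - mean) / (peak - mean)


def light_labels(times_h: np.ndarray, ld_days: int) -> tuple:
    """Light-regime label per bin: 12:12 LD for ``ld_days`` days, then DD."""
    labels = []
    for t in np.asarray(times_h, dtype=float):
        if t < 24.0 * ld_days:
            labels.append("L" if (t % 24.0) < 12.0 else "D")
        else:
            labels.append("DDsub")
    return tuple(labels)


def _fly_rng(seed: int, fly_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(fly_index)]))


def expected_bin_counts(params: GenParams, baseline: float, delta: float,
                        n_sub: int = 32) -> np.ndarray:
    """Integral of the rate over each bin (trapezoid on ``n_sub`` substeps)."""
    n_bins = params.n_days * params.bins_per_day
    w = params.bin_width_h
    edges = np.arange(n_bins + 1) * w
    # fine grid covering all bins at once
    sub = np.linspace(0.0, w, n_sub + 1)
    t = edges[:-1, None] + sub[None, :]          # (n_bins, n_sub+1)
    rate = baseline * np.exp(-t / params.trend_tau) if np.isfinite(params.trend_tau) \
        else baseline * np.ones_like(t)
    if params.mod_depth > 0:
        theta = 2.0 * np.pi * ((t - params.phase_h - delta) % params.period_h) / params.period_h
        rate = rate * (1.0 + params.mod_depth * _bump(theta, params.concentration))
    return np.trapezoid(rate, dx=w / n_sub, axis=1)


def generate_fly(params: GenParams, fly_index: int, genotype: str = "synthetic") -> EggRecord:
    """Draw one fly's record; deterministic given (params.seed, fly_index)."""
    params.validate()
    rng = _fly_rng(params.seed, fly_index)
    # lognormal baseline with mean baseline_rate and CV fly_cv (CV=0 -> constant)
    sigma = math.sqrt(math.log1p(params.fly_cv ** 2))
    baseline = params.baseline_rate * math.exp(sigma * rng.normal() - sigma ** 2 / 2.0)
    delta = rng.normal(0.0, params.phase_jitter_h)
    mu = expected_bin_counts(params, baseline, delta)
    counts = rng.poisson(mu)
    times = np.arange(len(mu)) * params.bin_width_h
    return EggRecord(
        fly_id=f"fly{fly_index:03d}",
        genotype=genotype,
        times_h=times,
        counts=counts.astype(np.int64),
        light=light_labels(times, params.ld_days),
        bin_width_h=params.bin_width_h,
    )


def generate_population(params: GenParams, n_flies: int,
                        frac_arrhythmic: float = 0.0,
                        genotype: str = "synthetic") -> list:
    """Generate a mixed population of rhythmic and arrhythmic flies.

    ``round(frac_arrhythmic * n_flies)`` flies (the first ones, by index)
    are generated with the modulation depth forced to zero; the rest use
    ``params.mod_depth``. Reproducible under ``params.seed``.
    """
    params.validate()
    if n_flies < 1:
        raise ParameterError(f"invalid GenParams field: n_flies={n_flies!r}")
    if not 0.0 <= frac_arrhythmic <= 1.0:
        raise ParameterError(f"invalid GenParams field: frac_arrhythmic={frac_arrhythmic!r}")
    n_arr = round(frac_arrhythmic * n_flies)
    null_params = replace(params, mod_depth=0.0)
    out = []
    for i in range(n_flies):
        p = null_params if i < n_arr else params
        out.append(generate_fly(p, i, genotype=genotype))
    return out
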