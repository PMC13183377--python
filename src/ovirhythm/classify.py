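"""Rhythmicity decision rules.

A *genotype* (population-average periodogram) is called strongly
rhythmic if it shows exactly one peak with period between 16 and 32 h
and that peak rises above the 0.05 randomization significance line;
otherwise it is arrhythmic (there is no weak class at genotype level).

An *individual* fly is called strong by the same rule applied to its own
periodogram (with significance lines from shuffling its own series);
failing that it is weakly rhythmic if its periodogram shows exactly one
peak between 18 and 32 h with power above 0.2 (on the Scargle
variance-normalized scale); otherwise arrhythmic. Strong takes
precedence over weak. Both window bounds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .periodogram import Periodogram, estimate_period, find_peaks
from .records import RecordError

__all__ = ["RhythmCall", "classify_genotype", "classify_individual", "percent_rhythmic"]

STRONG_WINDOW_H = (16.0, 32.0)
WEAK_WINDOW_H = (18.0, 32.0)
WEAK_POWER_CUTOFF = 0.2


@dataclass(frozen=True)
class RhythmCall:
    subject: str
    label: str                      # "strong" | "weak" | "arrhythmic"
    period_h: float | None = None
    uncertainty_h: float | None = None
    peak_power: float | None = None
    rule_trace: str = ""

    @property
    def rhythmic(self) -> bool:
        return self.label in ("strong", "weak")


def _strong_call(pg: Periodogram, subject: str, window, level: float):
    """Apply the genotype rule; returns a RhythmCall or None if it fails."""
    line = pg.sig_line(level)
    peaks = find_peaks(pg, window)
    if len(peaks) == 0:
        return None, "no in-window peak"
    if len(peaks) > 1:
        return None, f"multiple peaks ({len(peaks)}) in window"
    peak = peaks[0]
    if peak.power <= line:
        return None, f"peak power {peak.power:.3g} not above the {level} line {line:.3g}"
    est = estimate_period(pg, window)
    call = RhythmCall(
        subject=subject, label="strong", period_h=est.period_h,
        uncertainty_h=est.uncertainty_h, peak_power=peak.power,
        rule_trace=f"single peak at {peak.period_h:.2f} h above the {level} line",
    )
    return call, ""


def classify_genotype(pg: Periodogram, subject: str = "genotype",
                      window=STRONG_WINDOW_H, level: float = 0.05) -> RhythmCall:
    """Strong/arrhythmic call for a population-average periodogram."""
    call, why = _strong_call(pg, subject, window, level)
    if call is not None:
        return call
    return RhythmCall(subject=subject, label="arrhythmic", rule_trace=why)


def classify_individual(pg: Periodogram, subject: str = "fly",
                        strong_window=STRONG_WINDOW_H, weak_window=WEAK_WINDOW_H,
                        power_cutoff: float = WEAK_POWER_CUTOFF,
                        level: float = 0.05) -> RhythmCall:
    """Three-way strong/weak/arrhythmic call for one fly's periodogram."""
    call, why_strong = _strong_call(pg, subject, strong_window, level)
    if call is not None:
        return call
    peaks = find_peaks(pg, weak_window)
    if len(peaks) == 1 and peaks[0].power > power_cutoff:
        est = estimate_period(pg, weak_window)
        return RhythmCall(
            subject=subject, label="weak", period_h=est.period_h,
            uncertainty_h=est.uncertainty_h, peak_power=peaks[0].power,
            rule_trace=(f"not strong ({why_strong}); single peak at "
                        f"{peaks[0].period_h:.2f} h with power "
                        f"{peaks[0].power:.3g} > {power_cutoff}"),
        )
    why_weak = ("no single weak-window peak" if len(peaks) != 1
                else f"peak power {peaks[0].power:.3g} <= {power_cutoff}")
    return RhythmCall(subject=subject, label="arrhythmic",
                      rule_trace=f"not strong ({why_strong}); not weak ({why_weak})")


def percent_rhythmic(calls: list):
    """(n_rhythmic, n_total, fraction); rhythmic = strong + weak."""
    if not calls:
        raise RecordError("no rhythm calls supplied")
    n_r = sum(1 for c in calls if c.rhythmic)
    return n_r, len(calls), n_r / len(calls)
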