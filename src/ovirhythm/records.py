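"""Egg-count record container and CSV round-trip.

An egg record is one fly's time series of eggs counted per food well.
The collection device samples six 4-h wells per day, so a record of
``n_days`` days has ``6 * n_days`` bins. Times are bin-start hours from
the beginning of the experiment; each bin carries a light-regime label:
``L`` (lights on), ``D`` (lights off) or ``DDsub`` (subjective day under
constant darkness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LIGHT_LABELS = ("L", "D", "DDsub")

CSV_HEADER = ["fly_id", "genotype", "time_h", "bin_width_h", "count", "light"]


class RecordError(ValueError):
    """Raised for malformed egg records or incompatible record sets."""


@dataclass(frozen=True)
class EggRecord:
    """Binned egg counts for a single fly.

    Parameters
    ----------
    fly_id, genotype
        Identifiers carried through the pipeline into reports.
    times_h
        Strictly increasing bin-start times, hours from experiment start.
    counts
        Non-negative integer egg counts, one per bin.
    light
        Per-bin light label from :data:`LIGHT_LABELS`.
    bin_width_h
        Sampling interval in hours (the device moves flies to a fresh
        food well every 4 h).
    """

    fly_id: str
    genotype: str
    times_h: np.ndarray
    counts: np.ndarray
    light: tuple = field(default=())
    bin_width_h: float = 4.0

    def __post_init__(self):
        times = np.asarray(self.times_h, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "counts", counts)
        light = tuple(self.light) if len(self.light) else ("L",) * len(times)
        object.__setattr__(self, "light", light)
        if times.ndim != 1 or counts.ndim != 1:
            raise RecordError("times_h and counts must be 1-D")
        if len(times) != len(counts) or len(times) != len(light):
            raise RecordError(
                f"length mismatch in record {self.fly_id!r}: "
                f"{len(times)} times, {len(counts)} counts, {len(light)} light labels"
            )
        if len(times) and np.any(np.diff(times) <= 0):
            raise RecordError(f"times_h must be strictly increasing in {self.fly_id!r}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise RecordError(f"counts must be non-negative integers in {self.fly_id!r}")
        bad = set(light) - set(LIGHT_LABELS)
        if bad:
            raise RecordError(f"unknown light labels {sorted(bad)} in {self.fly_id!r}")
        if self.bin_width_h <= 0:
            raise RecordError("bin_width_h must be positive")

    def __len__(self) -> int:
        return len(self.times_h)


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        for t, c, l in zip(rec.times_h, rec.counts, rec.light):
            rows.append((rec.fly_id, rec.genotype, float(t), rec.bin_width_h, int(c), l))
    return pd.DataFrame(rows, columns=CSV_HEADER)


def write_records(records, path) -> None:
    """Write records to the device CSV dialect (one row per bin)."""
    records_to_frame(records).to_csv(path, index=False)


def read_records(path) -> list:
    """Read a device-format CSV back into :class:`EggRecord` objects.

    Flies appear in first-occurrence order; rows of one fly must share a
    genotype and bin width.
    """
    df = pd.read_csv(path)
    missing = set(CSV_HEADER) - set(df.columns)
    if missing:
        raise RecordError(f"egg-record CSV missing columns: {sorted(missing)}")
    out = []
    for fly_id, grp in df.groupby("fly_id", sort=False):
        genotypes = grp["genotype"].unique()
        widths = grp["bin_width_h"].unique()
        if len(genotypes) != 1 or len(widths) != 1:
            raise RecordError(f"inconsistent genotype/bin width for fly {fly_id!r}")
        grp = grp.sort_values("time_h")
        out.append(
            EggRecord(
                fly_id=str(fly_id),
                genotype=str(genotypes[0]),
                times_h=grp["time_h"].to_numpy(dtype=float),
                counts=grp["count"].to_numpy(dtype=np.int64),
                light=tuple(grp["light"]),
                bin_width_h=float(widths[0]),
            )
        )
    return out


def common_grid(records) -> np.ndarray:
    """Return the shared time grid, or raise if records disagree."""
    if not records:
        raise RecordError("no records supplied")
    grid = records[0].times_h
    for rec in records[1:]:
        if len(rec.times_h) != len(grid) or not np.allclose(rec.times_h, grid):
            raise RecordError(
                f"record {rec.fly_id!r} is not on the common time grid"
            )
    return grid
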