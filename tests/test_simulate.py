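"""Generator: distributional structure, determinism, device CSV format."""

import dataclasses

import numpy as np
import pytest

from ovirhythm.records import read_records, write_records
from ovirhythm.simulate import (GenParams, ParameterError, expected_bin_counts,
                                generate_fly, generate_population)

FLAT = GenParams(mod_depth=0.0, trend_tau=np.inf, fly_cv=0.0,
                 phase_jitter_h=0.0, baseline_rate=1.0, seed=7)


def test_flat_params_give_homogeneous_poisson_mean():
    """mod_depth=0 and no trend: mean count = rate x bin width (4 eggs/bin)."""
    counts = np.concatenate([generate_fly(FLAT, i).counts for i in range(200)])
    se = np.sqrt(4.0 / len(counts))  # Poisson var = mean
    assert abs(counts.mean() - 4.0) < 3 * se


def test_counts_are_nonnegative_integers_and_grid_is_6_per_day():
    rec = generate_fly(GenParams(seed=1), 0)
    assert rec.counts.dtype.kind == "i" and (rec.counts >= 0).all()
    assert len(rec) == 7 * 6
    assert np.allclose(np.diff(rec.times_h), 4.0)
    assert rec.light[0] == "L" and rec.light[-1] == "DDsub"


def test_same_seed_and_fly_index_reproduce_record():
    a = generate_fly(GenParams(seed=5), 3)
    b = generate_fly(GenParams(seed=5), 3)
    assert np.array_equal(a.counts, b.counts) and np.array_equal(a.times_h, b.times_h)
    c = generate_fly(GenParams(seed=5), 4)
    assert not np.array_equal(a.counts, c.counts)


def test_zero_modulation_expected_counts_follow_trend_only():
    """With mod_depth=0 the mean function depends on time only via the decay."""
    p = dataclasses.replace(FLAT, trend_tau=120.0)
    mu = expected_bin_counts(p, baseline=1.0, delta=0.0)
    ratio = mu[1:] / mu[:-1]
    assert np.allclose(ratio, np.exp(-4.0 / 120.0), rtol=1e-6)


def test_circular_mean_of_count_phase_matches_phase_parameter():
    """Count-weighted circular mean phase over 200 flies lands within one
    bin (4 h) of the generative peak phase."""
    p = GenParams(mod_depth=0.5, period_h=24.0, phase_h=10.0, trend_tau=np.inf,
                  phase_jitter_h=0.0, fly_cv=0.0, seed=11)
    z = 0.0
    for i in range(200):
        rec = generate_fly(p, i)
        mid = rec.times_h + rec.bin_width_h / 2
        ang = 2 * np.pi * (mid % 24.0) / 24.0
        z += np.sum(rec.counts * np.exp(1j * ang))
    est = (np.angle(z) * 24.0 / (2 * np.pi)) % 24.0
    diff = min(abs(est - 10.0), 24.0 - abs(est - 10.0))
    assert diff < 4.0


def test_daily_totals_decrease_under_trend():
    """Empirical daily means over 200 null flies are non-increasing within error."""
    p = GenParams(mod_depth=0.0, trend_tau=120.0, fly_cv=0.0, seed=2)
    daily = np.zeros(7)
    for i in range(200):
        daily += generate_fly(p, i).counts.reshape(7, 6).sum(axis=1)
    daily /= 200
    assert np.all(np.diff(daily) < 0.5)  # ~3 SE slack on a clearly decaying mean
    assert daily[-1] < daily[0] * 0.5


@pytest.mark.parametrize("n,frac,expected_null", [(21, 0.0, 0), (10, 0.3, 3), (10, 1.0, 10)])
def test_population_mixture_counts(n, frac, expected_null):
    params = GenParams(seed=9)
    recs = generate_population(params, n, frac_arrhythmic=frac)
    assert len(recs) == n
    assert len({r.fly_id for r in recs}) == n
    # arrhythmic flies are exactly those generated with mod_depth forced to 0
    null_counts = [generate_fly(dataclasses.replace(params, mod_depth=0.0), i).counts
                   for i in range(n)]
    n_null = sum(np.array_equal(r.counts, nc) for r, nc in zip(recs, null_counts))
    assert n_null == expected_null


@pytest.mark.parametrize("field,value", [
    ("baseline_rate", 0.0), ("trend_tau", -1.0), ("mod_depth", 1.5),
    ("concentration", -0.1), ("fly_cv", -1.0), ("n_days", 0),
])
def test_invalid_params_name_the_offending_field(field, value):
    with pytest.raises(ParameterError, match=field):
        generate_fly(dataclasses.replace(GenParams(), **{field: value}), 0)


def test_record_csv_round_trip(tmp_path):
    recs = generate_population(GenParams(seed=3), 5, frac_arrhythmic=0.4,
                               genotype="mixed")
    path = tmp_path / "records.csv"
    write_records(recs, path)
    header = path.read_text().splitlines()[0]
    assert header == "fly_id,genotype,time_h,bin_width_h,count,light"
    back = read_records(path)
    assert len(back) == len(recs)
    for a, b in zip(recs, back):
        assert a.fly_id == b.fly_id and a.genotype == b.genotype
        assert np.array_equal(a.counts, b.counts)
        assert np.allclose(a.times_h, b.times_h)
        assert a.light == b.light


def test_seed_determinism_gives_identical_files(tmp_path):
    for name in ("a.csv", "b.csv"):
        write_records(generate_population(GenParams(seed=4), 8), tmp_path / name)
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
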