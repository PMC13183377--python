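"""Independent brute-force oracles the implementation is checked against."""

import numpy as np


def lomb_scargle_bruteforce(times, values, periods_h):
    """Per-frequency least-squares sinusoid fit on mean-centred values.

    Power = variance reduction of the two-parameter (cos, sin) fit
    divided by twice the sample variance. Deliberately naive: one
    ``lstsq`` per frequency, no phase-shift trick.
    """
    times = np.asarray(times, float)
    y = np.asarray(values, float)
    yc = y - y.mean()
    var = yc.var(ddof=1)
    ss_tot = np.sum(yc ** 2)
    out = []
    for p in np.asarray(periods_h, float):
        w = 2 * np.pi / p
        X = np.column_stack([np.cos(w * times), np.sin(w * times)])
        beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
        ss_res = np.sum((yc - X @ beta) ** 2)
        out.append((ss_tot - ss_res) / (2 * var))
    return np.array(out)


def pearson_chi2_2x2(k1, n1, k2, n2):
    """Pearson chi-squared of a 2x2 table from observed/expected cells."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(np.sum((table - expected) ** 2 / expected))
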