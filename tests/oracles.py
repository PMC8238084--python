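"""Brute-force reference implementations of the exclusion rules.

Pure-Python re-derivations of each rule's threshold inequalities, used as
independent oracles against the vectorised implementations.  They share
nothing with the package code beyond the published formulas.
"""

import math
import statistics


def quantile_type7(xs, p):
    """Linear-interpolation quantile: h = (n-1) p + 1, v_j + g (v_{j+1} - v_j)."""
    s = sorted(xs)
    n = len(s)
    h = (n - 1) * p
    j = math.floor(h)
    g = h - j
    if j >= n - 1:
        return s[-1]
    return s[j] + g * (s[j + 1] - s[j])


def kept_none(xs):
    return [True] * len(xs)


def kept_cutoff(xs):
    m = statistics.fmean(xs)
    return [not (x < 200.0 or x > m + 1000.0) for x in xs]


def kept_sd(xs, k):
    m = statistics.fmean(xs)
    s = statistics.stdev(xs)
    return [not (x < m - k * s or x > m + k * s) for x in xs]


def kept_tukey(xs, c=1.5):
    q1 = quantile_type7(xs, 0.25)
    q3 = quantile_type7(xs, 0.75)
    iqr = q3 - q1
    return [not (x < q1 - c * iqr or x > q3 + c * iqr) for x in xs]


def kept_quantile(xs, p):
    lo = quantile_type7(xs, p)
    hi = quantile_type7(xs, 1.0 - p)
    return [not (x < lo or x > hi) for x in xs]


def kept_mad(xs, b, k=2.5):
    med = statistics.median(xs)
    mad = b * statistics.median([abs(x - med) for x in xs])
    if mad == 0.0:
        return [True] * len(xs)
    return [not (x < med - k * mad or x > med + k * mad) for x in xs]


def kept_transform(xs, z_crit=2.0):
    mn, mx = min(xs), max(xs)
    if mx == mn:
        return [True] * len(xs)
    ys = [math.sqrt((x - mn) / (mx - mn)) for x in xs]
    m = statistics.fmean(ys)
    s = statistics.stdev(ys)
    if s == 0.0:
        return [True] * len(xs)
    return [abs((y - m) / s) <= z_crit for y in ys]


#: method name -> oracle over a list of floats
ORACLES = {
    "no": kept_none,
    "cutoff": kept_cutoff,
    "2sd": lambda xs: kept_sd(xs, 2.0),
    "3sd": lambda xs: kept_sd(xs, 3.0),
    "tukey1.5": kept_tukey,
    "q10": lambda xs: kept_quantile(xs, 0.05),
    "q05": lambda xs: kept_quantile(xs, 0.025),
    "MAD": lambda xs: kept_mad(xs, 1.4826),
    "MAD_adjusted": lambda xs: kept_mad(xs, 1.1020),
    "transform": kept_transform,
}
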