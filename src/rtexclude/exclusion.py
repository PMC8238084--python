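"""The ten RT outlier-exclusion rules.

Every rule receives one RT vector (one condition's sample), computes its
thresholds *from that vector alone* — exclusion must work blind, without
ground truth — and returns a kept/excluded mask together with the
thresholds and the per-tail excluded proportions.

Rules and constants:

========  =============================  =============================
name      lower threshold                upper threshold
========  =============================  =============================
no            --                             --
cutoff    200 ms                         mean + 1000 ms
2sd       mean - 2 SD                    mean + 2 SD
3sd       mean - 3 SD                    mean + 3 SD
tukey1.5  q0.25 - 1.5 IQR                q0.75 + 1.5 IQR
q10       q0.05                          q0.95
q05       q0.025                         q0.975
MAD       median - 2.5 MAD (b=1.4826)    median + 2.5 MAD
MAD_adj.  median - 2.5 MAD (b=1.1020)    median + 2.5 MAD
transform |z| > 2 on sqrt of range-normalised values
========  =============================  =============================

with ``MAD = b * median(|x - median(x)|)``; ``b = 1.4826`` calibrates the
MAD to the Normal SD, ``b = 1.1020`` to the Ex-Gaussian.  Threshold
comparisons are strict (``< lower`` or ``> upper`` excluded); a value
exactly on a threshold is kept.  Sample SDs use the n-1 denominator and
quantiles the linear-interpolation convention ``h = (n-1) p + 1`` (the
default of R and NumPy).  Degenerate inputs (constant vectors, zero MAD,
too few values) exclude nothing and warn instead of erroring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Callable, Mapping, Union

import numpy as np

__all__ = [
    "MAD_NORMAL_CONSTANT",
    "MAD_EXGAUSS_CONSTANT",
    "METHOD_NAMES",
    "METHODS",
    "MethodSpec",
    "ExclusionOutcome",
    "exclude_none",
    "exclude_cutoff",
    "exclude_sd",
    "exclude_tukey",
    "exclude_quantile",
    "exclude_mad",
    "exclude_transform",
    "apply_method",
]

#: MAD scale constant calibrated to the Normal distribution.
MAD_NORMAL_CONSTANT = 1.4826
#: MAD scale constant adjusted to the Ex-Gaussian distribution.
MAD_EXGAUSS_CONSTANT = 1.1020


@dataclass
class ExclusionOutcome:
    """Result of applying one exclusion rule to one RT vector.

    ``prop_excluded_low + prop_excluded_high == 1 - mean(kept)``.
    Thresholds are ``None`` where a rule has no bound on that side (or, for
    the transform rule, no bound expressible in ms).
    """

    kept: np.ndarray
    lower: float | None
    upper: float | None
    prop_excluded_low: float
    prop_excluded_high: float
    degenerate: bool = False

    @property
    def prop_excluded(self) -> float:
        return self.prop_excluded_low + self.prop_excluded_high


def _keep_all(rts: np.ndarray, degenerate: bool = False) -> ExclusionOutcome:
    return ExclusionOutcome(
        kept=np.ones(rts.size, dtype=bool),
        lower=None,
        upper=None,
        prop_excluded_low=0.0,
        prop_excluded_high=0.0,
        degenerate=degenerate,
    )


def _bounded(rts: np.ndarray, lower: float, upper: float) -> ExclusionOutcome:
    """Strict two-sided threshold outcome: exclude < lower or > upper."""
    low = rts < lower
    high = rts > upper
    n = rts.size
    return ExclusionOutcome(
        kept=~(low | high),
        lower=float(lower),
        upper=float(upper),
        prop_excluded_low=low.sum() / n,
        prop_excluded_high=high.sum() / n,
    )


def _degenerate_warning(rule: str, reason: str) -> None:
    warnings.warn(f"{rule}: {reason}; excluding nothing", stacklevel=3)


def exclude_none(rts: np.ndarray) -> ExclusionOutcome:
    """No correction for outliers: keep everything."""
    rts = np.asarray(rts, dtype=float)
    return _keep_all(rts)


def exclude_cutoff(
    rts: np.ndarray, lower: float = 200.0, upper_offset: float = 1000.0
) -> ExclusionOutcome:
    """A-priori cutoffs: exclude below 200 ms or above mean + 1000 ms.

    The mean is computed on the input (contaminated) vector, so the upper
    cutoff adapts to the overall response speed of the sample.
    """
    rts = np.asarray(rts, dtype=float)
    return _bounded(rts, lower, rts.mean() + upper_offset)


def exclude_sd(rts: np.ndarray, k: float = 2.0) -> ExclusionOutcome:
    """Exclude values strictly outside mean +/- k standard deviations.

    The SD uses the n-1 denominator.  ``k = 2`` is the classic rule
    excluding ~5% under normality, ``k = 3`` the stricter ~0.5% variant.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        _degenerate_warning(f"{k:g}sd", "need at least 2 values for an SD")
        return _keep_all(rts, degenerate=True)
    m = rts.mean()
    s = rts.std(ddof=1)
    return _bounded(rts, m - k * s, m + k * s)


def exclude_tukey(rts: np.ndarray, c: float = 1.5) -> ExclusionOutcome:
    """Tukey's boxplot fences: exclude outside q0.25 - c IQR, q0.75 + c IQR."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 4:
        _degenerate_warning("tukey1.5", "need at least 4 values for quartiles")
        return _keep_all(rts, degenerate=True)
    q1, q3 = np.quantile(rts, [0.25, 0.75])
    iqr = q3 - q1
    return _bounded(rts, q1 - c * iqr, q3 + c * iqr)


def exclude_quantile(rts: np.ndarray, p: float) -> ExclusionOutcome:
    """Exclude values strictly below the p-quantile or above the (1-p)-quantile.

    ``p = 0.05`` trims a nominal 10% (rule "q10"), ``p = 0.025`` a nominal
    5% (rule "q05").  Because a fractional number of trials cannot be
    excluded, realised proportions deviate from the nominal rate in small
    samples.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        _degenerate_warning(f"q{int(round(2 * p * 100)):02d}", "need at least 2 values")
        return _keep_all(rts, degenerate=True)
    lo, hi = np.quantile(rts, [p, 1.0 - p])
    return _bounded(rts, lo, hi)


def exclude_mad(
    rts: np.ndarray, b: float = MAD_NORMAL_CONSTANT, k: float = 2.5
) -> ExclusionOutcome:
    """Exclude values strictly outside median +/- k * MAD.

    ``MAD = b * median(|x - median(x)|)``.  If the MAD is zero (more than
    half the values identical) nothing is excluded and a warning is
    emitted.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        _degenerate_warning("MAD", "need at least 2 values")
        return _keep_all(rts, degenerate=True)
    med = np.median(rts)
    mad = b * np.median(np.abs(rts - med))
    if mad == 0.0:
        _degenerate_warning("MAD", "MAD is zero")
        return _keep_all(rts, degenerate=True)
    return _bounded(rts, med - k * mad, med + k * mad)


def exclude_transform(rts: np.ndarray, z_crit: float = 2.0) -> ExclusionOutcome:
    """Square-root range-normalisation followed by a z-score criterion.

    ``y_i = sqrt((x_i - min) / (max - min))`` maps the sample to [0, 1] and
    symmetrises the right-skewed RT shape; values whose z-score on the y
    scale strictly exceeds ``+/- z_crit`` are excluded.  The thresholds are
    not expressible in ms, so ``lower``/``upper`` are ``None``.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 3:
        _degenerate_warning("transform", "need at least 3 values")
        return _keep_all(rts, degenerate=True)
    mn = rts.min()
    rng_ = rts.max() - mn
    if rng_ == 0.0:
        _degenerate_warning("transform", "all values identical (zero range)")
        return _keep_all(rts, degenerate=True)
    y = np.sqrt((rts - mn) / rng_)
    s = y.std(ddof=1)
    if s == 0.0:
        _degenerate_warning("transform", "zero variance after transformation")
        return _keep_all(rts, degenerate=True)
    z = (y - y.mean()) / s
    low = z < -z_crit
    high = z > z_crit
    n = rts.size
    return ExclusionOutcome(
        kept=~(low | high),
        lower=None,
        upper=None,
        prop_excluded_low=low.sum() / n,
        prop_excluded_high=high.sum() / n,
    )


@dataclass(frozen=True)
class MethodSpec:
    """A named exclusion rule plus its constants."""

    name: str
    fn: Callable[[np.ndarray], ExclusionOutcome]
    constants: Mapping[str, float] = field(default_factory=dict)
    description: str = ""

    def __call__(self, rts: np.ndarray) -> ExclusionOutcome:
        return self.fn(rts)


def _spec(name, fn, constants, description):
    return MethodSpec(name, fn, MappingProxyType(dict(constants)), description)


#: Registry of the ten rules, in the canonical study order.
METHODS: Mapping[str, MethodSpec] = MappingProxyType(
    {
        "no": _spec("no", exclude_none, {}, "no correction for outliers"),
        "cutoff": _spec(
            "cutoff",
            exclude_cutoff,
            {"lower_ms": 200.0, "upper_offset_ms": 1000.0},
            "a-priori cutoffs: 200 ms lower, mean + 1000 ms upper",
        ),
        "2sd": _spec(
            "2sd",
            lambda x: exclude_sd(x, k=2.0),
            {"k": 2.0},
            "mean +/- 2 standard deviations",
        ),
        "3sd": _spec(
            "3sd",
            lambda x: exclude_sd(x, k=3.0),
            {"k": 3.0},
            "mean +/- 3 standard deviations",
        ),
        "tukey1.5": _spec(
            "tukey1.5",
            lambda x: exclude_tukey(x, c=1.5),
            {"c": 1.5},
            "Tukey fences: quartiles +/- 1.5 IQR",
        ),
        "q10": _spec(
            "q10",
            lambda x: exclude_quantile(x, p=0.05),
            {"p": 0.05},
            "outer 10%: below q0.05 or above q0.95",
        ),
        "q05": _spec(
            "q05",
            lambda x: exclude_quantile(x, p=0.025),
            {"p": 0.025},
            "outer 5%: below q0.025 or above q0.975",
        ),
        "MAD": _spec(
            "MAD",
            lambda x: exclude_mad(x, b=MAD_NORMAL_CONSTANT),
            {"b": MAD_NORMAL_CONSTANT, "k": 2.5},
            "median +/- 2.5 MAD, Normal-calibrated constant",
        ),
        "MAD_adjusted": _spec(
            "MAD_adjusted",
            lambda x: exclude_mad(x, b=MAD_EXGAUSS_CONSTANT),
            {"b": MAD_EXGAUSS_CONSTANT, "k": 2.5},
            "median +/- 2.5 MAD, Ex-Gaussian-adjusted constant",
        ),
        "transform": _spec(
            "transform",
            lambda x: exclude_transform(x, z_crit=2.0),
            {"z_crit": 2.0},
            "z-scores of sqrt range-normalised RTs, |z| > 2",
        ),
    }
)

#: Canonical method names, in study order.
METHOD_NAMES = tuple(METHODS)


def apply_method(spec: Union[str, MethodSpec], rts: np.ndarray) -> ExclusionOutcome:
    """Apply an exclusion rule by name or spec.

    Raises
    ------
    ValueError
        For an unknown method name.
    """
    if isinstance(spec, str):
        try:
            spec = METHODS[spec]
        except KeyError:
            raise ValueError(
                f"unknown exclusion method {spec!r}; expected one of {METHOD_NAMES}"
            ) from None
    return spec.fn(np.asarray(rts, dtype=float))
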