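"""Outlier contamination of simulated RT samples.

Randomly chosen valid RTs are *replaced* by outliers (sample size never
changes).  The number of outliers per sample is ``round(u)`` with
``u ~ U(0, 0.1 N)``, so samples carry between 0% and 10% outliers.  Each
outlier is long (slow) with probability ``p_long ~ Beta(5, 1)`` (expected
long share 5/6 ~ 0.83, reflecting the physiological floor that compresses
the range available to fast guesses) and short (fast) otherwise.

Two generative schemes for the outlier values are implemented:

``tails``
    Outliers lie strictly outside the range of the pre-contamination
    sample: long outliers uniform on ``(max, max + 2000)`` ms, short
    outliers uniform on ``(100, min)`` ms.

``overlap``
    Outliers are drawn from shifted Ex-Gaussian distributions that may
    overlap the valid RTs: long ~ ExGauss(mean(valid) + 700,
    U(20, 50) + 10, U(150, 200)); short ~ ExGauss(mean(valid) - 200, 20,
    10).  Negative draws are sign-flipped.

Within a pair the outlier *counts* are shared between the two conditions,
while the outlier values and the replaced positions are drawn independently
per condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .distributions import RTSample, SIGMA_RANGE, TAU_RANGE

__all__ = [
    "APPROACHES",
    "SHORT_FLOOR_MS",
    "LONG_SPAN_MS",
    "OutlierPlan",
    "ContaminatedSample",
    "draw_outlier_plan",
    "inject_tails",
    "inject_overlap",
    "contaminate_pair",
]

#: The two outlier-generation schemes.
APPROACHES = ("tails", "overlap")

#: Physiological floor for short outliers in the tails scheme (ms).
SHORT_FLOOR_MS = 100.0
#: Width of the uniform band above the sample maximum for long outliers (ms).
LONG_SPAN_MS = 2000.0

#: Beta parameters of the long-outlier share.
P_LONG_ALPHA, P_LONG_BETA = 5.0, 1.0
#: Maximum outlier fraction per sample.
MAX_OUTLIER_FRACTION = 0.1

#: mu offsets of the overlap-scheme contaminant distributions (ms).
OVERLAP_LONG_MU_OFFSET = 700.0
OVERLAP_SHORT_MU_OFFSET = -200.0
#: sigma widening for overlap long outliers (ms); short sigma / tau constants.
OVERLAP_LONG_SIGMA_EXTRA = 10.0
OVERLAP_SHORT_SIGMA = 20.0
OVERLAP_SHORT_TAU = 10.0

# Integer tail codes used internally (compact storage in hot loops).
TAIL_NONE, TAIL_SHORT, TAIL_LONG = 0, 1, 2
_TAIL_NAMES = np.array(["none", "short", "long"])


@dataclass(frozen=True)
class OutlierPlan:
    """Outlier counts shared by the two conditions of a pair.

    ``n_long + n_short == n_outliers`` by construction; ``p_long`` is the
    Beta(5, 1) draw behind the split.
    """

    n_outliers: int
    n_long: int
    n_short: int
    p_long: float

    def __post_init__(self) -> None:
        if self.n_long + self.n_short != self.n_outliers:
            raise ValueError("n_long + n_short must equal n_outliers")
        if not 0.0 <= self.p_long <= 1.0:
            raise ValueError("p_long must lie in [0, 1]")
        if min(self.n_outliers, self.n_long, self.n_short) < 0:
            raise ValueError("outlier counts must be non-negative")


@dataclass
class ContaminatedSample:
    """An RT vector with ground-truth outlier annotation.

    Attributes
    ----------
    values : numpy.ndarray
        Contaminated RTs; same length as the valid sample (replacement,
        not addition).
    outlier_flag : numpy.ndarray
        Boolean per element; True where a valid RT was replaced.
    tail_code : numpy.ndarray
        int8 per element: 0 none, 1 short, 2 long.
    valid_reference : RTSample
        The pre-contamination sample.
    degenerate_short_range : bool
        True when the valid minimum was at or below the 100 ms floor and
        short outliers fell back to a (0, min) band.
    """

    values: np.ndarray
    outlier_flag: np.ndarray
    tail_code: np.ndarray
    valid_reference: RTSample
    degenerate_short_range: bool = False

    @property
    def tail_label(self) -> np.ndarray:
        """Per-element labels ``{"none", "short", "long"}``."""
        return _TAIL_NAMES[self.tail_code]


def draw_outlier_plan(n_trials: int, rng: np.random.Generator) -> OutlierPlan:
    """Draw the outlier counts for one pair of samples.

    ``n_outliers = round(u)``, ``u ~ U(0, 0.1 n_trials)``; the long count is
    ``round(p_long * n_outliers)`` with ``p_long ~ Beta(5, 1)`` and the
    short count is the remainder, so the counts always sum correctly.
    Rounding is round-half-to-even.

    One plan is drawn per pair and applied to both conditions.
    """
    if n_trials < 20:
        raise ValueError(f"n_trials must be >= 20, got {n_trials}")
    u = rng.uniform(0.0, MAX_OUTLIER_FRACTION * n_trials)
    n_outliers = round(u)
    p_long = rng.beta(P_LONG_ALPHA, P_LONG_BETA)
    n_long = round(p_long * n_outliers)
    return OutlierPlan(
        n_outliers=n_outliers,
        n_long=n_long,
        n_short=n_outliers - n_long,
        p_long=p_long,
    )


def _replace(
    valid: RTSample,
    plan: OutlierPlan,
    long_values: np.ndarray,
    short_values: np.ndarray,
    rng: np.random.Generator,
    degenerate: bool,
) -> ContaminatedSample:
    """Place outlier values at uniformly chosen positions without replacement."""
    n = valid.values.size
    values = valid.values.copy()
    flag = np.zeros(n, dtype=bool)
    code = np.zeros(n, dtype=np.int8)
    if plan.n_outliers:
        positions = rng.choice(n, size=plan.n_outliers, replace=False)
        long_pos = positions[: plan.n_long]
        short_pos = positions[plan.n_long :]
        values[long_pos] = long_values
        values[short_pos] = short_values
        flag[positions] = True
        code[long_pos] = TAIL_LONG
        code[short_pos] = TAIL_SHORT
    return ContaminatedSample(
        values=values,
        outlier_flag=flag,
        tail_code=code,
        valid_reference=valid,
        degenerate_short_range=degenerate,
    )


def inject_tails(
    valid: RTSample, plan: OutlierPlan, rng: np.random.Generator
) -> ContaminatedSample:
    """Replace valid RTs with outliers strictly outside the sample range.

    Long outliers: ``U(0, 1) * 2000 + max(valid)``.  Short outliers:
    ``U(0, 1) * (min(valid) - 100) + 100``, i.e. uniform on (100, min).
    min/max are taken on the pre-contamination sample.  If the valid minimum
    is at or below 100 ms the short band degenerates; short outliers are
    then drawn uniform on (0, min) and a warning is emitted.
    """
    v = valid.values
    degenerate = False
    long_values = np.empty(0)
    short_values = np.empty(0)
    if plan.n_long:
        long_values = rng.uniform(0.0, 1.0, plan.n_long) * LONG_SPAN_MS + v.max()
    if plan.n_short:
        mn = v.min()
        if mn > SHORT_FLOOR_MS:
            short_values = (
                rng.uniform(0.0, 1.0, plan.n_short) * (mn - SHORT_FLOOR_MS)
                + SHORT_FLOOR_MS
            )
        else:
            degenerate = True
            warnings.warn(
                f"valid minimum {mn:.1f} ms is at or below the {SHORT_FLOOR_MS:.0f} ms "
                "floor; drawing short outliers uniform on (0, min)",
                stacklevel=2,
            )
            short_values = rng.uniform(0.0, 1.0, plan.n_short) * mn
    return _replace(valid, plan, long_values, short_values, rng, degenerate)


def inject_overlap(
    valid: RTSample, plan: OutlierPlan, rng: np.random.Generator
) -> ContaminatedSample:
    """Replace valid RTs with outliers that may overlap the valid range.

    Long outliers are Ex-Gaussian with mu = mean(valid) + 700 ms,
    sigma = U(20, 50) + 10 ms and tau = U(150, 200) ms; sigma and tau are
    drawn once per call (one contaminant distribution per sample).  Short
    outliers are Ex-Gaussian with mu = mean(valid) - 200 ms, sigma = 20 ms,
    tau = 10 ms.  Negative draws are multiplied by -1 so all RTs stay
    positive.
    """
    m = float(valid.values.mean())
    long_values = np.empty(0)
    short_values = np.empty(0)
    if plan.n_long:
        sigma_long = rng.uniform(*SIGMA_RANGE) + OVERLAP_LONG_SIGMA_EXTRA
        tau_long = rng.uniform(*TAU_RANGE)
        long_values = rng.normal(
            m + OVERLAP_LONG_MU_OFFSET, sigma_long, plan.n_long
        ) + rng.exponential(tau_long, plan.n_long)
        np.abs(long_values, out=long_values)
    if plan.n_short:
        short_values = rng.normal(
            m + OVERLAP_SHORT_MU_OFFSET, OVERLAP_SHORT_SIGMA, plan.n_short
        ) + rng.exponential(OVERLAP_SHORT_TAU, plan.n_short)
        np.abs(short_values, out=short_values)
    return _replace(valid, plan, long_values, short_values, rng, False)


_INJECTORS = {"tails": inject_tails, "overlap": inject_overlap}


def contaminate_pair(
    pair: tuple[RTSample, RTSample],
    plan: OutlierPlan,
    approach: str,
    rng: np.random.Generator,
) -> tuple[ContaminatedSample, ContaminatedSample]:
    """Contaminate both conditions of a pair with the same outlier counts.

    Outlier values and replaced positions are drawn independently per
    condition; only the counts (and the underlying ``p_long``) are shared.

    Parameters
    ----------
    pair : (RTSample, RTSample)
        The two valid samples; must have equal length.
    plan : OutlierPlan
    approach : {"tails", "overlap"}
    rng : numpy.random.Generator
    """
    a, b = pair
    if a.values.size != b.values.size:
        raise ValueError("both conditions must share the same number of trials")
    try:
        inject = _INJECTORS[approach]
    except KeyError:
        raise ValueError(
            f"unknown approach {approach!r}; expected one of {APPROACHES}"
        ) from None
    return inject(a, plan, rng), inject(b, plan, rng)
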