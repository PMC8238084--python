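"""Ex-Gaussian response-time generation.

Empirical response-time (RT) distributions are right-skewed and are commonly
modelled as Ex-Gaussian: the sum of a Normal(mu, sigma) component (the
"bell") and an Exponential component with mean tau (the right tail).  This
module draws population parameters for simulated experiments and samples
pairs of RT distributions representing two experimental conditions whose
populations differ only by a shift of ``diff`` milliseconds in mu.

Parameter ranges (all in milliseconds, trial counts dimensionless)::

    N      ~ U{20, ..., 100}     trials per condition (integer)
    mu     ~ U(250, 500)
    sigma  ~ U(20, 50)
    tau    ~ U(150, 200)
    diff   in {0, 1, ..., 100}   population mu-shift of condition 2

N, sigma and tau are shared within a pair; only mu differs between the two
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "N_RANGE",
    "MU_RANGE",
    "SIGMA_RANGE",
    "TAU_RANGE",
    "DEFAULT_DIFF_GRID",
    "ExGaussParams",
    "PairConfig",
    "RTSample",
    "draw_pair_config",
    "sample_exgauss",
    "make_pair",
]

#: Inclusive integer range for the number of trials per condition.
N_RANGE = (20, 100)
#: Continuous uniform range for the Gaussian mean mu (ms).
MU_RANGE = (250.0, 500.0)
#: Continuous uniform range for the Gaussian SD sigma (ms).
SIGMA_RANGE = (20.0, 50.0)
#: Continuous uniform range for the exponential mean tau (ms).
TAU_RANGE = (150.0, 200.0)
#: Population mu-differences examined by the default study grid (ms).
DEFAULT_DIFF_GRID = tuple(range(101))


@dataclass(frozen=True)
class ExGaussParams:
    """Parameters of one Ex-Gaussian RT-generating distribution.

    Attributes
    ----------
    mu : float
        Mean of the Gaussian component, in ms.  Must be positive.
    sigma : float
        Standard deviation of the Gaussian component, in ms.  Must be
        positive.
    tau : float
        Mean of the Exponential component (the decay of the right tail),
        in ms.  Must be positive.
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.sigma > 0 and self.tau > 0):
            raise ValueError(
                f"ExGaussParams requires mu, sigma, tau > 0; "
                f"got mu={self.mu}, sigma={self.sigma}, tau={self.tau}"
            )

    @property
    def mean(self) -> float:
        """Population mean, ``mu + tau``."""
        return self.mu + self.tau

    @property
    def variance(self) -> float:
        """Population variance, ``sigma**2 + tau**2``."""
        return self.sigma**2 + self.tau**2

    @property
    def skewness(self) -> float:
        """Population skewness, ``2 tau^3 / (sigma^2 + tau^2)^(3/2)``."""
        return 2.0 * self.tau**3 / self.variance**1.5

    def shifted(self, delta: float) -> "ExGaussParams":
        """Return a copy with ``mu`` shifted by ``delta`` ms."""
        return replace(self, mu=self.mu + delta)


@dataclass(frozen=True)
class PairConfig:
    """Shared configuration of one simulated pair of conditions.

    ``n_trials``, ``sigma`` and ``tau`` are held constant within the pair;
    the population mu-shift of condition 2 is supplied separately by the
    experiment grid (see :func:`make_pair`).
    """

    n_trials: int
    base_params: ExGaussParams

    def __post_init__(self) -> None:
        if not (N_RANGE[0] <= self.n_trials <= N_RANGE[1]):
            raise ValueError(
                f"n_trials must lie in [{N_RANGE[0]}, {N_RANGE[1]}]; "
                f"got {self.n_trials}"
            )


@dataclass(frozen=True)
class RTSample:
    """A simulated RT sample for one condition.

    Attributes
    ----------
    values : numpy.ndarray
        RTs in ms, length equal to the pair's ``n_trials``.
    condition : int
        Condition label, 1 or 2.
    """

    values: np.ndarray
    condition: int


def draw_pair_config(rng: np.random.Generator) -> PairConfig:
    """Draw the shared population parameters of one sample pair.

    ``n_trials`` is an integer uniform on ``{20, ..., 100}``; ``mu``,
    ``sigma`` and ``tau`` are continuous uniform draws on their stated
    ranges.  The mu-shift ``diff`` of condition 2 is *not* drawn here; it is
    an experiment-grid input to :func:`make_pair`.

    Parameters
    ----------
    rng : numpy.random.Generator
        Source of randomness.

    Returns
    -------
    PairConfig
    """
    n_trials = int(rng.integers(N_RANGE[0], N_RANGE[1] + 1))
    mu = rng.uniform(*MU_RANGE)
    sigma = rng.uniform(*SIGMA_RANGE)
    tau = rng.uniform(*TAU_RANGE)
    return PairConfig(n_trials=n_trials, base_params=ExGaussParams(mu, sigma, tau))


def sample_exgauss(params: ExGaussParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` Ex-Gaussian RTs.

    Each value is one Normal(mu, sigma) draw plus one Exponential(mean tau)
    draw.

    Parameters
    ----------
    params : ExGaussParams
    n : int
        Number of values; must be at least 1.
    rng : numpy.random.Generator

    Returns
    -------
    numpy.ndarray
        Vector of ``n`` RTs in ms.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return rng.normal(params.mu, params.sigma, n) + rng.exponential(params.tau, n)


def make_pair(
    config: PairConfig, diff: float, rng: np.random.Generator
) -> tuple[RTSample, RTSample]:
    """Sample one pair of valid RT distributions with a known mu-shift.

    Condition 1 is sampled from ``config.base_params``; condition 2 from the
    same parameters with ``mu + diff``.  Both samples have length
    ``config.n_trials``.

    Parameters
    ----------
    config : PairConfig
    diff : float
        Population mu-difference in ms; must be non-negative.
    rng : numpy.random.Generator

    Returns
    -------
    (RTSample, RTSample)
        Samples for condition 1 and condition 2.
    """
    if diff < 0:
        raise ValueError(f"diff must be >= 0, got {diff}")
    a = sample_exgauss(config.base_params, config.n_trials, rng)
    b = sample_exgauss(config.base_params.shifted(diff), config.n_trials, rng)
    return RTSample(a, condition=1), RTSample(b, condition=2)
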