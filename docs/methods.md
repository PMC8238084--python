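# Methods

## The question

Response-time (RT) experiments routinely discard outlying trials before
testing condition differences, but the field uses many exclusion rules with
different assumptions. `rtexclude` implements a Monte-Carlo design that
quantifies how each rule distorts inference: simulate two RT samples whose
populations differ by a known amount, contaminate them with outliers,
exclude outliers by each rule, and compare each rule's rate of significant
two-sample tests against the rate obtained on the uncontaminated samples.

## Generating valid RT pairs

RTs are Ex-Gaussian: one draw is Normal(mu, sigma) plus Exponential(mean
tau), giving the characteristic right-skewed shape (population mean
mu + tau, variance sigma^2 + tau^2, skewness 2 tau^3 / (sigma^2 +
tau^2)^{3/2}). Per simulated pair the shared parameters are drawn as

* N ~ U{20, ..., 100} trials per condition,
* mu ~ U(250, 500) ms, sigma ~ U(20, 50) ms, tau ~ U(150, 200) ms,

and condition 2 adds a fixed mu-shift `diff`, varied over 0..100 ms in 1 ms
steps. N is drawn as an integer (trial counts are integers; the continuous
alternative has no physical reading); mu, sigma, tau stay continuous. The
Gaussian component can in principle go negative, but with mu >= 250 ms and
sigma <= 50 ms the probability is below 1e-7 per draw; values are not
clipped. The full design is 101 x 5000 pairs per contamination approach;
the package runs any replication level.

## Contaminating with outliers

Per pair, `n_outliers = round(u)`, `u ~ U(0, 0.1 N)` (at most ~10%
outliers: noisier data should be discarded wholesale, not repaired). Each
outlier is long with probability `p_long ~ Beta(5, 1)` (mean 5/6 ~ 0.83;
the physiological floor leaves little room for fast guesses), so
`n_long = round(p_long * n_outliers)` and the short count is the
remainder — taking the remainder rather than rounding both keeps the counts
summing correctly. Rounding is round-half-to-even throughout. Counts are
shared between the two conditions of a pair (`p_long` is drawn once per
pair); outlier values and the replaced positions (uniform, without
replacement) are independent per condition. Replacement keeps the sample
size unchanged.

Two generative schemes:

* **tails** — outliers strictly outside the valid range: long uniform on
  (max, max + 2000) ms, short uniform on (100, min) ms, with min/max taken
  on the pre-contamination sample. If a sample's minimum is at or below
  100 ms the short band degenerates; short outliers then come from
  (0, min) and the event is warned about and counted (it is rare: valid
  minima essentially never fall below 100 ms under the stated ranges).
* **overlap** — outliers from shifted Ex-Gaussians that can overlap the
  valid RTs: long with mu = mean(valid) + 700 ms, sigma = U(20, 50) + 10
  ms, tau = U(150, 200) ms; short with mu = mean(valid) - 200 ms, sigma =
  20 ms, tau = 10 ms. The long-outlier sigma and tau are drawn once per
  sample (one contaminant distribution per sample, not per outlier).
  Negative draws are sign-flipped so RTs stay positive.

## Exclusion rules

Ten rules (see the table in `exclusion.py`): none, a-priori cutoffs
(200 ms / mean + 1000 ms), mean +/- 2 or 3 SD, Tukey fences (quartiles +/-
1.5 IQR), symmetric quantile trims (outer 10% and 5%), median +/- 2.5 MAD
with the Normal constant b = 1.4826 or the Ex-Gaussian-adjusted b = 1.1020,
and a transform rule (z-scores of sqrt range-normalised values, |z| > 2).
Numerical conventions, applied uniformly:

* every statistic is computed on the contaminated sample itself — rules
  must work blind, never on ground truth;
* sample SDs use the n-1 denominator; quantiles use linear interpolation
  with `h = (n-1) p + 1` (R type 7 / NumPy default);
* threshold comparisons are strict: a value exactly on a threshold is kept
  ("larger/smaller than" reading of the bounds);
* degenerate inputs (constant vector, zero MAD, fewer values than a rule
  needs) exclude nothing and warn, so a pipeline never loses iterations.

## Inference and the bias statistic

Each pair (uncontaminated, and post-exclusion per rule) is tested with a
two-sided Student t-test with pooled variance at alpha = 0.05 — pooled
rather than Welch because the populations share sigma by design, and the
pooled formula handles the unequal sample sizes that exclusion produces.
If a rule leaves fewer than `min_n_after_exclusion` (default 3)
observations on either side, the test is undefined and the iteration is
recorded as non-significant for that rule, with a counter. Per method m,
approach and difference level,

    bias(m | diff) = p_sign(m | diff) - p_sign(valid | diff),

where p_sign is the proportion of significant tests. Positive bias means
the rule manufactures significance the clean data do not support (Type-I
direction); negative bias means it, or the retained outliers, mask true
effects (Type-II direction). The summary table averages bias over the
difference grid per approach plus the unweighted cross-approach mean, and
is sorted by decreasing |mean bias|.

Two auxiliary analyses: an OLS regression of the per-iteration t-values on
the population difference, the method indicators (reference: no exclusion)
and the post-exclusion sample SD and trial count averaged over the two
conditions (for the reference level these equal the contaminated values);
and the Pearson correlation between |bias| and the mean excluded
proportion, computed without the "no" rule, both over method x diff cells
and over per-method means — the aggregation unit of the published
correlation is not fixed, so both are reported and neither is asserted.

## Randomness and reproducibility

All randomness flows from one master seed. Each (approach, difference,
repetition) iteration uses a `SeedSequence` substream keyed by its
coordinates, so a single iteration is reproducible in isolation and
results are invariant to which subset of the grid is run. Per iteration
the draw order is: pair parameters, condition-1 sample, condition-2
sample, outlier plan, contamination of condition 1, then condition 2.

## Replication scales and test calibration

The full 101 x 5000 x 2 grid takes a few CPU-hours; all distributional
behaviour stabilises far earlier, so the package's own checks run the full
difference grid at reduced replication — 500 pairs per level in the test
suite, 300 in the acceptance script — where aggregate bias estimates carry
a Monte-Carlo SE near 0.002.

Qualitative claims are tested in forms whose error rates are controlled at
that replication level, chosen before running them:

* "conservative rules never show positive bias" is asserted per difference
  level as `bias <= max(0.01, 4 SE)`, with the SE estimated from the paired
  significance indicators, since the maximum of 400 noisy cells otherwise
  exceeds any fixed small constant with non-trivial probability;
* rank and sign assertions on the bias summary treat entries closer than
  0.005 (ranks) or 0.01 (per-approach signs) as unresolvable — gaps of
  0.001-0.003 between the three best-performing rules are below both this
  package's and the original design's Monte-Carlo resolution;
* power monotonicity in `diff` is checked on a 5 ms grid at 3000 reps,
  where the expected power increment per step dominates the noise.

## What the generator does and does not emulate

The generator reproduces the variability structure the design prescribes:
heterogeneous trial counts, means, spreads and outlier loads across
simulated "experiments". It does not model trial-order effects, sequential
dependencies, condition-specific outlier rates, accuracy/speed trade-offs,
or multiple subjects per condition (each iteration is a single pair of
samples; the t-test is unpaired because exclusion makes the sides unequal).
Passing tests therefore speak to how exclusion rules behave on skewed,
contaminated i.i.d. samples — not to designs where outlier processes
differ between conditions, which is exactly the situation exclusion cannot
repair.

## Known limitations

* The Ex-Gaussian adjustment b = 1.1020 for the MAD is adopted as a given
  constant; its derivation is not re-derived here.
* The `overlap` scheme's short-outlier sign-flip makes tiny RTs slightly
  more likely than a truncated distribution would; it follows the stated
  generative recipe.
* Bias is defined on significance rates, not on effect-size recovery; a
  rule can have small bias while still distorting summary statistics.
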