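"""Exclusion rules: worked examples, oracle equivalence, edge behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ORACLES
from rtexclude import (
    METHOD_NAMES,
    METHODS,
    apply_method,
    exclude_cutoff,
    exclude_mad,
    exclude_none,
    exclude_quantile,
    exclude_sd,
    exclude_transform,
    exclude_tukey,
)

SEVEN = [300.0, 320.0, 340.0, 360.0, 380.0, 400.0, 2000.0]


def kept_values(outcome, rts):
    return list(np.asarray(rts)[outcome.kept])


def test_no_exclusion_keeps_everything():
    out = exclude_none(SEVEN)
    assert out.kept.all()
    assert out.prop_excluded_low == out.prop_excluded_high == 0.0


@pytest.mark.parametrize(
    "rts,expected_kept",
    [
        ([150.0, 300.0, 400.0, 2000.0], [300.0, 400.0]),  # mean 712.5, upper 1712.5
        ([300.0, 400.0, 500.0], [300.0, 400.0, 500.0]),
        ([100.0, 250.0], [250.0]),  # mean 175, upper 1175; 100 below the 200 floor
        ([200.0, 300.0], [200.0, 300.0]),  # exactly on the lower cutoff: kept
    ],
)
def test_cutoff_uses_200ms_floor_and_mean_plus_second(rts, expected_kept):
    assert kept_values(exclude_cutoff(rts), rts) == expected_kept


def test_sd_rule_worked_example():
    # mean ~585.71, SD ~624.58: only 2000 lies beyond mean + 2 SD
    out2 = exclude_sd(SEVEN, k=2.0)
    assert out2.upper == pytest.approx(1834.87, abs=0.01)
    assert kept_values(out2, SEVEN) == SEVEN[:-1]
    # at 3 SD the upper bound ~2459.4 keeps everything
    out3 = exclude_sd(SEVEN, k=3.0)
    assert out3.upper == pytest.approx(2459.44, abs=0.01)
    assert out3.kept.all()


def test_constant_vector_excludes_nothing():
    x = [400.0] * 10
    assert exclude_sd(x, 2.0).kept.all()
    with pytest.warns(UserWarning, match="MAD is zero"):
        assert exclude_mad(x).kept.all()
    with pytest.warns(UserWarning, match="identical"):
        assert exclude_transform(x).kept.all()


def test_tukey_worked_example():
    x = [100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 5000.0]
    out = exclude_tukey(x)
    assert out.lower == pytest.approx(-250.0)
    assert out.upper == pytest.approx(1150.0)
    assert kept_values(out, x) == x[:-1]
    # a value equal to the (new) upper fence is kept; 5000 still falls
    x2 = x + [1150.0]
    out2 = exclude_tukey(x2)
    assert 1150.0 in kept_values(out2, x2)
    assert 5000.0 not in kept_values(out2, x2)


def test_quantile_rule_worked_examples():
    x = [float(v) for v in range(100, 2001, 100)]  # 20 values
    out10 = exclude_quantile(x, p=0.05)
    assert (out10.lower, out10.upper) == (pytest.approx(195.0), pytest.approx(1905.0))
    assert kept_values(out10, x) == x[1:-1]
    out05 = exclude_quantile(x, p=0.025)
    assert (out05.lower, out05.upper) == (pytest.approx(147.5), pytest.approx(1952.5))
    assert kept_values(out05, x) == x[1:-1]


def test_quantile_boundary_values_are_kept():
    # 21 equally spaced values: q0.05 / q0.95 land exactly on elements
    x = [float(v) for v in range(0, 2001, 100)]
    out = exclude_quantile(x, p=0.05)
    kept = kept_values(out, x)
    assert 100.0 in kept and 1900.0 in kept
    assert kept == x[1:-1]


def test_mad_rule_worked_example_both_constants():
    x = [235.0, 300.0, 320.0, 340.0, 360.0, 380.0, 400.0, 2000.0]
    out = exclude_mad(x, b=1.4826)  # MAD 59.30, bounds (201.7, 498.3)
    assert out.lower == pytest.approx(201.74, abs=0.01)
    assert kept_values(out, x) == x[:-1]
    out_adj = exclude_mad(x, b=1.1020)  # MAD 44.08, bounds (239.8, 460.2)
    assert out_adj.lower == pytest.approx(239.8, abs=0.01)
    assert kept_values(out_adj, x) == x[1:-1]  # stricter: drops 235 too


def test_transform_rule_worked_examples():
    x = [100.0] + [300.0] * 10 + [3000.0]
    out = exclude_transform(x)
    assert kept_values(out, x) == x[:-1]  # z(3000) ~ 3.0 > 2; z(100) ~ -1.3 kept
    assert out.prop_excluded_high == pytest.approx(1 / 12)
    x2 = [100.0, 200.0, 300.0, 400.0, 500.0, 2000.0]
    assert exclude_transform(x2).kept.all()  # z(2000) ~ 1.79 < 2


@pytest.mark.parametrize(
    "fn,n_min",
    [
        (lambda x: exclude_sd(x, 2.0), 2),
        (exclude_tukey, 4),
        (exclude_mad, 2),
        (exclude_transform, 3),
        (lambda x: exclude_quantile(x, 0.05), 2),
    ],
)
def test_too_few_values_warn_and_keep_all(fn, n_min):
    x = [400.0] * (n_min - 1)
    with pytest.warns(UserWarning):
        out = fn(x)
    assert out.kept.all() and out.degenerate


def test_dispatch_matches_direct_calls():
    for name in METHOD_NAMES:
        np.testing.assert_array_equal(
            apply_method(name, SEVEN).kept, METHODS[name].fn(np.asarray(SEVEN)).kept
        )
    assert METHODS["MAD"].constants["b"] == 1.4826
    assert METHODS["MAD_adjusted"].constants["b"] == 1.1020
    with pytest.raises(ValueError, match="unknown exclusion method"):
        apply_method("winsorize", SEVEN)


@pytest.mark.parametrize("name", METHOD_NAMES)
@settings(derandomize=True, max_examples=60)
@given(xs=st.lists(st.integers(100, 600), min_size=4, max_size=8))
def test_masks_match_brute_force_oracle(name, xs):
    """Each rule's mask equals an element-wise re-derivation of its inequalities."""
    values = [float(v) for v in xs]
    out = apply_method(name, values)
    assert list(out.kept) == ORACLES[name](values)
    # bookkeeping: kept + excluded_low + excluded_high accounts for every value
    assert out.prop_excluded_low + out.prop_excluded_high == pytest.approx(
        1.0 - out.kept.mean()
    )


@settings(derandomize=True, max_examples=100)
@given(
    xs=st.lists(
        st.floats(100.0, 5000.0, allow_nan=False, allow_infinity=False),
        min_size=2,
        max_size=40,
    )
)
def test_three_sd_exclusions_nest_inside_two_sd(xs):
    x = np.asarray(xs)
    ex2 = ~exclude_sd(x, 2.0).kept
    ex3 = ~exclude_sd(x, 3.0).kept
    assert not (ex3 & ~ex2).any()
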