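"""Shrinkage rules: frozen examples, branch limits, and structural properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavedn.shrinkage import (
    ShrinkageSpec,
    apply_shrinkage,
    shrink_hard,
    shrink_improved,
    shrink_semisoft,
    shrink_soft,
)

# Frozen expected values. The improved-rule entries were computed with an
# exact-rational sympy evaluation of
#   w - w*m/2.1**(100|w|/lam - 99)         (|w| > lam)
#   w*m/2.1**(1 - log_100(|w|/lam))        (|w| <= lam)
CASES = [
    (lambda w: shrink_hard(w, 1.0), 0.0, 0.0),
    (lambda w: shrink_hard(w, 1.0), 2.0, 2.0),
    (lambda w: shrink_hard(w, 1.0), -0.5, 0.0),
    (lambda w: shrink_soft(w, 1.0), 3.0, 2.0),
    (lambda w: shrink_soft(w, 1.0), -3.0, -2.0),
    (lambda w: shrink_soft(w, 1.0), 0.9, 0.0),
    (lambda w: shrink_semisoft(w, 1.0, 2.0), 0.5, 0.0),
    (lambda w: shrink_semisoft(w, 1.0, 2.0), 3.0, 3.0),
    (lambda w: shrink_semisoft(w, 1.0, 2.0), 1.5, 1.0),
    (lambda w: shrink_improved(w, 1.0, 1.05), 1.0, 0.5),
    (lambda w: shrink_improved(w, 1.0, 1.05), 0.0, 0.0),
    (lambda w: shrink_improved(w, 1.0, 1.05), 0.5, 0.22358423200402353),
    (lambda w: shrink_improved(w, 1.0, 1.05), 0.25, 0.09997981760165804),
    (lambda w: shrink_improved(w, 1.0, 1.05), 1.2, 1.1999997843421080),
]


@pytest.mark.parametrize("rule, w, expected", CASES)
def test_scalar_values(rule, w, expected):
    assert rule(w) == pytest.approx(expected, abs=1e-12)


def test_improved_asymptotic_identity():
    # beyond 2*lam the exponential correction is below float resolution
    w = np.linspace(2.0, 10.0, 200)
    assert np.max(np.abs(shrink_improved(w, 1.0, 1.05) - w)) < 1e-12


def test_improved_continuity_at_threshold():
    lam, m = 0.7, 1.05
    eps = 1e-8 * lam
    left = shrink_improved(lam - eps, lam, m)
    right = shrink_improved(lam + eps, lam, m)
    anchor = lam * m / 2.1
    assert abs(left - right) < 1e-6
    assert abs(left - anchor) < 1e-6 and abs(right - anchor) < 1e-6
    assert anchor == pytest.approx(lam / 2)


def test_improved_discontinuous_for_nondefault_m():
    # only m = 2.1/2 joins the branches exactly; m = 2 leaves a gap
    lam = 1.0
    gap = shrink_improved(lam + 1e-12, lam, 2.0) - shrink_improved(lam, lam, 2.0)
    assert abs(gap) > 0.4


@pytest.mark.parametrize(
    "rule",
    [
        lambda w: shrink_hard(w, 1.3),
        lambda w: shrink_soft(w, 1.3),
        lambda w: shrink_semisoft(w, 1.0, 2.6),
        lambda w: shrink_improved(w, 1.3, 1.05),
        lambda w: shrink_improved(w, 1.3, 0.4),
    ],
)
def test_odd_symmetry_on_grid(rule):
    w = np.linspace(-13.0, 13.0, 4001)
    np.testing.assert_allclose(rule(-w), -rule(w), atol=1e-14)


@pytest.mark.parametrize(
    "rule",
    [
        lambda w: shrink_soft(w, 1.0),
        lambda w: shrink_semisoft(w, 1.0, 2.0),
        lambda w: shrink_improved(w, 1.0, 1.05),
        lambda w: shrink_improved(w, 1.0, 2.1),
    ],
)
def test_shrinkage_bound(rule):
    w = np.linspace(-10.0, 10.0, 4001)
    assert np.all(np.abs(rule(w)) <= np.abs(w) + 1e-14)


@pytest.mark.parametrize(
    "rule",
    [
        lambda w: shrink_hard(w, 1.0),
        lambda w: shrink_soft(w, 1.0),
        lambda w: shrink_semisoft(w, 1.0, 2.0),
        lambda w: shrink_improved(w, 1.0, 1.05),
    ],
)
def test_monotone_nondecreasing(rule):
    w = np.arange(-10.0, 10.0, 1e-3)
    out = rule(w)
    assert np.all(np.diff(out) >= -1e-12)


def test_soft_improved_hard_sandwich():
    lam = 1.0
    w = np.linspace(lam + 1e-9, 10 * lam, 4001)
    soft, imp, hard = shrink_soft(w, lam), shrink_improved(w, lam, 1.05), shrink_hard(w, lam)
    assert np.all(soft <= imp + 1e-14) and np.all(imp <= hard + 1e-14)


@given(
    w=st.floats(-50, 50, allow_nan=False),
    lam=st.floats(1e-3, 10),
    m=st.floats(1e-3, 2.1),
)
@settings(max_examples=200, deadline=None)
def test_improved_properties_hypothesis(w, lam, m):
    out = shrink_improved(w, lam, m)
    assert abs(out) <= abs(w) + 1e-12  # shrinkage for m <= 2.1
    assert out * w >= 0  # sign preserved or zero
    assert shrink_improved(-w, lam, m) == pytest.approx(-out, abs=1e-12)


def test_hard_idempotent():
    w = np.linspace(-5, 5, 101)
    once = shrink_hard(w, 1.0)
    np.testing.assert_array_equal(shrink_hard(once, 1.0), once)


@pytest.mark.parametrize(
    "call",
    [
        lambda: shrink_hard(1.0, -0.1),
        lambda: shrink_soft(1.0, -0.1),
        lambda: shrink_semisoft(1.0, 2.0, 1.0),
        lambda: shrink_semisoft(1.0, 2.0, 2.0),
        lambda: shrink_improved(1.0, 0.0),
        lambda: shrink_improved(1.0, 1.0, -1.0),
        lambda: ShrinkageSpec(rule="garrote"),
        lambda: ShrinkageSpec(rule="improved", m=0.0),
        lambda: ShrinkageSpec(rule="semisoft", lam1=2.0, lam2=1.0),
    ],
)
def test_invalid_parameters_raise(call):
    with pytest.raises(ValueError):
        call()


class TestApplyShrinkage:
    def test_zero_array_maps_to_zero(self):
        z = np.zeros((7, 5))
        for rule in ("hard", "soft", "semisoft", "improved"):
            out = apply_shrinkage(z, ShrinkageSpec(rule, lam=1.0))
            assert out.shape == z.shape and not out.any()

    def test_matches_scalar_example(self):
        out = apply_shrinkage(np.array([3.0, 0.9]), ShrinkageSpec("soft", lam=1.0))
        np.testing.assert_allclose(out, [2.0, 0.0])

    @pytest.mark.parametrize("rule", ["hard", "soft", "semisoft", "improved"])
    def test_elementwise_matches_scalar_loop(self, rule, rng):
        coeffs = rng.normal(0, 2, size=(11, 13))
        spec = ShrinkageSpec(rule, lam=1.2, m=1.05)
        out = apply_shrinkage(coeffs, spec)
        scalar = {
            "hard": lambda w: shrink_hard(w, 1.2),
            "soft": lambda w: shrink_soft(w, 1.2),
            "semisoft": lambda w: shrink_semisoft(w, 1.2, 2.4),
            "improved": lambda w: shrink_improved(w, 1.2, 1.05),
        }[rule]
        brute = np.array([[scalar(w) for w in row] for row in coeffs])
        np.testing.assert_allclose(out, brute, atol=1e-15, rtol=0)

    def test_semisoft_default_bounds_from_lam(self):
        # lam alone implies lam1 = lam, lam2 = 2*lam
        out = apply_shrinkage(np.array([1.5]), ShrinkageSpec("semisoft", lam=1.0))
        assert out[0] == pytest.approx(1.0)

    def test_lam_zero_is_identity_for_all_rules(self, rng):
        coeffs = rng.normal(size=20)
        for rule in ("hard", "soft", "semisoft", "improved"):
            np.testing.assert_array_equal(
                apply_shrinkage(coeffs, ShrinkageSpec(rule, lam=0.0)), coeffs
            )
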