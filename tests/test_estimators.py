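"""Wald ratios, IVW, MR-Egger, and weighted-median estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrdiet import (
    HarmonizedSet,
    InsufficientInstrumentsError,
    InvalidInstrumentError,
    RatioSet,
    egger,
    ivw,
    wald_ratios,
    weighted_median,
    weighted_median_point,
)


def _hset_from(rng, j=10):
    gamma = rng.uniform(0.05, 0.4, j) * rng.choice([-1.0, 1.0], j)
    return HarmonizedSet.from_arrays(
        gamma,
        rng.uniform(0.005, 0.02, j),
        rng.normal(0.0, 0.3, j),
        rng.uniform(0.02, 0.2, j),
    )


class TestWaldRatios:
    def test_direct_division(self):
        hset = HarmonizedSet.from_arrays([0.1], [0.01], [0.2], [0.05])
        ratios = wald_ratios(hset)
        assert ratios.beta[0] == pytest.approx(2.0)
        assert ratios.se[0] == pytest.approx(0.5)

    def test_zero_outcome_effect_gives_zero_ratio(self):
        hset = HarmonizedSet.from_arrays([0.1], [0.01], [0.0], [0.05])
        assert wald_ratios(hset).beta[0] == 0.0

    def test_joint_sign_flip_leaves_ratios_unchanged(self):
        a = HarmonizedSet.from_arrays([0.1, 0.2], [0.01, 0.01], [0.3, -0.1], [0.05, 0.05])
        b = HarmonizedSet.from_arrays([-0.1, -0.2], [0.01, 0.01], [-0.3, 0.1], [0.05, 0.05])
        assert wald_ratios(a).beta == pytest.approx(wald_ratios(b).beta)
        assert wald_ratios(a).se == pytest.approx(wald_ratios(b).se)

    def test_zero_gamma_names_the_variant(self):
        hset = HarmonizedSet.from_arrays([0.1, 0.0], [0.01, 0.01], [0.2, 0.2], [0.05, 0.05],
                                         variant_ids=["rsOK", "rsBAD"])
        with pytest.raises(InvalidInstrumentError, match="rsBAD"):
            wald_ratios(hset)


class TestIvw:
    def test_hand_computed_weighted_mean(self):
        ratios = RatioSet.from_ratios([1.0, 3.0], [1.0, 1.0])
        est = ivw(ratios, "fixed")
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(1 / math.sqrt(2))

    def test_degenerate_homogeneity_fixed_equals_mre(self):
        ratios = RatioSet.from_ratios([0.7, 0.7, 0.7], [0.1, 0.2, 0.3])
        fixed, mre = ivw(ratios, "fixed"), ivw(ratios, "mre")
        assert fixed.beta == pytest.approx(0.7)
        assert mre.se == fixed.se  # Q = 0, inflation floored at 1

    def test_mre_inflates_never_deflates(self, rng):
        for _ in range(20):
            ratios = wald_ratios(_hset_from(rng))
            assert ivw(ratios, "mre").se >= ivw(ratios, "fixed").se

    def test_single_instrument_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(RatioSet.from_ratios([1.0], [0.5]))

    def test_equals_zero_intercept_wls_oracle(self, rng):
        """IVW is algebraically the zero-intercept WLS slope of Gamma on
        gamma with weights 1/sigma_Gamma^2; check both beta and SE to 1e-10
        against a brute-force normal-equations solve."""
        for _ in range(50):
            hset = _hset_from(rng)
            g, _, G, sG = hset.arrays()
            w = 1 / sG**2
            slope = float((w * g * G).sum() / (w * g * g).sum())
            se = float((w * g * g).sum() ** -0.5)
            est = ivw(wald_ratios(hset), "fixed")
            assert est.beta == pytest.approx(slope, abs=1e-10)
            assert est.se == pytest.approx(se, abs=1e-10)


class TestEgger:
    def test_exact_line_recovered(self, small_hset):
        fit = egger(small_hset)
        assert fit.intercept.beta == pytest.approx(0.1, abs=1e-10)
        assert fit.slope.beta == pytest.approx(2.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_requires_three_instruments(self):
        hset = HarmonizedSet.from_arrays([0.1, 0.2], [0.01, 0.01], [0.1, 0.2], [0.05, 0.05])
        with pytest.raises(InsufficientInstrumentsError):
            egger(hset)

    def test_matches_normal_equations_oracle(self, rng):
        """WLS coefficients and (inflated) SEs equal a brute-force solve of
        the weighted normal equations on the gamma-oriented design."""
        for _ in range(30):
            hset = _hset_from(rng)
            g, _, G, sG = hset.arrays()
            flip = g < 0
            g, G = np.abs(g), np.where(flip, -G, G)
            w = 1 / sG**2
            X = np.column_stack([np.ones_like(g), g])
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(X * sw[:, None], G * sw, rcond=None)
            resid = G - X @ coef
            phi = max(1.0, float((w * resid**2).sum()) / (len(g) - 2))
            cov = phi * np.linalg.inv(X.T @ (X * w[:, None]))
            fit = egger(hset)
            assert fit.intercept.beta == pytest.approx(coef[0], abs=1e-10)
            assert fit.slope.beta == pytest.approx(coef[1], abs=1e-10)
            assert fit.intercept.se == pytest.approx(math.sqrt(cov[0, 0]), abs=1e-10)
            assert fit.slope.se == pytest.approx(math.sqrt(cov[1, 1]), abs=1e-10)

    def test_orientation_invariance(self, rng):
        hset = _hset_from(rng)
        g, sg, G, sG = hset.arrays()
        flipped = HarmonizedSet.from_arrays(-g, sg, -G, sG)
        a, b = egger(hset), egger(flipped)
        assert a.slope.beta == pytest.approx(b.slope.beta)
        assert a.intercept.beta == pytest.approx(b.intercept.beta)


class TestWeightedMedian:
    def test_symmetric_median_with_equal_weights(self):
        ratios = RatioSet.from_ratios([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        est = weighted_median(ratios, n_boot=200, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_interpolation_formula_hand_computed(self):
        # weights {10, 1, 1} on betas {1, 2, 3}: p = (5/12, 10.5/12, 11.5/12)
        # -> interpolate between beta_1 and beta_2: 1 + (1/12)/(5.5/12) = 13/11
        se = (np.array([10.0, 1.0, 1.0])) ** -0.5
        ratios = RatioSet.from_ratios([1.0, 2.0, 3.0], se)
        est = weighted_median(ratios, n_boot=200, seed=1)
        assert est.beta == pytest.approx(13 / 11)

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(20):
            hset = _hset_from(rng)
            ratios = wald_ratios(hset)
            b = weighted_median_point(ratios.beta, ratios.weight)
            assert ratios.beta.min() <= b <= ratios.beta.max()

    def test_bootstrap_reproducible_and_warns_below_100(self):
        ratios = RatioSet.from_ratios([1.0, 2.0, 3.0, 4.0], [0.5, 0.5, 0.5, 0.5])
        a = weighted_median(ratios, n_boot=300, seed=42)
        b = weighted_median(ratios, n_boot=300, seed=42)
        assert a == b
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(ratios, n_boot=50, seed=42)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_estimators_invariant_to_reordering_and_joint_sign_flips(seed):
    rng = np.random.default_rng(seed)
    j = int(rng.integers(4, 12))
    g = rng.uniform(0.05, 0.4, j) * rng.choice([-1.0, 1.0], j)
    sg = rng.uniform(0.005, 0.02, j)
    G = rng.normal(0.0, 0.3, j)
    sG = rng.uniform(0.02, 0.2, j)
    base = HarmonizedSet.from_arrays(g, sg, G, sG)

    perm = rng.permutation(j)
    signs = rng.choice([-1.0, 1.0], j)
    transformed = HarmonizedSet.from_arrays(
        (g * signs)[perm], sg[perm], (G * signs)[perm], sG[perm]
    )
    for mode in ("fixed", "mre"):
        a, b = ivw(wald_ratios(base), mode), ivw(wald_ratios(transformed), mode)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)
    ea, eb = egger(base), egger(transformed)
    assert ea.slope.beta == pytest.approx(eb.slope.beta, rel=1e-9)
    wa = weighted_median_point(wald_ratios(base).beta, wald_ratios(base).weight)
    wb = weighted_median_point(wald_ratios(transformed).beta, wald_ratios(transformed).weight)
    assert wa == pytest.approx(wb, rel=1e-12)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    st.floats(min_value=-3, max_value=3, allow_nan=False),
    st.floats(min_value=0.01, max_value=2, allow_nan=False),
)
def test_or_and_ci_are_pure_exponential_transforms(beta, se):
    from mrdiet import MrEstimate

    est = MrEstimate("IVW_fixed", beta, se, 0.5, 10)
    assert est.or_value == pytest.approx(math.exp(beta))
    assert est.ci_low == pytest.approx(math.exp(beta - 1.96 * se))
    assert est.ci_high == pytest.approx(math.exp(beta + 1.96 * se))
    assert est.ci_low < est.or_value < est.ci_high
    assert math.log(est.or_value) == pytest.approx(beta, abs=1e-12)
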