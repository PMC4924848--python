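"""Wald ratios, IVW pooling, heterogeneity, MR-Egger, weighted median."""

import math

import numpy as np
import pytest

from mr2s.errors import ConfigError, DomainError
from mr2s.harmonize import HarmonizedInstrument
from mr2s.mr_core import (
    RatioEstimate,
    egger,
    heterogeneity,
    ivw_fixed,
    p_two_sided,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)


def _inst(snp="rs1", gamma=0.05, se_gamma=0.005, Gamma=0.02, se_Gamma=0.01, **kw):
    return HarmonizedInstrument(
        snp_id=snp, gamma=gamma, se_gamma=se_gamma, Gamma=Gamma, se_Gamma=se_Gamma, **kw
    )


def _random_instruments(rng, k, beta=0.4):
    out = []
    for j in range(k):
        g = rng.uniform(0.01, 0.1)
        seG = rng.uniform(0.005, 0.04)
        out.append(
            _inst(
                snp=f"r{j}",
                gamma=g,
                se_gamma=rng.uniform(0.001, 0.01),
                Gamma=beta * g + rng.normal(0, seG),
                se_Gamma=seG,
            )
        )
    return out


class TestWaldRatio:
    def test_null_outcome_gives_zero_ratio(self):
        r = wald_ratio(_inst(snp="rs1558902", gamma=0.082, Gamma=0.0, se_Gamma=0.0177758))
        assert r.ratio == 0.0

    def test_scale_cancellation(self):
        assert wald_ratio(_inst(gamma=0.003, Gamma=0.003)).ratio == pytest.approx(1.0)

    def test_delta_method_se(self):
        r = wald_ratio(_inst(gamma=0.05, se_Gamma=0.01))
        assert r.se_ratio == pytest.approx(0.2)

    def test_zero_exposure_effect_names_snp(self):
        with pytest.raises(DomainError, match="rs_null"):
            wald_ratio(_inst(snp="rs_null", gamma=0.0))


class TestIvwFixed:
    def test_single_ratio_passes_through(self):
        res = ivw_fixed([RatioEstimate("a", 0.3, 0.1)])
        assert res.beta == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1)
        assert res.het is None

    def test_two_identical_estimates_halve_the_variance(self):
        res = ivw_fixed([RatioEstimate("a", 0.3, 0.1), RatioEstimate("b", 0.3, 0.1)])
        assert res.beta == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1 / math.sqrt(2))

    def test_matches_explicit_summation_oracle(self):
        rng = np.random.default_rng(5)
        ratios = [
            RatioEstimate(f"r{j}", float(rng.normal(0.4, 0.3)), float(rng.uniform(0.05, 0.5)))
            for j in range(8)
        ]
        num = den = 0.0
        for r in ratios:
            w = 1.0 / r.se_ratio**2
            num += w * r.ratio
            den += w
        res = ivw_fixed(ratios)
        assert res.beta == pytest.approx(num / den, abs=1e-12)
        assert res.se == pytest.approx(den**-0.5, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            ivw_fixed([])

    def test_equals_zero_intercept_wls(self):
        """The pooled ratio estimate and the slope of a through-origin WLS
        of Gamma on gamma (weights 1/se_Gamma^2) are the same estimator."""
        rng = np.random.default_rng(17)
        instruments = _random_instruments(rng, 12)
        g = np.array([i.gamma for i in instruments])
        G = np.array([i.Gamma for i in instruments])
        w = np.array([1 / i.se_Gamma**2 for i in instruments])
        slope = np.sum(w * g * G) / np.sum(w * g * g)
        se = float(np.sum(w * g * g) ** -0.5)
        res = ivw_fixed(instruments)
        assert res.beta == pytest.approx(float(slope), abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)

    def test_ci_brackets_point_estimate(self):
        res = ivw_fixed([RatioEstimate("a", 0.3, 0.1)])
        assert res.ci_low < res.beta < res.ci_high


class TestHeterogeneity:
    def test_identical_estimates_have_no_dispersion(self):
        ratios = [RatioEstimate(f"r{j}", 0.25, 0.1) for j in range(4)]
        het = heterogeneity(ratios, 0.25)
        assert het.Q == 0.0
        assert het.i2 == 0.0

    def test_three_study_hand_computation(self):
        # Q = sum w (b - pooled)^2 accumulated term by term
        ratios = [RatioEstimate("a", 0.1, 0.1), RatioEstimate("b", 0.3, 0.2), RatioEstimate("c", 0.6, 0.3)]
        pooled = ivw_fixed(ratios).beta
        expected_q = (
            (0.1 - pooled) ** 2 / 0.01 + (0.3 - pooled) ** 2 / 0.04 + (0.6 - pooled) ** 2 / 0.09
        )
        het = heterogeneity(ratios, pooled)
        assert het.Q == pytest.approx(expected_q, abs=1e-12)
        assert het.df == 2
        expected_i2 = max(0.0, 100 * (expected_q - 2) / expected_q)
        assert het.i2 == pytest.approx(expected_i2, abs=1e-9)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(DomainError):
            heterogeneity([RatioEstimate("a", 0.1, 0.1)], 0.1)

    def test_i2_ci_brackets_and_truncates(self):
        rng = np.random.default_rng(2)
        ratios = [
            RatioEstimate(f"r{j}", float(rng.normal(0, 1)), float(rng.uniform(0.1, 0.3)))
            for j in range(10)
        ]
        het = heterogeneity(ratios, ivw_fixed(ratios).beta)
        assert 0.0 <= het.i2_ci_low <= het.i2 <= het.i2_ci_high <= 100.0


class TestEgger:
    def test_exact_line_recovered(self):
        instruments = [
            _inst(snp=f"r{j}", gamma=g, Gamma=0.01 + 0.5 * g, se_Gamma=0.02)
            for j, g in enumerate([0.02, 0.04, 0.06, 0.08])
        ]
        intercept, slope = egger(instruments)
        assert intercept.beta == pytest.approx(0.01, abs=1e-12)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(23)
        instruments = _random_instruments(rng, 15)
        g = np.array([i.gamma for i in instruments])
        G = np.array([i.Gamma for i in instruments])
        W = np.diag([1 / i.se_Gamma**2 for i in instruments])
        X = np.column_stack([np.ones_like(g), g])
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ G)
        cov = np.linalg.inv(X.T @ W @ X)
        intercept, slope = egger(instruments)
        assert intercept.beta == pytest.approx(coef[0], abs=1e-10)
        assert slope.beta == pytest.approx(coef[1], abs=1e-10)
        assert intercept.se == pytest.approx(math.sqrt(cov[0, 0]), abs=1e-10)
        assert slope.se == pytest.approx(math.sqrt(cov[1, 1]), abs=1e-10)

    def test_zero_intercept_constraint_reproduces_ivw(self):
        rng = np.random.default_rng(29)
        instruments = _random_instruments(rng, 10)
        g = np.array([i.gamma for i in instruments])
        G = np.array([i.Gamma for i in instruments])
        w = np.array([1 / i.se_Gamma**2 for i in instruments])
        constrained_slope = np.sum(w * g * G) / np.sum(w * g * g)
        assert ivw_fixed(instruments).beta == pytest.approx(float(constrained_slope), abs=1e-12)

    def test_negative_gammas_oriented_before_fit(self):
        """Jointly flipping (gamma, Gamma) of some SNPs is a relabeling of
        alleles and must not change the fit."""
        rng = np.random.default_rng(31)
        instruments = _random_instruments(rng, 9)
        flipped = []
        for j, i in enumerate(instruments):
            s = -1.0 if j % 2 else 1.0
            flipped.append(
                _inst(snp=i.snp_id, gamma=s * i.gamma, se_gamma=i.se_gamma,
                      Gamma=s * i.Gamma, se_Gamma=i.se_Gamma)
            )
        a = egger(instruments)
        b = egger(flipped)
        assert a[0].beta == pytest.approx(b[0].beta, abs=1e-12)
        assert a[1].beta == pytest.approx(b[1].beta, abs=1e-12)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(DomainError):
            egger([_inst(), _inst(snp="rs2")])

    def test_zero_gamma_spread_rejected(self):
        instruments = [_inst(snp=f"r{j}", gamma=0.05) for j in range(4)]
        with pytest.raises(DomainError):
            egger(instruments)


def _l1_grid_minimizer(values, weights, step=1e-5):
    """Brute-force minimizer of sum_j w_j |x - b_j| over a fine grid."""
    grid = np.arange(min(values), max(values) + step, step)
    costs = np.abs(grid[:, None] - np.asarray(values)[None, :]) @ np.asarray(weights)
    return float(grid[np.argmin(costs)])


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        ratios = [RatioEstimate(s, v, 1.0) for s, v in zip("abc", (0.1, 0.5, 0.9))]
        assert weighted_median_point(ratios) == pytest.approx(0.5)

    def test_equal_weights_odd_k_equals_plain_median(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            vals = rng.normal(0, 1, 7)
            ratios = [RatioEstimate(f"r{j}", float(v), 1.0) for j, v in enumerate(vals)]
            assert weighted_median_point(ratios) == pytest.approx(float(np.median(vals)), abs=1e-12)

    def test_step_convention_is_weighted_l1_minimizer(self):
        """The non-interpolated weighted median minimizes the weighted
        absolute deviation; checked against a 1e-5 grid search."""
        rng = np.random.default_rng(41)
        for _ in range(5):
            vals = rng.normal(0.5, 0.3, 7)
            ses = rng.uniform(0.05, 0.5, 7)
            ratios = [RatioEstimate(f"r{j}", float(v), float(s)) for j, (v, s) in enumerate(zip(vals, ses))]
            got = weighted_median_point(ratios, interpolate=False)
            want = _l1_grid_minimizer(vals, [r.weight for r in ratios])
            assert got == pytest.approx(want, abs=1e-4)

    def test_interpolated_within_one_gap_of_step_estimate(self):
        rng = np.random.default_rng(43)
        vals = np.sort(rng.normal(0, 1, 9))
        ses = rng.uniform(0.1, 0.5, 9)
        ratios = [RatioEstimate(f"r{j}", float(v), float(s)) for j, (v, s) in enumerate(zip(vals, ses))]
        gap = np.max(np.diff(vals))
        a = weighted_median_point(ratios, interpolate=True)
        b = weighted_median_point(ratios, interpolate=False)
        assert abs(a - b) <= gap + 1e-12

    def test_bootstrap_is_seed_deterministic(self):
        rng = np.random.default_rng(47)
        instruments = _random_instruments(rng, 8)
        a = weighted_median(instruments, n_boot=200, seed=9)
        b = weighted_median(instruments, n_boot=200, seed=9)
        assert a.se == b.se and a.beta == b.beta

    def test_invalid_n_boot_rejected(self):
        with pytest.raises(ConfigError):
            weighted_median([_inst(snp=f"r{j}", gamma=0.01 * (j + 1)) for j in range(3)], n_boot=0)

    def test_reordering_instruments_is_irrelevant(self):
        rng = np.random.default_rng(53)
        instruments = _random_instruments(rng, 8)
        a = weighted_median_point([wald_ratio(i) for i in instruments])
        b = weighted_median_point([wald_ratio(i) for i in reversed(instruments)])
        assert a == pytest.approx(b, abs=1e-14)


class TestPTwoSided:
    def test_null_z(self):
        assert p_two_sided(0.0) == 1.0

    def test_defining_quantile(self):
        assert p_two_sided(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_matches_erfc_oracle(self):
        assert p_two_sided(4.2) == pytest.approx(math.erfc(4.2 / math.sqrt(2)), abs=1e-12)

    def test_never_exactly_zero(self):
        assert p_two_sided(60.0) > 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            p_two_sided(float("nan"))
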