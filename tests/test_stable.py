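"""α-stable density evaluation, fitting, and the resampling protocol."""

import numpy as np
import pytest
from scipy import integrate, stats
from hypothesis import given, settings
from hypothesis import strategies as st

from cellwalk import (
    AlphaStableParams,
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
    StableWalkModel,
    pdf_overlay,
    sample_stable,
    stable_cdf,
    stable_pdf,
)
from cellwalk.stable import empirical_pdf, fit_stable_ecf, ks_distance


def s0_pdf_quadrature(x, alpha, beta, gamma, delta):
    """Independent oracle: direct quadrature of the S0 characteristic-function inversion."""

    def integrand(t):
        w = (gamma * t) ** alpha
        if alpha != 1.0:
            skew = 1j * beta * np.tan(np.pi * alpha / 2.0) * ((gamma * t) ** (1 - alpha) - 1)
        else:
            skew = -1j * beta * (2 / np.pi) * np.log(gamma * t)
        phi = np.exp(-w * (1 + skew) + 1j * delta * t)
        return (phi * np.exp(-1j * t * x)).real

    val, _ = integrate.quad(integrand, 0, np.inf, limit=400)
    return val / np.pi


class TestStablePdf:
    def test_gaussian_limit(self):
        # alpha=2, gamma=1/sqrt(2) is exactly N(0, 1)
        p = AlphaStableParams(2.0, 0.0, 2**-0.5, 0.0)
        assert stable_pdf(0.0, p) == pytest.approx(1.0 / np.sqrt(2 * np.pi), abs=1e-9)
        grid = np.linspace(-5, 5, 101)
        np.testing.assert_allclose(stable_pdf(grid, p), stats.norm.pdf(grid), atol=1e-6)

    def test_cauchy_limit(self):
        p = AlphaStableParams(1.0, 0.0, 1.0, 0.0)
        assert stable_pdf(0.0, p) == pytest.approx(1.0 / np.pi, abs=1e-9)
        grid = np.linspace(-5, 5, 101)
        np.testing.assert_allclose(stable_pdf(grid, p), stats.cauchy.pdf(grid), atol=1e-6)

    def test_skewed_case_against_quadrature_oracle(self):
        p = AlphaStableParams(1.5, 0.5, 1.0, 0.0)
        for x in (-1.0, 0.0, 1.0, 2.5):
            assert stable_pdf(x, p) == pytest.approx(
                s0_pdf_quadrature(x, 1.5, 0.5, 1.0, 0.0), abs=1e-7
            )

    @pytest.mark.parametrize("alpha,beta", [(1.3, 0.0), (1.7, 0.8)])
    def test_unit_integral(self, alpha, beta):
        p = AlphaStableParams(alpha, beta, 0.7, 0.3)
        val, _ = integrate.quad(lambda x: float(stable_pdf(x, p)), -np.inf, np.inf,
                                limit=200)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_symmetry_when_unskewed(self):
        p = AlphaStableParams(1.4, 0.0, 1.2, 0.8)
        x = np.linspace(0.1, 4.0, 9)
        np.testing.assert_allclose(
            stable_pdf(p.delta + x, p), stable_pdf(p.delta - x, p), rtol=1e-7
        )

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ParameterError):
            AlphaStableParams(0.0, 0.0, 1.0, 0.0)
        with pytest.raises(ParameterError):
            AlphaStableParams(2.5, 0.0, 1.0, 0.0)


class TestParameterisations:
    def test_s0_s1_round_trip(self):
        p = AlphaStableParams(1.5, 0.7, 2.0, 3.0, parameterisation="S0")
        back = p.as_s1().as_s0()
        np.testing.assert_allclose(back.astuple(), p.astuple())

    def test_locations_differ_by_skew_shift(self):
        # S1 delta = S0 delta - beta*gamma*tan(pi*alpha/2)
        p = AlphaStableParams(1.5, 1.0, 1.0, 0.0)
        assert p.as_s1().delta == pytest.approx(-np.tan(np.pi * 0.75))


class TestFit:
    def test_recovers_generating_parameters(self):
        true = AlphaStableParams(1.4, 0.0, 0.3, 0.5)
        x = sample_stable(true, 15000, seed=21)
        fit = StableWalkModel(x).fit()
        assert fit.params.alpha == pytest.approx(1.4, abs=0.05)
        assert fit.params.gamma == pytest.approx(0.3, rel=0.05)

    def test_gaussian_sample_hits_stability_boundary(self):
        rng = np.random.default_rng(8)
        fit = StableWalkModel(rng.standard_normal(15000)).fit()
        assert fit.params.alpha >= 1.9

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            StableWalkModel(np.arange(10.0))

    def test_degenerate_sample(self):
        with pytest.raises(DegenerateDataError):
            StableWalkModel(np.ones(1000))

    def test_scale_location_equivariance(self):
        x = sample_stable(AlphaStableParams(1.6, 0.0, 1.0, 0.0), 5000, seed=4)
        base = fit_stable_ecf(x)
        c, d = 3.5, -2.0
        trans = fit_stable_ecf(c * x + d)
        assert trans.alpha == pytest.approx(base.alpha, abs=1e-8)
        assert trans.gamma == pytest.approx(c * base.gamma, rel=1e-8)
        assert trans.delta == pytest.approx(c * base.delta + d, abs=1e-6)

    def test_mass_below_zero_diagnostic(self):
        x = sample_stable(AlphaStableParams(1.5, 0.5, 0.8, 2.6), 8000, seed=2)
        fit = StableWalkModel(np.abs(x)).fit()
        mass = fit.mass_below_zero()
        assert 0.0 <= mass < 0.2

    def test_summary_mentions_both_parameterisations(self):
        x = sample_stable(AlphaStableParams(1.5, 0.0, 1.0, 0.0), 2000, seed=1)
        text = StableWalkModel(x).fit().summary()
        assert "S0" in text and "S1" in text and "alpha" in text


class TestBootstrap:
    def test_protocol_counts_and_reproducibility(self):
        x = sample_stable(AlphaStableParams(1.5, 0.0, 0.5, 1.0), 4000, seed=0)
        fit = StableWalkModel(x).fit()
        b1 = fit.bootstrap(n_subsets=8, subset_size=1000, seed=42)
        b2 = fit.bootstrap(n_subsets=8, subset_size=1000, seed=42)
        assert b1.n_subsets == 8 and b1.subset_size == 1000
        assert b1.mean.astuple() == pytest.approx(b2.mean.astuple())
        assert all(v >= 0 for v in b1.sd.values())

    def test_two_seeds_agree_within_pooled_spread(self):
        x = sample_stable(AlphaStableParams(1.5, 0.0, 0.5, 1.0), 6000, seed=0)
        fit = StableWalkModel(x).fit()
        a = fit.bootstrap(n_subsets=10, subset_size=2000, seed=1)
        b = fit.bootstrap(n_subsets=10, subset_size=2000, seed=2)
        pooled = np.sqrt(np.array(list(a.sd.values())) ** 2
                         + np.array(list(b.sd.values())) ** 2)
        diff = np.abs(np.array(a.mean.astuple()) - np.array(b.mean.astuple()))
        assert np.all(diff <= 3.0 * pooled + 1e-12)

    def test_sd_shrinks_with_subset_size(self):
        x = sample_stable(AlphaStableParams(1.5, 0.0, 0.5, 1.0), 20000, seed=0)
        fit = StableWalkModel(x).fit()
        sds = [
            fit.bootstrap(n_subsets=12, subset_size=m, seed=5).sd["alpha"]
            for m in (500, 2000, 8000)
        ]
        assert sds[0] > sds[1] > sds[2]

    def test_invalid_subset_count(self):
        x = sample_stable(AlphaStableParams(1.5, 0.0, 0.5, 1.0), 2000, seed=0)
        with pytest.raises(ParameterError):
            StableWalkModel(x).fit().bootstrap(n_subsets=1, subset_size=100, seed=0)


class TestPdfOverlay:
    def test_empirical_density_integrates_to_one(self):
        x = sample_stable(AlphaStableParams(1.5, 0.0, 1.0, 0.0), 10000, seed=3)
        centres, density = empirical_pdf(x)
        widths = np.diff(centres).mean()
        assert np.sum(density) * widths == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_fit_overlays_closed_form(self):
        rng = np.random.default_rng(11)
        x = rng.normal(2.0, 1.0, size=15000)
        fit = StableWalkModel(x).fit()
        grid = np.linspace(-2, 6, 101)
        data = pdf_overlay(x, fit, grid)
        assert np.max(np.abs(data["fitted"] - stats.norm.pdf(grid, 2.0, 1.0))) < 0.02

    def test_ks_distance_small_for_matching_law(self):
        true = AlphaStableParams(1.5, 0.0, 1.0, 0.0)
        x = sample_stable(true, 15000, seed=6)
        # critical value of the one-sample KS test at n=15000, alpha=0.01
        crit = 1.628 / np.sqrt(15000)
        assert ks_distance(x, true) < crit

    def test_empty_grid_rejected(self):
        x = sample_stable(AlphaStableParams(1.5, 0.0, 1.0, 0.0), 1000, seed=0)
        fit = StableWalkModel(x).fit()
        with pytest.raises(ParameterError):
            pdf_overlay(x, fit, np.array([]))


class TestSampler:
    def test_deterministic_under_seed(self):
        p = AlphaStableParams(1.5, 0.5, 0.3, 0.5)
        np.testing.assert_array_equal(
            sample_stable(p, 100, seed=9), sample_stable(p, 100, seed=9)
        )

    def test_gaussian_limit_passes_normality(self):
        p = AlphaStableParams(2.0, 0.0, 1.0, 0.5)
        x = sample_stable(p, 10000, seed=13)
        # alpha=2 scale gamma corresponds to N(delta, 2 gamma^2)
        stat = stats.kstest(x, "norm", args=(0.5, np.sqrt(2.0)))
        assert stat.pvalue > 0.01

    def test_quantiles_match_stable_cdf(self):
        p = AlphaStableParams(1.5, 0.0, 1.0, 0.0)
        x = sample_stable(p, 20000, seed=17)
        for q in (0.25, 0.5, 0.75):
            emp = np.quantile(x, q)
            assert stable_cdf(emp, p) == pytest.approx(q, abs=0.01)

    def test_invalid_n(self):
        with pytest.raises(ParameterError):
            sample_stable(AlphaStableParams(1.5, 0.0, 1.0, 0.0), 0, seed=0)

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(alpha=st.floats(1.1, 2.0), beta=st.floats(-1.0, 1.0))
    def test_median_tracks_s0_location(self, alpha, beta):
        # in the continuous parameterisation the sample centre stays near delta
        p = AlphaStableParams(alpha, beta, 1.0, 5.0)
        x = sample_stable(p, 4000, seed=31)
        assert abs(np.median(x) - 5.0) < 1.5
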