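"""Score-moment machinery: selection bounds, truncated moments, estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from prspower import (
    PolygenicModel,
    StudyDesign,
    binary_trait,
    r2,
    score_moments,
    score_moments_allele_count,
    score_moments_linear,
    score_moments_shrinkage,
    selection_bounds,
    truncated_second_moment,
)
from prspower.metrics import mse
from prspower.moments import shrinkage_factor


class TestSelectionBounds:
    def test_no_selection_window(self):
        c0, c1 = selection_bounds(0.0, 1.0, 12345)
        assert c0 == 0.0 and math.isinf(c1)

    def test_standard_threshold(self):
        c0, c1 = selection_bounds(0.0, 0.05, 10000, 0.01)
        assert c0 == pytest.approx(0.019600, abs=5e-7)
        assert math.isinf(c1)

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            selection_bounds(0.5, 0.5, 100)
        with pytest.raises(ValueError):
            selection_bounds(0.0, 1.0, -5)

    def test_null_selection_fraction_matches_window(self, rng):
        """Fraction of simulated null estimates inside the bounds is q1 - q0."""
        n1, q0, q1 = 4000, 0.01, 0.2
        se = 1.0 / math.sqrt(n1)
        c0, c1 = selection_bounds(q0, q1, n1)
        draws = rng.normal(0.0, se, size=100_000)
        frac = np.mean((np.abs(draws) >= c0) & (np.abs(draws) <= c1))
        expect = q1 - q0
        tol = 3.0 * math.sqrt(expect * (1 - expect) / draws.size)
        assert abs(frac - expect) < tol


class TestTruncatedSecondMoment:
    def test_untruncated(self):
        assert truncated_second_moment(0.0, math.inf) == 1.0

    @pytest.mark.parametrize("a,b", [(1.0, 2.0), (0.5, math.inf), (0.0, 0.3),
                                     (2.0, 4.0), (0.01, 0.02)])
    def test_matches_quadrature(self, a, b):
        hi = b if not math.isinf(b) else 12.0
        num, _ = quad(lambda z: z * z * norm.pdf(z), a, hi, epsabs=1e-13)
        den, _ = quad(norm.pdf, a, hi, epsabs=1e-13)
        assert truncated_second_moment(a, b) == pytest.approx(num / den, abs=1e-10)

    def test_tail_truncation_inflates(self):
        assert truncated_second_moment(2.0) > truncated_second_moment(1.0) > 1.0

    def test_rejects_bad_interval(self):
        with pytest.raises(ValueError):
            truncated_second_moment(2.0, 1.0)
        with pytest.raises(ValueError):
            truncated_second_moment(-0.5, 1.0)


class TestLinearMoments:
    def test_full_window_closed_form(self):
        """With every marker included: varS = vg + m*varY1/n1, covSy = rho*sqrt(vg1 vg2)."""
        model = PolygenicModel(m=5000, vg1=0.3, vg2=0.2, rho12=0.4, pi0=0.6)
        design = StudyDesign(n1=1500, n2=1000)
        mom = score_moments_linear(model, design)
        assert mom.varS == pytest.approx(0.3 + 5000 / 1500, rel=1e-12)
        assert mom.covSy == pytest.approx(0.4 * math.sqrt(0.3 * 0.2), rel=1e-12)

    def test_full_window_invariant_to_pi0(self):
        design = StudyDesign(n1=2000, n2=2000)
        base = score_moments_linear(PolygenicModel(m=10000, vg1=0.3), design)
        for pi0 in (0.5, 0.9, 0.99):
            mom = score_moments_linear(PolygenicModel(m=10000, vg1=0.3, pi0=pi0), design)
            assert mom.varS == pytest.approx(base.varS, rel=1e-12)
            assert mom.covSy == pytest.approx(base.covSy, rel=1e-12)

    def test_zero_cross_trait_correlation_zeroes_covariance(self):
        model = PolygenicModel(m=1000, vg1=0.5, vg2=0.5, rho12=0.0)
        for est in ("linear", "shrinkage", "allele_count"):
            design = StudyDesign(n1=500, n2=500, q0=0.0, q1=0.2, estimator=est)
            assert score_moments(model, design).covSy == 0.0

    @pytest.mark.parametrize("vg,n1,m", [(0.1, 1000, 50000), (0.5, 3000, 10000),
                                         (0.8, 500, 100000), (0.287, 2000, 74062)])
    def test_daetwyler_limit(self, vg, n1, m):
        """Same trait, full panel, no nulls: R^2 = vg^2 / (vg + m/n1)."""
        model = PolygenicModel(m=m, vg1=vg)
        mom = score_moments_linear(model, StudyDesign(n1=n1, n2=1000))
        assert r2(mom) == pytest.approx(vg * vg / (vg + m / n1), abs=1e-10)

    def test_daetwyler_limit_dense_grid(self):
        for vg in np.linspace(0.05, 0.95, 10):
            for ratio in np.geomspace(0.01, 10.0, 10):
                m = 20000
                n1 = m * ratio
                mom = score_moments_linear(PolygenicModel(m=m, vg1=vg),
                                           StudyDesign(n1=n1, n2=100))
                assert r2(mom) == pytest.approx(vg * vg / (vg + 1 / ratio), abs=1e-10)

    def test_varS_decreasing_in_n1_toward_limit(self):
        model = PolygenicModel(m=10000, vg1=0.4, pi0=0.9)
        design = StudyDesign(n1=100, n2=100, q0=0.0, q1=1.0)
        sizes = [500, 2000, 10000, 100000]
        vals = [score_moments_linear(model, design.with_(n1=n)).varS for n in sizes]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        inf_mom = score_moments_linear(model, design.with_(n1=math.inf))
        assert vals[-1] > inf_mom.varS == pytest.approx(0.4, rel=1e-12)

    def test_covSy_nondecreasing_in_n1_full_window(self):
        model = PolygenicModel(m=10000, vg1=0.4, vg2=0.3, rho12=0.5, pi0=0.5)
        design = StudyDesign(n1=100, n2=100, q0=0.0, q1=0.05)
        vals = [score_moments_linear(model, design.with_(n1=n)).covSy
                for n in (500, 2000, 10000, 100000)]
        assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_binary_moments_are_linear_transforms_of_quantitative(self):
        """Applying the observed-scale transform marker-wise or to the
        aggregated moments gives the same answer: the binary-trait moments
        are an exact rescaling of the quantitative ones once the sampling
        variance is matched."""
        from prspower.liability import analysis_scale
        m, n1, vg1, vg2, rho = 8000, 3000, 0.35, 0.25, 0.6
        t1 = binary_trait(0.05, P=0.4)
        t2 = binary_trait(0.1, P=0.3)
        model = PolygenicModel(m=m, vg1=vg1, vg2=vg2, rho12=rho)
        design_b = StudyDesign(n1=n1, n2=1000, trait1=t1, trait2=t2)
        f1, varY1 = analysis_scale(t1)
        f2, varY2 = analysis_scale(t2)
        mom_b = score_moments_linear(model, design_b)
        # quantitative design with the same effective sampling variance
        design_q = StudyDesign(n1=n1 / varY1, n2=1000)
        mom_q = score_moments_linear(model, design_q)
        assert mom_b.covSy == pytest.approx(f1 * f2 * mom_q.covSy, rel=1e-12)
        noise_b = m * varY1 / n1
        noise_q = m / (n1 / varY1)
        assert mom_b.varS - noise_b == pytest.approx(
            f1 * f1 * (mom_q.varS - noise_q), rel=1e-10)


class TestShrinkage:
    def test_factor_tends_to_one(self):
        model = PolygenicModel(m=1000, vg1=0.5)
        d = StudyDesign(n1=10, n2=10)
        assert shrinkage_factor(model, d.with_(n1=1e9)) == pytest.approx(1.0, abs=1e-3)
        assert shrinkage_factor(model, d.with_(n1=math.inf)) == 1.0

    def test_moments_converge_to_linear(self):
        model = PolygenicModel(m=1000, vg1=0.5, pi0=0.5)
        d = StudyDesign(n1=1e8, n2=100, q0=0.0, q1=0.3)
        lin = score_moments_linear(model, d)
        shr = score_moments_shrinkage(model, d)
        assert shr.varS == pytest.approx(lin.varS, rel=1e-4)
        assert shr.covSy == pytest.approx(lin.covSy, rel=1e-5)

    def test_same_r2_as_linear_everywhere(self):
        grid = [(m, vg, pi0, q1, n1)
                for m in (2000, 50000) for vg in (0.1, 0.6)
                for pi0 in (0.0, 0.9) for q1 in (0.01, 1.0) for n1 in (500, 5000)]
        for m, vg, pi0, q1, n1 in grid:
            model = PolygenicModel(m=m, vg1=vg, vg2=vg, rho12=0.8, pi0=pi0)
            d = StudyDesign(n1=n1, n2=1000, q0=0.0, q1=q1)
            assert r2(score_moments_shrinkage(model, d)) == pytest.approx(
                r2(score_moments_linear(model, d)), abs=1e-12)

    def test_mse_never_worse_than_linear(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = int(rng.integers(1000, 100000))
            vg = float(rng.uniform(0.05, 0.95))
            pi0 = float(rng.uniform(0.0, 0.95))
            q1 = float(rng.uniform(0.001, 1.0))
            n1 = int(rng.integers(200, 20000))
            model = PolygenicModel(m=m, vg1=vg, vg2=vg, rho12=1.0, pi0=pi0)
            d = StudyDesign(n1=n1, n2=1000, q0=0.0, q1=q1)
            assert mse(score_moments_shrinkage(model, d)) <= mse(
                score_moments_linear(model, d)) + 1e-12


class TestAlleleCount:
    def test_covariance_matches_monte_carlo(self, rng):
        """Quadrature for the sign-agreement covariance integral against a
        10^6-draw Monte-Carlo evaluation of the same expectation."""
        m, n1 = 5000, 2000
        model = PolygenicModel(m=m, vg1=0.4, vg2=0.3, rho12=0.65, pi0=0.8)
        design = StudyDesign(n1=n1, n2=1000, q0=0.0, q1=0.1, estimator="allele_count")
        mom = score_moments_allele_count(model, design)

        s1 = math.sqrt(model.sigma1_sq)
        s12 = model.sigma12
        se = 1.0 / math.sqrt(n1)
        c0, c1 = selection_bounds(design.q0, design.q1, n1)
        ndraw = 1_000_000
        beta = rng.normal(0.0, s1, ndraw)
        bhat = beta + rng.normal(0.0, se, ndraw)
        sel = np.abs(bhat) >= c0 if math.isinf(c1) else (
            (np.abs(bhat) >= c0) & (np.abs(bhat) <= c1))
        beta2 = (s12 / s1**2) * beta  # conditional mean of the trait-2 effect
        contrib = np.where(sel, np.sign(bhat) * beta2, 0.0)
        mc = s1 * m * (1 - model.pi0) * contrib.mean()
        mc_se = s1 * m * (1 - model.pi0) * contrib.std(ddof=1) / math.sqrt(ndraw)
        assert abs(mom.covSy - mc) < 3.0 * mc_se

    def test_association_weaker_than_linear_for_strong_polygenic_design(self, cc_design):
        """For the large schizophrenia-style configuration, the unweighted
        score is less strongly associated at every threshold."""
        model = PolygenicModel(m=74062, vg1=0.287, pi0=0.5)
        for q1 in (0.001, 0.01, 0.1, 0.5, 1.0):
            d_lin = cc_design.with_(q1=q1)
            d_ac = cc_design.with_(q1=q1, estimator="allele_count")
            assert r2(score_moments(model, d_ac)) < r2(score_moments(model, d_lin))

    def test_infinite_sample_limit(self):
        model = PolygenicModel(m=1000, vg1=0.5, vg2=0.5, rho12=1.0)
        d = StudyDesign(n1=math.inf, n2=100, estimator="allele_count")
        mom = score_moments_allele_count(model, d)
        s1 = math.sqrt(model.sigma1_sq)
        assert mom.varS == pytest.approx(0.5, rel=1e-12)
        assert mom.covSy == pytest.approx(1000 * s1 * s1 * math.sqrt(2 / math.pi), rel=1e-12)
        # perfect-information sign agreement still loses information: r2 < vg
        assert r2(mom) == pytest.approx(0.5 * 2 / math.pi, rel=1e-12)


@settings(max_examples=60, deadline=None)
@given(
    m=st.integers(100, 200000),
    vg1=st.floats(0.0, 1.0),
    vg2=st.floats(0.0, 1.0),
    rho=st.floats(-1.0, 1.0),
    pi0=st.floats(0.0, 0.99),
    n1=st.integers(10, 100000),
    q=st.tuples(st.floats(0.0, 1.0), st.floats(0.0, 1.0)).filter(lambda t: t[0] < t[1]),
    estimator=st.sampled_from(["linear", "shrinkage", "allele_count"]),
)
def test_cauchy_schwarz_everywhere(m, vg1, vg2, rho, pi0, n1, q, estimator):
    """Every ScoreMoments satisfies covSy^2 <= varS * varY2 (checked in the
    ScoreMoments constructor, so constructing is the assertion)."""
    model = PolygenicModel(m=m, vg1=vg1, vg2=vg2, rho12=rho, pi0=pi0)
    design = StudyDesign(n1=n1, n2=100, q0=q[0], q1=q[1], estimator=estimator)
    mom = score_moments(model, design)
    assert mom.covSy**2 <= mom.varS * mom.varY2 * (1 + 1e-9)
    if rho == 0:
        assert mom.covSy == 0.0
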