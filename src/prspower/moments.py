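"""First two moments of the estimated polygenic score.

Markers are tested one at a time in the training sample; the estimated
coefficient of marker ``j`` is asymptotically normal around its true effect
with sampling variance ``varY1 / n1`` (the residual variance is
conservatively taken as the full trait variance, effects being small).
Selecting markers whose two-sided P-value falls in ``(q0, q1]`` is
equivalent to selecting on ``|beta_hat|`` between two bounds obtained from
the Wald statistic, so the score's variance mixes truncated-normal second
moments of the null and non-null coefficient distributions, and its
covariance with the tested trait follows from the regression of the
trait-2 effect on the estimated coefficient, which is unchanged by the
selection.

Three estimators are supported: per-marker least squares (``linear``), a
common posterior shrinkage of those estimates (``shrinkage`` — same
correlation-based metrics, smaller mean square error), and a fixed-magnitude
signed score equivalent to counting risk alleles (``allele_count``).
"""

from __future__ import annotations

import math

from scipy.integrate import quad
from scipy.special import ndtr, ndtri

from .liability import analysis_scale
from .model import PolygenicModel, ScoreMoments, StudyDesign

__all__ = [
    "selection_bounds",
    "truncated_second_moment",
    "score_moments",
    "score_moments_linear",
    "score_moments_shrinkage",
    "score_moments_allele_count",
    "shrinkage_factor",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _phi(x: float) -> float:
    return math.exp(-0.5 * x * x) / _SQRT_2PI


def _sf(x: float) -> float:
    """Standard normal upper tail."""
    return float(ndtr(-x))


def selection_bounds(q0: float, q1: float, n1: float,
                     standard_error: float | None = None) -> tuple[float, float]:
    """Bounds on |beta_hat| equivalent to a two-sided P-value in ``(q0, q1]``.

    ``standard_error`` is the standard error of the estimated coefficient
    used in the Wald statistic (``sqrt(varY1/n1)``; defaults to
    ``1/sqrt(n1)`` for a standardised trait).  Returns ``(c0, c1)`` with
    ``c0`` the bound for ``q1`` (more significant P-values need larger
    |beta_hat|) and ``c1`` for ``q0``; ``q1 = 1`` gives ``c0 = 0`` and
    ``q0 = 0`` gives ``c1 = inf``.
    """
    if not 0.0 <= q0 < q1 <= 1.0:
        raise ValueError(f"need 0 <= q0 < q1 <= 1, got q0={q0}, q1={q1}")
    if not n1 > 0:
        raise ValueError(f"n1 must be positive, got {n1}")
    if standard_error is None:
        standard_error = 1.0 / math.sqrt(n1)
    if standard_error <= 0:
        raise ValueError("standard error must be positive")
    c0 = 0.0 if q1 >= 1.0 else float(-ndtri(q1 / 2.0)) * standard_error
    c1 = math.inf if q0 <= 0.0 else float(-ndtri(q0 / 2.0)) * standard_error
    return c0, c1


def truncated_second_moment(a: float, b: float = math.inf) -> float:
    """``E[Z^2 | a <= |Z| <= b]`` for standard normal ``Z``.

    Closed form from integrating ``z^2 phi(z)`` by parts:
    ``int_a^b z^2 phi(z) dz = Phi(b) - Phi(a) + a phi(a) - b phi(b)``.
    Equals 1 for the untruncated case and grows as the retained region moves
    into the tails.
    """
    if a < 0:
        raise ValueError(f"a must be >= 0, got {a}")
    if not a < b:
        raise ValueError(f"need a < b, got a={a}, b={b}")
    if a == 0.0 and math.isinf(b):
        return 1.0
    if math.isinf(b):
        p = _sf(a)
        num = p + a * _phi(a)
    else:
        p = float(ndtr(b)) - float(ndtr(a))
        num = p + a * _phi(a) - b * _phi(b)
    if p <= 0.0:
        # window entirely beyond numerical support; limit E[Z^2 | |Z|=a] = a^2
        return a * a
    return num / p


def _scales(model: PolygenicModel, design: StudyDesign):
    """Per-marker effect moments and sampling variance on the analysis scale."""
    f1, varY1 = analysis_scale(design.trait1)
    f2, varY2 = analysis_scale(design.trait2)
    s1_sq = f1 * f1 * model.sigma1_sq
    s12 = f1 * f2 * model.sigma12
    v = 0.0 if math.isinf(design.n1) else varY1 / design.n1
    return s1_sq, s12, v, varY2


def _selection(model: PolygenicModel, design: StudyDesign, s1_sq: float, v: float):
    """Selection probabilities and truncated second-moment factors.

    Returns (p_null, t_null, p_nonnull, t_nonnull, marginal variance of the
    non-null estimate).
    """
    se = math.sqrt(v)
    c0, c1 = selection_bounds(design.q0, design.q1, design.n1, se)
    s_sq = s1_sq + v
    s = math.sqrt(s_sq)
    p_null = design.q1 - design.q0
    t_null = truncated_second_moment(c0 / se if se > 0 else 0.0,
                                     c1 / se if se > 0 and not math.isinf(c1) else math.inf)
    a, b = c0 / s, c1 / s
    if math.isinf(b):
        p_nn = 2.0 * _sf(a)
    else:
        p_nn = 2.0 * (float(ndtr(b)) - float(ndtr(a)))
    t_nn = truncated_second_moment(a, b)
    return p_null, t_null, p_nn, t_nn, s_sq


def _moments_infinite_n1(model: PolygenicModel, design: StudyDesign,
                         s1_sq: float, s12: float, varY2: float,
                         allele_count: bool) -> ScoreMoments:
    # Without sampling error the estimate equals the true effect: non-null
    # markers have P-value -> 0 (selected iff q0 = 0), null markers have
    # beta_hat = 0 and contribute nothing to the moments either way.
    m1 = model.m * (1.0 - model.pi0)
    if design.q0 > 0.0:
        return ScoreMoments(0.0, 0.0, varY2)
    if allele_count:
        c = math.sqrt(s1_sq)
        varS = c * c * m1
        # sign always agrees with the true effect; E|beta| = s1 * sqrt(2/pi)
        covSy = c * m1 * (s12 / s1_sq) * math.sqrt(s1_sq) * math.sqrt(2.0 / math.pi)
    else:
        varS = m1 * s1_sq
        covSy = m1 * s12
    return ScoreMoments(varS, covSy, varY2)


def score_moments_linear(model: PolygenicModel, design: StudyDesign) -> ScoreMoments:
    """Score moments for the per-marker least-squares estimator."""
    s1_sq, s12, v, varY2 = _scales(model, design)
    if math.isinf(design.n1):
        return _moments_infinite_n1(model, design, s1_sq, s12, varY2, False)
    p_null, t_null, p_nn, t_nn, s_sq = _selection(model, design, s1_sq, v)
    m0 = model.m * model.pi0
    m1 = model.m * (1.0 - model.pi0)
    varS = m0 * p_null * v * t_null + m1 * p_nn * s_sq * t_nn
    # regression of the trait-2 effect on the estimate has slope s12 / s_sq
    # regardless of the selection; times E[beta_hat^2 | selected]
    covSy = m1 * p_nn * s12 * t_nn
    return ScoreMoments(varS, covSy, varY2)


def shrinkage_factor(model: PolygenicModel, design: StudyDesign) -> float:
    """Common posterior shrinkage multiplier sigma^2 / (sigma^2 + varY1/n1).

    The prior for a marker effect is a single normal with the non-null
    per-marker variance; with normal sampling error the posterior mean
    shrinks every estimate by the same factor.
    """
    s1_sq, _, v, _ = _scales(model, design)
    if math.isinf(design.n1):
        return 1.0
    return s1_sq / (s1_sq + v)


def score_moments_shrinkage(model: PolygenicModel, design: StudyDesign) -> ScoreMoments:
    """Score moments for the common-factor shrinkage estimator.

    All coefficients shrink by the same factor, so the score is a rescaled
    version of the least-squares score: correlation, non-centrality, power
    and AUC are unchanged; only the mean square error improves.
    """
    nu = shrinkage_factor(model, design)
    base = score_moments_linear(model, design)
    return ScoreMoments(nu * nu * base.varS, nu * base.covSy, base.varY2)


def score_moments_allele_count(model: PolygenicModel, design: StudyDesign,
                               quad_tol: float = 1e-10) -> ScoreMoments:
    """Score moments for the fixed-magnitude signed (allele-count) estimator.

    Every selected marker contributes the same magnitude ``c`` with the sign
    of its estimated coefficient.  ``c`` is set to the non-null per-marker
    effect standard deviation on the analysis scale; every correlation-based
    metric is invariant to this choice (mean square error is not, and is not
    defined for this estimator).  The covariance requires a one-dimensional
    integral over the non-null effect distribution of the probability that
    the estimated sign agrees (minus disagrees) with selection, times the
    conditional mean of the trait-2 effect; evaluated by adaptive quadrature.
    """
    s1_sq, s12, v, varY2 = _scales(model, design)
    if math.isinf(design.n1):
        return _moments_infinite_n1(model, design, s1_sq, s12, varY2, True)
    p_null, _, p_nn, _, _ = _selection(model, design, s1_sq, v)
    m0 = model.m * model.pi0
    m1 = model.m * (1.0 - model.pi0)
    c = math.sqrt(s1_sq)
    varS = c * c * (m0 * p_null + m1 * p_nn)

    if s12 == 0.0 or s1_sq == 0.0:
        return ScoreMoments(varS, 0.0, varY2)

    se = math.sqrt(v)
    c0, c1 = selection_bounds(design.q0, design.q1, design.n1, se)
    s1 = math.sqrt(s1_sq)
    slope = s12 / s1_sq  # E[beta2 | beta1] = slope * beta1

    def integrand(zb: float) -> float:
        b = zb * s1  # true trait-1 effect on the analysis scale
        hi = c1 if not math.isinf(c1) else None
        # P(beta_hat in [c0, c1] | b) minus P(beta_hat in [-c1, -c0] | b)
        pos = (float(ndtr((hi - b) / se)) if hi is not None else 1.0) - float(ndtr((c0 - b) / se))
        neg = float(ndtr((-c0 - b) / se)) - (float(ndtr((-hi - b) / se)) if hi is not None else 0.0)
        return _phi(zb) * (pos - neg) * slope * b

    # integrand is even in zb; mass beyond 8 marginal SDs is < 1e-15
    val, err = quad(integrand, 0.0, 8.0, epsabs=quad_tol, epsrel=1e-10, limit=200)
    if err > max(100 * quad_tol, 1e-6 * abs(val)):
        raise ArithmeticError(
            f"allele-count covariance quadrature achieved tolerance {err:.2e} only")
    covSy = c * m1 * 2.0 * val
    return ScoreMoments(varS, covSy, varY2)


def score_moments(model: PolygenicModel, design: StudyDesign) -> ScoreMoments:
    """Dispatch on the design's estimator."""
    if design.estimator == "linear":
        return score_moments_linear(model, design)
    if design.estimator == "shrinkage":
        return score_moments_shrinkage(model, design)
    return score_moments_allele_count(model, design)
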