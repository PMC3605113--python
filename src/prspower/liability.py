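"""Liability-threshold machinery for binary traits.

A binary trait arises when a standard-normal liability exceeds the threshold
``T = Phi^-1(1 - K)`` set by the population prevalence ``K``.  Marker effects
act on liability; for small effects there is a linear map between an effect
on liability and the corresponding regression coefficient on the observed
0/1 trait.  In a prospective (cohort) sample the factor is ``z``, the normal
density at the threshold.  Under case/control ascertainment with case
fraction ``P`` the factor becomes ``z * P(1-P) / (K(1-K))``, assuming the
genotype variance stays near 1 in the ascertained sample; the two factors
coincide when ``P = K``.

This module also provides the AUC of a normally distributed score (driven by
the liability-scale variance it explains), the observed/liability R^2
transform, the classical sibling-recurrence-risk conversion to heritability
of liability, and the log-risk alternative model for rare diseases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.special import ndtr, ndtri

from .model import PolygenicModel, StudyDesign, TraitSpec

__all__ = [
    "LiabilityContext",
    "liability_threshold",
    "observed_scale_factor",
    "liability_to_observed",
    "observed_to_liability",
    "analysis_scale",
    "liability_r2",
    "liability_r2_to_observed",
    "auc_from_liability_r2",
    "auc",
    "h2_liability_from_sibling_rr",
    "logrisk_variance_from_sibling_rr",
    "logrisk_auc",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _phi(x: float) -> float:
    return math.exp(-0.5 * x * x) / _SQRT_2PI


def liability_threshold(K: float) -> tuple[float, float]:
    """Threshold ``T`` and normal density ``z`` at the threshold for prevalence ``K``."""
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence must be in (0,1), got {K}")
    T = -ndtri(K)  # upper-K quantile
    return T, _phi(T)


@dataclass(frozen=True)
class LiabilityContext:
    """Prevalence, sampling fraction and derived threshold quantities."""

    K: float
    P: float | None = None
    ascertained: bool = False
    T: float = None  # type: ignore[assignment]
    z: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        T, z = liability_threshold(self.K)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "z", z)
        if self.P is None:
            object.__setattr__(self, "P", self.K)
        if not 0.0 < self.P < 1.0:
            raise ValueError(f"case fraction must be in (0,1), got {self.P}")
        if not self.ascertained and not math.isclose(self.P, self.K, rel_tol=1e-12):
            raise ValueError("P must equal K unless the sample is ascertained")

    @classmethod
    def from_trait(cls, trait: TraitSpec) -> "LiabilityContext":
        if not trait.is_binary:
            raise ValueError("LiabilityContext requires a binary trait")
        return cls(K=trait.K, P=trait.P, ascertained=trait.ascertained)


def observed_scale_factor(ctx: LiabilityContext) -> float:
    """Multiplier taking a liability-scale effect to the observed 0/1 scale."""
    if ctx.ascertained:
        return ctx.z * ctx.P * (1.0 - ctx.P) / (ctx.K * (1.0 - ctx.K))
    return ctx.z


def liability_to_observed(effect: float, ctx: LiabilityContext) -> float:
    """Rescale a liability-scale regression coefficient to the observed trait."""
    return effect * observed_scale_factor(ctx)


def observed_to_liability(effect: float, ctx: LiabilityContext) -> float:
    return effect / observed_scale_factor(ctx)


def analysis_scale(trait: TraitSpec) -> tuple[float, float]:
    """(effect scale factor, trait variance) on the scale the data are analysed on.

    Quantitative traits are standardised: ``(1, 1)``.  Binary traits are
    analysed as 0/1 responses in linear regression: effects on liability are
    multiplied by the observed-scale factor and the trait variance is the
    binomial ``P(1-P)``.
    """
    if not trait.is_binary:
        return 1.0, 1.0
    ctx = LiabilityContext.from_trait(trait)
    return observed_scale_factor(ctx), trait.P * (1.0 - trait.P)


def liability_r2(r2_obs: float, ctx: LiabilityContext) -> float:
    """Observed-scale R^2 of the score on a 0/1 trait, moved to the liability scale.

    The genetic effects are rescaled through the inverse observed-scale
    factor and the binomial trait variance replaced with the unit liability
    variance; by construction the result is invariant to the case sampling
    fraction.  Values outside [0, 1] (possible since the transform is a
    small-effect approximation) are reported with a warning, not clipped.
    """
    f = observed_scale_factor(ctx)
    out = r2_obs * ctx.P * (1.0 - ctx.P) / (f * f)
    if out > 1.0:
        warnings.warn(
            f"liability-scale R^2 = {out:.4g} exceeds 1; the linear liability "
            "transform is outside its small-effect regime", stacklevel=2)
    return out


def liability_r2_to_observed(r2_liab: float, ctx: LiabilityContext) -> float:
    f = observed_scale_factor(ctx)
    return r2_liab * f * f / (ctx.P * (1.0 - ctx.P))


def auc_from_liability_r2(r2_liab: float, K: float) -> float:
    """AUC of a normal score explaining ``r2_liab`` of the liability variance.

    The score and liability are jointly normal, so the case and control
    conditional means and variances follow from truncated-normal selection
    moments: with ``i = z/K`` (mean liability of cases) and ``i2 = z/(1-K)``,

        AUC = Phi( (i + i2) r / sqrt(2 - r^2 [i(i - T) + i2(i2 + T)]) ),

    where ``r = sqrt(r2_liab)``.  AUC is invariant to linear rescaling of the
    score and to case/control sampling, so a single formula serves both
    prospective and ascertained designs once ``r2_liab`` is in hand.
    """
    if r2_liab <= 0:
        return 0.5
    T, z = liability_threshold(K)
    i = z / K
    i2 = z / (1.0 - K)
    r = math.sqrt(min(r2_liab, 1.0))
    denom = 2.0 - r * r * (i * (i - T) + i2 * (i2 + T))
    return float(ndtr((i + i2) * r / math.sqrt(denom)))


def auc(model: PolygenicModel, design: StudyDesign) -> float:
    """Expected AUC of the estimated score for a binary tested trait."""
    if not design.trait2.is_binary:
        raise ValueError("AUC requires a binary tested trait")
    from .metrics import r2 as _r2
    from .moments import score_moments

    mom = score_moments(model, design)
    ctx = LiabilityContext.from_trait(design.trait2)
    return auc_from_liability_r2(liability_r2(_r2(mom), ctx), design.trait2.K)


def h2_liability_from_sibling_rr(K: float, lambda_s: float) -> float:
    """Heritability of liability implied by prevalence and sibling relative risk.

    Classical threshold-model conversion (Falconer, with the Reich et al.
    curvature correction): the sibling liability correlation ``a = h2/2``
    satisfies

        a = [T - T_R sqrt(1 - (T^2 - T_R^2)(1 - T/i))] / [i + T_R^2 (i - T)]

    with ``T_R`` the threshold at the sibling recurrence risk ``lambda_s*K``
    and ``i = z/K``.  An approximation, but it agrees with the exact
    bivariate-normal solution to ~1e-4 at common-disease prevalences.
    """
    if lambda_s < 1.0:
        raise ValueError(f"sibling relative risk must be >= 1, got {lambda_s}")
    if lambda_s * K >= 1.0:
        raise ValueError("lambda_s * K must be < 1")
    if lambda_s == 1.0:
        return 0.0
    T, z = liability_threshold(K)
    i = z / K
    TR = -ndtri(lambda_s * K)
    a = (T - TR * math.sqrt(1.0 - (T * T - TR * TR) * (1.0 - T / i))) / (
        i + TR * TR * (i - T))
    return 2.0 * a


def logrisk_variance_from_sibling_rr(lambda_s: float) -> float:
    """Total variance of the normally distributed log risk implied by lambda_s.

    Under the log-risk model (logistic in the rare-disease limit) siblings
    share half the log-risk variance, so ``lambda_s = exp(v/2)``, i.e.
    ``v = 2 log(lambda_s)``.
    """
    if lambda_s < 1.0:
        raise ValueError(f"sibling relative risk must be >= 1, got {lambda_s}")
    return 2.0 * math.log(lambda_s)


def logrisk_auc(score_variance: float) -> float:
    """AUC under the log-risk model for a score with the given variance.

    The score has equal variance in cases and controls and the case-control
    mean difference equals its variance ``v``, so AUC = Phi(sqrt(v/2)).
    """
    if score_variance < 0:
        raise ValueError("score variance must be >= 0")
    if score_variance == 0:
        return 0.5
    return float(ndtr(math.sqrt(score_variance / 2.0)))
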