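"""Accuracy and association metrics derived from score moments.

All metrics are deterministic functions of the architecture and design:
R^2 (squared correlation of score and tested trait), prediction mean square
error, the 1-df non-centrality parameter ``ncp = n2 * R^2`` of the chi-square
association test, its power at a two-tailed level alpha, the expected
-log10 P used to draw threshold curves, and (for binary tested traits) the
liability-scale R^2 and AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import chi2, ncx2

from .liability import LiabilityContext, auc_from_liability_r2, liability_r2
from .model import PolygenicModel, ScoreMoments, StudyDesign
from .moments import score_moments

__all__ = [
    "r2",
    "mse",
    "ncp",
    "power",
    "expected_neglog10p",
    "AccuracyReport",
    "accuracy_report",
]


def r2(moments: ScoreMoments) -> float:
    """Coefficient of determination of the score on the tested trait.

    Not clipped: for binary traits under extreme ascertainment the
    observed-scale approximation can push this above 1, and the downstream
    liability-scale transform needs the raw value.
    """
    if moments.varS == 0.0:
        return 0.0
    return moments.covSy**2 / (moments.varS * moments.varY2)


def mse(moments: ScoreMoments) -> float:
    """Prediction mean square error E[(y2 - S)^2] (score and trait centred)."""
    return moments.varY2 - 2.0 * moments.covSy + moments.varS


def ncp(moments: ScoreMoments, n2: float) -> float:
    """Non-centrality of the 1-df chi-square test of the score in sample 2."""
    if n2 < 1:
        raise ValueError(f"n2 must be >= 1, got {n2}")
    return n2 * r2(moments)


def power(ncp_value: float, alpha: float = 0.05) -> float:
    """Two-tailed power of the association test at level ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if ncp_value < 0:
        raise ValueError("non-centrality must be >= 0")
    crit = chi2.isf(alpha, 1)
    if ncp_value == 0.0:
        return alpha
    return float(ncx2.sf(crit, 1, ncp_value))


def expected_neglog10p(ncp_value: float, statistic: str = "mean") -> float:
    """-log10 P of the association statistic at its expectation.

    The chi-square statistic has mean ``1 + ncp``; its two-sided P-value at
    that point summarises the expected strength of association (used for
    threshold curves).  ``statistic='median'`` evaluates at the exact median
    of the non-central distribution instead.
    """
    if ncp_value < 0:
        raise ValueError("non-centrality must be >= 0")
    if statistic == "mean":
        stat = 1.0 + ncp_value
    elif statistic == "median":
        stat = float(chi2.ppf(0.5, 1)) if ncp_value == 0 else float(
            ncx2.ppf(0.5, 1, ncp_value))
    else:
        raise ValueError("statistic must be 'mean' or 'median'")
    p = float(chi2.sf(stat, 1))
    return -math.log10(p)


@dataclass(frozen=True)
class AccuracyReport:
    """All accuracy/association metrics for one (model, design) pair."""

    r2_obs: float
    ncp: float
    power: float
    exp_neglog10p: float
    mse: float | None = None          # undefined for the allele-count estimator
    r2_liab: float | None = None      # binary tested trait only
    auc: float | None = None          # binary tested trait only


def accuracy_report(model: PolygenicModel, design: StudyDesign) -> AccuracyReport:
    mom = score_moments(model, design)
    r2_obs = r2(mom)
    lam = ncp(mom, design.n2)
    fields = dict(
        r2_obs=r2_obs,
        ncp=lam,
        power=power(lam, design.alpha),
        exp_neglog10p=expected_neglog10p(lam),
    )
    if design.estimator != "allele_count":
        fields["mse"] = mse(mom)
    if design.trait2.is_binary:
        ctx = LiabilityContext.from_trait(design.trait2)
        r2l = liability_r2(r2_obs, ctx)
        fields["r2_liab"] = r2l
        fields["auc"] = auc_from_liability_r2(r2l, design.trait2.K)
    return AccuracyReport(**fields)
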