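"""Estimating one architecture parameter from an observed score association.

The regression coefficient of the tested trait on the score has a normal
sampling distribution whose mean, after scaling by its standard error, is
the square root of the model non-centrality parameter.  Matching the
observed 1-df chi-square statistic ``S`` to the model therefore gives the
point estimate as the solution of ``ncp(theta) = S``, and an approximate
95% confidence interval from ``sqrt(ncp(theta)) = sqrt(S) -/+ 1.96``.
The free parameter may be the explained variance (shared or per trait), the
cross-trait effect correlation, or the null-marker proportion; all other
parameters are held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri
from scipy.stats import chi2

from .metrics import ncp as _ncp
from .model import PolygenicModel, StudyDesign
from .moments import score_moments

__all__ = ["EstimationResult", "estimate_parameter", "chi2_from_pvalue"]

_DOMAINS = {
    "vg": (0.0, 1.0),
    "vg1": (0.0, 1.0),
    "vg2": (0.0, 1.0),
    "rho12": (0.0, 1.0),   # the chi-square is signless: |rho12| is identified
    "pi0": (0.0, 1.0),
}
_EDGE = 1e-9


def chi2_from_pvalue(p: float | None = None, neglog10p: float | None = None) -> float:
    """Two-sided P-value (or its -log10) to the equivalent 1-df chi-square."""
    if (p is None) == (neglog10p is None):
        raise ValueError("give exactly one of p or neglog10p")
    if p is not None:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p must be in (0,1], got {p}")
        neglog10p = -math.log10(p)
    if neglog10p < 0:
        raise ValueError("neglog10p must be >= 0")
    # chi2_1 upper quantile via the normal quantile, stable for tiny P
    z = -ndtri(0.5 * 10.0 ** (-neglog10p)) if neglog10p < 300 else math.sqrt(
        2.0 * (neglog10p * math.log(10.0) - math.log(2.0)))
    return z * z


@dataclass(frozen=True)
class EstimationResult:
    param: str
    estimate: float
    ci_lower: float
    ci_upper: float
    observed_stat: float
    level: float = 0.95
    flags: tuple[str, ...] = field(default_factory=tuple)


def _model_with(model: PolygenicModel, param: str, value: float) -> PolygenicModel:
    if param == "vg":
        return model.with_(vg1=value, vg2=value)
    return model.with_(**{param: value})


def estimate_parameter(
    observed_stat: float | None,
    param: str,
    model: PolygenicModel,
    design: StudyDesign,
    *,
    p_value: float | None = None,
    neglog10p: float | None = None,
    level: float = 0.95,
) -> EstimationResult:
    """Invert the model NCP at an observed chi-square (or P-value).

    ``model`` supplies every fixed parameter; the ``param`` slot is treated
    as free (its value in ``model`` is ignored).  The NCP must be monotone
    in the free parameter over its domain, which is checked numerically; a
    non-monotone profile (e.g. ``pi0`` with the full inclusion window, where
    the NCP does not depend on it) raises a ``ValueError``.
    """
    if param not in _DOMAINS:
        raise ValueError(f"param must be one of {sorted(_DOMAINS)}, got {param!r}")
    if observed_stat is None:
        observed_stat = chi2_from_pvalue(p_value, neglog10p)
    elif p_value is not None or neglog10p is not None:
        raise ValueError("give either observed_stat or a P-value, not both")
    if observed_stat < 0:
        raise ValueError("observed statistic must be >= 0")

    lo, hi = _DOMAINS[param]
    lo += _EDGE
    hi -= _EDGE

    def lam(theta: float) -> float:
        return _ncp(score_moments(_model_with(model, param, theta), design), design.n2)

    grid = np.linspace(lo, hi, 17)
    vals = np.array([lam(t) for t in grid])
    diffs = np.diff(vals)
    scale = max(abs(vals).max(), 1.0)
    if np.all(diffs >= -1e-9 * scale) and vals[-1] > vals[0] + 1e-12 * scale:
        increasing = True
    elif np.all(diffs <= 1e-9 * scale) and vals[0] > vals[-1] + 1e-12 * scale:
        increasing = False
    else:
        raise ValueError(
            f"model NCP is not monotone in {param!r} over [{lo:.3g}, {hi:.3g}]; "
            "the estimating equation has no unique inversion")
    if not increasing:
        grid, vals = grid[::-1], vals[::-1]

    flags: list[str] = []

    def solve(target: float, flag_low: str, flag_high: str) -> float:
        lam_lo, lam_hi = vals[0], vals[-1]
        if target <= lam_lo:
            flags.append(flag_low)
            return grid[0]
        if target >= lam_hi:
            flags.append(flag_high)
            return grid[-1]
        a, b = (lo, hi) if increasing else (hi, lo)
        return float(brentq(lambda t: lam(t) - target, min(a, b), max(a, b),
                            xtol=1e-12, rtol=1e-12))

    estimate = solve(observed_stat, "estimate_at_domain_floor", "estimate_at_domain_ceiling")
    z = -float(ndtri((1.0 - level) / 2.0))
    root = math.sqrt(observed_stat)
    ci_a = solve(max(root - z, 0.0) ** 2, "ci_lower_at_domain_floor", "ci_lower_at_domain_ceiling")
    ci_b = solve((root + z) ** 2, "ci_upper_at_domain_floor", "ci_upper_at_domain_ceiling")
    ci_lower, ci_upper = sorted((ci_a, ci_b))

    def snap(x: float) -> float:
        dom_lo, dom_hi = _DOMAINS[param]
        if abs(x - (dom_lo + _EDGE)) < 2 * _EDGE:
            return dom_lo
        if abs(x - (dom_hi - _EDGE)) < 2 * _EDGE:
            return dom_hi
        return x

    return EstimationResult(
        param=param,
        estimate=snap(estimate),
        ci_lower=snap(ci_lower),
        ci_upper=snap(ci_upper),
        observed_stat=observed_stat,
        level=level,
        flags=tuple(flags),
    )
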