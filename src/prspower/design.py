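"""Inverse design: required sample sizes, optimal split, optimal threshold.

Association power depends on both samples; the accuracy of individual
prediction (correlation, AUC) depends only on the training sample.  The
sample-size solver therefore varies both samples together for the power
objective and the training sample alone for accuracy objectives, after
first checking that the target is reachable in the infinite-sample limit.

The inclusion-threshold maximisation uses a bounded Brent search on the raw
probability scale with an absolute tolerance of ~1.2e-4.  This coarse
tolerance is deliberate: optimal thresholds for strongly non-null
architectures sit in the 1e-5..1e-3 range where the objective is extremely
flat, and resolving the optimum more finely changes reported thresholds and
required sample sizes by amounts far below any practical meaning.  A dense
log-spaced grid with local refinement is available via ``method="grid"``
for callers who want the sharper optimum.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .liability import (
    LiabilityContext,
    auc_from_liability_r2,
    h2_liability_from_sibling_rr,
    liability_r2,
)
from .metrics import expected_neglog10p, ncp as _ncp, power as _power, r2 as _r2
from .model import PolygenicModel, StudyDesign, binary_trait
from .moments import score_moments

__all__ = [
    "optimal_threshold",
    "required_n",
    "optimal_split",
    "reproduce_tables",
    "threshold_curve",
]

# Brent tolerance matching the granularity of reported optimal thresholds
_COARSE_XATOL = float(np.finfo(float).eps ** 0.25)


def _objective_fn(model: PolygenicModel, design: StudyDesign, objective: str) -> Callable[[float], float]:
    """Objective as a function of the upper threshold q1 (q0 from the design)."""
    if objective not in ("ncp", "r2", "auc", "correlation"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective == "auc" and not design.trait2.is_binary:
        raise ValueError("AUC objective requires a binary tested trait")
    ctx = LiabilityContext.from_trait(design.trait2) if design.trait2.is_binary else None

    def fn(q1: float) -> float:
        if not design.q0 < q1 <= 1.0:
            return -math.inf
        mom = score_moments(model, design.with_(q1=q1))
        r2v = _r2(mom)
        if objective == "r2":
            return r2v
        if objective == "correlation":
            return math.sqrt(r2v)
        if objective == "ncp":
            return _ncp(mom, design.n2)
        return auc_from_liability_r2(liability_r2(r2v, ctx), design.trait2.K)

    return fn


def optimal_threshold(
    model: PolygenicModel,
    design: StudyDesign,
    objective: str = "ncp",
    method: str = "brent",
) -> tuple[float, float]:
    """Upper P-value threshold maximising the objective, and its value.

    Returns ``(q1, value)``.  With no null markers and the linear estimator
    the optimum is the full panel, ``q1 = 1``.
    """
    fn = _objective_fn(model, design, objective)
    lo = max(design.q0 + 1e-12, 1e-12)
    if method == "brent":
        res = minimize_scalar(lambda q: -fn(q), bounds=(lo, 1.0), method="bounded",
                              options={"xatol": _COARSE_XATOL})
        q_best, v_best = float(res.x), -float(res.fun)
    elif method == "grid":
        grid = np.geomspace(max(lo, 1e-8), 1.0, 40)
        vals = [fn(q) for q in grid]
        k = int(np.argmax(vals))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(lambda q: -fn(q), bounds=(a, b), method="bounded",
                              options={"xatol": a * 1e-3})
        q_best, v_best = float(res.x), -float(res.fun)
        if vals[k] > v_best:
            q_best, v_best = float(grid[k]), float(vals[k])
    else:
        raise ValueError("method must be 'brent' or 'grid'")
    # the boundary is never interior to a bounded search: check it explicitly
    v_full = fn(1.0)
    if v_full >= v_best:
        q_best, v_best = 1.0, v_full
    return q_best, v_best


def _value_at(model: PolygenicModel, design: StudyDesign, objective: str,
              optimize_threshold: bool, method: str = "brent") -> float:
    if optimize_threshold:
        return optimal_threshold(model, design, objective, method=method)[1]
    return _objective_fn(model, design, objective)(design.q1)


def required_n(
    model: PolygenicModel,
    design_template: StudyDesign,
    objective: str,
    target: float,
    *,
    optimize_threshold: bool = False,
    rounding: int = 1,
    count: str = "subjects",
    alpha: float | None = None,
    max_n: float = 1e12,
) -> tuple[int, float | None]:
    """Smallest sample size reaching the target, in units of ``rounding``.

    ``objective`` is ``"power"`` (varies both samples: n1 = n2 = n),
    ``"auc"`` or ``"correlation"`` (vary the training sample only).
    ``count="cases"`` interprets the returned number as cases (and as many
    controls) per sample for a binary training trait with case fraction P,
    i.e. ``n = count / P``.  Returns ``(n, q1_at_solution)`` where the
    threshold is ``None`` unless ``optimize_threshold`` is set.

    Raises ``ValueError`` if the target exceeds the infinite-training-sample
    maximum, reporting that maximum.
    """
    if objective == "power":
        obj = "ncp"  # power is monotone in the NCP
        alpha = design_template.alpha if alpha is None else alpha
        if not 0 < target < 1:
            raise ValueError(f"target power must be in (0,1), got {target}")
    else:
        obj = objective
    if count not in ("subjects", "cases"):
        raise ValueError("count must be 'subjects' or 'cases'")
    per_subject = 1.0
    if count == "cases":
        if not design_template.trait1.is_binary:
            raise ValueError("count='cases' requires a binary training trait")
        per_subject = design_template.trait1.P

    def design_at(n_units: float) -> StudyDesign:
        n = n_units * rounding / per_subject
        if objective == "power":
            return design_template.with_(n1=n, n2=n)
        return design_template.with_(n1=n)

    def achieved(n_units: float) -> float:
        d = design_at(n_units)
        val = _value_at(model, d, obj, optimize_threshold)
        if objective == "power":
            return _power(val, alpha)
        return val

    # feasibility at the infinite-sample limit (threshold is then irrelevant)
    d_inf = design_template.with_(n1=math.inf, q0=0.0, q1=1.0)
    if objective == "power":
        limit = 1.0
    else:
        limit = _value_at(model, d_inf, obj, False)
        if target > limit:
            raise ValueError(
                f"target {objective} {target:.6g} exceeds the infinite-sample "
                f"maximum {limit:.6g} for this architecture")

    lo_u, hi_u = 0, 1
    while achieved(hi_u) < target:
        lo_u = hi_u
        hi_u *= 2
        if hi_u * rounding > max_n:
            raise ValueError(
                f"target {objective} {target:.6g} not reached by n = {max_n:.3g}")
    while hi_u - lo_u > 1:
        mid = (lo_u + hi_u) // 2
        if achieved(mid) >= target:
            hi_u = mid
        else:
            lo_u = mid
    n_units = hi_u
    q1 = None
    if optimize_threshold:
        q1 = optimal_threshold(model, design_at(n_units), obj)[0]
    return n_units * rounding, q1


def optimal_split(
    total_cases: float,
    total_controls: float,
    model: PolygenicModel,
    design_template: StudyDesign,
    grid_points: int = 41,
) -> tuple[float, pd.DataFrame]:
    """Training fraction maximising the association NCP, with the NCP curve.

    Cases and controls are split with the same fraction, so the case
    proportion is constant across the two samples.  Returns the optimal
    fraction and a DataFrame (fraction, ncp) for symmetry inspection.
    """
    total = total_cases + total_controls

    def ncp_at(f: float) -> float:
        n1 = f * total
        n2 = (1.0 - f) * total
        d = design_template.with_(n1=n1, n2=n2)
        return _ncp(score_moments(model, d), n2)

    res = minimize_scalar(lambda f: -ncp_at(f), bounds=(0.02, 0.98), method="bounded",
                          options={"xatol": 1e-6})
    fracs = np.linspace(0.05, 0.95, grid_points)
    curve = pd.DataFrame({"fraction": fracs, "ncp": [ncp_at(f) for f in fracs]})
    return float(res.x), curve


def threshold_curve(
    model: PolygenicModel,
    design: StudyDesign,
    thresholds: np.ndarray | None = None,
    metric: str = "exp_neglog10p",
) -> pd.DataFrame:
    """Metric as a function of the upper inclusion threshold (figure-style)."""
    if thresholds is None:
        thresholds = np.geomspace(1e-6, 1.0, 61)
    rows = []
    ctx = LiabilityContext.from_trait(design.trait2) if design.trait2.is_binary else None
    for q1 in thresholds:
        if q1 <= design.q0:
            continue
        mom = score_moments(model, design.with_(q1=float(q1)))
        r2v = _r2(mom)
        lam = _ncp(mom, design.n2)
        if metric == "exp_neglog10p":
            val = expected_neglog10p(lam)
        elif metric == "r2":
            val = r2v
        elif metric == "power":
            val = _power(lam, design.alpha)
        elif metric == "auc":
            val = auc_from_liability_r2(liability_r2(r2v, ctx), design.trait2.K)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        rows.append((float(q1), val))
    return pd.DataFrame(rows, columns=["q1", metric])


# ---------------------------------------------------------------------------
# table regeneration

_T45_DISEASES = [
    # (label, h2 of liability, prevalence)
    ("crohns", 0.76, 0.001),
    ("breast_cancer", 0.44, 0.036),
]
_T4_PI0 = (0.99, 0.90, 0.75, 0.0)
_T5_PI0 = (0.999, 0.99, 0.90, 0.75, 0.0)
_REL_TARGETS = (0.90, 0.95, 0.99)

_T2_DISEASES = [
    # Evans-style WTCCC configurations tested at q1 = 0.8
    ("bipolar_disorder", 0.01, 0.69),
    ("coronary_artery_disease", 0.056, 0.72),
    ("crohns_disease", 0.001, 0.76),
    ("hypertension", 0.3, 1.0),
    ("type2_diabetes", 0.03, 0.6),
]

_T3_STUDIES = [
    # label, K, h2, pi0, (n1 cases, n1 controls), (n2 cases, n2 controls), m, q1
    ("schizophrenia", 0.01, 0.8, 0.0, (3322, 3587), (2687, 2656), 74062, 0.5),
    ("multiple_sclerosis", 0.001, 0.5, 0.0, (931, 2431), (876, 2077), 59470, 1.0),
    ("breast_cancer", 0.036, 0.44, 0.0, (1029, 1029), (114, 114), 161702, 1.0),
    ("prostate_cancer", 0.024, 0.44, 0.0, (1025, 1025), (114, 114), 165508, 1.0),
]


def _auc_table(m: int, vg_of_h2: Callable[[float], float], pi0s, label: str) -> pd.DataFrame:
    rows = []
    for disease, h2, K in _T45_DISEASES:
        vg = vg_of_h2(h2)
        model0 = PolygenicModel(m=m, vg1=vg, vg2=vg, rho12=1.0, pi0=0.0)
        trait = binary_trait(K, P=0.5)
        template = StudyDesign(n1=100, n2=100, trait1=trait, trait2=trait)
        max_auc = _value_at(model0, template.with_(n1=math.inf), "auc", False)
        targets = [("0.75", 0.75)] + [
            (f"{rel:.2f}*Max", rel * max_auc) for rel in _REL_TARGETS]
        for tgt_label, tgt in targets:
            for pi0 in pi0s:
                model = model0.with_(pi0=pi0)
                try:
                    n, q1 = required_n(model, template, "auc", tgt,
                                       optimize_threshold=True, rounding=1000,
                                       count="cases")
                    cell_n: float | str = n // 1000
                except ValueError:
                    cell_n, q1 = "unreachable", math.nan
                rows.append({"table": label, "disease": disease, "h2": h2, "K": K,
                             "max_auc": max_auc, "target": tgt_label,
                             "target_value": tgt, "pi0": pi0,
                             "n_cases_1000s": cell_n, "threshold": q1})
    return pd.DataFrame(rows)


def _corr_table() -> pd.DataFrame:
    rows = []
    for h2 in (0.8, 0.4):
        model0 = PolygenicModel(m=1_000_000, vg1=h2, vg2=h2, rho12=1.0, pi0=0.0)
        template = StudyDesign(n1=100, n2=100)
        max_corr = math.sqrt(h2)
        for rel in _REL_TARGETS:
            tgt = rel * max_corr
            for pi0 in (0.999, 0.99, 0.90, 0.75, 0.0):
                model = model0.with_(pi0=pi0)
                n, q1 = required_n(model, template, "correlation", tgt,
                                   optimize_threshold=True, rounding=1000)
                rows.append({"table": "table6", "h2": h2, "max_corr": max_corr,
                             "target": f"{rel:.2f}*Max", "target_value": tgt,
                             "pi0": pi0, "n_subjects_1000s": n // 1000,
                             "threshold": q1})
    return pd.DataFrame(rows)


def _evans_table() -> pd.DataFrame:
    rows = []
    m = 74062
    for disease, K, h2 in _T2_DISEASES:
        trait = binary_trait(K, P=2000 / 3480)
        template = StudyDesign(n1=3480, n2=100, trait1=trait, trait2=trait,
                               q0=0.0, q1=0.8)
        for frac, lbl in ((0.5, "half_h2"), (1.0, "full_h2")):
            vg = frac * h2
            model = PolygenicModel(m=m, vg1=vg, vg2=vg, rho12=1.0, pi0=0.0)
            for est in ("linear", "allele_count"):
                d = template.with_(estimator=est)
                auc_f = _value_at(model, d, "auc", False)
                auc_inf = _value_at(model, d.with_(n1=math.inf, q1=1.0), "auc", False)
                rows.append({"table": "table2", "disease": disease, "K": K, "h2": h2,
                             "panel": lbl, "estimator": est,
                             "auc": auc_f, "auc_infinite_n": auc_inf})
    return pd.DataFrame(rows)


def _liab_r2_table() -> pd.DataFrame:
    from .liability import liability_r2 as _lr2
    rows = []
    for study, K, h2, pi0, (c1, co1), (c2, co2), m, q1 in _T3_STUDIES:
        n1, n2 = c1 + co1, c2 + co2
        t1 = binary_trait(K, P=c1 / n1)
        t2 = binary_trait(K, P=c2 / n2)
        design = StudyDesign(n1=n1, n2=n2, trait1=t1, trait2=t2, q0=0.0, q1=q1)
        ctx = LiabilityContext.from_trait(t2)
        for frac, lbl in ((0.25, "quarter_h2"), (0.5, "half_h2"), (1.0, "full_h2")):
            vg = frac * h2
            model = PolygenicModel(m=m, vg1=vg, vg2=vg, rho12=1.0, pi0=pi0)
            mom = score_moments(model, design)
            r2l = _lr2(_r2(mom), ctx)
            mom_inf = score_moments(model, design.with_(n1=math.inf, q1=1.0))
            r2l_inf = _lr2(_r2(mom_inf), ctx)
            rows.append({"table": "table3", "study": study, "K": K, "h2": h2,
                         "panel": lbl, "r2_liab": r2l, "r2_liab_infinite_n": r2l_inf,
                         "auc": auc_from_liability_r2(r2l, K),
                         "auc_infinite_n": auc_from_liability_r2(r2l_inf, K)})
    return pd.DataFrame(rows)


def reproduce_tables(which: str) -> pd.DataFrame:
    """Regenerate one of the published-style grids.

    ``table4``: cases/controls (1000s, rounded up) for target AUC, panel of
    100,000 markers explaining half the heritability.  ``table5``: the same
    with 1,000,000 markers explaining the full heritability.  ``table6``:
    subjects for a target correlation with a quantitative trait.  ``table2``:
    analytic AUC for WTCCC-style designs.  ``table3``: liability-scale R^2
    for published study designs (restricted to the studies whose sample
    sizes are known here).  The assumed lower threshold is q0 = 0
    throughout.
    """
    if which == "table4":
        return _auc_table(100_000, lambda h2: h2 / 2.0, _T4_PI0, "table4")
    if which == "table5":
        return _auc_table(1_000_000, lambda h2: h2, _T5_PI0, "table5")
    if which == "table6":
        return _corr_table()
    if which == "table2":
        return _evans_table()
    if which == "table3":
        return _liab_r2_table()
    raise ValueError(f"unknown table {which!r}")


def sibling_rr_model(m: int, K: float, lambda_s: float, fraction_explained: float = 1.0,
                     pi0: float = 0.0) -> PolygenicModel:
    """Architecture whose explained variance is a fraction of the heritability
    of liability implied by prevalence and sibling relative risk."""
    h2 = h2_liability_from_sibling_rr(K, lambda_s)
    vg = fraction_explained * h2
    return PolygenicModel(m=m, vg1=vg, vg2=vg, rho12=1.0, pi0=pi0)
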