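"""Domain types: genetic architecture, study design, and score moments.

The model describes a panel of ``m`` independent, standardised markers whose
per-marker effects on two (possibly different) traits are exchangeable random
draws.  A proportion ``pi0`` of markers has no effect on either trait; the
remaining markers have effects with per-marker variances chosen so that the
TOTAL variance explained in trait t equals ``vg_t`` regardless of ``pi0``.
Effects on the two traits are correlated with coefficient ``rho12``.

Binary traits follow a liability-threshold model: a standard-normal liability
with genetic effects acting on it, thresholded at the upper ``K`` quantile.
Case/control sampling (case fraction ``P`` different from prevalence ``K``)
is modelled through a linear rescaling of effects onto the observed 0/1
trait, see :mod:`prspower.liability`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace


__all__ = [
    "PolygenicModel",
    "TraitSpec",
    "StudyDesign",
    "ScoreMoments",
    "quantitative_trait",
    "binary_trait",
]

_ESTIMATORS = ("linear", "shrinkage", "allele_count")


@dataclass(frozen=True)
class PolygenicModel:
    """Genetic architecture of a marker panel.

    Parameters
    ----------
    m:
        Number of independent markers in the panel (an *effective* number:
        mapping a genotyping product with LD onto independent markers is the
        caller's responsibility).
    vg1, vg2:
        Total variance of trait 1 (training) and trait 2 (tested) explained
        by the panel, on the standardised-genotype scale.  For binary traits
        this is variance in liability.  ``vg2`` defaults to ``vg1``.
    rho12:
        Correlation of per-marker effects across the two traits.  ``1`` means
        the same trait (or perfectly shared effects).
    pi0:
        Proportion of markers with zero effect on both traits.
    """

    m: int
    vg1: float
    vg2: float | None = None
    rho12: float = 1.0
    pi0: float = 0.0

    def __post_init__(self) -> None:
        if self.vg2 is None:
            object.__setattr__(self, "vg2", self.vg1)
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        for name in ("vg1", "vg2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.rho12 <= 1.0:
            raise ValueError(f"rho12 must be in [-1, 1], got {self.rho12}")
        if not 0.0 <= self.pi0 < 1.0:
            raise ValueError(f"pi0 must be in [0, 1), got {self.pi0}")

    @property
    def n_causal(self) -> int:
        """Number of markers with effects, round(m * (1 - pi0))."""
        return int(round(self.m * (1.0 - self.pi0)))

    @property
    def sigma1_sq(self) -> float:
        """Per-marker effect variance of non-null markers, trait 1."""
        return self.vg1 / (self.m * (1.0 - self.pi0))

    @property
    def sigma2_sq(self) -> float:
        return self.vg2 / (self.m * (1.0 - self.pi0))

    @property
    def sigma12(self) -> float:
        """Per-marker effect covariance of non-null markers across traits."""
        return self.rho12 * math.sqrt(self.sigma1_sq * self.sigma2_sq)

    def with_(self, **kwargs) -> "PolygenicModel":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TraitSpec:
    """One trait: quantitative, or binary with prevalence and sampling."""

    kind: str = "quantitative"
    K: float | None = None
    P: float | None = None
    ascertained: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "binary"):
            raise ValueError(f"kind must be quantitative|binary, got {self.kind!r}")
        if self.kind == "binary":
            if self.K is None or not 0.0 < self.K < 1.0:
                raise ValueError(f"binary trait requires prevalence K in (0,1), got {self.K}")
            if self.P is None:
                object.__setattr__(self, "P", self.K)
            if not 0.0 < self.P < 1.0:
                raise ValueError(f"case fraction P must be in (0,1), got {self.P}")
            if not self.ascertained and not math.isclose(self.P, self.K, rel_tol=1e-12):
                raise ValueError("prospective sampling requires P == K")
        else:
            if self.K is not None or self.P is not None:
                raise ValueError("K and P are only valid for binary traits")

    @property
    def is_binary(self) -> bool:
        return self.kind == "binary"


def quantitative_trait() -> TraitSpec:
    return TraitSpec()


def binary_trait(K: float, P: float | None = None, ascertained: bool | None = None) -> TraitSpec:
    """Binary trait with prevalence ``K``; ascertained iff ``P`` differs from ``K``."""
    if ascertained is None:
        ascertained = P is not None and not math.isclose(P, K, rel_tol=1e-12)
    return TraitSpec(kind="binary", K=K, P=P if P is not None else K, ascertained=ascertained)


@dataclass(frozen=True)
class StudyDesign:
    """Two-sample layout: training sample 1, replication/testing sample 2.

    ``q0 < q1`` is the P-value window for selecting markers into the score:
    a marker enters iff its two-sided training P-value lies in ``(q0, q1]``.
    ``n1 = math.inf`` is accepted and means the infinite-training-sample
    (no sampling error) limit.
    """

    n1: float
    n2: float
    trait1: TraitSpec = field(default_factory=quantitative_trait)
    trait2: TraitSpec = field(default_factory=quantitative_trait)
    q0: float = 0.0
    q1: float = 1.0
    estimator: str = "linear"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n1", "n2"):
            n = getattr(self, name)
            if not (n >= 1 or math.isinf(n)):
                raise ValueError(f"{name} must be >= 1, got {n}")
        if math.isinf(self.n2):
            raise ValueError("n2 must be finite")
        if not 0.0 <= self.q0 < self.q1 <= 1.0:
            raise ValueError(f"need 0 <= q0 < q1 <= 1, got q0={self.q0}, q1={self.q1}")
        if self.estimator not in _ESTIMATORS:
            raise ValueError(f"estimator must be one of {_ESTIMATORS}, got {self.estimator!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")

    def with_(self, **kwargs) -> "StudyDesign":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ScoreMoments:
    """First two moments of the estimated polygenic score.

    ``varS`` is the variance of the score per replication subject and
    ``covSy`` its covariance with the tested trait, both on the analysis
    scale of trait 2 (standardised for quantitative traits, observed 0/1
    for binary).  ``varY2`` is the trait-2 variance on the same scale.
    """

    varS: float
    covSy: float
    varY2: float

    def __post_init__(self) -> None:
        if self.varS < 0:
            raise ValueError(f"varS must be >= 0, got {self.varS}")
        if self.varY2 <= 0:
            raise ValueError(f"varY2 must be > 0, got {self.varY2}")
        # Cauchy-Schwarz holds exactly for quantitative traits.  For binary
        # traits the observed-scale moments come from a small-effect linear
        # approximation which can break the bound under extreme
        # ascertainment (rare disease, half cases, large explained
        # variance); that regime is reported, not rejected, because the
        # liability-scale quantities derived from it remain valid.
        if self.covSy**2 > self.varS * self.varY2 * (1 + 1e-9):
            warnings.warn(
                "covSy^2 exceeds varS * varY2: observed-scale moments are "
                "outside the small-effect regime", stacklevel=2)
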