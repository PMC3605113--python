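"""Preset designs for published polygenic-score analyses.

These bundles record the sample sizes, marker-panel sizes, prevalences,
inclusion thresholds and observed score-association P-values of the classic
polygenic-score studies that are used as worked examples throughout the
package: the ISC schizophrenia score and its cross-application to WTCCC
bipolar disorder, the IMSGC multiple-sclerosis score, the Machiela et al.
breast/prostate cancer cross-validated scores, and the Simonson et al.
Framingham Risk Score analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .liability import h2_liability_from_sibling_rr
from .model import PolygenicModel, StudyDesign, binary_trait, quantitative_trait

__all__ = [
    "StudyPreset",
    "isc_schizophrenia",
    "isc_to_bipolar",
    "imsgc_multiple_sclerosis",
    "machiela_breast",
    "machiela_prostate",
    "framingham_risk_score",
]


@dataclass(frozen=True)
class StudyPreset:
    name: str
    model: PolygenicModel
    design: StudyDesign
    observed_p: float | None = None


def _cc_design(n1_cases, n1_controls, n2_cases, n2_controls, K1, K2=None, **kw) -> StudyDesign:
    K2 = K1 if K2 is None else K2
    n1 = n1_cases + n1_controls
    n2 = n2_cases + n2_controls
    return StudyDesign(
        n1=n1, n2=n2,
        trait1=binary_trait(K1, P=n1_cases / n1),
        trait2=binary_trait(K2, P=n2_cases / n2),
        **kw,
    )


def isc_schizophrenia(vg: float = 0.287, pi0: float = 0.0, q1: float = 0.5) -> StudyPreset:
    """ISC schizophrenia: train 3322/3587, replicate in MGS-EA 2687/2656.

    74,062 near-independent SNPs, prevalence 1%; the most significant score
    association used SNPs with training P < 0.5 and reached P = 2e-28.
    """
    return StudyPreset(
        name="isc_schizophrenia",
        model=PolygenicModel(m=74062, vg1=vg, vg2=vg, rho12=1.0, pi0=pi0),
        design=_cc_design(3322, 3587, 2687, 2656, K1=0.01, q0=0.0, q1=q1),
        observed_p=2e-28,
    )


def isc_to_bipolar(vg: float = 0.287, rho12: float = 1.0, pi0: float = 0.0,
                   q1: float = 0.5) -> StudyPreset:
    """Schizophrenia-trained score tested on WTCCC bipolar disorder (1829/2935).

    Explained variance assumed equal in both traits; the observed cross-trait
    association was P = 1.4e-12 at inclusion threshold 0.5.
    """
    return StudyPreset(
        name="isc_to_bipolar",
        model=PolygenicModel(m=74062, vg1=vg, vg2=vg, rho12=rho12, pi0=pi0),
        design=_cc_design(3322, 3587, 1829, 2935, K1=0.01, q0=0.0, q1=q1),
        observed_p=1.4e-12,
    )


def imsgc_multiple_sclerosis(vg: float = 0.3, pi0: float = 0.0) -> StudyPreset:
    """IMSGC multiple sclerosis: train 931/2431, replicate 876/2077.

    59,470 near-independent SNPs, prevalence 0.1%; the all-SNP score reached
    P = 2e-20.
    """
    return StudyPreset(
        name="imsgc_multiple_sclerosis",
        model=PolygenicModel(m=59470, vg1=vg, vg2=vg, rho12=1.0, pi0=pi0),
        design=_cc_design(931, 2431, 876, 2077, K1=0.001, q0=0.0, q1=1.0),
        observed_p=2e-20,
    )


def _machiela(name: str, total: int, m: int, K: float, lambda_s: float,
              split: float, fraction_explained: float) -> StudyPreset:
    h2 = h2_liability_from_sibling_rr(K, lambda_s)
    vg = fraction_explained * h2
    n1 = split * total
    n2 = (1.0 - split) * total
    trait = binary_trait(K, P=0.5)
    return StudyPreset(
        name=name,
        model=PolygenicModel(m=m, vg1=vg, vg2=vg, rho12=1.0, pi0=0.0),
        design=StudyDesign(n1=n1, n2=n2, trait1=trait, trait2=trait),
    )


def machiela_breast(split: float = 0.9, fraction_explained: float = 1.0) -> StudyPreset:
    """Machiela et al. breast cancer: 2287 subjects (half cases), 9:1 CV split,
    161,702 SNPs, prevalence 3.6%, sibling relative risk 2.5."""
    return _machiela("machiela_breast", 2287, 161702, 0.036, 2.5,
                     split, fraction_explained)


def machiela_prostate(split: float = 0.9, fraction_explained: float = 1.0) -> StudyPreset:
    """Machiela et al. prostate cancer: 2277 subjects (half cases), 9:1 split,
    165,508 SNPs, prevalence 2.4%, sibling relative risk 2.8."""
    return _machiela("machiela_prostate", 2277, 165508, 0.024, 2.8,
                     split, fraction_explained)


def framingham_risk_score(vg: float = 1.0, q0: float = 0.0, q1: float = 0.1) -> StudyPreset:
    """Simonson et al. Framingham Risk Score: quantitative trait, 10-fold CV
    (train 1575, test 175), panel treated as 100,000 independent SNPs."""
    return StudyPreset(
        name="framingham_risk_score",
        model=PolygenicModel(m=100_000, vg1=vg, vg2=vg, rho12=1.0, pi0=0.0),
        design=StudyDesign(n1=1575, n2=175, trait1=quantitative_trait(),
                           trait2=quantitative_trait(), q0=q0, q1=q1),
    )
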