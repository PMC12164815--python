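"""Deterministic USEPA dose and risk formulas.

Average daily dose (ADD, mg/kg/day) per pathway:

- ingestion:   ADD = Cs * IR * EF * ED / (BW * AT) * CF
- inhalation:  ADD = C * InhR * EF * ED / (PEF * BW * AT)
- dermal:      ADD = C * AF * ABS * EV * EF * ED * CF * SA / (BW * AT)

The carcinogenic dose (cADD) re-averages over the lifetime averaging
time cAT, i.e. cADD = ADD * AT / cAT.  Hazard quotient HQ = ADD / RfD,
hazard index HI = sum of HQs over pathways, carcinogenic risk is derived
from cADD and the slope factor SF under one of two conventions (see
:func:`cancer_risk`), and the accumulated carcinogenic risk aCR is the
sum of CRs over pathways.

All dose functions are vectorised: concentration and body weight may be
scalars or numpy arrays (broadcast together), so the Monte Carlo engine
reuses exactly the code paths validated point-wise here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .params import ExposureFactors, Pathway, ToxCriteria

__all__ = [
    "DoseResult",
    "RiskAggregate",
    "add_ingestion",
    "add_inhalation",
    "add_dermal",
    "pathway_add",
    "carcinogenic_add",
    "hazard_quotient",
    "cancer_risk",
    "hazard_index",
    "accumulated_cancer_risk",
    "screen_add",
    "point_estimate",
]


@dataclass(frozen=True)
class DoseResult:
    """Point doses and risks for one (age group, pathway) cell."""

    age_group: str
    pathway: Pathway
    add: float
    cadd: float
    hq: float
    cr: float


@dataclass(frozen=True)
class RiskAggregate:
    """Across-pathway sums for one age group."""

    age_group: str
    hi: float
    acr: float


def _nonneg(value, name: str):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def add_ingestion(cs, f: ExposureFactors, bw=None):
    """Oral (ingestion) average daily dose, mg/kg/day.

    ``bw`` defaults to the group's mean body weight; pass an array of
    sampled weights for probabilistic evaluation.
    """
    cs = _nonneg(cs, "Cs")
    bw = f.BW_mean if bw is None else np.asarray(bw, dtype=float)
    return cs * f.IR * f.EF * f.ED / (bw * f.AT) * f.CF


def add_inhalation(c, f: ExposureFactors, bw=None):
    """Inhalation average daily dose, mg/kg/day."""
    c = _nonneg(c, "C")
    bw = f.BW_mean if bw is None else np.asarray(bw, dtype=float)
    return c * f.InhR * f.EF * f.ED / (f.PEF * bw * f.AT)


def add_dermal(c, f: ExposureFactors, bw=None):
    """Dermal-contact average daily dose, mg/kg/day."""
    c = _nonneg(c, "C")
    bw = f.BW_mean if bw is None else np.asarray(bw, dtype=float)
    return c * f.AF * f.ABS * f.EV * f.EF * f.ED * f.CF * f.SA / (bw * f.AT)


_PATHWAY_FUNCS = {
    Pathway.ORAL: add_ingestion,
    Pathway.INHALATION: add_inhalation,
    Pathway.DERMAL: add_dermal,
}


def pathway_add(pathway: Pathway, c, f: ExposureFactors, bw=None):
    """Dispatch the ADD formula for ``pathway``."""
    return _PATHWAY_FUNCS[Pathway(pathway)](c, f, bw=bw)


def carcinogenic_add(add, at: float, cat: float):
    """Carcinogenic dose: re-scale the averaging time from AT to cAT.

    Identical to re-evaluating the pathway formula with cAT in the
    denominator, since AT enters every formula linearly.
    """
    if at <= 0 or cat <= 0:
        raise ValueError("AT and cAT must be positive")
    return np.asarray(add, dtype=float) * (at / cat)


def hazard_quotient(add, rfd: float):
    """HQ = ADD / RfD (dimensionless)."""
    if rfd <= 0:
        raise ValueError(f"reference dose must be positive, got {rfd}")
    return np.asarray(add, dtype=float) / rfd


def cancer_risk(cadd, sf: float, convention: str = "printed"):
    """Carcinogenic risk from the carcinogenic dose.

    ``"printed"`` returns cADD / SF — the convention the published Araró
    risk tables follow.  ``"standard"`` returns cADD * SF, the usual
    USEPA definition.  With SF = 1.5 the two differ by a factor 2.25.
    """
    if sf <= 0:
        raise ValueError(f"slope factor must be positive, got {sf}")
    cadd = np.asarray(cadd, dtype=float)
    if convention == "printed":
        return cadd / sf
    if convention == "standard":
        return cadd * sf
    raise ValueError(
        f"unknown CR convention {convention!r}; expected 'printed' or 'standard'"
    )


def hazard_index(hqs: Sequence):
    """HI = sum of hazard quotients (elementwise for arrays)."""
    return _checked_sum(hqs, "hazard quotient")


def accumulated_cancer_risk(crs: Sequence):
    """aCR = sum of per-pathway carcinogenic risks."""
    return _checked_sum(crs, "cancer risk")


def _checked_sum(values: Iterable, name: str):
    values = list(values)
    if not values:
        return 0.0
    total = 0.0
    for v in values:
        total = total + _nonneg(v, name)
    return total


def screen_add(add: float, pathway: Pathway, criteria: ToxCriteria) -> bool:
    """True iff the dose strictly exceeds the pathway's screening limit."""
    return bool(np.all(np.asarray(add) > criteria.screening_limit(Pathway(pathway))))


def point_estimate(
    f: ExposureFactors,
    criteria: ToxCriteria,
    age_group: str = "",
    cr_convention: str = "printed",
    concentration: Optional[float] = None,
    bw: Optional[float] = None,
) -> tuple[dict[Pathway, DoseResult], RiskAggregate]:
    """Deterministic doses/risks at point values (defaults: the means).

    Returns one :class:`DoseResult` per pathway plus the across-pathway
    :class:`RiskAggregate`.
    """
    c = f.AsC_mean if concentration is None else concentration
    results: dict[Pathway, DoseResult] = {}
    for pathway in Pathway:
        add = float(pathway_add(pathway, c, f, bw=bw))
        cadd = float(carcinogenic_add(add, f.AT, f.cAT))
        hq = float(hazard_quotient(add, criteria.hq_reference_dose(pathway)))
        cr = float(cancer_risk(cadd, criteria.slope_factor(pathway), cr_convention))
        results[pathway] = DoseResult(
            age_group=age_group, pathway=pathway, add=add, cadd=cadd, hq=hq, cr=cr
        )
    agg = RiskAggregate(
        age_group=age_group,
        hi=float(hazard_index([r.hq for r in results.values()])),
        acr=float(accumulated_cancer_risk([r.cr for r in results.values()])),
    )
    return results, agg
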