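"""Dust-survey containers, campaign sizing and regulatory screening.

The required number of samples for a campaign over an area of A hectares
follows the Mexican dust/soil sampling norm, n = 2.26 * A^0.31 truncated
to an integer (the 11,400 ha Araró area yields 40 samples).  Measured
concentrations below the XRF limit of detection carry a ``below_lod``
flag and can be substituted (half-LOD or LOD) or dropped before
summarisation.  Surveys are screened against a regulatory threshold —
22 mg As/kg for Mexican residential soil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SurveyRecord",
    "DustSurvey",
    "SurveySummary",
    "required_sample_count",
    "summarize_survey",
    "censor_below_lod",
    "MEXICAN_SOIL_THRESHOLD",
]

#: NOM-147 residential soil threshold for arsenic, mg/kg.
MEXICAN_SOIL_THRESHOLD = 22.0

CENSOR_POLICIES = ("half_lod", "lod", "drop")


@dataclass(frozen=True)
class SurveyRecord:
    sample_id: str
    concentration: float  # mg/kg
    below_lod: bool = False


@dataclass
class DustSurvey:
    """A collection of per-sample dust concentration records.

    ``lod`` is the analytical limit of detection (mg/kg); ``area_ha`` the
    sampled area in hectares, if known.
    """

    records: List[SurveyRecord]
    lod: float
    area_ha: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lod <= 0:
            raise ValueError(f"LOD must be positive, got {self.lod}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.concentration <= 0:
                raise ValueError(
                    f"sample {rec.sample_id!r}: concentration must be positive, "
                    f"got {rec.concentration}"
                )
            if rec.below_lod and rec.concentration > self.lod:
                raise ValueError(
                    f"sample {rec.sample_id!r}: flagged below LOD but "
                    f"concentration {rec.concentration} > LOD {self.lod}"
                )
            if rec.sample_id in seen:
                raise ValueError(f"duplicate sample id {rec.sample_id!r}")
            seen.add(rec.sample_id)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([r.concentration for r in self.records], dtype=float)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "concentration_mg_kg": [r.concentration for r in self.records],
                "below_lod": [r.below_lod for r in self.records],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, lod: float = 4.0, area_ha: Optional[float] = None
    ) -> "DustSurvey":
        """Read the survey CSV schema (``sample_id, concentration_mg_kg,
        below_lod``; extra columns such as lat/lon are ignored)."""
        df = pd.read_csv(path)
        required = {"sample_id", "concentration_mg_kg", "below_lod"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(
                f"{path}: missing required column(s) {', '.join(sorted(missing))}"
            )
        records = []
        for idx, row in df.iterrows():
            try:
                conc = float(row["concentration_mg_kg"])
                flag = _parse_bool(row["below_lod"])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed row {idx + 2} "
                    f"(sample_id={row['sample_id']!r}): {exc}"
                ) from exc
            records.append(
                SurveyRecord(str(row["sample_id"]), conc, flag)
            )
        return cls(records=records, lod=lod, area_ha=area_ha)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no", ""}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a below-LOD flag")


@dataclass(frozen=True)
class SurveySummary:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    frac_above_threshold: float


def required_sample_count(area_ha: float) -> int:
    """Samples required by the sampling norm: floor(2.26 * A^0.31), min 1."""
    if area_ha <= 0:
        raise ValueError(f"area must be positive, got {area_ha} ha")
    return max(1, math.floor(2.26 * area_ha**0.31))


def summarize_survey(
    survey: DustSurvey, threshold: float = MEXICAN_SOIL_THRESHOLD
) -> SurveySummary:
    """Descriptive statistics and threshold exceedance of a survey.

    The SD is the sample standard deviation (ddof=1; 0 for n=1) and the
    exceedance fraction counts strictly greater concentrations.
    """
    x = survey.concentrations
    if x.size == 0:
        raise ValueError("cannot summarize an empty survey")
    return SurveySummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        frac_above_threshold=float(np.mean(x > threshold)),
    )


def censor_below_lod(survey: DustSurvey, policy: str = "half_lod") -> DustSurvey:
    """Apply a below-LOD substitution policy, returning a new survey.

    ``half_lod`` replaces flagged values with LOD/2, ``lod`` with the
    LOD, and ``drop`` removes flagged records.
    """
    if policy not in CENSOR_POLICIES:
        raise ValueError(
            f"unknown censoring policy {policy!r}; expected one of {CENSOR_POLICIES}"
        )
    if policy == "drop":
        records = [r for r in survey.records if not r.below_lod]
    else:
        sub = survey.lod / 2 if policy == "half_lod" else survey.lod
        records = [
            replace(r, concentration=sub) if r.below_lod else r
            for r in survey.records
        ]
    return DustSurvey(records=records, lod=survey.lod, area_ha=survey.area_ha)
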