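"""Typed registry of exposure, anthropometric and toxicity parameters.

The study population is stratified into four biological age groups
(preschooler, elementary, adolescent, adult) and three exposure pathways
(oral ingestion of dust, dermal contact, inhalation of resuspended
particles).  Every parameter that enters a dose formula is carried in a
validated :class:`ExposureFactors` bundle per age group; toxicity
reference values (reference doses, cancer slope factor, regulatory risk
limits) live in :class:`ToxCriteria`; :class:`StudyConfig` ties the four
groups, toxicity criteria and the Monte Carlo settings together and is
what the simulation engine consumes.

:func:`default_araro_config` returns the parameterisation of the Araró
(Michoacán, México) dust survey: a community of roughly 11,400 ha in the
Trans-Mexican volcanic belt whose settled dust carries geogenic arsenic
(measured mean 15.6 mg/kg, observed range 5.94-42.53 mg/kg).
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import Dict, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class AgeGroup(str, Enum):
    """The four receptor age groups; the label set is closed."""

    PRESCHOOLER = "preschooler"
    ELEMENTARY = "elementary"
    ADOLESCENT = "adolescent"
    ADULT = "adult"


class Pathway(str, Enum):
    """Exposure pathways; the label set is closed."""

    ORAL = "oral"
    DERMAL = "dermal"
    INHALATION = "inhalation"


class ExposureFactors(BaseModel):
    """Per age-group exposure and anthropometric parameters.

    Units follow standard USEPA dose-equation conventions:

    - ``AsC_*``: arsenic concentration in dust, mg/kg (mean, min, max, sd)
    - ``EF``: exposure frequency, days/year
    - ``ED``: exposure duration, years
    - ``BW_*``: body weight, kg (mean and population range)
    - ``AT``: non-carcinogenic averaging time, days
    - ``cAT``: carcinogenic (lifetime) averaging time, days
    - ``IR``: dust ingestion rate, mg/day
    - ``InhR``: inhalation rate, m3/day
    - ``PEF``: particle emission factor, m3/kg
    - ``SA``: exposed skin surface area, cm2
    - ``AF``: dust-to-skin adherence factor, mg/cm2
    - ``ABS``: dermal absorption fraction, dimensionless
    - ``EV``: event frequency, events/day
    - ``CF``: mass conversion factor, kg/mg (fixed at 1e-6)
    """

    model_config = ConfigDict(extra="forbid")

    AsC_mean: float = Field(gt=0)
    AsC_min: float = Field(gt=0)
    AsC_max: float = Field(gt=0)
    AsC_sd: float = Field(ge=0)
    EF: float = Field(gt=0)
    ED: float = Field(gt=0)
    BW_mean: float = Field(gt=0)
    BW_min: float = Field(gt=0)
    BW_max: float = Field(gt=0)
    AT: float = Field(gt=0)
    cAT: float = Field(gt=0)
    IR: float = Field(gt=0)
    InhR: float = Field(gt=0)
    PEF: float = Field(gt=0)
    SA: float = Field(gt=0)
    AF: float = Field(gt=0)
    ABS: float = Field(gt=0)
    EV: float = Field(gt=0)
    CF: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_consistency(self) -> "ExposureFactors":
        if not self.AsC_min <= self.AsC_mean <= self.AsC_max:
            raise ValueError(
                f"AsC ordering violated: min {self.AsC_min} <= mean "
                f"{self.AsC_mean} <= max {self.AsC_max} required"
            )
        if not self.BW_min <= self.BW_mean <= self.BW_max:
            raise ValueError(
                f"BW ordering violated: min {self.BW_min} <= mean "
                f"{self.BW_mean} <= max {self.BW_max} required"
            )
        if not math.isclose(self.CF, 1e-6, rel_tol=1e-9):
            raise ValueError(f"CF must be 1e-6 kg/mg, got {self.CF}")
        # AT is defined as ED * EF; all published parameter sets satisfy
        # this to within a day of rounding.
        if abs(self.AT - self.ED * self.EF) > 1.0:
            raise ValueError(
                f"AT ({self.AT} d) inconsistent with ED * EF "
                f"({self.ED} y * {self.EF} d/y = {self.ED * self.EF:.1f} d)"
            )
        return self


class ToxCriteria(BaseModel):
    """Toxicity reference values and regulatory limits for arsenic.

    ``RfD_oral`` (3.0e-4 mg/kg/day) divides oral hazard quotients and
    screens oral and inhalation doses.  ``RfD_inhalation`` (1.5e-5
    mg/kg/day, the USEPA inhalation reference value for arsenic) divides
    inhalation hazard quotients, while ``RfD_inhalation_screen`` keeps the
    3.0e-4 screening limit used when flagging raw inhalation doses.
    Dermal doses are screened against ``RfD_dermal_screen`` (1.23e-4) but
    the dermal hazard quotient divides by ``RfD_hq_dermal`` (3.0e-4),
    which is what reproduces the published dermal quotients.  ``SF`` is
    the oral cancer slope factor; per-pathway overrides are optional and
    fall back to ``SF``.
    """

    model_config = ConfigDict(extra="forbid")

    RfD_oral: float = Field(default=3.0e-4, gt=0)
    RfD_inhalation: float = Field(default=1.5e-5, gt=0)
    RfD_inhalation_screen: float = Field(default=3.0e-4, gt=0)
    RfD_hq_dermal: float = Field(default=3.0e-4, gt=0)
    RfD_dermal_screen: float = Field(default=1.23e-4, gt=0)
    SF: float = Field(default=1.5, gt=0)
    SF_dermal: Optional[float] = Field(default=None, gt=0)
    SF_inhalation: Optional[float] = Field(default=None, gt=0)
    HQ_limit: float = Field(default=1.0, gt=0)
    CR_limit: float = Field(default=1e-5, gt=0)

    @model_validator(mode="after")
    def _check_limits(self) -> "ToxCriteria":
        if not math.isclose(self.HQ_limit, 1.0, rel_tol=1e-12):
            raise ValueError(f"HQ_limit must be 1, got {self.HQ_limit}")
        if not math.isclose(self.CR_limit, 1e-5, rel_tol=1e-12):
            raise ValueError(f"CR_limit must be 1e-5, got {self.CR_limit}")
        return self

    def slope_factor(self, pathway: Pathway) -> float:
        """Cancer slope factor for a pathway, (mg/kg/day)^-1."""
        if pathway is Pathway.DERMAL and self.SF_dermal is not None:
            return self.SF_dermal
        if pathway is Pathway.INHALATION and self.SF_inhalation is not None:
            return self.SF_inhalation
        return self.SF

    def hq_reference_dose(self, pathway: Pathway) -> float:
        """Reference dose dividing the hazard quotient for a pathway."""
        if pathway is Pathway.ORAL:
            return self.RfD_oral
        if pathway is Pathway.INHALATION:
            return self.RfD_inhalation
        return self.RfD_hq_dermal

    def screening_limit(self, pathway: Pathway) -> float:
        """Safety-criteria limit an average daily dose is screened against."""
        if pathway is Pathway.ORAL:
            return self.RfD_oral
        if pathway is Pathway.INHALATION:
            return self.RfD_inhalation_screen
        return self.RfD_dermal_screen


CrConvention = Literal["printed", "standard"]


class StudyConfig(BaseModel):
    """Full study configuration: four age groups + toxicity + simulation.

    ``cr_convention`` selects how carcinogenic risk is derived from the
    carcinogenic dose: ``"printed"`` divides by the slope factor (the
    convention the published Araró risk tables follow) and ``"standard"``
    multiplies (conventional USEPA practice).

    ``dermal_contact_factor_DFS`` (mg*year/kg/day) is inert metadata: it
    appears in the published parameter table but no dose formula consumes
    it.
    """

    model_config = ConfigDict(extra="forbid")

    age_groups: Dict[AgeGroup, ExposureFactors]
    toxicity: ToxCriteria = Field(default_factory=ToxCriteria)
    n_iterations: int = Field(default=10_000, ge=1)
    seed: int = 20_180_000
    cr_convention: CrConvention = "printed"
    bw_range_coverage: float = Field(default=0.99, gt=0, lt=1)
    dermal_contact_factor_DFS: float = 362.4

    @model_validator(mode="after")
    def _check_groups(self) -> "StudyConfig":
        missing = [g.value for g in AgeGroup if g not in self.age_groups]
        if missing:
            raise ValueError(f"missing age group(s): {', '.join(missing)}")
        return self

    # convenience accessors -------------------------------------------------
    @property
    def preschooler(self) -> ExposureFactors:
        return self.age_groups[AgeGroup.PRESCHOOLER]

    @property
    def elementary(self) -> ExposureFactors:
        return self.age_groups[AgeGroup.ELEMENTARY]

    @property
    def adolescent(self) -> ExposureFactors:
        return self.age_groups[AgeGroup.ADOLESCENT]

    @property
    def adult(self) -> ExposureFactors:
        return self.age_groups[AgeGroup.ADULT]


# ---------------------------------------------------------------------------
# Araró defaults

# (ED years, BW mean/min/max kg, AT days, IR mg/day, InhR m3/day, SA cm2)
_GROUP_TABLE = {
    AgeGroup.PRESCHOOLER: (3.51, 16.31, 10.0, 39.0, 1_229.0, 100.0, 9.5, 760.0),
    AgeGroup.ELEMENTARY: (8.82, 33.8, 14.0, 95.7, 3_087.0, 100.0, 12.0, 1_080.0),
    AgeGroup.ADOLESCENT: (15.88, 60.91, 25.9, 158.4, 5_558.0, 30.0, 15.75, 1_840.0),
    AgeGroup.ADULT: (42.94, 72.67, 45.0, 194.2, 15_029.0, 30.0, 14.67, 1_935.0),
}


def default_araro_config() -> StudyConfig:
    """Study configuration of the Araró dust arsenic survey.

    Dust arsenic: mean 15.6 mg/kg, SD 5.94 mg/kg, observed range
    5.94-42.53 mg/kg.  Exposure frequency 350 d/y for all groups; the
    carcinogenic averaging time is a 70-year lifetime (25,550 days) and
    the dermal event frequency is the residential default of 1/day.
    """
    groups = {
        g: ExposureFactors(
            AsC_mean=15.6,
            AsC_min=5.94,
            AsC_max=42.53,
            AsC_sd=5.94,
            EF=350.0,
            ED=ed,
            BW_mean=bw,
            BW_min=bw_lo,
            BW_max=bw_hi,
            AT=at,
            cAT=25_550.0,
            IR=ir,
            InhR=inhr,
            PEF=1.36e9,
            SA=sa,
            AF=0.5,
            ABS=0.03,
            EV=1.0,
            CF=1e-6,
        )
        for g, (ed, bw, bw_lo, bw_hi, at, ir, inhr, sa) in _GROUP_TABLE.items()
    }
    return StudyConfig(age_groups=groups)


# ---------------------------------------------------------------------------
# Serialization

def config_to_dict(config: StudyConfig) -> dict:
    """Serialize a config to the on-disk dict layout.

    Top-level keys: ``age_groups`` (one block per group), ``toxicity``,
    ``simulation`` (iterations, seed, cr_convention, bw_range_coverage)
    and ``metadata``.
    """
    return {
        "age_groups": {
            g.value: f.model_dump() for g, f in config.age_groups.items()
        },
        "toxicity": config.toxicity.model_dump(),
        "simulation": {
            "iterations": config.n_iterations,
            "seed": config.seed,
            "cr_convention": config.cr_convention,
            "bw_range_coverage": config.bw_range_coverage,
        },
        "metadata": {"DFS": config.dermal_contact_factor_DFS},
    }


def save_config(config: StudyConfig, path: str | Path) -> None:
    """Write a config as YAML (``.yaml``/``.yml``) or JSON (anything else)."""
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def _deep_merge(base: dict, override: dict) -> dict:
    merged = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key] = _deep_merge(merged[key], value)
        else:
            merged[key] = value
    return merged


def config_from_dict(data: dict) -> StudyConfig:
    """Build a validated config from a (possibly partial) dict.

    Unspecified fields fall back to the Araró defaults; unknown age-group
    labels are rejected.
    """
    valid_labels = {g.value for g in AgeGroup}
    unknown = set(data.get("age_groups", {})) - valid_labels
    if unknown:
        raise ValueError(
            f"unknown age group label(s): {', '.join(sorted(unknown))}; "
            f"valid labels are {', '.join(sorted(valid_labels))}"
        )
    merged = _deep_merge(config_to_dict(default_araro_config()), data)
    sim = merged.get("simulation", {})
    meta = merged.get("metadata", {})
    return StudyConfig(
        age_groups={
            AgeGroup(label): ExposureFactors(**block)
            for label, block in merged["age_groups"].items()
        },
        toxicity=ToxCriteria(**merged.get("toxicity", {})),
        n_iterations=sim.get("iterations", 10_000),
        seed=sim.get("seed", 20_180_000),
        cr_convention=sim.get("cr_convention", "printed"),
        bw_range_coverage=sim.get("bw_range_coverage", 0.99),
        dermal_contact_factor_DFS=meta.get("DFS", 362.4),
    )


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML or JSON config file, filling gaps with Araró defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text) or {}
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)
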