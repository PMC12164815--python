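"""Synthetic dust surveys and body-weight populations.

Emulates the field inputs the risk pipeline consumes, so every stage is
testable without field data.  Measured concentrations follow a simple
XRF-style error model: truth drawn from a lognormal, multiplied by a
constant recovery factor (the instrument's accuracy, 117% in the Araró
quality-control run) and by multiplicative lognormal noise with the
instrument's repeatability CV (0.75%); values below the limit of
detection (4 mg/kg) are flagged.  The model deliberately omits spatial
autocorrelation and sieving physics — concentrations are exchangeable
across sampling sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .montecarlo import LognormalSpec, sample
from .params import AgeGroup
from .survey import DustSurvey, SurveyRecord, required_sample_count

__all__ = ["AQCProfile", "generate_dust_survey", "generate_bw_population", "write_bw_csv"]


@dataclass(frozen=True)
class AQCProfile:
    """Analytical quality control constants of the measuring instrument.

    ``cv``: repeatability coefficient of variation (proportion);
    ``accuracy``: recovery factor (measured/true, proportion);
    ``lod``: limit of detection, mg/kg.  Defaults are the Araró XRF run.
    """

    cv: float = 0.0075
    accuracy: float = 1.17
    lod: float = 4.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"cv must be non-negative, got {self.cv}")
        if self.accuracy <= 0:
            raise ValueError(f"accuracy must be positive, got {self.accuracy}")
        if self.lod <= 0:
            raise ValueError(f"lod must be positive, got {self.lod}")


def generate_dust_survey(
    area_ha: float,
    true_spec: LognormalSpec,
    aqc: AQCProfile = AQCProfile(),
    seed: Optional[int] = None,
    correct_recovery: bool = False,
) -> DustSurvey:
    """Simulate a dust survey over ``area_ha`` hectares.

    The number of records is fixed by the sampling norm
    (:func:`required_sample_count`).  Measured value = truth x recovery x
    unit-mean multiplicative noise; with ``correct_recovery`` the
    recovery factor is divided back out, as a laboratory would when
    reporting recovery-corrected concentrations.
    """
    n = required_sample_count(area_ha)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = sample(true_spec, n, rng)
    if aqc.cv > 0:
        sigma_n = math.sqrt(math.log1p(aqc.cv**2))
        noise = rng.lognormal(-(sigma_n**2) / 2, sigma_n, size=n)  # mean 1
    else:
        noise = np.ones(n)
    measured = truth * aqc.accuracy * noise
    if correct_recovery:
        measured = measured / aqc.accuracy
    records = [
        SurveyRecord(
            sample_id=f"S{i + 1:03d}",
            concentration=float(c),
            below_lod=bool(c < aqc.lod),
        )
        for i, c in enumerate(measured)
    ]
    return DustSurvey(records=records, lod=aqc.lod, area_ha=area_ha)


def generate_bw_population(
    group: AgeGroup,
    spec: LognormalSpec,
    n: int,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Draw ``n`` body weights (kg) for one age group from its spec.

    Truncation bounds on the spec keep every draw inside the group's
    plausible weight range.
    """
    AgeGroup(group)  # validate the label
    return sample(spec, n, seed)


def write_bw_csv(path: str | Path, group: AgeGroup, weights: np.ndarray) -> None:
    """Write a body-weight population as ``age_group, bw_kg`` CSV."""
    pd.DataFrame(
        {"age_group": AgeGroup(group).value, "bw_kg": np.asarray(weights, dtype=float)}
    ).to_csv(path, index=False)
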