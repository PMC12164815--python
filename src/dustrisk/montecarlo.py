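"""Lognormal input distributions and the Monte Carlo risk engine.

Two inputs are random, matching the published analysis: the dust arsenic
concentration (AsC) and the body weight (BW) of each age group; every
other exposure factor is held at its point value.  AsC is fitted by the
method of moments from its arithmetic mean and SD and truncated to the
observed concentration range; BW, reported only as a mean plus a
population range, is fitted by reading the range as a central-coverage
interval (99% by default) of the underlying lognormal and truncated to
it.

Each of the ``n_iterations`` scenarios draws one (AsC, BW) pair per age
group, shared across the three pathways, so the hazard index and the
accumulated carcinogenic risk are genuine within-scenario sums.
Summaries report mean, SD, median, min, max, P95, P97 and the fraction
of scenarios exceeding the relevant safety limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import dose
from .params import AgeGroup, ExposureFactors, Pathway, StudyConfig

__all__ = [
    "LognormalSpec",
    "MCSummary",
    "PathwayOutcome",
    "GroupOutcome",
    "SimulationResult",
    "fit_lognormal_moments",
    "fit_lognormal_range",
    "sample",
    "run_simulation",
    "sensitivity_contributions",
    "rank_contributions",
    "concentration_spec",
    "body_weight_spec",
]


@dataclass(frozen=True)
class LognormalSpec:
    """A (possibly truncated) lognormal distribution.

    ``mu`` and ``sigma`` are the log-scale location and spread; ``lower``
    and ``upper`` are truncation bounds in natural units.  The default
    bounds (0, inf) mean no truncation.
    """

    mu: float
    sigma: float
    lower: float = 0.0
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.lower < 0:
            raise ValueError(f"lower bound must be non-negative, got {self.lower}")
        if not self.lower < self.upper:
            raise ValueError(
                f"lower bound {self.lower} must be below upper bound {self.upper}"
            )

    @property
    def median(self) -> float:
        """Median of the untruncated distribution, e^mu."""
        return math.exp(self.mu)

    @property
    def mean(self) -> float:
        """Mean of the untruncated distribution, e^(mu + sigma^2/2)."""
        return math.exp(self.mu + self.sigma**2 / 2)

    def with_bounds(self, lower: float, upper: float) -> "LognormalSpec":
        return LognormalSpec(self.mu, self.sigma, lower, upper)

    def truncation_mass(self) -> float:
        """Probability mass of the untruncated law inside [lower, upper]."""
        if self.sigma == 0:
            return 1.0 if self.lower <= self.median <= self.upper else 0.0
        lo = (math.log(self.lower) - self.mu) / self.sigma if self.lower > 0 else -math.inf
        hi = (
            (math.log(self.upper) - self.mu) / self.sigma
            if math.isfinite(self.upper)
            else math.inf
        )
        return float(stats.norm.cdf(hi) - stats.norm.cdf(lo))


def fit_lognormal_moments(mean: float, sd: float) -> LognormalSpec:
    """Method-of-moments lognormal fit from arithmetic mean and SD.

    sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2; the
    returned spec is untruncated.
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    return LognormalSpec(mu=math.log(mean) - sigma2 / 2, sigma=math.sqrt(sigma2))


def fit_lognormal_range(
    mean: float, lo: float, hi: float, coverage: float = 0.99
) -> LognormalSpec:
    """Lognormal fit from an arithmetic mean plus a population range.

    The range [lo, hi] is read as the central ``coverage`` interval of
    the untruncated lognormal, giving sigma = (ln hi - ln lo)/(2 z) with
    z the standard-normal quantile of (1+coverage)/2; mu then matches
    the arithmetic mean.  The spec is truncated to [lo, hi].
    """
    if not 0 < lo < mean < hi:
        raise ValueError(
            f"require 0 < lo < mean < hi, got lo={lo}, mean={mean}, hi={hi}"
        )
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    z = stats.norm.ppf((1 + coverage) / 2)
    sigma = (math.log(hi) - math.log(lo)) / (2 * z)
    mu = math.log(mean) - sigma**2 / 2
    return LognormalSpec(mu=mu, sigma=sigma, lower=lo, upper=hi)


_MAX_REJECTION_ROUNDS = 100


def sample(
    spec: LognormalSpec,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` values; out-of-bounds draws are rejected and redrawn.

    ``seed`` may be an integer or a numpy Generator (the latter lets a
    caller thread one deterministic stream through several calls).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.sigma == 0:
        value = spec.median
        if not spec.lower <= value <= spec.upper:
            raise RuntimeError(
                f"degenerate value {value} lies outside truncation bounds "
                f"[{spec.lower}, {spec.upper}]"
            )
        return np.full(n, value)
    if spec.truncation_mass() <= 0:
        raise RuntimeError(
            f"truncation bounds [{spec.lower}, {spec.upper}] carry no "
            f"probability mass for mu={spec.mu}, sigma={spec.sigma}"
        )
    out = np.empty(n)
    filled = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        need = n - filled
        draws = rng.lognormal(spec.mu, spec.sigma, size=max(need * 2, 128))
        keep = draws[(draws >= spec.lower) & (draws <= spec.upper)][:need]
        out[filled : filled + keep.size] = keep
        filled += keep.size
        if filled == n:
            return out
    raise RuntimeError(
        f"rejection sampling failed to fill {n} draws within "
        f"{_MAX_REJECTION_ROUNDS} rounds (acceptance too low)"
    )


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class MCSummary:
    """Summary statistics of one simulated quantity over all scenarios."""

    mean: float
    sd: float
    median: float
    min: float
    max: float
    p95: float
    p97: float
    exceed_frac: Optional[float]
    n_iter: int
    percentiles: Mapping[float, float] = field(default_factory=dict)

    @classmethod
    def from_samples(
        cls,
        x: np.ndarray,
        limit: Optional[float] = None,
        percentiles: Sequence[float] = (),
    ) -> "MCSummary":
        x = np.asarray(x, dtype=float)
        qs = {float(q): float(np.percentile(x, q)) for q in percentiles}
        return cls(
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            median=float(np.median(x)),
            min=float(np.min(x)),
            max=float(np.max(x)),
            p95=float(np.percentile(x, 95)),
            p97=float(np.percentile(x, 97)),
            exceed_frac=float(np.mean(x > limit)) if limit is not None else None,
            n_iter=int(x.size),
            percentiles=qs,
        )


@dataclass(frozen=True)
class PathwayOutcome:
    """ADD / HQ / CR summaries for one pathway (or the pathway sum)."""

    add: MCSummary
    hq: MCSummary
    cr: MCSummary


@dataclass(frozen=True)
class GroupOutcome:
    """All simulated outcomes for one age group."""

    pathways: Dict[Pathway, PathwayOutcome]
    total: PathwayOutcome
    hi_samples: Optional[np.ndarray] = None

    @property
    def hi(self) -> MCSummary:
        """Hazard index (within-scenario sum of HQs)."""
        return self.total.hq

    @property
    def acr(self) -> MCSummary:
        """Accumulated carcinogenic risk (within-scenario sum of CRs)."""
        return self.total.cr


@dataclass(frozen=True)
class SimulationResult:
    groups: Dict[AgeGroup, GroupOutcome]
    config: StudyConfig

    def to_frame(self, quantity: str) -> pd.DataFrame:
        """Tabulate one quantity (``add``, ``hq`` or ``cr``).

        One row per (age group, pathway) plus a per-group ``sum`` row;
        columns mean, sd, median, min, max, p95, limit.
        """
        if quantity not in {"add", "hq", "cr"}:
            raise ValueError(f"unknown quantity {quantity!r}")
        tox = self.config.toxicity
        rows = []
        for group, outcome in self.groups.items():
            cells = [(p.value, outcome.pathways[p]) for p in Pathway]
            cells.append(("sum", outcome.total))
            for label, cell in cells:
                s: MCSummary = getattr(cell, quantity)
                if quantity == "add":
                    limit = (
                        tox.screening_limit(Pathway(label)) if label != "sum" else np.nan
                    )
                elif quantity == "hq":
                    limit = tox.HQ_limit
                else:
                    limit = tox.CR_limit
                rows.append(
                    {
                        "age_group": group.value,
                        "pathway": label,
                        "mean": s.mean,
                        "sd": s.sd,
                        "median": s.median,
                        "min": s.min,
                        "max": s.max,
                        "p95": s.p95,
                        "limit": limit,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Input specs from exposure factors


def concentration_spec(f: ExposureFactors) -> LognormalSpec:
    """AsC distribution: moment fit, truncated to the observed range."""
    spec = fit_lognormal_moments(f.AsC_mean, f.AsC_sd)
    if spec.sigma == 0:
        return spec
    return spec.with_bounds(f.AsC_min, f.AsC_max)


def body_weight_spec(f: ExposureFactors, coverage: float = 0.99) -> LognormalSpec:
    """BW distribution from mean + range; degenerate if the range collapses."""
    if f.BW_min == f.BW_max:
        return LognormalSpec(mu=math.log(f.BW_mean), sigma=0.0)
    return fit_lognormal_range(f.BW_mean, f.BW_min, f.BW_max, coverage)


# ---------------------------------------------------------------------------
# Engine


def _group_outcome(
    f: ExposureFactors,
    config: StudyConfig,
    rng: np.random.Generator,
    keep_draws: bool,
) -> GroupOutcome:
    tox = config.toxicity
    n = config.n_iterations
    asc = sample(concentration_spec(f), n, rng)
    bw = sample(body_weight_spec(f, config.bw_range_coverage), n, rng)

    adds: Dict[Pathway, np.ndarray] = {}
    hqs: Dict[Pathway, np.ndarray] = {}
    crs: Dict[Pathway, np.ndarray] = {}
    pathways: Dict[Pathway, PathwayOutcome] = {}
    for p in Pathway:
        add = dose.pathway_add(p, asc, f, bw=bw)
        cadd = dose.carcinogenic_add(add, f.AT, f.cAT)
        hq = dose.hazard_quotient(add, tox.hq_reference_dose(p))
        cr = dose.cancer_risk(cadd, tox.slope_factor(p), config.cr_convention)
        adds[p], hqs[p], crs[p] = add, hq, cr
        pathways[p] = PathwayOutcome(
            add=MCSummary.from_samples(add, limit=tox.screening_limit(p)),
            hq=MCSummary.from_samples(hq, limit=tox.HQ_limit),
            cr=MCSummary.from_samples(cr, limit=tox.CR_limit),
        )

    add_sum = dose.hazard_index(list(adds.values()))  # elementwise sum
    hi = dose.hazard_index(list(hqs.values()))
    acr = dose.accumulated_cancer_risk(list(crs.values()))
    total = PathwayOutcome(
        add=MCSummary.from_samples(add_sum),
        hq=MCSummary.from_samples(hi, limit=tox.HQ_limit),
        cr=MCSummary.from_samples(acr, limit=tox.CR_limit),
    )
    return GroupOutcome(
        pathways=pathways,
        total=total,
        hi_samples=np.asarray(hi) if keep_draws else None,
    )


def run_simulation(config: StudyConfig, keep_draws: bool = False) -> SimulationResult:
    """Propagate AsC and BW uncertainty through every dose formula.

    Deterministic for a fixed config: each age group gets an independent
    child stream spawned from ``config.seed``.  With ``keep_draws`` the
    per-scenario hazard-index vectors are retained (for histograms).
    """
    children = np.random.SeedSequence(config.seed).spawn(len(AgeGroup))
    groups = {
        group: _group_outcome(
            config.age_groups[group], config, np.random.default_rng(child), keep_draws
        )
        for group, child in zip(AgeGroup, children)
    }
    return SimulationResult(groups=groups, config=config)


# ---------------------------------------------------------------------------
# Sensitivity


def rank_contributions(
    inputs: Mapping[str, np.ndarray], output: np.ndarray
) -> Dict[str, float]:
    """Squared Spearman rank correlations, normalised to sum to one.

    Inputs with zero variance are excluded; a single varying input gets
    the whole contribution.
    """
    varying = {
        name: np.asarray(x)
        for name, x in inputs.items()
        if np.ptp(np.asarray(x)) > 0
    }
    if not varying:
        return {}
    if len(varying) == 1:
        return {next(iter(varying)): 1.0}
    rho2 = {
        name: float(stats.spearmanr(x, output).statistic ** 2)
        for name, x in varying.items()
    }
    total = sum(rho2.values())
    if total == 0:
        return {name: 1.0 / len(rho2) for name in rho2}
    return {name: r / total for name, r in rho2.items()}


def sensitivity_contributions(
    config: StudyConfig,
    group: AgeGroup,
    pathway: Pathway,
    seed: Optional[int] = None,
) -> Dict[str, float]:
    """Contribution of each random input to one pathway's simulated dose."""
    f = config.age_groups[AgeGroup(group)]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    asc = sample(concentration_spec(f), config.n_iterations, rng)
    bw = sample(body_weight_spec(f, config.bw_range_coverage), config.n_iterations, rng)
    out = dose.pathway_add(Pathway(pathway), asc, f, bw=bw)
    return rank_contributions({"AsC": asc, "BW": bw}, out)
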