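"""Lognormal fitting, truncated sampling, the MC engine, sensitivity."""

import math

import numpy as np
import pytest
from scipy import stats

from dustrisk.dose import add_ingestion, point_estimate
from dustrisk.montecarlo import (
    LognormalSpec,
    MCSummary,
    body_weight_spec,
    concentration_spec,
    fit_lognormal_moments,
    fit_lognormal_range,
    rank_contributions,
    run_simulation,
    sample,
    sensitivity_contributions,
)
from dustrisk.params import AgeGroup, Pathway


# ---------------------------------------------------------------------------
# Fitting

def test_moment_fit_closed_form():
    spec = fit_lognormal_moments(15.21, 5.94)
    assert spec.mu == pytest.approx(2.651, abs=1e-3)
    assert spec.sigma == pytest.approx(0.3768, abs=1e-4)
    assert spec.median == pytest.approx(14.17, abs=0.01)


def test_moment_fit_degenerate_and_errors():
    spec = fit_lognormal_moments(12.0, 0.0)
    assert spec.sigma == 0.0
    assert spec.mu == pytest.approx(math.log(12.0))
    with pytest.raises(ValueError):
        fit_lognormal_moments(-1.0, 1.0)


def test_moment_fit_recovers_moments_by_simulation():
    spec = fit_lognormal_moments(15.21, 5.94)
    x = sample(spec, 1_000_000, seed=11)
    assert np.mean(x) == pytest.approx(15.21, rel=0.01)
    assert np.std(x, ddof=1) == pytest.approx(5.94, rel=0.01)


def test_range_fit_closed_form():
    spec = fit_lognormal_range(16.31, 10.0, 39.0, coverage=0.99)
    assert spec.sigma == pytest.approx(0.2642, abs=2e-4)
    assert spec.mu == pytest.approx(2.757, abs=1e-3)
    assert (spec.lower, spec.upper) == (10.0, 39.0)


def test_range_fit_sigma_monotone_in_range_width():
    narrow = fit_lognormal_range(16.31, 12.0, 25.0)
    wide = fit_lognormal_range(16.31, 10.0, 39.0)
    wider = fit_lognormal_range(16.31, 5.0, 80.0)
    assert narrow.sigma < wide.sigma < wider.sigma


def test_range_fit_rejects_bad_ordering():
    with pytest.raises(ValueError):
        fit_lognormal_range(16.31, 20.0, 39.0)
    with pytest.raises(ValueError):
        fit_lognormal_range(16.31, 10.0, 39.0, coverage=1.5)


# ---------------------------------------------------------------------------
# Sampling

def test_sampling_respects_truncation_bounds():
    spec = fit_lognormal_range(16.31, 10.0, 39.0)
    x = sample(spec, 10_000, seed=3)
    assert x.min() >= 10.0 and x.max() <= 39.0


def test_sampling_deterministic_under_seed():
    spec = fit_lognormal_moments(15.6, 5.94)
    assert np.array_equal(sample(spec, 1000, seed=42), sample(spec, 1000, seed=42))


def test_degenerate_spec_yields_constant_vector():
    spec = LognormalSpec(mu=math.log(7.0), sigma=0.0)
    x = sample(spec, 5, seed=1)
    assert np.ptp(x) == 0.0
    assert x[0] == pytest.approx(7.0)


def test_truncated_median_matches_numeric_quantile():
    spec = concentration_spec_default()
    x = sample(spec, 100_000, seed=5)
    # median of the truncated law via the untruncated normal CDF
    lo = stats.norm.cdf((math.log(spec.lower) - spec.mu) / spec.sigma)
    hi = stats.norm.cdf((math.log(spec.upper) - spec.mu) / spec.sigma)
    q = math.exp(spec.mu + spec.sigma * stats.norm.ppf(lo + 0.5 * (hi - lo)))
    assert np.median(x) == pytest.approx(q, rel=0.02)


def concentration_spec_default():
    spec = fit_lognormal_moments(15.6, 5.94)
    return spec.with_bounds(5.94, 42.53)


def test_infeasible_truncation_raises():
    spec = LognormalSpec(mu=0.0, sigma=0.1, lower=1e6, upper=2e6)
    with pytest.raises(RuntimeError):
        sample(spec, 10, seed=0)


def test_summary_order_invariants():
    x = np.random.default_rng(0).lognormal(0, 1, 5000)
    s = MCSummary.from_samples(x, limit=1.0, percentiles=(50,))
    assert s.min <= s.median <= s.p95 <= s.p97 <= s.max
    assert 0 <= s.exceed_frac <= 1
    assert s.percentiles[50.0] == pytest.approx(s.median)


# ---------------------------------------------------------------------------
# Engine

def test_degenerate_config_collapses_to_point_estimate(config):
    groups = {
        g: f.model_copy(
            update={"AsC_sd": 0.0, "BW_min": f.BW_mean, "BW_max": f.BW_mean}
        )
        for g, f in config.age_groups.items()
    }
    cfg = config.model_copy(update={"age_groups": groups, "n_iterations": 100})
    res = run_simulation(cfg)
    for g, outcome in res.groups.items():
        point, agg = point_estimate(
            groups[g], cfg.toxicity, g.value, cfg.cr_convention
        )
        for p in Pathway:
            cell = outcome.pathways[p]
            assert cell.add.sd <= 1e-12 * cell.add.mean
            assert cell.add.mean == pytest.approx(point[p].add, rel=1e-9)
            assert cell.hq.mean == pytest.approx(point[p].hq, rel=1e-9)
            assert cell.cr.mean == pytest.approx(point[p].cr, rel=1e-9)
        assert outcome.hi.mean == pytest.approx(agg.hi, rel=1e-9)
        assert outcome.acr.mean == pytest.approx(agg.acr, rel=1e-9)


def test_hi_mean_is_sum_of_hq_means(config):
    cfg = config.model_copy(update={"n_iterations": 2000})
    res = run_simulation(cfg)
    for outcome in res.groups.values():
        hq_sum = sum(outcome.pathways[p].hq.mean for p in Pathway)
        assert outcome.hi.mean == pytest.approx(hq_sum, rel=1e-12)


def test_simulation_reproducible_for_identical_config(config):
    cfg = config.model_copy(update={"n_iterations": 2000})
    a, b = run_simulation(cfg), run_simulation(cfg)
    for g in AgeGroup:
        for p in Pathway:
            assert a.groups[g].pathways[p].add == b.groups[g].pathways[p].add


def test_median_factorization_for_untruncated_ratio(config):
    # ADD = k * C/BW with independent lognormals: the simulated median
    # must match k * exp(muC - muB) within 3 bootstrap SEs.
    f = config.preschooler
    c_spec = fit_lognormal_moments(f.AsC_mean, f.AsC_sd)
    b_spec = LognormalSpec(
        body_weight_spec(f).mu, body_weight_spec(f).sigma
    )  # bounds removed
    rng = np.random.default_rng(17)
    c, b = sample(c_spec, 20_000, rng), sample(b_spec, 20_000, rng)
    add = add_ingestion(c, f, bw=b)
    k = f.IR * f.EF * f.ED * f.CF / f.AT
    theoretical = k * math.exp(c_spec.mu - b_spec.mu)
    boots = [
        np.median(rng.choice(add, size=add.size, replace=True)) for _ in range(200)
    ]
    se = np.std(boots, ddof=1)
    assert abs(np.median(add) - theoretical) < 3 * se


def test_mean_inflation_jensen(config):
    # E[C/BW] >= E[C]/E[BW]: randomising BW inflates the mean dose above
    # the deterministic dose at the mean inputs.
    cfg = config.model_copy(update={"n_iterations": 50_000})
    res = run_simulation(cfg)
    for g, outcome in res.groups.items():
        f = cfg.age_groups[g]
        det = float(add_ingestion(f.AsC_mean, f))
        # allow tiny slack: truncation pulls E[C] slightly below AsC_mean
        assert outcome.pathways[Pathway.ORAL].add.mean > det * 0.995


def test_simulated_moments_match_closed_form_ratio(config):
    # Untruncated C/BW is lognormal(muC-muB, sqrt(sC^2+sB^2)); at 1e6
    # draws the simulated mean and median agree with it within 1%.
    f = config.preschooler
    c_spec = fit_lognormal_moments(f.AsC_mean, f.AsC_sd)
    bws = body_weight_spec(f)
    b_spec = LognormalSpec(bws.mu, bws.sigma)
    rng = np.random.default_rng(23)
    c, b = sample(c_spec, 1_000_000, rng), sample(b_spec, 1_000_000, rng)
    add = add_ingestion(c, f, bw=b)
    k = f.IR * f.EF * f.ED * f.CF / f.AT
    mu = c_spec.mu - b_spec.mu
    s2 = c_spec.sigma**2 + b_spec.sigma**2
    assert np.median(add) == pytest.approx(k * math.exp(mu), rel=0.01)
    assert np.mean(add) == pytest.approx(k * math.exp(mu + s2 / 2), rel=0.01)


def test_simulation_reproduces_published_oral_median(config):
    res = run_simulation(config)
    got = res.groups[AgeGroup.PRESCHOOLER].pathways[Pathway.ORAL].add.median
    assert got == pytest.approx(9.59e-5, rel=0.20)


# ---------------------------------------------------------------------------
# Sensitivity

def test_single_varying_input_takes_all_contribution(config):
    groups = dict(config.age_groups)
    f = groups[AgeGroup.ADULT]
    groups[AgeGroup.ADULT] = f.model_copy(
        update={"BW_min": f.BW_mean, "BW_max": f.BW_mean}
    )
    cfg = config.model_copy(update={"age_groups": groups, "n_iterations": 2000})
    contrib = sensitivity_contributions(cfg, AgeGroup.ADULT, Pathway.ORAL)
    assert contrib == {"AsC": 1.0}


def test_contributions_sum_to_one(config):
    cfg = config.model_copy(update={"n_iterations": 5000})
    contrib = sensitivity_contributions(cfg, AgeGroup.PRESCHOOLER, Pathway.ORAL)
    assert set(contrib) == {"AsC", "BW"}
    assert sum(contrib.values()) == pytest.approx(1.0)
    assert contrib["AsC"] > contrib["BW"]  # AsC has the wider log-spread


def test_symmetric_inputs_share_contribution_equally():
    rng = np.random.default_rng(99)
    spec = LognormalSpec(mu=0.0, sigma=0.4)
    x, y = sample(spec, 50_000, rng), sample(spec, 50_000, rng)
    contrib = rank_contributions({"X": x, "Y": y}, x / y)
    assert contrib["X"] == pytest.approx(contrib["Y"], abs=0.03)
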