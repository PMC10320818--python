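"""Beta grid construction, PDA synthetic likelihood, grid search and BIC."""

import math

import numpy as np
import pytest

from bmsampler.fitting import (
    FULL_CHAIN_LENGTHS,
    BMSGridSearch,
    ParameterGrid,
    SimulationBank,
    beta_tvd,
    bic,
    bic_weights,
    build_beta_grid,
    fit_unit,
    kde_log_density,
    matched_beta,
    parameter_recovery,
    pda_log_likelihood,
    silverman_bandwidth,
)
from bmsampler.judgment import simulate_response_table
from bmsampler.networks import enumerate_queries

PRINTED_BETAS = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1,
                 1.11, 1.26, 1.45, 1.73, 2.14, 2.83, 4.14, 7.35, 21.54]


def test_beta_tvd_oracle_values():
    assert beta_tvd(1.0) == 0.0
    # arcsine-law closed form for Beta(1/2, 1/2)
    x0 = (1 - math.sqrt(1 - 4 / math.pi**2)) / 2
    arcsine_cdf = (2 / math.pi) * math.asin(math.sqrt(x0))
    assert beta_tvd(0.5) == pytest.approx(2 * (arcsine_cdf - x0), abs=1e-6)
    # polynomial closed form for Beta(2, 2): f(x) = 6x(1-x)
    x0 = (1 - math.sqrt(1 / 3)) / 2
    cdf = 3 * x0**2 - 2 * x0**3
    assert beta_tvd(2.0) == pytest.approx(2 * (x0 - cdf), abs=1e-6)
    with pytest.raises(ValueError):
        beta_tvd(0.0)


def test_beta_tvd_increases_away_from_uniform():
    grid = build_beta_grid()
    below = [b for b in grid if 0 < b < 1]
    above = [b for b in grid if b > 1]
    tvd_below = [beta_tvd(b) for b in below]
    tvd_above = [beta_tvd(b) for b in above]
    assert all(a > b for a, b in zip(tvd_below, tvd_below[1:]))  # decreasing to 1
    assert all(b > a for a, b in zip(tvd_above, tvd_above[1:]))  # increasing past 1


def test_matched_beta_pairs():
    assert matched_beta(0.5) == pytest.approx(2.14, abs=0.005)
    assert matched_beta(0.1) == pytest.approx(21.54, abs=0.005)


def test_beta_grid_reproduces_printed_values():
    grid = build_beta_grid()
    assert len(grid) == 21
    assert [round(b, 2) for b in grid[:-1]] == [0.0] + PRINTED_BETAS
    assert grid[-1] == 100.0


def test_full_grid_dimensions():
    grid = ParameterGrid.full()
    assert len(grid.chain_lengths) == 35
    assert grid.chain_lengths[0] == 2 and grid.chain_lengths[-1] == 70
    assert grid.size == 735


def test_silverman_bandwidth_degenerate():
    assert silverman_bandwidth(np.full(100, 50.0)) is None
    assert silverman_bandwidth(np.array([1.0])) is None
    assert silverman_bandwidth(np.random.default_rng(0).normal(size=500)) > 0


def test_pda_log_likelihood_contracts():
    sims = np.full(200, 50.0) + np.random.default_rng(0).normal(0, 0.5, 200)
    assert pda_log_likelihood(sims, []) == 0.0
    # density is higher where the simulated mass is
    assert pda_log_likelihood(sims, [50.0]) > pda_log_likelihood(sims, [100.0])
    # far outside the support the floor keeps things finite
    assert np.isfinite(pda_log_likelihood(sims, [1e6]))
    # degenerate simulated set engages the fallback bandwidth
    assert np.isfinite(kde_log_density(np.full(50, 50.0), np.array([48.0]))[0])


def test_bic_and_weights():
    assert bic(0.0, 1, 27) == pytest.approx(math.log(27))
    assert bic_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])
    w = bic_weights([0.0, 2.0])
    assert w == pytest.approx([0.731, 0.269], abs=5e-4)
    assert w.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        bic_weights([1.0])


@pytest.fixture(scope="module")
def small_bank(cc_joint):
    grid = ParameterGrid((4, 24), (0.0, 1.0, 21.54))
    rng = np.random.default_rng(8)
    return SimulationBank(cc_joint, grid, enumerate_queries(), 600, rng)


def test_grid_search_returns_argmax_cell(cc_joint, small_bank):
    queries = enumerate_queries()
    observed = simulate_response_table(
        cc_joint, queries, 24, 1.0, 30, np.random.default_rng(1)
    ).mean(axis=0)
    est = BMSGridSearch(model="bms", simulations=small_bank).fit(observed)
    assert est.log_likelihood_ == pytest.approx(est.loglik_grid_["loglik"].max())
    assert (est.chain_length_, est.beta_) in [
        (c, b) for c in small_bank.grid.chain_lengths for b in small_bank.grid.betas
    ]
    assert est.bic_ == pytest.approx(2 * math.log(27) - 2 * est.log_likelihood_)


def test_ms_fit_is_bms_restricted_to_beta_zero(cc_joint, small_bank):
    queries = enumerate_queries()
    observed = simulate_response_table(
        cc_joint, queries, 4, 0.0, 30, np.random.default_rng(2)
    ).mean(axis=0)
    ms = BMSGridSearch(model="ms", simulations=small_bank).fit(observed)
    bms = BMSGridSearch(model="bms", simulations=small_bank).fit(observed)
    assert ms.beta_ == 0.0 and ms.k_ == 1
    zero_rows = bms.loglik_grid_[bms.loglik_grid_["beta"] == 0.0]
    assert ms.log_likelihood_ == pytest.approx(zero_rows["loglik"].max())


def test_fit_input_validation(small_bank):
    with pytest.raises(ValueError):
        BMSGridSearch(simulations=small_bank).fit([])
    with pytest.raises(ValueError):
        BMSGridSearch(simulations=small_bank).fit([150.0] * 27)
    with pytest.raises(ValueError):
        BMSGridSearch(model="nope", simulations=small_bank).fit([50.0] * 27)


def test_fit_unit_wrapper(small_bank):
    res = fit_unit([50.0] * 27, model="bms", simulations=small_bank)
    assert res.n_obs == 27 and res.model == "bms"
    assert res.bic == pytest.approx(2 * math.log(27) - 2 * res.log_likelihood)


def test_recovery_correlations_meet_the_bound(recovery_run):
    """Generate-and-refit across the grid recovers both parameters with
    Pearson correlations at or above the .75 identifiability benchmark."""
    r_cl = np.corrcoef(recovery_run.true_chain_length, recovery_run.est_chain_length)[0, 1]
    r_beta = np.corrcoef(recovery_run.true_beta, recovery_run.est_beta)[0, 1]
    assert r_cl >= 0.75
    assert r_beta >= 0.75


def test_long_chains_are_harder_to_identify(recovery_run):
    """Cells with long true chains are less identifiable (model predictions
    change little past moderate chain lengths), so the chain-length
    estimation error is larger above the 40-sample mark."""
    err = (recovery_run.est_chain_length - recovery_run.true_chain_length).abs()
    short = recovery_run.true_chain_length <= 40
    assert err[short].mean() <= err[~short].mean()
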