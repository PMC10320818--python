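"""MS/BMS judgment rules and simulated response distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmsampler.judgment import (
    BayesianMutationSampler,
    bms_estimate,
    classify_response,
    exact_response_type_probabilities,
    ms_estimate,
    response_type_table,
    responses_from_counts,
    scaled_estimate,
    simulate_response_table,
    simulate_responses,
)
from bmsampler.networks import (
    Query,
    enumerate_queries,
    normative_probability,
    query_masks,
    state_index,
)
from bmsampler.sampler import run_chains


def counts_for(conflict_query, n_match, n_other, elsewhere=0):
    counts = np.zeros(8)
    counts[state_index((1, 1, 0))] = n_match
    counts[state_index((0, 1, 0))] = n_other
    counts[state_index((1, 1, 1))] = elsewhere
    return counts


def test_ms_estimate_examples(conflict_query):
    assert ms_estimate(counts_for(conflict_query, 0, 0, elsewhere=5), conflict_query) == 0.5
    assert ms_estimate(counts_for(conflict_query, 2, 0), conflict_query) == pytest.approx(
        1.0, abs=1e-9
    )
    assert ms_estimate(counts_for(conflict_query, 3, 1), conflict_query) == pytest.approx(0.75)


def test_ms_estimate_accepts_state_mapping(conflict_query):
    assert ms_estimate({(1, 1, 0): 3, (0, 1, 0): 1}, conflict_query) == pytest.approx(0.75)


def test_bms_estimate_examples(conflict_query):
    assert bms_estimate(counts_for(conflict_query, 0, 0), conflict_query, 1.0) == 0.5
    assert bms_estimate(counts_for(conflict_query, 3, 1), conflict_query, 1.0) == pytest.approx(
        4 / 6
    )
    with pytest.raises(ValueError):
        bms_estimate(counts_for(conflict_query, 1, 1), conflict_query, -0.5)


@settings(max_examples=60, deadline=None)
@given(
    counts=st.lists(st.integers(0, 20), min_size=8, max_size=8),
    query_idx=st.integers(0, 26),
)
def test_beta_zero_reduces_bms_to_ms(counts, query_idx):
    query = enumerate_queries()[query_idx]
    counts = np.asarray(counts, dtype=float)
    assert bms_estimate(counts, query, 0.0) == ms_estimate(counts, query)


@settings(max_examples=40, deadline=None)
@given(
    counts=st.lists(st.integers(0, 20), min_size=8, max_size=8),
    query_idx=st.integers(0, 26),
    betas=st.tuples(st.floats(0.01, 5), st.floats(0.01, 5)),
)
def test_bms_is_monotone_toward_half_in_beta(counts, query_idx, betas):
    query = enumerate_queries()[query_idx]
    counts = np.asarray(counts, dtype=float)
    lo, hi = sorted(betas)
    p_lo = bms_estimate(counts, query, lo)
    p_hi = bms_estimate(counts, query, hi)
    assert abs(p_hi - 0.5) <= abs(p_lo - 0.5) + 1e-12


def test_scaled_estimate():
    assert scaled_estimate(0.5, 1.0) == 0.5
    assert scaled_estimate(0.9, 1.2) == pytest.approx(1.08)  # may exceed the scale
    assert scaled_estimate(0.0, 3.0) == 0.0
    with pytest.raises(ValueError):
        scaled_estimate(0.5, 0.0)


def test_positive_beta_never_yields_extreme_responses(cc_joint, conflict_query, rng):
    responses = simulate_responses(cc_joint, conflict_query, 12, 0.1, 2_000, rng)
    assert responses.min() > 0.0 and responses.max() < 100.0


def test_huge_beta_pins_responses_near_fifty(cc_joint, conflict_query, rng):
    responses = simulate_responses(cc_joint, conflict_query, 12, 100.0, 1_000, rng)
    assert np.all((responses >= 45.0) & (responses <= 55.0))


def test_mean_ms_response_converges_to_normative(cc_joint, queries):
    """With very long chains the mean simulated MS response approaches the
    exact conditional for every query (within 1 percentage point)."""
    table = simulate_response_table(
        cc_joint, queries, 10_000, 0.0, 500, np.random.default_rng(3)
    )
    normative = np.array([100 * normative_probability(cc_joint, q) for q in queries])
    assert np.abs(table.mean(axis=0) - normative).max() < 1.0


def test_classification_matches_visitation_logic(cc_joint, conflict_query, rng):
    match, other = query_masks(conflict_query)
    counts = run_chains(cc_joint, 6, 500, rng)
    responses = responses_from_counts(counts, [conflict_query], 0.0)[:, 0]
    for row, resp in zip(counts, responses):
        kind = classify_response(row, conflict_query)
        if kind == "computed":
            assert 0.0 < resp < 100.0 and row[match].sum() > 0 and row[other].sum() > 0
        elif kind == "100":
            assert resp == pytest.approx(100.0, abs=1e-6)
        elif kind == "0":
            assert resp == pytest.approx(0.0, abs=1e-6)
        else:
            assert resp == pytest.approx(50.0, abs=1e-6)


def test_response_type_table_rows_partition(cc_joint, conflict_query, rng):
    table = response_type_table(cc_joint, conflict_query, [2, 6, 12], 2_000, rng)
    assert np.allclose(table.sum(axis=1), 1.0)
    assert table.loc[2, "computed"] == 0.0  # two samples cannot reach both states


def test_exact_enumeration_matches_monte_carlo(cc_joint, conflict_query):
    exact = exact_response_type_probabilities(cc_joint, conflict_query, 6)
    table = response_type_table(
        cc_joint, conflict_query, [6], 20_000, np.random.default_rng(5)
    )
    for kind in ("computed", "0", "50", "100"):
        assert table.loc[6, kind] == pytest.approx(exact[kind], abs=0.01)
    assert sum(exact.values()) == pytest.approx(1.0, abs=1e-9)


def test_bayesian_mutation_sampler_estimator(cc_joint, conflict_query):
    est = BayesianMutationSampler(
        chain_length=24, beta=1.0, n_sims=2_000, random_state=0
    )
    params = est.get_params()
    assert params["beta"] == 1.0 and params["chain_length"] == 24
    sample = est.sample([conflict_query])
    assert sample.shape == (2_000, 1)
    pred = est.predict([conflict_query])
    # conservative: between 50 and the normative 75
    assert 50.0 < pred[0] < 75.0
    assert est.normative([conflict_query])[0] == pytest.approx(75.0)
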