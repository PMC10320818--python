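"""From sampled chains to probability judgments.

The Mutation Sampler (MS) answers a conditional-probability query by relative
frequency: with N_match the number of recorded samples consistent with the
conditioning in which the target takes the queried value, and N_other the
count for the complementary target value,

    p_hat_MS = N_match / (N_match + N_other),

with every contributing state's count initialized at 1e-10 so that an entirely
unvisited pair of outcome sets yields the 50% default rather than 0/0.

The Bayesian Mutation Sampler (BMS) adds beta pseudo-observations from a
symmetric Beta(beta, beta) prior to both outcome counts and responds with the
posterior mean:

    p_hat_BMS = (N_match + beta) / (N_match + N_other + 2*beta).

beta = 0 recovers the MS exactly.  Responses are reported on the 0-100 percent
scale.  Queries that leave a non-queried variable unknown marginalize over it:
both of its values contribute to N_match / N_other.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .networks import (
    CausalParameters,
    JointDistribution,
    Query,
    build_joint,
    enumerate_queries,
    normative_probability,
    query_masks,
)
from .sampler import run_chains

__all__ = [
    "VISIT_FLOOR",
    "ms_estimate",
    "bms_estimate",
    "scaled_estimate",
    "simulate_responses",
    "simulate_response_table",
    "responses_from_counts",
    "classify_response",
    "response_type_table",
    "exact_response_type_probabilities",
    "BayesianMutationSampler",
]

#: Per-state visit-count initialization preventing 0/0 in the MS rule.
VISIT_FLOOR = 1e-10

_RESPONSE_TYPES = ("computed", "0", "50", "100")


def _counts_array(counts: Mapping | np.ndarray | Sequence[float]) -> np.ndarray:
    if isinstance(counts, Mapping):
        from .networks import state_index

        arr = np.zeros(8, dtype=float)
        for state, n in counts.items():
            arr[state_index(state)] += n
        return arr
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (8,):
        raise ValueError("counts must cover the 8 network states")
    return arr


def _outcome_counts(
    counts: np.ndarray, query: Query, floor: bool
) -> tuple[float, float]:
    match, other = query_masks(query)
    n_match = float(counts[match].sum())
    n_other = float(counts[other].sum())
    if floor:
        n_match += VISIT_FLOOR * int(match.sum())
        n_other += VISIT_FLOOR * int(other.sum())
    return n_match, n_other


def ms_estimate(counts, query: Query) -> float:
    """Relative-frequency probability estimate of the Mutation Sampler."""
    arr = _counts_array(counts)
    n_match, n_other = _outcome_counts(arr, query, floor=True)
    return n_match / (n_match + n_other)


def bms_estimate(counts, query: Query, beta: float) -> float:
    """Posterior-mean estimate under the symmetric Beta(beta, beta) prior."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if beta == 0:
        return ms_estimate(counts, query)
    arr = _counts_array(counts)
    n_match, n_other = _outcome_counts(arr, query, floor=False)
    return (n_match + beta) / (n_match + n_other + 2.0 * beta)


def scaled_estimate(p: float, s: float) -> float:
    """Linear response mapping ``s * p``.

    Deliberately not clipped: with ``s > 1`` the mapping can produce values
    outside the response scale, and whether to clip is the caller's decision.
    """
    if s <= 0:
        raise ValueError("scaling factor must be positive")
    return s * p


def responses_from_counts(
    counts: np.ndarray, queries: Sequence[Query], beta: float
) -> np.ndarray:
    """Percent-scale responses for many chains x many queries.

    ``counts`` is an ``(n_chains, 8)`` visit-count matrix (one row per chain);
    the result is ``(n_chains, len(queries))``.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    counts = np.asarray(counts, dtype=float)
    out = np.empty((counts.shape[0], len(queries)))
    for j, query in enumerate(queries):
        match, other = query_masks(query)
        n_match = counts[:, match].sum(axis=1)
        n_other = counts[:, other].sum(axis=1)
        if beta == 0:
            n_match = n_match + VISIT_FLOOR * int(match.sum())
            n_other = n_other + VISIT_FLOOR * int(other.sum())
            out[:, j] = 100.0 * n_match / (n_match + n_other)
        else:
            out[:, j] = 100.0 * (n_match + beta) / (n_match + n_other + 2.0 * beta)
    return out


def simulate_responses(
    joint: JointDistribution,
    query: Query,
    chain_length: int,
    beta: float,
    n_sims: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n_sims`` model responses (percent scale) for one query.

    Each response is the model's point judgment from one fresh chain: the
    posterior mean under Beta(beta, beta), or the relative frequency when
    ``beta = 0``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    counts = run_chains(joint, chain_length, n_sims, rng)
    return responses_from_counts(counts, [query], beta)[:, 0]


def simulate_response_table(
    joint: JointDistribution,
    queries: Sequence[Query],
    chain_length: int,
    beta: float,
    n_sims: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulated responses for all queries, sharing one set of chains.

    The chain-generation process does not depend on the query, so the same
    ``n_sims`` chains can answer every query; each column has exactly the
    marginal distribution of independently simulated responses.
    """
    counts = run_chains(joint, chain_length, n_sims, rng)
    return responses_from_counts(counts, queries, beta)


def classify_response(counts, query: Query) -> str:
    """Classify an MS response as 'computed' or a '0'/'50'/'100' default.

    Classification uses the state-visitation criterion: a response is
    computed iff both outcome sets were visited, avoiding floating-point
    comparisons against the default values.
    """
    arr = _counts_array(counts)
    n_match, n_other = _outcome_counts(arr, query, floor=False)
    if n_match > 0 and n_other > 0:
        return "computed"
    if n_match > 0:
        return "100"
    if n_other > 0:
        return "0"
    return "50"


def response_type_table(
    joint: JointDistribution,
    query: Query,
    chain_lengths: Sequence[int],
    n_chains: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Proportions of computed vs. default responses per chain length.

    One row per chain length with columns ``computed``, ``0``, ``50``,
    ``100``; each row sums to 1.
    """
    match, other = query_masks(query)
    rows = []
    for length in chain_lengths:
        counts = run_chains(joint, length, n_chains, rng)
        n_match = counts[:, match].sum(axis=1)
        n_other = counts[:, other].sum(axis=1)
        both = (n_match > 0) & (n_other > 0)
        rows.append(
            {
                "chain_length": length,
                "computed": both.mean(),
                "0": ((n_match == 0) & (n_other > 0)).mean(),
                "50": ((n_match == 0) & (n_other == 0)).mean(),
                "100": ((n_match > 0) & (n_other == 0)).mean(),
            }
        )
    return pd.DataFrame(rows).set_index("chain_length")


def exact_response_type_probabilities(
    joint: JointDistribution, query: Query, chain_length: int
) -> dict[str, float]:
    """Exact computed/default probabilities by transfer-matrix enumeration.

    Propagates the exact distribution over (current state, visited the
    match set?, visited the other set?) through the Metropolis kernel, so the
    result is the exact probability of each response type for the given chain
    length — the quantity the Monte-Carlo proportions of
    :func:`response_type_table` estimate.
    """
    if chain_length < 1:
        raise ValueError("chain_length must be at least 1")
    match, other = query_masks(query)
    p = joint.probs
    in_match = [bool(match[i]) for i in range(8)]
    in_other = [bool(other[i]) for i in range(8)]
    dist: dict[tuple[int, bool, bool], float] = {}
    for start in (7, 0):
        key = (start, in_match[start], in_other[start])
        dist[key] = dist.get(key, 0.0) + 0.5
    for _ in range(chain_length - 1):
        new: dict[tuple[int, bool, bool], float] = {}
        for (s, va, vb), pr in dist.items():
            for flip in (4, 2, 1):
                t = s ^ flip
                accept = min(1.0, p[t] / p[s]) if p[s] > 0 else 1.0
                for nxt, w in ((t, accept), (s, 1.0 - accept)):
                    if w == 0.0:
                        continue
                    key = (nxt, va or in_match[nxt], vb or in_other[nxt])
                    new[key] = new.get(key, 0.0) + pr * w / 3.0
        dist = new
    out = {"computed": 0.0, "0": 0.0, "50": 0.0, "100": 0.0}
    for (s, va, vb), pr in dist.items():
        if va and vb:
            out["computed"] += pr
        elif va:
            out["100"] += pr
        elif vb:
            out["0"] += pr
        else:
            out["50"] += pr
    return out


class BayesianMutationSampler(BaseEstimator):
    """Generative BMS responder with fixed parameters.

    A thin estimator-style wrapper bundling a network, a chain length and a
    prior so that simulated response distributions and mean predictions can
    be produced with one object.  ``beta=0`` gives the plain Mutation
    Sampler.

    Parameters
    ----------
    chain_length : int
        Number of recorded samples per judgment.
    beta : float
        Shape of the symmetric Beta(beta, beta) prior; 0 disables it.
    structure : str
        Network topology ('chain', 'common_cause' or 'common_effect').
    params : CausalParameters, optional
        Network parameterization; defaults to the taught values.
    n_sims : int
        Simulated responses per query for :meth:`sample` / :meth:`predict`.
    random_state : int or numpy Generator, optional
    """

    def __init__(
        self,
        chain_length: int = 12,
        beta: float = 1.0,
        structure: str = "common_cause",
        params: CausalParameters | None = None,
        n_sims: int = 10_000,
        random_state=None,
    ):
        self.chain_length = chain_length
        self.beta = beta
        self.structure = structure
        self.params = params
        self.n_sims = n_sims
        self.random_state = random_state

    def _joint(self) -> JointDistribution:
        return build_joint(self.structure, self.params)

    def _rng(self) -> np.random.Generator:
        return np.random.default_rng(self.random_state)

    def fit(self, X=None, y=None):
        """No-op present for estimator-protocol compatibility."""
        self.joint_ = self._joint()
        return self

    def sample(self, queries: Sequence[Query] | None = None) -> np.ndarray:
        """Simulated responses, shape ``(n_sims, len(queries))``."""
        queries = list(queries) if queries is not None else enumerate_queries()
        return simulate_response_table(
            self._joint(), queries, self.chain_length, self.beta, self.n_sims, self._rng()
        )

    def predict(self, queries: Sequence[Query] | None = None) -> np.ndarray:
        """Mean simulated response per query (percent scale)."""
        return self.sample(queries).mean(axis=0)

    def normative(self, queries: Sequence[Query] | None = None) -> np.ndarray:
        """Exact normative answers for reference, percent scale."""
        queries = list(queries) if queries is not None else enumerate_queries()
        joint = self._joint()
        return np.array([100.0 * normative_probability(joint, q) for q in queries])
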