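"""Prototype-initialized Metropolis-Hastings sampling over network states.

The Mutation Sampler draws a short chain of network states: it starts at one
of the two prototype states ((1,1,1) or (0,0,0), equiprobably), then repeatedly
proposes one of the three states differing in a single variable and accepts
with the usual Metropolis ratio min(1, P(proposal)/P(current)).  Rejected
proposals re-record the current state, so a chain of length ``n`` consists of
the start state plus ``n - 1`` recorded transitions.  There is no burn-in and
no thinning: the prototype bias of short chains is the model's substance, not
a numerical artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import PROTOTYPES, STATES, JointDistribution, state_index

__all__ = [
    "SamplerConfig",
    "prototype_start",
    "propose_neighbor",
    "acceptance_probability",
    "run_chain",
    "run_chains",
    "state_counts",
]

# XOR-ing a state index with these masks flips X1, Y, X2 respectively
_FLIP_MASKS = np.array([4, 2, 1], dtype=np.int64)


@dataclass(frozen=True)
class SamplerConfig:
    """Chain length (recorded samples per judgment) and optional seed."""

    chain_length: int
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.chain_length < 1:
            raise ValueError("chain_length must be at least 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def prototype_start(rng: np.random.Generator) -> tuple[int, int, int]:
    """One of the two prototype states, each with probability 1/2."""
    return PROTOTYPES[0] if rng.random() < 0.5 else PROTOTYPES[1]


def propose_neighbor(
    state: tuple[int, int, int], rng: np.random.Generator
) -> tuple[int, int, int]:
    """Uniformly one of the three states at Hamming distance 1 ('mutation')."""
    idx = state_index(state) ^ int(_FLIP_MASKS[rng.integers(0, 3)])
    return STATES[idx]


def acceptance_probability(
    joint: JointDistribution,
    current: tuple[int, int, int],
    proposal: tuple[int, int, int],
) -> float:
    """Metropolis acceptance probability min(1, P(proposal)/P(current))."""
    p_cur = joint.prob(current)
    if p_cur <= 0.0:
        raise ValueError("current state has zero probability; ratio undefined")
    return min(1.0, joint.prob(proposal) / p_cur)


def run_chain(
    joint: JointDistribution, chain_length: int, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """One chain of ``chain_length`` recorded states (start state included)."""
    if chain_length < 1:
        raise ValueError("chain_length must be at least 1")
    current = prototype_start(rng)
    chain = [current]
    p = joint.probs
    cur_idx = state_index(current)
    for _ in range(chain_length - 1):
        prop_idx = cur_idx ^ int(_FLIP_MASKS[rng.integers(0, 3)])
        # u * P(cur) < P(prop)  <=>  u < min(1, P(prop)/P(cur)) for u ~ U(0,1)
        if rng.random() * p[cur_idx] < p[prop_idx]:
            cur_idx = prop_idx
        chain.append(STATES[cur_idx])
    return chain


def run_chains(
    joint: JointDistribution,
    chain_length: int,
    n_chains: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Visit counts for many independent chains, vectorized over chains.

    Returns an ``(n_chains, 8)`` integer array whose rows sum to
    ``chain_length``; column ``i`` counts visits to ``STATES[i]``.  Equivalent
    in distribution to ``state_counts(run_chain(...))`` per row.
    """
    if chain_length < 1:
        raise ValueError("chain_length must be at least 1")
    if n_chains < 1:
        raise ValueError("n_chains must be at least 1")
    p = joint.probs
    cur = np.where(rng.random(n_chains) < 0.5, 7, 0).astype(np.int64)
    counts = np.zeros((n_chains, 8), dtype=np.int64)
    rows = np.arange(n_chains)
    counts[rows, cur] = 1
    for _ in range(chain_length - 1):
        prop = cur ^ _FLIP_MASKS[rng.integers(0, 3, n_chains)]
        accept = rng.random(n_chains) * p[cur] < p[prop]
        cur = np.where(accept, prop, cur)
        counts[rows, cur] += 1
    return counts


def state_counts(chain: list[tuple[int, int, int]]) -> np.ndarray:
    """Per-state visit tallies N(state) for one chain, in state-index order."""
    if not chain:
        raise ValueError("chain must be non-empty")
    counts = np.zeros(8, dtype=np.int64)
    for state in chain:
        counts[state_index(state)] += 1
    return counts
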