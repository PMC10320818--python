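"""Three-variable causal Bayesian networks and exact inference.

The package models judgments about small causal systems with three binary
variables.  Following the usual convention, ``Y`` denotes the middle variable
and ``X1``/``X2`` the terminal variables, so the three supported topologies are

* ``chain``:          X1 -> Y -> X2
* ``common_cause``:   X1 <- Y -> X2
* ``common_effect``:  X1 -> Y <- X2   (noisy-OR combination of the causes)

Joint-state ordering convention
-------------------------------
The eight joint states of ``(X1, Y, X2)`` are indexed by the bit triple
``x1*4 + y*2 + x2``; index 0 is ``(0, 0, 0)`` and index 7 is ``(1, 1, 1)``.
This ordering is fixed so that visit counts and CSV exports are stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "VARIABLES",
    "STATES",
    "STRUCTURES",
    "CausalParameters",
    "JointDistribution",
    "Query",
    "state_index",
    "build_joint",
    "default_joint",
    "marginal",
    "normative_probability",
    "enumerate_queries",
    "query_masks",
    "network_from_config",
    "load_network",
]

VARIABLES: tuple[str, str, str] = ("X1", "Y", "X2")
STRUCTURES: tuple[str, str, str] = ("chain", "common_cause", "common_effect")

#: All eight network states as (X1, Y, X2) triples, in index order.
STATES: tuple[tuple[int, int, int], ...] = tuple(
    ((i >> 2) & 1, (i >> 1) & 1, i & 1) for i in range(8)
)

#: The two prototype states: all variables present / all absent.
PROTOTYPES: tuple[tuple[int, int, int], tuple[int, int, int]] = ((1, 1, 1), (0, 0, 0))


def state_index(state: Sequence[int]) -> int:
    """Index of a ``(X1, Y, X2)`` state under the package ordering."""
    x1, y, x2 = state
    return int(x1) * 4 + int(y) * 2 + int(x2)


def _check_prob(p: float, name: str) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    return p


@dataclass(frozen=True)
class CausalParameters:
    """Parameterization of a three-variable network.

    Parameters
    ----------
    base_rate : float
        Marginal probability of presence for every root variable.
    link_present, link_absent : float
        For chain and common-cause structures: probability that a child is
        present given its parent is present / absent.
    strengths : (float, float)
        Noisy-OR causal strengths of ``X1`` and ``X2`` on ``Y`` in the
        common-effect structure.
    leak : float
        Noisy-OR leak: probability the effect occurs with no cause present.

    The defaults are the parameterization taught in the experiments this
    package emulates: base rates .5, child probabilities .75/.25, noisy-OR
    strengths .5 with zero leak (so the effect never occurs without a cause).
    """

    base_rate: float = 0.5
    link_present: float = 0.75
    link_absent: float = 0.25
    strengths: tuple[float, float] = (0.5, 0.5)
    leak: float = 0.0

    def __post_init__(self) -> None:
        _check_prob(self.base_rate, "base_rate")
        _check_prob(self.link_present, "link_present")
        _check_prob(self.link_absent, "link_absent")
        if len(self.strengths) != 2:
            raise ValueError("strengths must provide one value per cause")
        for s in self.strengths:
            _check_prob(s, "strength")
        _check_prob(self.leak, "leak")

    def noisy_or(self, x1: int, x2: int) -> float:
        """P(Y=1 | X1=x1, X2=x2) under the noisy-OR gate."""
        q = 1.0 - self.leak
        if x1:
            q *= 1.0 - self.strengths[0]
        if x2:
            q *= 1.0 - self.strengths[1]
        return 1.0 - q


@dataclass(frozen=True)
class JointDistribution:
    """Exact joint distribution over the eight network states.

    ``probs[i]`` is the probability of ``STATES[i]``.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.shape != (8,):
            raise ValueError("a joint over three binary variables has 8 states")
        if np.any(arr < 0.0):
            raise ValueError("joint probabilities must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError("joint probabilities must sum to 1")
        object.__setattr__(self, "probs", arr)

    def prob(self, state: Sequence[int]) -> float:
        return float(self.probs[state_index(state)])

    def as_dict(self) -> dict[tuple[int, int, int], float]:
        return {s: float(self.probs[i]) for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class Query:
    """One conditional-probability query over the network.

    ``target`` is the queried variable, asked at ``target_value`` (present=1
    by default, matching the experimental design).  ``conditioning`` assigns
    binary values to a subset of the other variables; variables not mentioned
    are unknown and are marginalized over.
    """

    target: str
    target_value: int = 1
    conditioning: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.target not in VARIABLES:
            raise ValueError(f"unknown variable {self.target!r}")
        if self.target_value not in (0, 1):
            raise ValueError("target_value must be 0 or 1")
        seen = set()
        for var, val in self.conditioning:
            if var not in VARIABLES:
                raise ValueError(f"unknown variable {var!r}")
            if var == self.target:
                raise ValueError("target may not appear in the conditioning set")
            if var in seen:
                raise ValueError(f"variable {var!r} conditioned twice")
            if val not in (0, 1):
                raise ValueError("conditioning values must be 0 or 1")
            seen.add(var)
        # canonical variable order makes Query hashable/comparable regardless
        # of the order the caller supplied
        ordered = tuple(
            sorted(self.conditioning, key=lambda item: VARIABLES.index(item[0]))
        )
        object.__setattr__(self, "conditioning", ordered)

    @property
    def given(self) -> dict[str, int]:
        return dict(self.conditioning)

    @property
    def label(self) -> str:
        cond = ", ".join(f"{v}={s}" for v, s in self.conditioning)
        head = f"P({self.target}={self.target_value}"
        return head + (f" | {cond})" if cond else ")")


def build_joint(structure: str, params: CausalParameters | None = None) -> JointDistribution:
    """Exact product-form joint for one of the three structures.

    For the common-effect structure the two causes combine through a noisy-OR
    gate: ``P(Y=1 | causes) = 1 - (1-leak) * prod over present causes of
    (1-strength)``.
    """
    params = params or CausalParameters()
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    probs = np.empty(8)
    br = params.base_rate
    for i, (x1, y, x2) in enumerate(STATES):
        if structure == "chain":
            p_x1 = br if x1 else 1.0 - br
            p_y1 = params.link_present if x1 else params.link_absent
            p_y = p_y1 if y else 1.0 - p_y1
            p_x21 = params.link_present if y else params.link_absent
            p_x2 = p_x21 if x2 else 1.0 - p_x21
            probs[i] = p_x1 * p_y * p_x2
        elif structure == "common_cause":
            p_y = br if y else 1.0 - br
            p_x11 = params.link_present if y else params.link_absent
            p_x21 = params.link_present if y else params.link_absent
            p_x1 = p_x11 if x1 else 1.0 - p_x11
            p_x2 = p_x21 if x2 else 1.0 - p_x21
            probs[i] = p_y * p_x1 * p_x2
        else:  # common_effect
            p_x1 = br if x1 else 1.0 - br
            p_x2 = br if x2 else 1.0 - br
            p_y1 = params.noisy_or(x1, x2)
            p_y = p_y1 if y else 1.0 - p_y1
            probs[i] = p_x1 * p_x2 * p_y
    return JointDistribution(probs)


def default_joint(structure: str) -> JointDistribution:
    """Joint under the default (taught) parameterization."""
    return build_joint(structure, CausalParameters())


def _assignment_mask(assignment: Mapping[str, int]) -> np.ndarray:
    mask = np.ones(8, dtype=bool)
    for var, val in assignment.items():
        axis = VARIABLES.index(var)
        mask &= np.array([s[axis] == val for s in STATES])
    return mask


def query_masks(query: Query) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over the 8 states for the query's two outcome sets.

    The first mask selects states consistent with the conditioning where the
    target takes ``target_value``; the second selects the complementary
    target outcome.  Unknown variables contribute both of their values.
    """
    base = dict(query.conditioning)
    match = _assignment_mask({**base, query.target: query.target_value})
    other = _assignment_mask({**base, query.target: 1 - query.target_value})
    return match, other


def marginal(joint: JointDistribution, variable: str, value: int) -> float:
    """Exact marginal probability P(variable = value)."""
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    return float(joint.probs[_assignment_mask({variable: value})].sum())


def normative_probability(joint: JointDistribution, query: Query) -> float:
    """Exact conditional probability of the query under the joint.

    Raises
    ------
    ValueError
        If the conditioning event has zero probability (the conditional is
        undefined; the 0.5 default belongs to the sampler-based estimators,
        not to exact inference).
    """
    match, other = query_masks(query)
    p_match = float(joint.probs[match].sum())
    p_other = float(joint.probs[other].sum())
    denom = p_match + p_other
    if denom <= 0.0:
        raise ValueError(f"conditioning event of {query.label} has probability 0")
    return p_match / denom


def enumerate_queries() -> list[Query]:
    """The 27 inferences of the experimental design, in a fixed stable order.

    Each trial queries one variable (asked at value 1) while each of the two
    non-queried variables is either present, absent, or unknown: 3 targets x
    3 x 3 conditioning states = 27 distinct queries, including 3 pure
    base-rate queries (both non-targets unknown).
    """
    queries: list[Query] = []
    for target in VARIABLES:
        others = [v for v in VARIABLES if v != target]
        for v1 in (1, 0, None):
            for v2 in (1, 0, None):
                cond = tuple(
                    (var, val) for var, val in zip(others, (v1, v2)) if val is not None
                )
                queries.append(Query(target=target, conditioning=cond))
    return queries


def network_from_config(config: Mapping) -> tuple[str, CausalParameters, JointDistribution]:
    """Build a network from a config mapping.

    Recognized keys: ``structure`` (required), ``base_rate``, ``link_present``,
    ``link_absent``, ``strengths``, ``leak``.  Missing keys fall back to the
    default taught parameterization.
    """
    if "structure" not in config:
        raise ValueError("network config requires a 'structure' key")
    structure = config["structure"]
    kwargs = {}
    for key in ("base_rate", "link_present", "link_absent", "leak"):
        if key in config:
            kwargs[key] = float(config[key])
    if "strengths" in config:
        kwargs["strengths"] = tuple(float(s) for s in config["strengths"])
    params = CausalParameters(**kwargs)
    return structure, params, build_joint(structure, params)


def load_network(path: str | Path) -> tuple[str, CausalParameters, JointDistribution]:
    """Read a network spec from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    config = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return network_from_config(config)
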