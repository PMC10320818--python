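"""Distributional summaries of observed or simulated judgments.

Implements the Gini Mean Difference dispersion index, the accuracy and
conservatism scores, and the symmetry-based collapsing of the 27 inferences
into seven groups (chain and common-cause structures only; the two share one
normative joint).  Collapsing pools queries related by terminal-variable
exchange, by presence/absence mirroring (responses to queries whose normative
probability is below 50% are flipped to ``100 - response``), and by
unknown-variable symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .networks import Query, default_joint, normative_probability

__all__ = [
    "InferenceGroup",
    "GROUPS",
    "gmd",
    "accuracy",
    "conservatism",
    "flip_value",
    "assign_group",
    "collapse_responses",
    "group_summary",
    "predicted_group_gmd",
]

#: Variable pairs joined by an edge (ignoring direction) in both the chain
#: (X1 -> Y -> X2) and common-cause (X1 <- Y -> X2) structures.
_ADJACENT = {frozenset({"X1", "Y"}), frozenset({"Y", "X2"})}

_COLLAPSIBLE_STRUCTURES = ("chain", "common_cause")


@dataclass(frozen=True)
class InferenceGroup:
    """One of the seven symmetry groups of inferences."""

    id: int
    label: str
    normative: float  # canonical normative response, percent
    obs_per_participant: int  # over 2 structures x 3 deadlines


GROUPS: dict[int, InferenceGroup] = {
    g.id: g
    for g in [
        InferenceGroup(1, "Conflict 1", 75.0, 24),
        InferenceGroup(2, "Conflict 2", 50.0, 12),
        InferenceGroup(3, "Ambiguous 1", 75.0, 48),
        InferenceGroup(4, "Ambiguous 2", 62.5, 24),
        InferenceGroup(5, "Consistent 1", 75.0, 24),
        InferenceGroup(6, "Consistent 2", 90.0, 12),
        InferenceGroup(7, "Base rates", 50.0, 18),
    ]
}


def gmd(values: Sequence[float]) -> float:
    """Gini Mean Difference: mean |v_i - v_j| over all unordered pairs.

    Computed via the sorted-sample identity in O(n log n); identical to the
    mean over ordered pairs i != j.
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("GMD requires at least two observations")
    i = np.arange(n)
    pair_sum = float(np.sum((2 * i - (n - 1)) * x))
    return pair_sum / (n * (n - 1) / 2)


def accuracy(response: float, normative: float) -> float:
    """Negated absolute distance from the normative answer (higher = better)."""
    return -abs(float(response) - float(normative))


def conservatism(response: float) -> float:
    """Negated absolute distance from 50% (higher = more conservative)."""
    return -abs(float(response) - 50.0)


def flip_value(response: float) -> float:
    """Presence/absence mirror on the percent scale."""
    return 100.0 - float(response)


def assign_group(query: Query, structure: str) -> tuple[int, bool]:
    """Symmetry group and flip flag for one query.

    The group is determined by how many conditioning variables are known,
    whether their values agree, and whether the queried variable is the
    middle variable (two known) or graph-adjacent to the known one (one
    known).  The flip flag is true iff the query's exact normative
    probability is below 50%, in which case the canonical response is
    ``100 - response``; exactly-50% queries are never flipped.
    """
    if structure not in _COLLAPSIBLE_STRUCTURES:
        raise ValueError(
            f"grouping is defined for {_COLLAPSIBLE_STRUCTURES}, got {structure!r}"
        )
    known = dict(query.conditioning)
    if len(known) == 0:
        group = 7
    elif len(known) == 1:
        (var,) = known
        adjacent = frozenset({query.target, var}) in _ADJACENT
        group = 3 if adjacent else 4
    else:
        values = set(known.values())
        consistent = len(values) == 1
        middle = query.target == "Y"
        if consistent:
            group = 6 if middle else 5
        else:
            group = 2 if middle else 1
    p = normative_probability(default_joint(structure), query)
    return group, p < 0.5


def collapse_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Collapse a trial table into canonical grouped responses.

    Rows for the common-effect structure are dropped (too few symmetric
    observations for stable variability estimates).  Returns a tidy frame
    with participant, structure, deadline, group, label, canonical_value.
    """
    from .synthetic import row_to_query

    records = []
    for _, row in responses.iterrows():
        if row["structure"] not in _COLLAPSIBLE_STRUCTURES:
            continue
        query = row_to_query(row)
        group, flip = assign_group(query, row["structure"])
        value = flip_value(row["response"]) if flip else float(row["response"])
        records.append(
            {
                "participant": row["participant"],
                "structure": row["structure"],
                "deadline": row["deadline"],
                "group": group,
                "label": GROUPS[group].label,
                "canonical_value": value,
            }
        )
    return pd.DataFrame(records)


def group_summary(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Per participant x group mean and GMD of canonical responses."""
    out = (
        collapsed.groupby(["participant", "group"])["canonical_value"]
        .agg(mean="mean", gmd=gmd, n="size")
        .reset_index()
    )
    out["label"] = out["group"].map(lambda g: GROUPS[g].label)
    return out


def predicted_group_gmd(
    distributions: Sequence[np.ndarray],
    rng: np.random.Generator,
    n_draws: int = 10_000,
) -> float:
    """GMD of an equal-weight mixture of predicted response distributions.

    ``distributions`` are the per-query predicted response samples of one
    inference group (flips already applied), pooled over deadlines and
    structures.  Draws ``n_draws`` responses from the mixture and returns
    their GMD, mirroring how predicted variability is summarized.
    """
    arrays = [np.asarray(d, dtype=float).ravel() for d in distributions]
    if not arrays:
        raise ValueError("need at least one predicted distribution")
    which = rng.integers(0, len(arrays), n_draws)
    draws = np.empty(n_draws)
    for k, arr in enumerate(arrays):
        mask = which == k
        draws[mask] = arr[rng.integers(0, arr.size, int(mask.sum()))]
    return gmd(draws)
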