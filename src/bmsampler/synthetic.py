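"""Synthetic experiments: BMS responders on the full trial design.

Generates complete trial tables for the 27-query x 3-structure x 3-deadline
design (243 trials per participant), populated by simulated BMS responders
with known parameters.  Every downstream stage (collapsing, grid-search
fitting, model comparison, parameter recovery) can therefore be exercised
without any empirical download.

Deadline conditions are labels without behavioral effect by default; an
optional hook injects deadline-dependent chain lengths, and an optional
contamination rate mixes in uniform random responses for robustness checks.
Both are off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .networks import (
    STRUCTURES,
    VARIABLES,
    JointDistribution,
    Query,
    default_joint,
    enumerate_queries,
)
from .judgment import responses_from_counts
from .sampler import run_chains

__all__ = [
    "DEADLINES",
    "SCHEMA_COLUMNS",
    "SyntheticParticipant",
    "generate_design",
    "generate_participant",
    "generate_experiment",
    "query_to_row",
    "row_to_query",
    "validate_responses",
    "read_responses",
    "write_responses",
]

DEADLINES: tuple[str, str, str] = ("3s", "9s", "20s")

SCHEMA_COLUMNS: tuple[str, ...] = (
    "participant",
    "structure",
    "deadline",
    "x1_state",
    "y_state",
    "x2_state",
    "queried_var",
    "queried_value",
    "response",
)

_STATE_COLUMNS = {"X1": "x1_state", "Y": "y_state", "X2": "x2_state"}


@dataclass(frozen=True)
class SyntheticParticipant:
    """A simulated BMS responder with known true parameters."""

    id: str
    chain_length: int
    beta: float
    seed: int


def generate_design() -> list[tuple[str, str, Query]]:
    """All 243 (structure, deadline, query) trial cells in a stable order."""
    return [
        (structure, deadline, query)
        for structure in STRUCTURES
        for deadline in DEADLINES
        for query in enumerate_queries()
    ]


def query_to_row(query: Query) -> dict[str, object]:
    """Encode a query as the trial-table state/target columns."""
    row: dict[str, object] = {col: "unknown" for col in _STATE_COLUMNS.values()}
    for var, val in query.conditioning:
        row[_STATE_COLUMNS[var]] = str(val)
    row["queried_var"] = query.target
    row["queried_value"] = int(query.target_value)
    return row


def row_to_query(row: Mapping[str, object]) -> Query:
    """Decode one trial-table row back into a query."""
    target = str(row["queried_var"])
    conditioning = []
    for var in VARIABLES:
        if var == target:
            continue
        raw = str(row[_STATE_COLUMNS[var]])
        if raw != "unknown":
            conditioning.append((var, int(raw)))
    return Query(target=target, target_value=int(row["queried_value"]), conditioning=tuple(conditioning))


def generate_participant(
    participant: SyntheticParticipant,
    joints: Mapping[str, JointDistribution] | None = None,
    chain_length_by_deadline: Mapping[str, int] | None = None,
    contamination: float = 0.0,
) -> pd.DataFrame:
    """One participant's 243-trial table, fully reproducible from the seed.

    Each trial runs one fresh chain and maps it through the BMS judgment rule
    (times 100 to the percent scale).  ``chain_length_by_deadline`` optionally
    overrides the chain length per deadline; ``contamination`` replaces each
    response with a uniform draw on [0, 100] with the given probability.
    """
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination must be a probability")
    joints = joints or {s: default_joint(s) for s in STRUCTURES}
    rng = np.random.default_rng(participant.seed)
    queries = enumerate_queries()
    records = []
    for structure in STRUCTURES:
        joint = joints[structure]
        for deadline in DEADLINES:
            length = (
                chain_length_by_deadline[deadline]
                if chain_length_by_deadline is not None
                else participant.chain_length
            )
            counts = run_chains(joint, length, len(queries), rng)
            # chain i answers query i: one independent chain per trial
            table = responses_from_counts(counts, queries, participant.beta)
            responses = np.diagonal(table).copy()
            if contamination > 0:
                guess = rng.random(len(queries)) < contamination
                responses[guess] = 100.0 * rng.random(int(guess.sum()))
            for query, response in zip(queries, responses):
                record = {
                    "participant": participant.id,
                    "structure": structure,
                    "deadline": deadline,
                    **query_to_row(query),
                    "response": float(response),
                }
                records.append(record)
    return pd.DataFrame(records, columns=list(SCHEMA_COLUMNS))


def generate_experiment(
    n_participants: int,
    seed: int | None = None,
    chain_lengths: Sequence[int] | None = None,
    betas: Sequence[float] | None = None,
    contamination: float = 0.0,
) -> tuple[pd.DataFrame, list[SyntheticParticipant]]:
    """A full synthetic experiment with participants spanning the grid.

    True parameters are drawn uniformly from the supplied value sets
    (defaults: the full estimation grid).  Returns the pooled trial table and
    the list of participants with their true parameters.
    """
    from .fitting import FULL_CHAIN_LENGTHS, build_beta_grid

    if n_participants < 1:
        raise ValueError("need at least one participant")
    chain_lengths = list(chain_lengths) if chain_lengths is not None else list(FULL_CHAIN_LENGTHS)
    betas = list(betas) if betas is not None else list(build_beta_grid())
    rng = np.random.default_rng(seed)
    participants = []
    tables = []
    for i in range(n_participants):
        participant = SyntheticParticipant(
            id=f"S{i + 1:03d}",
            chain_length=int(rng.choice(chain_lengths)),
            beta=float(rng.choice(betas)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        participants.append(participant)
        tables.append(
            generate_participant(participant, contamination=contamination)
        )
    return pd.concat(tables, ignore_index=True), participants


def validate_responses(responses: pd.DataFrame) -> list[str]:
    """Schema check for a trial table; returns human-readable row errors."""
    errors: list[str] = []
    missing = [c for c in SCHEMA_COLUMNS if c not in responses.columns]
    if missing:
        return [f"missing columns: {missing}"]
    for idx, row in responses.iterrows():
        line = int(idx) + 2  # 1-based with header
        if row["structure"] not in STRUCTURES:
            errors.append(f"line {line}: unknown structure {row['structure']!r}")
            continue
        try:
            query = row_to_query(row)
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
            continue
        state_col = _STATE_COLUMNS[query.target]
        if str(row[state_col]) != "unknown":
            errors.append(f"line {line}: queried variable must be marked 'unknown'")
        try:
            response = float(row["response"])
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric response {row['response']!r}")
            continue
        if not 0.0 <= response <= 100.0:
            errors.append(f"line {line}: response {response} outside [0, 100]")
    return errors


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index=False)


def read_responses(path: str | Path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in ("x1_state", "y_state", "x2_state")})
    if validate:
        errors = validate_responses(df)
        if errors:
            raise ValueError("invalid response table:\n" + "\n".join(errors[:20]))
    return df
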