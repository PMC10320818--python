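"""Grid-search fitting of the MS/BMS by kernel-density synthetic likelihood.

Neither model has a closed-form likelihood, so fitting follows the
probability-density-approximation (PDA) approach: for every cell of a
(chain length, beta) grid, simulate a large set of model responses per query,
smooth each simulated set with a Gaussian kernel density estimate, and score
the observed responses by the summed log of the estimated densities.  The
estimated parameters are the grid cell with the highest synthetic
log-likelihood; models are compared by BIC (k = 1 free parameter for the MS,
k = 2 for the BMS) and BIC weights.

The beta grid is built on a symmetry principle: every sub-uniform prior
(beta < 1) is paired with the supra-uniform beta > 1 whose Beta(beta, beta)
distribution has the same total variation distance from the uniform
distribution; beta = 100 stands in as the counterpart of beta = 0 (a
Beta(inf, inf) prior would put every response at exactly 50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .networks import (
    JointDistribution,
    Query,
    build_joint,
    default_joint,
    enumerate_queries,
)
from .judgment import responses_from_counts
from .sampler import run_chains

__all__ = [
    "FULL_CHAIN_LENGTHS",
    "ParameterGrid",
    "FitResult",
    "beta_tvd",
    "matched_beta",
    "build_beta_grid",
    "silverman_bandwidth",
    "kde_log_density",
    "pda_log_likelihood",
    "SimulationBank",
    "BMSGridSearch",
    "fit_unit",
    "bic",
    "bic_weights",
    "fit_dataset",
    "compare_models",
    "parameter_recovery",
    "recovery_correlations",
]

#: Chain lengths of the full estimation grid: 2, 4, ..., 70 (35 values).
FULL_CHAIN_LENGTHS: tuple[int, ...] = tuple(range(2, 71, 2))

#: Density floor preventing -inf synthetic log-likelihoods.
DENSITY_FLOOR = 1e-10

#: Fallback kernel bandwidth (percent points) for degenerate simulated sets.
FALLBACK_BANDWIDTH = 2.0


def beta_tvd(beta: float) -> float:
    """Total variation distance between Beta(beta, beta) and the uniform.

    TVD = 1/2 * integral over [0, 1] of \\|f(x) - 1\\| dx.  The symmetric Beta
    density crosses 1 at exactly two points symmetric about 1/2, so the
    integral reduces to 2 * \\|F(x0) - x0\\| with x0 the crossing in (0, 1/2);
    the crossing is found by root-solving, giving absolute accuracy well
    below 1e-6.
    """
    if beta <= 0:
        raise ValueError(
            "beta must be positive (Beta(0,0) is the two-point extreme prior "
            "and has no density)"
        )
    if beta == 1:
        return 0.0
    dist = stats.beta(beta, beta)
    # log f is monotone on (0, 1/2): increasing for beta > 1, decreasing for
    # beta < 1, so f(x) = 1 has a unique crossing there
    lo, hi = 1e-12, 0.5 - 1e-12
    x0 = optimize.brentq(lambda x: dist.logpdf(x), lo, hi, xtol=1e-13)
    return 2.0 * abs(dist.cdf(x0) - x0)


def matched_beta(beta0: float) -> float:
    """The beta > 1 whose prior is as far from uniform as Beta(beta0, beta0)."""
    if not 0 < beta0 < 1:
        raise ValueError("beta0 must lie strictly between 0 and 1")
    target = beta_tvd(beta0)
    return optimize.brentq(lambda b: beta_tvd(b) - target, 1.0 + 1e-9, 1e4, xtol=1e-10)


def build_beta_grid() -> tuple[float, ...]:
    """The 21-value beta grid: 0, 0.1..0.9, 1, the nine TVD-matched values, 100."""
    subs = [round(0.1 * i, 1) for i in range(1, 10)]
    matched = sorted(matched_beta(b) for b in subs)
    return tuple([0.0] + subs + [1.0] + matched + [100.0])


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered (chain length, beta) estimation grid."""

    chain_lengths: tuple[int, ...]
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.chain_lengths or not self.betas:
            raise ValueError("grid must contain at least one value per parameter")
        object.__setattr__(self, "chain_lengths", tuple(int(c) for c in self.chain_lengths))
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))

    @property
    def size(self) -> int:
        return len(self.chain_lengths) * len(self.betas)

    @classmethod
    def full(cls) -> "ParameterGrid":
        """The full 35 x 21 = 735-cell estimation grid."""
        return cls(FULL_CHAIN_LENGTHS, build_beta_grid())

    @classmethod
    def coarse(cls) -> "ParameterGrid":
        """Coarser grid used for parameter-recovery refits.

        Every other chain length (2, 6, ..., 70) and a spread of eleven beta
        values covering both halves of the full beta grid.
        """
        return cls(
            tuple(range(2, 71, 4)),
            (0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.45, 2.14, 4.14, 21.54, 100.0),
        )


def silverman_bandwidth(values: np.ndarray) -> float | None:
    """Silverman rule-of-thumb bandwidth; None if the sample is degenerate."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        return None
    std = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    sigma = min(std, iqr / 1.349) if iqr > 0 else std
    if not np.isfinite(sigma) or sigma < 1e-8:
        return None
    return 0.9 * sigma * n ** (-0.2)


def kde_log_density(
    simulated: np.ndarray,
    observed: np.ndarray,
    bandwidth: float | None = None,
    fallback_bandwidth: float = FALLBACK_BANDWIDTH,
    floor: float = DENSITY_FLOOR,
) -> np.ndarray:
    """Log Gaussian-KDE density of ``observed`` under ``simulated``.

    The bandwidth defaults to Silverman's rule on the simulated set, with a
    fixed fallback when the simulated responses are (near-)degenerate.  The
    density is floored so observations far outside the simulated support
    yield a finite log-density.
    """
    simulated = np.asarray(simulated, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if simulated.size == 0:
        raise ValueError("simulated response set must be non-empty")
    bw = bandwidth if bandwidth is not None else silverman_bandwidth(simulated)
    if bw is None or bw <= 0:
        bw = fallback_bandwidth
    z = (observed[:, None] - simulated[None, :]) / bw
    dens = np.exp(-0.5 * z * z).mean(axis=1) / (bw * math.sqrt(2.0 * math.pi))
    return np.log(np.maximum(dens, floor))


def pda_log_likelihood(
    simulated: np.ndarray,
    observed: Sequence[float],
    bandwidth: float | None = None,
    fallback_bandwidth: float = FALLBACK_BANDWIDTH,
    floor: float = DENSITY_FLOOR,
) -> float:
    """Synthetic log-likelihood of observed responses for one query."""
    observed = np.asarray(list(observed), dtype=float)
    if observed.size == 0:
        return 0.0
    return float(
        kde_log_density(simulated, observed, bandwidth, fallback_bandwidth, floor).sum()
    )


def bic(log_likelihood: float, k: int, n_obs: int) -> float:
    """Bayesian information criterion ``k ln(n) - 2 logL``."""
    if n_obs < 1:
        raise ValueError("n_obs must be positive")
    return k * math.log(n_obs) - 2.0 * log_likelihood


def bic_weights(bics: Sequence[float]) -> np.ndarray:
    """BIC weights exp(-delta/2)/sum; approximate posterior model probabilities."""
    bics = np.asarray(list(bics), dtype=float)
    if bics.size < 2:
        raise ValueError("model comparison needs at least two BIC values")
    delta = bics - bics.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


class SimulationBank:
    """Pre-simulated model responses for every grid cell and query.

    Because the simulated grid does not depend on the data being fitted, it
    can be built once and reused across participants and conditions.  Chains
    are shared across beta values at the same chain length (the prior enters
    only the judgment rule), and across queries within a cell.
    """

    def __init__(
        self,
        joint: JointDistribution,
        grid: ParameterGrid,
        queries: Sequence[Query],
        n_sims: int,
        rng: np.random.Generator,
    ):
        self.grid = grid
        self.queries = list(queries)
        self.n_sims = int(n_sims)
        self._responses: dict[tuple[int, float], np.ndarray] = {}
        for length in grid.chain_lengths:
            counts = run_chains(joint, length, self.n_sims, rng)
            for beta in grid.betas:
                table = responses_from_counts(counts, self.queries, beta)
                self._responses[(length, beta)] = table.astype(np.float32)

    def responses(self, chain_length: int, beta: float) -> np.ndarray:
        """Simulated ``(n_sims, n_queries)`` response table for one cell."""
        return self._responses[(int(chain_length), float(beta))]


@dataclass(frozen=True)
class FitResult:
    """Best grid cell for one participant x condition unit."""

    model: str
    chain_length: int
    beta: float
    log_likelihood: float
    bic: float
    n_obs: int


class BMSGridSearch(BaseEstimator):
    """Grid-search estimator for the BMS (or MS) by synthetic likelihood.

    Fits one unit of observed responses (one participant in one condition,
    27 responses in the standard design) by simulating the model at every
    grid cell and maximizing the summed per-query kernel-density synthetic
    log-likelihood.  The MS is the beta = 0 row of the same grid, so
    ``model='ms'`` restricts the search and uses k = 1 in the BIC.

    Parameters
    ----------
    model : {'bms', 'ms'}
    grid : ParameterGrid, optional
        Defaults to the full 35 x 21 grid.
    structure : str
        Network used to simulate (default 'common_cause'); ignored when a
        prebuilt ``simulations`` bank is supplied.
    n_sims : int
        Simulated responses per grid cell.
    bandwidth : float, optional
        Fixed KDE bandwidth; default Silverman's rule per simulated set.
    fallback_bandwidth, density_floor : float
        Degenerate-set bandwidth and density floor of the PDA likelihood.
    simulations : SimulationBank, optional
        Reusable pre-simulated grid (recommended when fitting many units).
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    chain_length_, beta_ : best-fitting parameters
    log_likelihood_ : synthetic log-likelihood at the optimum
    bic_ : BIC with k = 2 ('bms') or k = 1 ('ms')
    n_obs_ : number of responses fitted
    loglik_grid_ : DataFrame of the synthetic log-likelihood over all cells
    """

    def __init__(
        self,
        model: str = "bms",
        grid: ParameterGrid | None = None,
        structure: str = "common_cause",
        n_sims: int = 10_000,
        bandwidth: float | None = None,
        fallback_bandwidth: float = FALLBACK_BANDWIDTH,
        density_floor: float = DENSITY_FLOOR,
        simulations: SimulationBank | None = None,
        random_state=None,
    ):
        self.model = model
        self.grid = grid
        self.structure = structure
        self.n_sims = n_sims
        self.bandwidth = bandwidth
        self.fallback_bandwidth = fallback_bandwidth
        self.density_floor = density_floor
        self.simulations = simulations
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _unit_loglik(self, sims: np.ndarray, observed: np.ndarray) -> float:
        total = 0.0
        for j in range(observed.size):
            total += float(
                kde_log_density(
                    sims[:, j],
                    observed[j : j + 1],
                    self.bandwidth,
                    self.fallback_bandwidth,
                    self.density_floor,
                )[0]
            )
        return total

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None, queries: Sequence[Query] | None = None):
        """Fit one unit of responses.

        ``X`` is a 1-D array of responses on the 0-100 scale, aligned with
        ``queries`` (default: the canonical order of
        :func:`~bmsampler.networks.enumerate_queries`).
        """
        if self.model not in ("bms", "ms"):
            raise ValueError("model must be 'bms' or 'ms'")
        observed = np.asarray(X, dtype=float).ravel()
        if observed.size == 0:
            raise ValueError("cannot fit an empty set of responses")
        if not np.all(np.isfinite(observed)):
            raise ValueError("responses must be finite")
        if observed.min() < 0 or observed.max() > 100:
            raise ValueError("responses must lie on the 0-100 scale")

        queries = list(queries) if queries is not None else enumerate_queries()
        if self.simulations is not None:
            bank = self.simulations
            grid = bank.grid
            if len(bank.queries) != len(queries):
                raise ValueError("simulation bank was built for a different query set")
        else:
            bank = None
            grid = self.grid or ParameterGrid.full()
        if observed.size != len(queries):
            raise ValueError(
                f"expected one response per query ({len(queries)}), got {observed.size}"
            )

        betas = grid.betas if self.model == "bms" else (0.0,)
        if self.model == "ms" and 0.0 not in grid.betas and bank is not None:
            raise ValueError("simulation bank lacks the beta = 0 row needed for 'ms'")
        rng = np.random.default_rng(self.random_state)
        joint = build_joint(self.structure) if bank is None else None

        records = []
        best = None  # (loglik, chain_length, beta); ties -> smaller cl, then beta
        for length in grid.chain_lengths:
            counts = None
            if bank is None:
                counts = run_chains(joint, length, self.n_sims, rng)
            for beta in betas:
                if bank is not None:
                    sims = bank.responses(length, beta)
                else:
                    sims = responses_from_counts(counts, queries, beta)
                ll = self._unit_loglik(sims, observed)
                records.append({"chain_length": length, "beta": beta, "loglik": ll})
                if best is None or ll > best[0]:
                    best = (ll, length, beta)

        k = 2 if self.model == "bms" else 1
        self.queries_ = queries
        self.loglik_grid_ = pd.DataFrame(records)
        self.log_likelihood_ = best[0]
        self.chain_length_ = best[1]
        self.beta_ = best[2]
        self.n_obs_ = int(observed.size)
        self.k_ = k
        self.bic_ = bic(self.log_likelihood_, k, self.n_obs_)
        return self

    def predict(self, queries: Sequence[Query] | None = None) -> np.ndarray:
        """Mean predicted response per query at the fitted parameters."""
        if not hasattr(self, "chain_length_"):
            raise AttributeError("estimator is not fitted")
        queries = list(queries) if queries is not None else self.queries_
        joint = build_joint(self.structure)
        counts = run_chains(
            joint, self.chain_length_, self.n_sims, np.random.default_rng(self.random_state)
        )
        return responses_from_counts(counts, queries, self.beta_).mean(axis=0)

    def score(self, X, y=None) -> float:
        """Synthetic log-likelihood of ``X`` at the fitted parameters."""
        if not hasattr(self, "chain_length_"):
            raise AttributeError("estimator is not fitted")
        observed = np.asarray(X, dtype=float).ravel()
        if self.simulations is not None:
            sims = self.simulations.responses(self.chain_length_, self.beta_)
        else:
            joint = build_joint(self.structure)
            counts = run_chains(
                joint, self.chain_length_, self.n_sims, np.random.default_rng(self.random_state)
            )
            sims = responses_from_counts(counts, self.queries_, self.beta_)
        return self._unit_loglik(sims, observed)


def fit_unit(
    observed: Sequence[float],
    grid: ParameterGrid | None = None,
    model: str = "bms",
    structure: str = "common_cause",
    n_sims: int = 10_000,
    queries: Sequence[Query] | None = None,
    simulations: SimulationBank | None = None,
    random_state=None,
) -> FitResult:
    """Functional wrapper over :class:`BMSGridSearch` for one unit."""
    est = BMSGridSearch(
        model=model,
        grid=grid,
        structure=structure,
        n_sims=n_sims,
        simulations=simulations,
        random_state=random_state,
    ).fit(observed, queries=queries)
    return FitResult(
        model=model,
        chain_length=est.chain_length_,
        beta=est.beta_,
        log_likelihood=est.log_likelihood_,
        bic=est.bic_,
        n_obs=est.n_obs_,
    )


def _observed_vector(unit_df: pd.DataFrame, queries: Sequence[Query]) -> np.ndarray:
    """Align a unit's rows with the canonical query order."""
    from .synthetic import row_to_query

    index = {q: i for i, q in enumerate(queries)}
    obs = np.full(len(queries), np.nan)
    for _, row in unit_df.iterrows():
        q = row_to_query(row)
        obs[index[q]] = row["response"]
    if np.isnan(obs).any():
        missing = [q.label for q, i in index.items() if np.isnan(obs[i])]
        raise ValueError(f"unit is missing responses for: {missing[:5]}")
    return obs


def fit_dataset(
    responses: pd.DataFrame,
    grid: ParameterGrid | None = None,
    models: Sequence[str] = ("bms", "ms"),
    n_sims: int = 10_000,
    random_state=None,
) -> pd.DataFrame:
    """Fit every participant x structure x deadline unit with each model.

    One simulation bank per structure is shared across all units.  Returns a
    tidy frame with one row per unit x model (participant, structure,
    deadline, model, chain_length, beta, loglik, bic, n_obs).
    """
    grid = grid or ParameterGrid.full()
    rng = np.random.default_rng(random_state)
    queries = enumerate_queries()
    banks: dict[str, SimulationBank] = {}
    for structure in sorted(responses["structure"].unique()):
        banks[structure] = SimulationBank(
            default_joint(structure), grid, queries, n_sims, rng
        )
    rows = []
    group_cols = ["participant", "structure", "deadline"]
    for (participant, structure, deadline), unit in responses.groupby(group_cols):
        obs = _observed_vector(unit, queries)
        for model in models:
            res = fit_unit(
                obs,
                model=model,
                queries=queries,
                simulations=banks[structure],
            )
            rows.append(
                {
                    "participant": participant,
                    "structure": structure,
                    "deadline": deadline,
                    "model": model,
                    "chain_length": res.chain_length,
                    "beta": res.beta,
                    "loglik": res.log_likelihood,
                    "bic": res.bic,
                    "n_obs": res.n_obs,
                }
            )
    return pd.DataFrame(rows)


def parameter_recovery(
    n_participants: int = 30,
    grid: ParameterGrid | None = None,
    true_chain_lengths: Sequence[int] | None = None,
    true_betas: Sequence[float] | None = None,
    structure: str = "common_cause",
    n_sims: int = 2_000,
    random_state=None,
) -> pd.DataFrame:
    """Generate-and-refit recovery study for the BMS grid search.

    Each synthetic participant gets true parameters drawn uniformly from the
    full grid (or the supplied value sets) and produces one unit of 27 BMS
    responses, which is refit by grid search on ``grid`` (default: the coarse
    recovery grid) with ``n_sims`` simulations per cell.  Returns one row per
    participant with true and estimated parameters; Pearson correlations are
    the recovery summary (see :func:`recovery_correlations`).
    """
    if n_participants < 2:
        raise ValueError("recovery needs at least two participants")
    grid = grid or ParameterGrid.coarse()
    true_chain_lengths = (
        list(true_chain_lengths) if true_chain_lengths is not None else list(FULL_CHAIN_LENGTHS)
    )
    true_betas = list(true_betas) if true_betas is not None else list(build_beta_grid())
    rng = np.random.default_rng(random_state)
    queries = enumerate_queries()
    joint = default_joint(structure)
    bank = SimulationBank(joint, grid, queries, n_sims, rng)
    rows = []
    for i in range(n_participants):
        true_cl = int(rng.choice(true_chain_lengths))
        true_beta = float(rng.choice(true_betas))
        counts = run_chains(joint, true_cl, len(queries), rng)
        observed = np.diagonal(responses_from_counts(counts, queries, true_beta)).copy()
        res = fit_unit(observed, model="bms", queries=queries, simulations=bank)
        rows.append(
            {
                "participant": f"R{i + 1:03d}",
                "true_chain_length": true_cl,
                "true_beta": true_beta,
                "est_chain_length": res.chain_length,
                "est_beta": res.beta,
                "loglik": res.log_likelihood,
                "bic": res.bic,
            }
        )
    return pd.DataFrame(rows)


def recovery_correlations(recovery: pd.DataFrame) -> dict[str, float]:
    """Pearson correlations between true and estimated parameters."""
    return {
        "chain_length": float(
            np.corrcoef(recovery["true_chain_length"], recovery["est_chain_length"])[0, 1]
        ),
        "beta": float(np.corrcoef(recovery["true_beta"], recovery["est_beta"])[0, 1]),
    }


def compare_models(fits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit delta BIC / BIC weights and per-participant mean weights.

    Returns ``(per_unit, per_participant)``.  ``delta_bic`` is BIC(BMS) -
    BIC(MS), so negative values favor the BMS; per-participant posterior
    model probabilities are the arithmetic mean of the unit-level weights.
    """
    wide = fits.pivot_table(
        index=["participant", "structure", "deadline"], columns="model", values="bic"
    )
    if not {"bms", "ms"} <= set(wide.columns):
        raise ValueError("comparison requires both 'bms' and 'ms' fits")
    records = []
    for (participant, structure, deadline), row in wide.iterrows():
        w_bms, w_ms = bic_weights([row["bms"], row["ms"]])
        records.append(
            {
                "participant": participant,
                "structure": structure,
                "deadline": deadline,
                "delta_bic": row["bms"] - row["ms"],
                "weight_bms": w_bms,
                "weight_ms": w_ms,
            }
        )
    per_unit = pd.DataFrame(records)
    per_participant = (
        per_unit.groupby("participant")[["weight_bms", "weight_ms"]]
        .mean()
        .reset_index()
    )
    return per_unit, per_participant
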