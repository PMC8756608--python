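"""Synthetic agent populations and seeded choice simulation.

Populations stand in for experimental participants.  Two generators are
supported:

``cpt``
    The *well-specified* case: agents choose from the prospect-theory
    accept-reject model itself, with heterogeneous loss aversion
    (λ log-normal, median 2, log-sd 0.3) and response bias
    (normal, mean 0, sd 0.5); curvature and choice sensitivity are fixed
    across agents.  Data simulated this way are the positive control: the
    fitted model family matches the generator, so λ ranks should recover.

``dbs``
    The *misspecified* case: agents choose by decision-by-sampling rank
    comparison (sensitivity normal around 3, fixed tremble), using each
    condition's own attribute levels as the comparison context.  Fitting
    the prospect-theory model to these choices creates an omitted-variable
    problem, which is the phenomenon under study.

Latent accept probabilities are resolved into Bernoulli accept/reject
decisions.  A master seed streams per-agent (and per-condition) sub-seeds
through ``numpy.random.SeedSequence([master_seed, agent_index, ...])``, so
any slice of a population is reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from . import cpt as _cpt
from .cpt import CHOICE_COLUMNS, CPTParams
from .dbs import ComparisonContext, DbSParams, dbs_accept_probability
from .design import Condition
from .errors import InvalidInputError

CPT_HYPERPARAM_DEFAULTS: dict[str, float] = {
    "lam_median": 2.0,   # λ ~ log-normal with this median
    "lam_log_sd": 0.3,   # sd of log λ
    "bias_mean": 0.0,
    "bias_sd": 0.5,
    "mu": 1.0,           # fixed across agents
    "alpha": 0.9,        # fixed across agents; beta = alpha
}

DBS_HYPERPARAM_DEFAULTS: dict[str, float] = {
    "sensitivity_mean": 3.0,
    "sensitivity_sd": 0.5,
    "tremble": 0.05,     # fixed across agents
}


@dataclass(frozen=True)
class CPTAgent:
    """An agent whose choices come from the prospect-theory model."""

    agent_id: str
    params: CPTParams

    def accept_probabilities(self, condition: Condition) -> np.ndarray:
        gains = np.array([g.gain for g in condition.gambles])
        losses = np.array([g.loss for g in condition.gambles])
        return _cpt.accept_probabilities(gains, losses, self.params)


@dataclass(frozen=True)
class DbSAgent:
    """An agent whose choices come from rank-based (DbS) valuation.

    The comparison context is task-endogenous: the condition's own gain and
    loss levels.
    """

    agent_id: str
    params: DbSParams

    def accept_probabilities(self, condition: Condition) -> np.ndarray:
        ctx = ComparisonContext.from_condition(condition)
        return np.array(
            [dbs_accept_probability(g, ctx, self.params) for g in condition.gambles]
        )


Agent = Union[CPTAgent, DbSAgent]


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a heterogeneous agent population.

    generator : ``"cpt"`` (well-specified) or ``"dbs"`` (misspecified).
    hyperparams : overrides for the generator's distribution settings; keys
        not given fall back to the module defaults above.
    """

    n_agents: int
    generator: str
    seed: int = 0
    hyperparams: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise InvalidInputError("n_agents must be >= 1")
        if self.generator not in ("cpt", "dbs"):
            raise InvalidInputError(f"unknown generator {self.generator!r}")
        defaults = (
            CPT_HYPERPARAM_DEFAULTS if self.generator == "cpt" else DBS_HYPERPARAM_DEFAULTS
        )
        unknown = set(self.hyperparams) - set(defaults)
        if unknown:
            raise InvalidInputError(f"unknown hyperparams {sorted(unknown)}")
        merged = dict(defaults)
        merged.update(self.hyperparams)
        if not all(math.isfinite(v) for v in merged.values()):
            raise InvalidInputError("hyperparams must be finite")
        object.__setattr__(self, "hyperparams", merged)

    def to_dict(self) -> dict:
        return {
            "n_agents": self.n_agents,
            "generator": self.generator,
            "seed": self.seed,
            "hyperparams": dict(self.hyperparams),
        }


def _agent_ids(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"a{i:0{width}d}" for i in range(n)]


def sample_population(spec: PopulationSpec) -> list[Agent]:
    """Draw a population of agents; deterministic given ``spec.seed``.

    Agent ids are stable (``a000``, ``a001``, ...) and returned in order.
    """
    rng = np.random.default_rng(spec.seed)
    h = spec.hyperparams
    ids = _agent_ids(spec.n_agents)
    agents: list[Agent] = []
    if spec.generator == "cpt":
        lams = np.exp(rng.normal(math.log(h["lam_median"]), h["lam_log_sd"], spec.n_agents))
        biases = rng.normal(h["bias_mean"], h["bias_sd"], spec.n_agents)
        for aid, lam, bias in zip(ids, lams, biases):
            agents.append(
                CPTAgent(
                    aid,
                    CPTParams(
                        alpha=h["alpha"],
                        beta=h["alpha"],
                        lam=float(lam),
                        mu=h["mu"],
                        bias=float(bias),
                    ),
                )
            )
    else:
        sens = np.maximum(
            rng.normal(h["sensitivity_mean"], h["sensitivity_sd"], spec.n_agents), 0.0
        )
        for aid, s in zip(ids, sens):
            agents.append(DbSAgent(aid, DbSParams(sensitivity=float(s), tremble=h["tremble"])))
    return agents


def min_reps(condition: Condition, min_trials: int = 256) -> int:
    """Smallest repetition count giving at least ``min_trials`` trials."""
    return max(1, math.ceil(min_trials / condition.n_gambles))


def simulate_choices(
    agent: Agent, condition: Condition, n_reps: int = 1, seed: int = 0
) -> pd.DataFrame:
    """Bernoulli-resolve one agent's accept probabilities over a condition.

    Every gamble is presented ``n_reps`` times; each presentation is an
    independent Bernoulli draw from the agent's latent accept probability.
    Deterministic given ``seed``.
    """
    if condition.n_gambles == 0:
        raise InvalidInputError("condition has no gambles")
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    probs = agent.accept_probabilities(condition)
    rng = np.random.default_rng(seed)
    accepted = (rng.random((n_reps, probs.size)) < probs[None, :]).astype(np.int8)
    gains = np.array([g.gain for g in condition.gambles])
    losses = np.array([g.loss for g in condition.gambles])
    return pd.DataFrame(
        {
            "agent_id": agent.agent_id,
            "condition": condition.label,
            "gain": np.tile(gains, n_reps),
            "loss": np.tile(losses, n_reps),
            "accepted": accepted.ravel(),
        },
        columns=CHOICE_COLUMNS,
    )


def subseed(*keys: int) -> int:
    """Deterministic sub-seed (< 2**31) derived from integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] & 0x7FFFFFFF)


def simulate_experiment(
    agents: Sequence[Agent],
    conditions: Sequence[Condition],
    n_reps: int | None = None,
    seed: int = 0,
    assignment: str = "between",
) -> pd.DataFrame:
    """Simulate a whole experiment.

    assignment ``"between"`` assigns agent ``i`` to condition ``i % k``
    (the between-subjects 2x2 design); ``"within"`` runs every agent
    through every condition.  ``n_reps=None`` picks, per condition, the
    smallest repetition count giving each agent at least 256 trials --
    enough that random halves of an agent's data remain fittable.
    """
    if assignment not in ("between", "within"):
        raise InvalidInputError(f"unknown assignment {assignment!r}")
    frames = []
    for i, agent in enumerate(agents):
        conds = (
            [conditions[i % len(conditions)]] if assignment == "between" else conditions
        )
        for j, cond in enumerate(conds):
            reps = n_reps if n_reps is not None else min_reps(cond)
            frames.append(simulate_choices(agent, cond, reps, subseed(seed, i, j)))
    return pd.concat(frames, ignore_index=True)
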