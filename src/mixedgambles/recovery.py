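"""Split-half λ-rank generalization experiment.

Does an individual's estimated loss aversion generalize across two random
halves of their own choices?  Per replicate: each agent's records are
randomly split in half; λ is estimated on the first half and agents are
ranked by λ̂; the agents sitting at target percentiles of that ranking are
identified; λ is re-estimated on the second half and those same agents'
new rank positions are recorded.  Aggregated over replicates, the rank
distributions show how far a "median-λ person" can wander.

A *stochasticity-only* null isolates the dispersion expected purely from
resolving latent choice probabilities into Bernoulli responses: fresh
choices are simulated from each agent's own first-half *fitted* model on
the second-half gambles, refitted and re-ranked.  Any spread beyond that
null is attributable to the change of choice set interacting with model
misspecification, not to response noise.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cpt import CHOICE_COLUMNS, CPTParams, accept_probabilities
from .errors import InsufficientDataError, InvalidInputError
from .fitting import CPTFitResults, FitSpec, fit_population
from .population import subseed

_log = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (5, 25, 50, 75, 95)

#: Parameters whose box-bound (or separation) flag invalidates a λ ranking.
#: Curvature or sensitivity pinned at a bound still yields a usable λ̂.
_RANK_CRITICAL = ("lam", "bias")


@dataclass
class RecoveryReport:
    """Aggregated outcome of the split-half rank-generalization experiment.

    rank_distributions : per target percentile, the second-half rank
        positions (one per replicate) of the agent at that percentile of
        the first-half λ̂ ranking.
    null_distributions : same quantity under the stochasticity-only
        resampling, or None if the null was not run.
    split_rank_correlation : Spearman correlation of λ̂ between halves,
        averaged over replicates.
    """

    percentiles: tuple[int, ...]
    n_agents: int
    n_replicates: int
    rank_distributions: dict[int, list[int]]
    null_distributions: dict[int, list[int]] | None
    split_rank_correlation: float
    replicate_correlations: list[float] = field(default_factory=list)
    n_usable: list[int] = field(default_factory=list)

    def iqr(self, percentile: int, which: str = "observed") -> float:
        """Interquartile range of the rank distribution at one percentile."""
        dist = (
            self.rank_distributions if which == "observed" else self.null_distributions
        )
        if dist is None:
            raise InvalidInputError("null distributions were not computed")
        ranks = np.asarray(dist[percentile], dtype=float)
        return float(np.percentile(ranks, 75) - np.percentile(ranks, 25))

    def to_dict(self) -> dict:
        return {
            "percentiles": list(self.percentiles),
            "n_agents": self.n_agents,
            "n_replicates": self.n_replicates,
            "rank_distributions": {str(k): v for k, v in self.rank_distributions.items()},
            "null_distributions": (
                None
                if self.null_distributions is None
                else {str(k): v for k, v in self.null_distributions.items()}
            ),
            "split_rank_correlation": self.split_rank_correlation,
            "replicate_correlations": self.replicate_correlations,
            "n_usable": self.n_usable,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RecoveryReport":
        return cls(
            percentiles=tuple(int(p) for p in d["percentiles"]),
            n_agents=int(d["n_agents"]),
            n_replicates=int(d["n_replicates"]),
            rank_distributions={int(k): list(v) for k, v in d["rank_distributions"].items()},
            null_distributions=(
                None
                if d.get("null_distributions") is None
                else {int(k): list(v) for k, v in d["null_distributions"].items()}
            ),
            split_rank_correlation=float(d["split_rank_correlation"]),
            replicate_correlations=list(d.get("replicate_correlations", [])),
            n_usable=list(d.get("n_usable", [])),
        )


def split_half(records: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly partition each agent's records into two near-equal halves.

    Within each agent the split is as even as possible (sizes differ by at
    most one; the second half gets the odd record).  Agents with fewer than
    two records are skipped with a logged warning.  Deterministic given
    ``seed``; the union of the halves is the input (minus skipped agents).
    """
    rng = np.random.default_rng(seed)
    idx_a: list[np.ndarray] = []
    idx_b: list[np.ndarray] = []
    for agent_id, group in sorted(records.groupby("agent_id"), key=lambda kv: str(kv[0])):
        n = len(group)
        if n < 2:
            _log.warning("agent %s has %d record(s); skipped from split", agent_id, n)
            continue
        perm = rng.permutation(n)
        half = n // 2
        idx_a.append(group.index.to_numpy()[perm[:half]])
        idx_b.append(group.index.to_numpy()[perm[half:]])
    a = records.loc[np.concatenate(idx_a)] if idx_a else records.iloc[:0]
    b = records.loc[np.concatenate(idx_b)] if idx_b else records.iloc[:0]
    return a.reset_index(drop=True), b.reset_index(drop=True)


def _lambda_ranks(lams: Mapping[str, float]) -> dict[str, int]:
    """Rank agents 1..n by ascending λ̂; ties broken by agent id."""
    ordered = sorted(lams, key=lambda aid: (lams[aid], aid))
    return {aid: r + 1 for r, aid in enumerate(ordered)}

def _percentile_rank(pct: int, n: int) -> int:
    """Nearest-rank position of a percentile in a ranking of size n."""
    return min(max(1, math.ceil(pct / 100.0 * n)), n)


def _usable_ids(*fit_maps: Mapping[str, CPTFitResults]) -> list[str]:
    ids = set(fit_maps[0])
    for m in fit_maps[1:]:
        ids &= set(m)
    usable = []
    for aid in sorted(ids):
        ok = all(
            m[aid].converged and not (m[aid].at_bound & set(_RANK_CRITICAL))
            for m in fit_maps
        )
        if ok:
            usable.append(aid)
    return usable


def _simulate_from_fits(
    params_by_agent: Mapping[str, CPTParams],
    designs: Mapping[str, pd.DataFrame],
    seed: int,
) -> pd.DataFrame:
    """Bernoulli data from fitted accept probabilities on given gamble lists."""
    frames = []
    for i, aid in enumerate(sorted(params_by_agent)):
        design = designs[aid]
        gains = design["gain"].to_numpy(dtype=float)
        losses = design["loss"].to_numpy(dtype=float)
        probs = accept_probabilities(gains, losses, params_by_agent[aid])
        rng = np.random.default_rng(subseed(seed, i))
        accepted = (rng.random(probs.size) < probs).astype(np.int8)
        frames.append(
            pd.DataFrame(
                {
                    "agent_id": aid,
                    "condition": design["condition"].to_numpy()
                    if "condition" in design
                    else "null",
                    "gain": gains,
                    "loss": losses,
                    "accepted": accepted,
                },
                columns=CHOICE_COLUMNS,
            )
        )
    return pd.concat(frames, ignore_index=True)


def _as_params(fit_or_params) -> CPTParams:
    return fit_or_params.params if hasattr(fit_or_params, "params") else fit_or_params


def stochasticity_null(
    half_a_fits: Mapping[str, CPTFitResults | CPTParams],
    half_b_designs: Mapping[str, pd.DataFrame],
    fit_spec: FitSpec | None = None,
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
    n_replicates: int = 50,
    seed: int = 0,
) -> dict[int, list[int]]:
    """Rank dispersion expected from Bernoulli response noise alone.

    Per replicate, each agent's first-half fitted model generates fresh
    choices on that agent's second-half gambles; the model is refitted and
    agents re-ranked.  Returns, per target percentile, the list of
    second-half-null ranks of the agent at that percentile of the original
    (first-half) λ̂ ranking.  Model misspecification plays no role here:
    the generator *is* the fitted model.
    """
    fit_spec = fit_spec or FitSpec()
    params_by_agent = {aid: _as_params(f) for aid, f in half_a_fits.items()}
    if len(params_by_agent) < 10:
        raise InsufficientDataError(
            f"need >= 10 agents for a rank analysis, got {len(params_by_agent)}"
        )
    base_ranks = _lambda_ranks({aid: p.lam for aid, p in params_by_agent.items()})
    n = len(base_ranks)
    rank_by_position = {r: aid for aid, r in base_ranks.items()}
    out: dict[int, list[int]] = {int(p): [] for p in percentiles}
    for rep in range(n_replicates):
        sim = _simulate_from_fits(params_by_agent, half_b_designs, subseed(seed, rep, 0))
        refits = fit_population(
            sim, _respec(fit_spec, subseed(seed, rep, 1))
        )
        new_ranks = _lambda_ranks({aid: f.params.lam for aid, f in refits.items()})
        for pct in percentiles:
            target = rank_by_position[_percentile_rank(pct, n)]
            out[int(pct)].append(new_ranks[target])
    return out


def _respec(spec: FitSpec, seed: int) -> FitSpec:
    return FitSpec(
        bounds=spec.bounds,
        alpha_equals_beta=spec.alpha_equals_beta,
        n_starts=spec.n_starts,
        seed=seed,
    )


def rank_generalization(
    records: pd.DataFrame,
    fit_spec: FitSpec | None = None,
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
    n_replicates: int = 50,
    seed: int = 0,
    include_null: bool = True,
) -> RecoveryReport:
    """Run the split-half λ-rank generalization experiment.

    Per replicate, agents whose fit on either half failed to converge or
    pinned λ at a box bound (or showed perfect separation) are excluded
    from that replicate's ranking, with a warning when more than 20% drop.

    Raises
    ------
    InsufficientDataError
        Fewer than 10 usable agents in some replicate.
    """
    fit_spec = fit_spec or FitSpec()
    percentiles = tuple(int(p) for p in percentiles)
    agents = sorted(records["agent_id"].astype(str).unique())
    n_agents = len(agents)
    rank_dists: dict[int, list[int]] = {p: [] for p in percentiles}
    null_dists: dict[int, list[int]] | None = {p: [] for p in percentiles} if include_null else None
    correlations: list[float] = []
    n_usable_list: list[int] = []

    for rep in range(n_replicates):
        half_a, half_b = split_half(records, subseed(seed, rep, 0))
        fits_a = fit_population(half_a, _respec(fit_spec, subseed(seed, rep, 1)))
        fits_b = fit_population(half_b, _respec(fit_spec, subseed(seed, rep, 2)))
        usable = _usable_ids(fits_a, fits_b)
        if len(usable) < 10:
            raise InsufficientDataError(
                f"replicate {rep}: only {len(usable)} usable agents (< 10)"
            )
        if len(usable) < 0.8 * n_agents:
            _log.warning(
                "replicate %d: %d of %d agents usable (boundary/convergence drops)",
                rep,
                len(usable),
                n_agents,
            )
        lams_a = {aid: fits_a[aid].params.lam for aid in usable}
        lams_b = {aid: fits_b[aid].params.lam for aid in usable}
        ranks_a = _lambda_ranks(lams_a)
        ranks_b = _lambda_ranks(lams_b)
        rho = spearmanr(
            [lams_a[aid] for aid in usable], [lams_b[aid] for aid in usable]
        ).statistic
        correlations.append(float(rho))
        n_usable_list.append(len(usable))

        rank_to_agent = {r: aid for aid, r in ranks_a.items()}
        targets = {
            pct: rank_to_agent[_percentile_rank(pct, len(usable))] for pct in percentiles
        }
        for pct, aid in targets.items():
            rank_dists[pct].append(ranks_b[aid])

        if include_null:
            designs = {
                aid: group[["condition", "gain", "loss"]]
                for aid, group in half_b.groupby("agent_id")
                if str(aid) in usable
            }
            null_params = {aid: fits_a[aid].params for aid in usable}
            sim = _simulate_from_fits(null_params, designs, subseed(seed, rep, 3))
            refits = fit_population(sim, _respec(fit_spec, subseed(seed, rep, 4)))
            null_ranks = _lambda_ranks({aid: f.params.lam for aid, f in refits.items()})
            for pct, aid in targets.items():
                null_dists[pct].append(null_ranks[aid])

    return RecoveryReport(
        percentiles=percentiles,
        n_agents=n_agents,
        n_replicates=n_replicates,
        rank_distributions=rank_dists,
        null_distributions=null_dists,
        split_rank_correlation=float(np.mean(correlations)),
        replicate_correlations=correlations,
        n_usable=n_usable_list,
    )


def write_recovery_report(report: RecoveryReport, path) -> None:
    """Serialize a report to structured (JSON) text; round-trips exactly."""
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_recovery_report(path) -> RecoveryReport:
    with open(path) as fh:
        return RecoveryReport.from_dict(json.load(fh))
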