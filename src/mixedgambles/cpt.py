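"""Prospect-theory accept-reject choice model.

The reduced form used throughout the accept-reject literature for 50-50
mixed gambles: a power value function with loss-aversion coefficient
``lam`` (λ),

    v(x) = x**alpha            for x >= 0
    v(x) = -lam * (-x)**beta   for x < 0,

an expected subjective value ``U = 0.5*v(gain) + 0.5*v(-loss)``, and a
logistic choice rule ``P(accept) = logistic(mu*U + bias)``.  ``mu`` is the
choice sensitivity and ``bias`` an intercept capturing a tendency to accept
(positive) or reject (negative) mixed gambles irrespective of the amounts
on offer.  No probability weighting is applied: both outcomes sit at
probability one half, so any weight on 0.5 is absorbed into ``mu``.

λ > 1 means losses loom larger than gains.  The knife-edge case: a 50-50
gamble to win 20 or lose 10 has U = 0 exactly at λ = 2 (linear value), so a
loss-averse agent with λ > 2 rejects it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import MixedGamble
from .errors import InvalidInputError

#: Probability clamp applied inside the log-likelihood so it stays finite at
#: boundary parameter values.
LIKELIHOOD_EPS = 1e-9

CHOICE_COLUMNS = ["agent_id", "condition", "gain", "loss", "accepted"]


@dataclass(frozen=True)
class CPTParams:
    """Prospect-theory parameter vector for the accept-reject model.

    alpha, beta : gain/loss curvature exponents (> 0)
    lam : loss-aversion coefficient λ (> 0)
    mu : choice sensitivity (>= 0)
    bias : accept/reject intercept (unbounded)
    """

    alpha: float = 0.9
    beta: float = 0.9
    lam: float = 2.0
    mu: float = 1.0
    bias: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.lam > 0):
            raise InvalidInputError(
                f"alpha, beta, lam must be > 0, got "
                f"({self.alpha}, {self.beta}, {self.lam})"
            )
        if self.mu < 0:
            raise InvalidInputError(f"mu must be >= 0, got {self.mu}")


@dataclass(frozen=True)
class ChoiceRecord:
    """One agent's accept/reject response to one gamble."""

    agent_id: str
    condition: str
    gamble: MixedGamble
    accepted: bool

    def __post_init__(self) -> None:
        if not self.agent_id:
            raise InvalidInputError("agent_id must be non-empty")


Records = Union[pd.DataFrame, Sequence[ChoiceRecord]]


def cpt_value(x, p: CPTParams):
    """Subjective value of a signed amount (vectorized over ``x``)."""
    x = np.asarray(x, dtype=float)
    mag = np.abs(x)
    out = np.where(x >= 0, mag**p.alpha, -p.lam * mag**p.beta)
    return out if out.ndim else float(out)


def accept_probability(g: MixedGamble, p: CPTParams) -> float:
    """P(accept) for a single mixed gamble."""
    return float(accept_probabilities(np.array([g.gain]), np.array([g.loss]), p)[0])


def accept_probabilities(gains: np.ndarray, losses: np.ndarray, p: CPTParams) -> np.ndarray:
    """Vectorized P(accept) over arrays of gains and loss magnitudes."""
    gains = np.asarray(gains, dtype=float)
    losses = np.asarray(losses, dtype=float)
    u = 0.5 * gains**p.alpha - 0.5 * p.lam * losses**p.beta
    return expit(p.mu * u + p.bias)


def log_likelihood(records: Records, p: CPTParams) -> float:
    """Bernoulli log-likelihood of accept/reject responses under ``p``.

    Probabilities are clamped to ``[eps, 1-eps]`` (eps = 1e-9) so the
    likelihood stays finite at boundary parameters.  An empty record list
    has log-likelihood 0.
    """
    gains, losses, accepted = choice_arrays(records)
    if gains.size == 0:
        return 0.0
    probs = np.clip(
        accept_probabilities(gains, losses, p), LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS
    )
    return float(np.sum(np.where(accepted, np.log(probs), np.log1p(-probs))))


# ---------------------------------------------------------------------------
# record container conversions

def choice_arrays(records: Records) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (gains, losses, accepted) arrays from either record container."""
    if isinstance(records, pd.DataFrame):
        gains = records["gain"].to_numpy(dtype=float)
        losses = records["loss"].to_numpy(dtype=float)
        accepted = records["accepted"].to_numpy().astype(bool)
    else:
        records = list(records)
        gains = np.array([r.gamble.gain for r in records], dtype=float)
        losses = np.array([r.gamble.loss for r in records], dtype=float)
        accepted = np.array([r.accepted for r in records], dtype=bool)
    return gains, losses, accepted


def records_to_frame(records: Iterable[ChoiceRecord]) -> pd.DataFrame:
    """Convert ChoiceRecord objects to the canonical choice table."""
    rows = [
        (r.agent_id, r.condition, r.gamble.gain, r.gamble.loss, int(r.accepted))
        for r in records
    ]
    return pd.DataFrame(rows, columns=CHOICE_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[ChoiceRecord]:
    """Convert a choice table back to ChoiceRecord objects."""
    return [
        ChoiceRecord(
            agent_id=str(row.agent_id),
            condition=str(row.condition),
            gamble=MixedGamble(row.gain, row.loss),
            accepted=bool(row.accepted),
        )
        for row in frame.itertuples(index=False)
    ]
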