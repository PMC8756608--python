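"""Decision-by-sampling (DbS) valuation and choice.

Under DbS the subjective magnitude of an amount is its *relative rank* among
comparison values drawn from recent experience: a £10 gain feels large when
experienced gains span £0-£20 (it beats half of them) and small when they
span £0-£40 (it beats only a quarter).  Gains are compared against
experienced gains and losses against experienced losses, so manipulating
the two ranges independently shifts which of a gamble's outcomes looms
larger -- and hence the probability of accepting the gamble -- without any
change to the gamble itself.

The theory makes directional predictions only; to simulate choices we close
it with a logistic rule on the gain-rank minus loss-rank difference, plus a
tremble (uniform lapse) probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import Condition, MixedGamble
from .errors import InvalidContextError, InvalidInputError


@dataclass(frozen=True)
class DbSParams:
    """Parameters of the rank-difference choice rule.

    sensitivity : slope of the logistic on the rank difference (>= 0);
        0 makes every choice a coin flip.
    tremble : probability in [0, 0.5) of responding uniformly at random.
    """

    sensitivity: float = 3.0
    tremble: float = 0.05

    def __post_init__(self) -> None:
        if self.sensitivity < 0:
            raise InvalidInputError(f"sensitivity must be >= 0, got {self.sensitivity}")
        if not 0 <= self.tremble < 0.5:
            raise InvalidInputError(f"tremble must be in [0, 0.5), got {self.tremble}")


@dataclass(frozen=True)
class ComparisonContext:
    """Pools of experienced gain and loss magnitudes.

    Amounts are non-negative; losses are magnitudes.  The default context
    for a condition is *task-endogenous*: the condition's own attribute
    levels (see :meth:`from_condition`).  :func:`uniform_pool` offers the
    dense-grid alternative over [0, max].
    """

    gain_pool: tuple[float, ...]
    loss_pool: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, pool in (("gain_pool", self.gain_pool), ("loss_pool", self.loss_pool)):
            if len(pool) == 0:
                raise InvalidContextError(f"{name} must be non-empty")
            arr = np.asarray(pool, dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise InvalidContextError(f"{name} entries must be finite and >= 0")

    @classmethod
    def from_condition(cls, condition: Condition) -> "ComparisonContext":
        return cls(condition.gain_levels, condition.loss_levels)


def uniform_pool(maximum: float, n_points: int = 41) -> tuple[float, ...]:
    """An equally spaced comparison pool spanning [0, maximum] inclusive."""
    if maximum <= 0 or n_points < 2:
        raise InvalidContextError("uniform_pool needs maximum > 0 and n_points >= 2")
    return tuple(np.linspace(0.0, float(maximum), n_points))


def relative_rank(x: float, pool: Sequence[float]) -> float:
    """Relative rank of ``x`` within ``pool``, in [0, 1].

    Mid-rank convention with ties; if ``x`` itself occurs in the pool, one
    instance is excluded from its own comparison set.  Under this convention
    the median of a symmetric grid has rank exactly 0.5 and the pool maximum
    has rank 1.

    Raises
    ------
    InvalidContextError
        If the pool is empty.
    """
    arr = np.asarray(pool, dtype=float)
    if arr.size == 0:
        raise InvalidContextError("comparison pool is empty")
    x = float(x)
    n_less = int(np.count_nonzero(arr < x))
    n_eq = int(np.count_nonzero(arr == x))
    denom = arr.size
    if n_eq > 0:  # exclude one instance of x itself
        n_eq -= 1
        denom -= 1
    if denom == 0:
        return 0.5  # x compared against nothing but itself: indifference
    return (n_less + 0.5 * n_eq) / denom


def dbs_accept_probability(
    g: MixedGamble, ctx: ComparisonContext, params: DbSParams
) -> float:
    """Probability of accepting gamble ``g`` under rank-based valuation.

    ``logistic(sensitivity * (rank(gain) - rank(loss)))``, mixed with a
    tremble: the returned value is ``(1 - 2*tremble) * p + tremble``.
    """
    r_gain = relative_rank(g.gain, ctx.gain_pool)
    r_loss = relative_rank(g.loss, ctx.loss_pool)
    p = float(expit(params.sensitivity * (r_gain - r_loss)))
    return (1.0 - 2.0 * params.tremble) * p + params.tremble


def predicted_proportion_table(
    conditions: Iterable[Condition],
    common: Sequence[MixedGamble],
    params: DbSParams | None = None,
) -> pd.DataFrame:
    """Mean DbS accept probability over the common gambles, per condition.

    Each condition's comparison context is its own attribute levels, so the
    same common gamble receives different ranks -- and a different accept
    probability -- in different conditions.  Columns:
    ``condition, mean_accept, n_common_gambles``.

    Raises
    ------
    InvalidInputError
        If the common set is empty.
    """
    common = list(common)
    if not common:
        raise InvalidInputError("predicted_proportion_table needs a non-empty common set")
    params = params or DbSParams()
    rows = []
    for cond in conditions:
        ctx = ComparisonContext.from_condition(cond)
        probs = [dbs_accept_probability(g, ctx, params) for g in common]
        rows.append(
            {
                "condition": cond.label,
                "mean_accept": float(np.mean(probs)),
                "n_common_gambles": len(common),
            }
        )
    return pd.DataFrame(rows, columns=["condition", "mean_accept", "n_common_gambles"])
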