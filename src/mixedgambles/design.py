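"""Choice-set construction for range-manipulated mixed-gamble experiments.

A *mixed gamble* offers a monetary gain or a monetary loss, each with
probability one half.  Experiments in this paradigm manipulate the range of
gains and losses a participant experiences by crossing a low/high maximum
gain with a low/high maximum loss (a 2x2 design), building each condition's
choice set as the full factorial of equally spaced gain and loss levels.
Because cross-condition comparisons are only meaningful on the same
instrument, analyses restrict attention to the *common gambles* -- the
gain/loss pairs present in every condition.

Losses are stored as positive magnitudes throughout the package; sign is
applied only inside value functions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import InvalidDesignError

_log = logging.getLogger(__name__)

#: Decimal places levels are rounded to at construction time.  Levels from
#: different conditions must compare exactly equal when they coincide on
#: paper; rounding makes the float grid arithmetic stable.
_LEVEL_DECIMALS = 12


@dataclass(frozen=True, order=True)
class MixedGamble:
    """A 50-50 two-outcome prospect: win ``gain`` or lose ``loss``.

    Both outcomes occur with probability one half (implicit and fixed).
    ``loss`` is a positive magnitude.  Ordering and equality are by the
    ``(gain, loss)`` pair, so sorted gamble lists are ordered by gain then
    loss.
    """

    gain: float
    loss: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gain", float(self.gain))
        object.__setattr__(self, "loss", float(self.loss))
        if not (self.gain > 0 and self.loss > 0):
            raise InvalidDesignError(
                f"gamble outcomes must be strictly positive magnitudes, "
                f"got gain={self.gain}, loss={self.loss}"
            )


@dataclass(frozen=True)
class Condition:
    """A labelled choice set generated from a (max_gain, max_loss) range pair.

    ``gambles`` is the full factorial of ``gain_levels`` x ``loss_levels``
    (gain-major order).  Levels are strictly positive and strictly
    increasing, and the largest level equals the condition maximum.
    """

    label: str
    max_gain: float
    max_loss: float
    gain_levels: tuple[float, ...]
    loss_levels: tuple[float, ...]
    gambles: tuple[MixedGamble, ...] = field(repr=False)

    def __post_init__(self) -> None:
        for name, levels, mx in (
            ("gain", self.gain_levels, self.max_gain),
            ("loss", self.loss_levels, self.max_loss),
        ):
            if len(levels) < 1 or any(v <= 0 for v in levels):
                raise InvalidDesignError(f"{name}_levels must be strictly positive")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise InvalidDesignError(f"{name}_levels must be strictly increasing")
            if levels[-1] != mx:
                raise InvalidDesignError(
                    f"max({name}_levels) = {levels[-1]} != max_{name} = {mx}"
                )
        if len(self.gambles) != len(self.gain_levels) * len(self.loss_levels):
            raise InvalidDesignError("gambles must be the full factorial of the levels")

    @classmethod
    def from_levels(
        cls,
        label: str,
        gain_levels: Sequence[float],
        loss_levels: Sequence[float],
    ) -> "Condition":
        """Build a condition from explicit level lists (full factorial)."""
        g = tuple(round(float(v), _LEVEL_DECIMALS) for v in gain_levels)
        l = tuple(round(float(v), _LEVEL_DECIMALS) for v in loss_levels)
        gambles = tuple(
            MixedGamble(gi, li) for gi, li in itertools.product(g, l)
        )
        return cls(
            label=label,
            max_gain=g[-1] if g else 0.0,
            max_loss=l[-1] if l else 0.0,
            gain_levels=g,
            loss_levels=l,
            gambles=gambles,
        )

    @property
    def n_gambles(self) -> int:
        return len(self.gambles)


def build_condition(
    max_gain: float, max_loss: float, n_levels: int, label: str
) -> Condition:
    """Construct a condition with ``n_levels`` equally spaced levels per attribute.

    Gain levels are ``max_gain * k / n_levels`` for ``k = 1..n_levels`` (so the
    grid ends exactly at the maximum and excludes zero); likewise for losses.
    The gamble list is the full factorial.

    Raises
    ------
    InvalidDesignError
        If either maximum is non-positive or ``n_levels < 2``.
    """
    if not (max_gain > 0 and max_loss > 0):
        raise InvalidDesignError(
            f"condition maxima must be positive, got ({max_gain}, {max_loss})"
        )
    if n_levels < 2:
        raise InvalidDesignError(f"n_levels must be >= 2, got {n_levels}")
    gain_levels = [max_gain * k / n_levels for k in range(1, n_levels + 1)]
    loss_levels = [max_loss * k / n_levels for k in range(1, n_levels + 1)]
    return Condition.from_levels(label, gain_levels, loss_levels)


def standard_design(
    low: float = 20.0, high: float = 40.0, n_levels: int = 20
) -> list[Condition]:
    """The 2x2 range-manipulation design: maximum gain x maximum loss in {low, high}.

    Labels encode (max gain, max loss): ``LL``, ``LH``, ``HL``, ``HH`` --
    e.g. ``LH`` is the *low maximum gain, high maximum loss* condition.  With
    the defaults (20, 40, 20 levels) the low and high grids share every
    second level, so the common-gamble set is a 10 x 10 sub-grid.
    """
    return [
        build_condition(low, low, n_levels, "LL"),
        build_condition(low, high, n_levels, "LH"),
        build_condition(high, low, n_levels, "HL"),
        build_condition(high, high, n_levels, "HH"),
    ]


def common_gambles(conditions: Iterable[Condition]) -> list[MixedGamble]:
    """Gambles present in every condition, sorted by gain then loss.

    An empty intersection is returned as an empty list with a logged
    warning, not an error.
    """
    conditions = list(conditions)
    if len(conditions) < 2:
        raise InvalidDesignError("common_gambles needs at least two conditions")
    common = set(conditions[0].gambles)
    for cond in conditions[1:]:
        common &= set(cond.gambles)
    if not common:
        _log.warning(
            "no gambles are shared between conditions %s",
            [c.label for c in conditions],
        )
    return sorted(common)
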