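"""Model-free analysis: accept proportions on the common gambles.

Comparing raw accept proportions on the gambles shared by every condition
sidesteps model fitting (and its identifiability problems) entirely: the
instrument is identical across conditions, so any difference in acceptance
is a context effect, not a measurement artifact.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .design import MixedGamble
from .errors import InvalidInputError

_log = logging.getLogger(__name__)

PROPORTION_COLUMNS = ["condition", "aggregation", "proportion", "n_trials", "n_agents"]


def accept_proportions_by_condition(
    records: pd.DataFrame,
    common: Sequence[MixedGamble],
    aggregation: str = "by_agent",
) -> pd.DataFrame:
    """Accept proportion per condition, restricted to the common gambles.

    ``by_agent`` (default) averages per-agent proportions, treating the
    participant as the sampling unit; ``pooled`` counts accepts over all
    trials.  The two agree exactly when every agent contributes the same
    trials.  Conditions with no common-gamble trials are omitted with a
    logged warning.

    Raises
    ------
    InvalidInputError
        Empty common set or unknown aggregation.
    """
    common = list(common)
    if not common:
        raise InvalidInputError("common gamble set is empty")
    if aggregation not in ("pooled", "by_agent"):
        raise InvalidInputError(f"unknown aggregation {aggregation!r}")

    key = pd.DataFrame(
        {"gain": [g.gain for g in common], "loss": [g.loss for g in common]}
    )
    filtered = records.merge(key, on=["gain", "loss"], how="inner")
    dropped = set(records["condition"].unique()) - set(filtered["condition"].unique())
    for cond in sorted(dropped):
        _log.warning("condition %s has no trials on common gambles; omitted", cond)

    rows = []
    for cond, group in filtered.groupby("condition", sort=True):
        if aggregation == "pooled":
            prop = group["accepted"].mean()
        else:
            prop = group.groupby("agent_id")["accepted"].mean().mean()
        rows.append(
            {
                "condition": cond,
                "aggregation": aggregation,
                "proportion": float(prop),
                "n_trials": int(len(group)),
                "n_agents": int(group["agent_id"].nunique()),
            }
        )
    return pd.DataFrame(rows, columns=PROPORTION_COLUMNS)
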