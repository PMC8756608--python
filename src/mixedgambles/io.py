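"""Delimited-text readers and writers for every artifact the pipeline emits.

All formats are plain CSV with headers; floats are written at full
precision so every reader/writer round-trips its own output bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .cpt import CHOICE_COLUMNS
from .design import Condition
from .errors import InvalidInputError
from .fitting import CPTFitResults

FIT_COLUMNS = [
    "agent_id", "alpha", "beta", "lam", "mu", "bias",
    "loglik", "converged", "at_bound", "n_trials",
]


def write_choices(records: pd.DataFrame, path) -> None:
    """Write a choice table (agent_id, condition, gain, loss, accepted)."""
    records.to_csv(path, index=False, columns=CHOICE_COLUMNS)


def read_choices(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, dtype={"agent_id": str, "condition": str}, float_precision="round_trip"
    )
    missing = set(CHOICE_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidInputError(f"choice table missing columns {sorted(missing)}")
    frame["gain"] = frame["gain"].astype(float)
    frame["loss"] = frame["loss"].astype(float)
    frame["accepted"] = frame["accepted"].astype(np.int8)
    return frame[CHOICE_COLUMNS]


def conditions_to_frame(conditions: Iterable[Condition]) -> pd.DataFrame:
    rows = [
        (c.label, g.gain, g.loss) for c in conditions for g in c.gambles
    ]
    return pd.DataFrame(rows, columns=["label", "gain", "loss"])


def write_condition_table(conditions: Iterable[Condition], path) -> None:
    """One row per gamble, columns (label, gain, loss); round-trips exactly."""
    conditions_to_frame(conditions).to_csv(path, index=False)


def read_condition_table(path) -> list[Condition]:
    frame = pd.read_csv(path, dtype={"label": str}, float_precision="round_trip")
    conditions = []
    for label in frame["label"].unique():  # preserve file order
        sub = frame[frame["label"] == label]
        gain_levels = sorted(sub["gain"].unique())
        loss_levels = sorted(sub["loss"].unique())
        cond = Condition.from_levels(str(label), gain_levels, loss_levels)
        if cond.n_gambles != len(sub):
            raise InvalidInputError(
                f"condition {label!r} is not a full factorial of its levels"
            )
        conditions.append(cond)
    return conditions


def write_fit_table(fits: Mapping[str, CPTFitResults], path) -> None:
    """Per-agent fit results; ``at_bound`` encoded as ';'-joined names."""
    rows = []
    for agent_id in sorted(fits):
        d = fits[agent_id].to_dict()
        rows.append(
            {
                "agent_id": agent_id,
                "alpha": d["alpha"],
                "beta": d["beta"],
                "lam": d["lam"],
                "mu": d["mu"],
                "bias": d["bias"],
                "loglik": d["loglik"],
                "converged": int(d["converged"]),
                "at_bound": ";".join(d["at_bound"]),
                "n_trials": d["n_trials"],
            }
        )
    pd.DataFrame(rows, columns=FIT_COLUMNS).to_csv(path, index=False)


def read_fit_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"agent_id": str}, float_precision="round_trip")
    frame["at_bound"] = frame["at_bound"].fillna("")
    return frame


def write_table(frame: pd.DataFrame, path) -> None:
    """Generic delimited export (proportion and prediction tables)."""
    frame.to_csv(path, index=False)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, command: str, config: Mapping, seeds: Mapping | None = None) -> None:
    """Record what produced an artifact: config (hashed), seeds, versions."""
    manifest = {
        "command": command,
        "config": dict(config),
        "config_hash": config_hash(config),
        "seeds": dict(seeds or {}),
        "versions": {
            "mixedgambles": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
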