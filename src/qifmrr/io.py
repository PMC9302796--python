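"""Readers and writers: long-format trajectory CSVs, summary tables, provenance.

Trajectory files are long-format CSV with header
``subject,visit,state,action,response``; visits are 1-based and every
subject must have the complete run 1..K (dropout is out of scope).
Summary tables mirror the Mean/SE/RMSE layout of simulation-study tables at
4 decimals, with full-precision values and run provenance in a JSON sidecar.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Cohort
from .simulation import ReplicationSummary

__all__ = ["read_trajectories", "write_trajectories", "write_summary", "provenance"]

TRAJECTORY_COLUMNS = ["subject", "visit", "state", "action", "response"]


class SchemaError(ValueError):
    """A trajectory or summary file violates the expected schema."""


def _package_version() -> str:
    try:
        return version("qifmrr")
    except PackageNotFoundError:  # pragma: no cover - running from a source tree
        return "unknown"


def provenance(config: dict, seed: int | None = None) -> dict:
    """Resolved-configuration block emitted alongside every result."""
    return {"package": "qifmrr", "version": _package_version(),
            "seed": seed, "config": config}


def read_trajectories(path) -> Cohort:
    """Read a long-format trajectory CSV into a Cohort.

    Validates rectangularity (every subject has visits 1..K exactly once)
    and numeric cells; subject order follows first appearance in the file.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in ("visit", "state", "action", "response"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric or missing {col!r} at data row {bad[0] + 1}"
            )
        df[col] = vals
    dup = df.duplicated(subset=["subject", "visit"])
    if dup.any():
        row = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate (subject, visit) = ({row['subject']}, {int(row['visit'])})"
        )
    subjects = list(dict.fromkeys(df["subject"]))
    K = int(df["visit"].max())
    expected = set(range(1, K + 1))
    n = len(subjects)
    S = np.empty((n, K))
    A = np.empty((n, K))
    Y = np.empty((n, K))
    grouped = dict(list(df.groupby("subject", sort=False)))
    for i, sid in enumerate(subjects):
        g = grouped[sid]
        visits = set(int(v) for v in g["visit"])
        if visits != expected:
            lost = sorted(expected - visits)
            raise SchemaError(
                f"{path}: subject {sid} has ragged visits (missing {lost}, expected 1..{K})"
            )
        g = g.sort_values("visit")
        S[i], A[i], Y[i] = g["state"], g["action"], g["response"]
    return Cohort(subject_ids=subjects, states=S, actions=A, responses=Y)


def write_trajectories(cohort: Cohort, path) -> None:
    """Write a Cohort back to the long-format CSV schema (1-based visits)."""
    n, K = cohort.n, cohort.K
    df = pd.DataFrame({
        "subject": np.repeat(cohort.subject_ids, K),
        "visit": np.tile(np.arange(1, K + 1), n),
        "state": cohort.states.ravel(),
        "action": cohort.actions.ravel(),
        "response": cohort.responses.ravel(),
    })
    df.to_csv(path, index=False)


def write_summary(summary: ReplicationSummary, path, config: dict | None = None) -> None:
    """Write a Mean/SE/RMSE block as CSV (4 decimals) plus a JSON sidecar.

    The CSV mirrors the presentation of simulation-study tables; the sidecar
    keeps full-precision values and the provenance block.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("coefficient,mean,se,rmse\n")
        for name, row in summary.table.iterrows():
            fh.write(f"{name},{row['mean']:.4f},{row['se']:.4f},{row['rmse']:.4f}\n")
    sidecar = {
        "provenance": provenance(config or summary.metadata(), seed=summary.seed),
        "summary": {name: {k: float(v) for k, v in row.items()}
                    for name, row in summary.table.iterrows()},
        "metadata": summary.metadata(),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
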