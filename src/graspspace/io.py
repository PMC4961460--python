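"""On-disk session schema: plain CSV tables plus a JSON manifest.

A session directory contains ``conditions.csv`` (id, shape, size_mm,
grip_class, block), ``trials.csv`` (trial id, condition id, event times),
``units.csv`` (unit id, area, subarray), ``spikes.csv`` (unit id, trial id,
spike time) and ``kinematics.csv`` (trial id, time, 27 angle columns), with
``session.json`` recording seed and config hash.  All times are seconds
relative to fixation onset.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import N_JOINT_ANGLES, SessionData

_ANGLE_COLUMNS = [f"angle_{i:02d}" for i in range(N_JOINT_ANGLES)]


def write_session(session: SessionData, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    session.conditions.to_csv(directory / "conditions.csv", index=False)
    session.units.to_csv(directory / "units.csv", index=False)
    session.trials.to_csv(directory / "trials.csv", index=False)

    unit_col, trial_col, time_col = [], [], []
    for t, trial_spikes in enumerate(session.spikes):
        for u, train in enumerate(trial_spikes):
            unit_col.append(np.full(train.size, u, dtype=int))
            trial_col.append(np.full(train.size, t, dtype=int))
            time_col.append(train)
    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate(unit_col) if unit_col else [],
            "trial_id": np.concatenate(trial_col) if trial_col else [],
            "spike_time": np.concatenate(time_col) if time_col else [],
        }
    )
    spikes.to_csv(directory / "spikes.csv", index=False)

    frames = []
    dt = 1.0 / session.kin_rate_hz
    for t, traj in enumerate(session.kinematics):
        frame = pd.DataFrame(traj, columns=_ANGLE_COLUMNS)
        frame.insert(0, "time", np.arange(len(traj)) * dt)
        frame.insert(0, "trial_id", t)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        directory / "kinematics.csv", index=False
    )

    manifest = {
        "seed": session.seed,
        "config_hash": session.config_hash,
        "kin_rate_hz": session.kin_rate_hz,
        "n_trials": session.n_trials,
        "n_units": session.n_units,
    }
    (directory / "session.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return directory


def read_session(directory: str | Path) -> SessionData:
    """Load a session directory written by :func:`write_session`.

    Generative ground truth (unit specs, prototypes) is not part of the
    schema and comes back as ``None``.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "session.json").read_text())

    conditions = pd.read_csv(directory / "conditions.csv", dtype={"id": str})
    units = pd.read_csv(directory / "units.csv")
    trials = pd.read_csv(directory / "trials.csv", dtype={"condition_id": str})

    n_trials, n_units = len(trials), len(units)
    spikes_df = pd.read_csv(directory / "spikes.csv")
    spikes: list[list[np.ndarray]] = [
        [np.empty(0) for _ in range(n_units)] for _ in range(n_trials)
    ]
    if len(spikes_df):
        for (t, u), group in spikes_df.groupby(["trial_id", "unit_id"], sort=False):
            spikes[int(t)][int(u)] = np.sort(group["spike_time"].to_numpy())

    kin_df = pd.read_csv(directory / "kinematics.csv")
    kinematics = [
        group[_ANGLE_COLUMNS].to_numpy()
        for _, group in kin_df.groupby("trial_id", sort=True)
    ]

    return SessionData(
        conditions=conditions,
        units=units,
        trials=trials,
        spikes=spikes,
        kinematics=kinematics,
        seed=int(manifest["seed"]),
        config_hash=manifest["config_hash"],
        kin_rate_hz=float(manifest.get("kin_rate_hz", 50.0)),
    )
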