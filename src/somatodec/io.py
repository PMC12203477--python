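"""On-disk layout for session bundles.

A session is a directory::

    counts.npz       dense channels x bins integer matrix, key 'counts';
                     row order matches array_map.csv
    trials.csv       trial_id, movement_label, baseline_onset_s,
                     movement_onset_s, rest_onset_s, end_s
    kinematics.csv   time_s, vx, vy, vz, vg, phase_label, click_state
                     (absent when the task has no kinematics)
    array_map.csv    channel_id, array_id, grid_row, grid_col,
                     mediolateral_pos
    meta.json        bin_rate, seed, task, free-form metadata

Times are seconds from session start; bin k covers [k/50, (k+1)/50).
CSVs are UTF-8 with a header row and '.' decimal separator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SessionBundle


def save_session(bundle: SessionBundle, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path / "counts.npz", counts=bundle.counts)
    bundle.trials.to_csv(path / "trials.csv", index=False)
    bundle.array_map.to_csv(path / "array_map.csv", index=False)
    if bundle.kinematics is not None:
        bundle.kinematics.to_csv(path / "kinematics.csv", index=False)
    meta = {
        "bin_rate": bundle.bin_rate,
        "seed": int(bundle.seed),
        "task": bundle.task,
        **bundle.meta,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    return path


def load_session(path: str | Path) -> SessionBundle:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    with np.load(path / "counts.npz") as npz:
        counts = npz["counts"]
    kin_path = path / "kinematics.csv"
    return SessionBundle(
        counts=counts,
        trials=pd.read_csv(path / "trials.csv"),
        array_map=pd.read_csv(path / "array_map.csv"),
        kinematics=pd.read_csv(kin_path) if kin_path.exists() else None,
        bin_rate=float(meta.pop("bin_rate")),
        seed=int(meta.pop("seed")),
        task=meta.pop("task", ""),
        meta=meta,
    )
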