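"""Log serialization: game-log CSV + JSON sidecar, and a column-mapped
importer for externally recorded behavior logs.

The CSV schema is the trial stream (one row per communication event); the
JSON sidecar carries configuration, seeds, and agent-state snapshots so a
game can be reloaded losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import BehaviorLog
from .game import GameLog, TrialRecord
from .intergm import AgentState, Hyperparameters
from .stimuli import StimulusSet, read_stimulus_csv, write_stimulus_csv

__all__ = [
    "game_log_to_frame",
    "write_game_log",
    "read_game_log",
    "import_behavior_log",
]

LOG_COLUMNS = [
    "pass", "item_id", "speaker", "proposed_sign", "listener_sign_before",
    "listener_category", "r_mh", "decision", "listener_category_after",
    "p_num", "p_den", "model_name", "model_prob",
]


def game_log_to_frame(log: GameLog) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pass": [t.pass_index for t in log.trials],
            "item_id": [t.item_id for t in log.trials],
            "speaker": [t.speaker for t in log.trials],
            "proposed_sign": [t.proposed_sign for t in log.trials],
            "listener_sign_before": [t.listener_sign_before for t in log.trials],
            "listener_category": [t.listener_category for t in log.trials],
            "r_mh": [t.r_mh for t in log.trials],
            "decision": [t.decision for t in log.trials],
            "listener_category_after": [t.listener_category_after for t in log.trials],
            "p_num": [t.p_num for t in log.trials],
            "p_den": [t.p_den for t in log.trials],
            "model_name": [t.model_name for t in log.trials],
            "model_prob": [t.model_prob for t in log.trials],
        }
    )


def write_game_log(log: GameLog, out_dir) -> None:
    """Write trials.csv, stimuli.csv and meta.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    game_log_to_frame(log).to_csv(out / "trials.csv", index=False)
    write_stimulus_csv(log.stimuli, out / "stimuli.csv")
    meta = {
        "seed": log.seed,
        "n_passes": log.n_passes,
        "hyper": log.hyper.to_dict(),
        "initial_states": {a: s.to_dict() for a, s in log.initial_states.items()},
        "final_states": {a: s.to_dict() for a, s in log.final_states.items()},
        "snapshots": [{a: s.to_dict() for a, s in snap.items()} for snap in log.snapshots],
    }
    with open(out / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_game_log(in_dir) -> GameLog:
    src = Path(in_dir)
    df = pd.read_csv(src / "trials.csv", keep_default_na=False,
                     na_values=[""], dtype={"model_name": str})
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials.csv missing columns: {sorted(missing)}")
    stimuli = read_stimulus_csv(src / "stimuli.csv")
    with open(src / "meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    trials = [
        TrialRecord(
            pass_index=int(row["pass"]), item_id=int(row["item_id"]),
            speaker=str(row["speaker"]), proposed_sign=int(row["proposed_sign"]),
            listener_sign_before=int(row["listener_sign_before"]),
            listener_category=int(row["listener_category"]), r_mh=float(row["r_mh"]),
            decision=int(row["decision"]),
            listener_category_after=int(row["listener_category_after"]),
            p_num=float(row["p_num"]), p_den=float(row["p_den"]),
            model_name="" if pd.isna(row["model_name"]) else str(row["model_name"]),
            model_prob=float(row["model_prob"]) if not pd.isna(row["model_prob"]) else np.nan,
        )
        for _, row in df.iterrows()
    ]
    return GameLog(
        trials=trials,
        stimuli=stimuli,
        hyper=Hyperparameters.from_dict(meta["hyper"]),
        seed=int(meta["seed"]),
        n_passes=int(meta["n_passes"]),
        initial_states={a: AgentState.from_dict(s) for a, s in meta["initial_states"].items()},
        final_states={a: AgentState.from_dict(s) for a, s in meta["final_states"].items()},
        snapshots=[
            {a: AgentState.from_dict(s) for a, s in snap.items()}
            for snap in meta.get("snapshots", [])
        ],
    )


DEFAULT_IMPORT_COLUMNS = {
    "pass": "pass",
    "item_id": "item_id",
    "proposed_sign": "proposed_sign",
    "own_sign_before": "own_sign_before",
    "own_category": "own_category",
    "decision": "decision",
    "own_category_after": "own_category_after",
}


def import_behavior_log(
    trials_csv,
    participant_id: str,
    pair_id: str,
    dataset_label: str,
    initial_c,
    initial_s,
    column_map: dict | None = None,
    sign_labels: str = "ABCDE",
) -> BehaviorLog:
    """Map an externally recorded trial CSV onto the analysis schema.

    ``column_map`` declares which source column holds each schema field
    (schema name -> source name); unmapped fields fall back to identical
    names.  Letter-coded signs/categories (A-E) are converted to indices.
    Schema violations are reported with the offending row number.
    """
    cmap = {**DEFAULT_IMPORT_COLUMNS, **(column_map or {})}
    df = pd.read_csv(trials_csv)
    missing = [src for src in cmap.values() if src not in df.columns]
    if missing:
        raise ValueError(f"import CSV missing columns: {missing}")
    out = pd.DataFrame({schema: df[src] for schema, src in cmap.items()})

    def decode(col):
        if out[col].dtype == object:
            lut = {ch: i for i, ch in enumerate(sign_labels)}
            bad = ~out[col].astype(str).str.strip().isin(lut)
            if bad.any():
                raise ValueError(
                    f"unrecognized label in column {col!r} at row {int(np.flatnonzero(bad)[0])}"
                )
            out[col] = out[col].astype(str).str.strip().map(lut)
        out[col] = out[col].astype(int)

    for col in ("proposed_sign", "own_sign_before", "own_category",
                "own_category_after", "pass", "item_id", "decision"):
        decode(col)
    bad = ~out["decision"].isin([0, 1])
    if bad.any():
        raise ValueError(f"non-binary decision at row {int(np.flatnonzero(bad)[0])}")
    init_c = _decode_vec(initial_c, sign_labels)
    init_s = _decode_vec(initial_s, sign_labels)
    return BehaviorLog(
        participant_id=participant_id, pair_id=pair_id, dataset_label=dataset_label,
        trials=out, initial_c=init_c, initial_s=init_s,
    )


def _decode_vec(values, sign_labels: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    lut = {ch: i for i, ch in enumerate(sign_labels)}
    try:
        return np.array([lut[str(v).strip()] for v in arr], dtype=int)
    except KeyError as e:
        raise ValueError(f"unrecognized label {e.args[0]!r} in initial assignment") from None
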