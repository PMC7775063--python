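"""CSV readers/writers for simulation traces.

Traces round-trip losslessly at double precision (floats are written with
17 significant digits).  Gait traces carry run metadata (period, ground
height, touchdown events) in a JSON sidecar next to the CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import TorqueTrace
from .biomech import N_COORDS, GaitTrace
from .planar import PlanarTrace

__all__ = ["write_trace", "read_trace", "write_torque_trace", "read_torque_trace"]

_FLOAT = "%.17g"


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trace(path: str | Path, trace: PlanarTrace | GaitTrace) -> None:
    """Write a planar or gait trace as CSV (plus a JSON metadata sidecar)."""
    path = Path(path)
    trace.to_dataframe().to_csv(path, index=False, float_format=_FLOAT)
    if isinstance(trace, GaitTrace):
        meta = {
            "type": "gait",
            "period": trace.period,
            "ground_height": trace.ground_height,
            "touchdowns": [
                [t, side, list(map(float, pos))] for t, side, pos in trace.touchdowns
            ],
        }
    else:
        meta = {"type": "planar", "period": trace.period}
    _meta_path(path).write_text(json.dumps(meta))


def _require(df: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"trace file is missing columns: {missing}")


def read_trace(path: str | Path) -> PlanarTrace | GaitTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # surface the line number
        raise ValueError(f"malformed trace file {path}: {exc}") from exc
    meta = json.loads(_meta_path(path).read_text())
    if meta["type"] == "planar":
        cols = (
            ["t"]
            + [f"q{i}" for i in (1, 2, 3)]
            + [f"qd{i}" for i in (1, 2, 3)]
            + [f"x{i}" for i in (1, 2, 3)]
            + [f"y{i}" for i in (1, 2, 3)]
            + ["com_x", "com_y", "comv_x", "comv_y"]
            + ["j1", "j2", "T_bw", "T_bt", "f_x", "f_y", "M_z", "stance_side"]
        )
        _require(df, cols)
        link_xy = np.stack(
            [df[[f"x{i}", f"y{i}"]].to_numpy() for i in (1, 2, 3)], axis=1
        )
        return PlanarTrace(
            t=df["t"].to_numpy(),
            q=df[["q1", "q2", "q3"]].to_numpy(),
            qdot=df[["qd1", "qd2", "qd3"]].to_numpy(),
            com=df[["com_x", "com_y"]].to_numpy(),
            com_vel=df[["comv_x", "comv_y"]].to_numpy(),
            link_xy=link_xy,
            joint_angles=df[["j1", "j2"]].to_numpy(),
            torques=df[["T_bw", "T_bt"]].to_numpy(),
            grf=df[["f_x", "f_y"]].to_numpy(),
            ground_moment=df["M_z"].to_numpy(),
            stance_side=df["stance_side"].to_numpy(),
            period=meta["period"],
        )
    cols = ["t"] + [f"q{i + 1}" for i in range(N_COORDS)] + ["contact"]
    _require(df, cols)

    def vec(name):
        return df[[f"{name}_{ax}" for ax in "xyz"]].to_numpy()

    return GaitTrace(
        t=df["t"].to_numpy(),
        q=df[[f"q{i + 1}" for i in range(N_COORDS)]].to_numpy(),
        contact=df["contact"].to_numpy(),
        tiptoe_left=vec("tiptoe_left"),
        tiptoe_right=vec("tiptoe_right"),
        hip_left=vec("hip_left"),
        hip_right=vec("hip_right"),
        com=vec("com"),
        ground_height=meta["ground_height"],
        period=meta["period"],
        touchdowns=[
            (t, side, np.asarray(pos)) for t, side, pos in meta["touchdowns"]
        ],
    )


def write_torque_trace(path: str | Path, trace: TorqueTrace) -> None:
    path = Path(path)
    cols = {"t": trace.t}
    for i in range(3, N_COORDS):
        cols[f"G{i + 1}"] = trace.torques[:, i]
    for k, ax in enumerate("xyz"):
        cols[f"fc_{ax}"] = trace.contact_force[:, k]
    cols["contact"] = trace.contact
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT)
    _meta_path(path).write_text(
        json.dumps({"type": "torque", "period": trace.period,
                    "time_scale": trace.time_scale})
    )


def read_torque_trace(path: str | Path) -> TorqueTrace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(_meta_path(path).read_text())
    _require(df, ["t", "G4", "G33", "fc_x", "contact"])
    torques = np.zeros((len(df), N_COORDS))
    for i in range(3, N_COORDS):
        torques[:, i] = df[f"G{i + 1}"].to_numpy()
    return TorqueTrace(
        t=df["t"].to_numpy(),
        torques=torques,
        contact_force=df[["fc_x", "fc_y", "fc_z"]].to_numpy(),
        contact=df["contact"].to_numpy(),
        period=meta["period"],
        time_scale=meta["time_scale"],
    )
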