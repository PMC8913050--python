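"""Readers/writers for headered motion text files (.mot/.sto dialect) and CSV.

The dialect is the minimal OpenSim-style storage format: a name line,
``nRows=``/``nColumns=`` lines, an ``endheader`` line, then a tab-separated
table.  Columns are ``time`` (cycle fraction 0–1), ``knee_flexion``,
``knee_adduction``, ``knee_rotation`` (degrees), one row per cycle sample.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .gait_synth import GaitKinematics

COLUMNS = ["time", "knee_flexion", "knee_adduction", "knee_rotation"]


class MotionFileError(ValueError):
    """Malformed motion file; message names the file and offending line."""


def write_mot(path: str | Path, kin: GaitKinematics, name: str | None = None) -> None:
    path = Path(path)
    df = kin.to_frame()
    buf = io.StringIO()
    buf.write(f"{name or kin.subject_id}\n")
    buf.write(f"nRows={len(df)}\n")
    buf.write("nColumns=4\n")
    buf.write("endheader\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.9g")
    path.write_text(buf.getvalue())


def read_mot(path: str | Path, stance_fraction: float = 0.60) -> GaitKinematics:
    path = Path(path)
    lines = path.read_text().splitlines()
    n_rows = None
    header_end = None
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped.startswith("nRows"):
            try:
                n_rows = int(stripped.split("=", 1)[1])
            except (IndexError, ValueError):
                raise MotionFileError(f"{path}: line {i + 1}: unparseable nRows line {line!r}")
        if stripped == "endheader":
            header_end = i
            break
    if header_end is None:
        raise MotionFileError(f"{path}: no 'endheader' line found")
    body = "\n".join(lines[header_end + 1 :])
    try:
        df = pd.read_csv(io.StringIO(body), sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise MotionFileError(f"{path}: line {header_end + 2}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise MotionFileError(
            f"{path}: line {header_end + 2}: missing columns {missing}"
        )
    if n_rows is not None and len(df) != n_rows:
        raise MotionFileError(
            f"{path}: header declares nRows={n_rows} but table has {len(df)} rows"
        )
    if not np.all(np.isfinite(df[COLUMNS].to_numpy())):
        bad = int(np.argwhere(~np.isfinite(df[COLUMNS].to_numpy()))[0][0])
        raise MotionFileError(f"{path}: non-finite value in data row {bad + 1}")
    return GaitKinematics(
        subject_id=path.stem,
        flexion=df["knee_flexion"].to_numpy(),
        adduction=df["knee_adduction"].to_numpy(),
        internal_rotation=df["knee_rotation"].to_numpy(),
        stance_fraction=stance_fraction,
        n_points=len(df),
    )


def write_csv(path: str | Path, kin: GaitKinematics) -> None:
    kin.to_frame().to_csv(Path(path), index=False, float_format="%.9g")


def read_csv(path: str | Path, stance_fraction: float = 0.60) -> GaitKinematics:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise MotionFileError(f"{path}: missing columns {missing}")
    return GaitKinematics(
        subject_id=path.stem,
        flexion=df["knee_flexion"].to_numpy(),
        adduction=df["knee_adduction"].to_numpy(),
        internal_rotation=df["knee_rotation"].to_numpy(),
        stance_fraction=stance_fraction,
        n_points=len(df),
    )
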