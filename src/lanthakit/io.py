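"""Plain-text readers and writers for all pipeline inputs.

Formats are deliberately simple and diffable:

* titration tables — delimited text with header ``titrant_M,signal``;
* melting curves — ``temp_C,signal``;
* inversion-recovery series — ``ti_ms,signal`` plus ``# key: value``
  header lines for field strength, concentration and label;
* NMRD profiles — ``freq_MHz,R1_per_s``;
* trajectories — concatenated extended-XYZ blocks (count line, comment
  line, then ``name x y z`` records, Å); the name column is the group
  label.

Comment lines starting with ``#`` ahead of the header carry metadata
and generator provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import TitrationCurve
from .relaxometry import IRSeries, NMRDProfile
from .trajectory import Frame, Trajectory

__all__ = [
    "read_titration_table",
    "write_titration_table",
    "read_melting_table",
    "read_ir_series",
    "write_ir_series",
    "read_nmrd_profile",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
]


def _read_commented_csv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                meta[key.strip()] = value.strip()
        else:
            body_start = i
            break
    else:
        raise ValueError(f"{path}: no data rows found")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    if df.empty:
        raise ValueError(f"{path}: table contains no data rows")
    return df, meta


def read_titration_table(path: str | Path) -> TitrationCurve:
    df, meta = _read_commented_csv(path)
    if not {"titrant_M", "signal"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns titrant_M,signal")
    return TitrationCurve(df["titrant_M"].to_numpy(), df["signal"].to_numpy(), meta)


def write_titration_table(path: str | Path, curve: TitrationCurve) -> None:
    with open(path, "w") as fh:
        for key, value in curve.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("titrant_M,signal\n")
        for t, s in zip(curve.titrant, curve.signal):
            fh.write(f"{t:.10g},{s:.10g}\n")


def read_melting_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df, _ = _read_commented_csv(path)
    if not {"temp_C", "signal"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns temp_C,signal")
    return df["temp_C"].to_numpy(), df["signal"].to_numpy()


def read_ir_series(path: str | Path) -> IRSeries:
    df, meta = _read_commented_csv(path)
    if not {"ti_ms", "signal"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns ti_ms,signal")
    return IRSeries(
        ti=df["ti_ms"].to_numpy(),
        signal=df["signal"].to_numpy(),
        field=float(meta.get("field_T", 0.0)),
        label=meta.get("label", Path(path).stem),
        conc_gd=float(meta.get("conc_gd_mM", 0.0)),
        meta=meta,
    )


def write_ir_series(path: str | Path, series: IRSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"# field_T: {series.field}\n")
        fh.write(f"# conc_gd_mM: {series.conc_gd}\n")
        fh.write(f"# label: {series.label}\n")
        for key, value in series.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("ti_ms,signal\n")
        for t, s in zip(series.ti, series.signal):
            fh.write(f"{t:.10g},{s:.10g}\n")


def read_nmrd_profile(path: str | Path) -> NMRDProfile:
    df, meta = _read_commented_csv(path)
    if not {"freq_MHz", "R1_per_s"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns freq_MHz,R1_per_s")
    return NMRDProfile(
        frequency=df["freq_MHz"].to_numpy(),
        r1_observed=df["R1_per_s"].to_numpy(),
        temperature=float(meta.get("temperature_C", 25.0)),
        conc=float(meta.get("conc_mM", 1.0)),
    )


def write_xyz_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Concatenated extended-XYZ blocks; atom name = group label."""
    with open(path, "w") as fh:
        for frame in traj.frames:
            n_atoms = sum(len(c) for c in frame.groups.values())
            fh.write(f"{n_atoms}\n")
            fh.write(f"time_ps={frame.time}\n")
            for name, coords in frame.groups.items():
                for x, y, z in coords:
                    fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_trajectory(path: str | Path) -> Trajectory:
    """Parse concatenated XYZ blocks; malformed lines raise with line numbers."""
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from exc
        comment = lines[i + 1].strip() if i + 1 < len(lines) else ""
        time = 0.0
        if comment.startswith("time_ps="):
            time = float(comment.split("=", 1)[1])
        groups: dict[str, list[list[float]]] = {}
        for j in range(n_atoms):
            lineno = i + 2 + j
            if lineno >= len(lines):
                raise ValueError(f"{path}: truncated frame at line {lineno + 1}")
            parts = lines[lineno].split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno + 1}: expected 'name x y z'")
            try:
                xyz = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno + 1}: bad coordinate") from exc
            groups.setdefault(parts[0], []).append(xyz)
        frames.append(Frame(
            groups={k: np.asarray(v) for k, v in groups.items()}, time=time
        ))
        i += 2 + n_atoms
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(frames)
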