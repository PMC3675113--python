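"""T1 relaxometry from inversion-recovery null times.

In an inversion-recovery experiment the longitudinal magnetisation
passes through zero at the inversion time TI_null = T1 * ln 2, so the
nulling time read off a magnitude image gives T1 directly:
T1 = -TI_null / ln(0.5).  Relaxivity r1 (s^-1 mM^-1) is the slope of
the paramagnetic rate enhancement per unit Gd3+ concentration,

    r1 = (1/T1_sample - 1/T1_reference) / c(Gd3+),

with T1 in ms internally and rates reported in s^-1.  The module also
covers NMRD-profile referencing (the same formula per Larmor
frequency), the receptor-density detectability model (receptor copies
per cell averaged over a spherical cell volume), and the voxel-volume
arithmetic of the imaging protocol.

Note the nulling time of a sample and the T1 of the plain solvent are
distinct quantities even though both are conventionally written TI(0);
here they are kept apart by name (``null_time`` vs ``t1_ref``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.constants import Avogadro

__all__ = [
    "IRSeries",
    "RelaxivityRecord",
    "NMRDProfile",
    "t1_from_null_time",
    "null_time",
    "ir_signal",
    "find_null_time",
    "relaxivity_r1",
    "summarize_r1",
    "receptor_concentration",
    "voxel_volume",
    "nmrd_relaxivity",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class IRSeries:
    """Inversion-recovery magnitudes over a grid of inversion times (ms)."""

    ti: np.ndarray
    signal: np.ndarray
    field: float  # tesla
    label: str = ""
    conc_gd: float = 0.0  # mM; 0 marks a reference (buffer) series
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        ti = np.asarray(self.ti, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if ti.shape != s.shape or ti.ndim != 1:
            raise ValueError("ti and signal must be 1-D of equal length")
        if np.any(ti <= 0) or np.any(np.diff(ti) <= 0):
            raise ValueError("ti must be positive and strictly increasing")
        if np.any(s < 0):
            raise ValueError("magnitudes must be >= 0")
        object.__setattr__(self, "ti", ti)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class RelaxivityRecord:
    """One sample's T1 against a reference, with its Gd3+ concentration."""

    t1_sample: float  # ms
    t1_ref: float  # ms
    conc_gd: float  # mM
    field: float  # tesla
    label: str = ""

    @property
    def r1(self) -> float:
        return relaxivity_r1(self.t1_sample, self.t1_ref, self.conc_gd)


@dataclass(frozen=True)
class NMRDProfile:
    """Observed longitudinal rates versus proton Larmor frequency."""

    frequency: np.ndarray  # MHz, strictly increasing
    r1_observed: np.ndarray  # s^-1
    temperature: float = 25.0  # Celsius
    conc: float = 1.0  # mM

    def __post_init__(self):
        f = np.asarray(self.frequency, dtype=float)
        r = np.asarray(self.r1_observed, dtype=float)
        if f.shape != r.shape or f.ndim != 1:
            raise ValueError("frequency and r1_observed must be 1-D of equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency must be strictly increasing")
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "r1_observed", r)


def t1_from_null_time(ti0: float) -> float:
    """T1 (ms) from the signal-nulling inversion time: T1 = ti0 / ln 2."""
    if ti0 <= 0:
        raise ValueError("null time must be > 0")
    return ti0 / LN2


def null_time(t1: float) -> float:
    """Inversion time at which the signal nulls: T1 * ln 2 (ms)."""
    if t1 <= 0:
        raise ValueError("t1 must be > 0")
    return t1 * LN2


def ir_signal(s0: float, t1: float, ti) -> np.ndarray | float:
    """Inversion-recovery magnitude |s0 (1 - 2 exp(-ti/t1))|."""
    if s0 <= 0 or t1 <= 0:
        raise ValueError("s0 and t1 must be > 0")
    ti = np.asarray(ti, dtype=float)
    if np.any(ti < 0):
        raise ValueError("ti must be >= 0")
    out = np.abs(s0 * (1.0 - 2.0 * np.exp(-ti / t1)))
    return float(out) if out.ndim == 0 else out


def find_null_time(series: IRSeries) -> float:
    """Locate the signal null by parabolic interpolation at the minimum.

    Fits a parabola through the minimum-magnitude point and its two
    neighbours; a minimum at the grid edge means the null is not
    bracketed and is an error.
    """
    if series.ti.size < 5:
        raise ValueError("need >= 5 inversion times")
    i = int(np.argmin(series.signal))
    if i == 0 or i == series.ti.size - 1:
        raise ValueError("signal minimum at grid edge: null time not bracketed")
    x0, x1, x2 = series.ti[i - 1 : i + 2]
    y0, y1, y2 = series.signal[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a <= 0:  # degenerate/flat: fall back to the grid minimum
        return float(series.ti[i])
    vertex = -b / (2.0 * a)
    return float(np.clip(vertex, series.ti[0], series.ti[-1]))


def relaxivity_r1(t1_sample: float, t1_ref: float, conc_gd: float) -> float:
    """r1 = (1/T1_sample - 1/T1_ref) / c, T1 in ms, c in mM, r1 in s^-1 mM^-1."""
    if t1_sample <= 0 or t1_ref <= 0:
        raise ValueError("T1 values must be > 0")
    if conc_gd <= 0:
        raise ValueError("conc_gd must be > 0")
    return (1000.0 / t1_sample - 1000.0 / t1_ref) / conc_gd


def summarize_r1(records: Sequence[RelaxivityRecord]) -> dict[float, tuple[float, float]]:
    """Per-field mean and sample SD of r1 over replicate wells."""
    by_field: dict[float, list[float]] = {}
    for rec in records:
        by_field.setdefault(rec.field, []).append(rec.r1)
    out = {}
    for fld, values in sorted(by_field.items()):
        if len(values) < 2:
            raise ValueError(f"need >= 2 records at field {fld} T to form a summary")
        arr = np.asarray(values)
        out[fld] = (float(arr.mean()), float(arr.std(ddof=1)))
    return out


def receptor_concentration(n_receptors: float, diameter_um: float) -> float:
    """Cell-averaged receptor concentration in µM for a spherical cell.

    c = N / (N_A * V) with V = (pi/6) d^3; sets the ceiling on the
    cell-averaged concentration a receptor-targeted agent can reach.
    """
    if n_receptors < 0:
        raise ValueError("n_receptors must be >= 0")
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    volume_l = (math.pi / 6.0) * diameter_um**3 * 1e-15  # µm^3 -> L
    molar = n_receptors / (Avogadro * volume_l)
    return molar * 1e6


def voxel_volume(
    fov_read_mm: float,
    matrix_read: int,
    phase_fraction: float = 1.0,
    slice_mm: float = 3.0,
    rounding: int | None = 1,
) -> float:
    """Voxel volume (mm^3) from FOV, matrix size and slice thickness.

    Pixel size = FOV/matrix, optionally rounded to ``rounding`` decimals
    (protocol convention; ``None`` keeps exact arithmetic); the phase
    pixel is the read pixel divided by the phase-resolution fraction.
    """
    if matrix_read <= 0:
        raise ValueError("matrix_read must be > 0")
    if fov_read_mm <= 0 or slice_mm <= 0 or phase_fraction <= 0:
        raise ValueError("dimensions must be > 0")
    pixel = fov_read_mm / matrix_read
    if rounding is not None:
        pixel = round(pixel, rounding)
    return pixel * (pixel / phase_fraction) * slice_mm


def nmrd_relaxivity(profile: NMRDProfile, solvent_r1: np.ndarray) -> np.ndarray:
    """Reference an NMRD profile: (R1_observed - R1_solvent)/c per frequency."""
    solvent = np.asarray(solvent_r1, dtype=float)
    if solvent.shape != profile.frequency.shape:
        raise ValueError("solvent grid does not match the profile frequency grid")
    if profile.conc <= 0:
        raise ValueError("profile concentration must be > 0")
    return (profile.r1_observed - solvent) / profile.conc
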