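"""Contact forces at the body-seat interface: frames, balance, Sim-vs-Exp statistics.

A seated subject loads three surfaces: the seat back (SB), the seat pan (SP)
and the foot support (FS).  Forces live in the sagittal plane and are
expressed either in the global frame (x forward-horizontal, z upward,
right-handed about the lateral y axis) or in a surface-local frame whose
x axis lies in the surface plane and z axis is the surface normal.  The
local frame of a surface tilted by ``a`` degrees about y is obtained by
rotating the global frame by ``a``.

Seat geometry is described by the seat-pan angle SPA (tilt of the pan from
horizontal) and the seat-pan-to-backrest angle SP2BA (included angle between
pan and backrest planes); the backrest tilt from vertical follows as
``SPA + SP2BA - 90``, and that is also its plane's tilt used for the local
frame.  The footrest is horizontal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SURFACES = ("SB", "SP", "FS")
FRAMES = ("global", "local")


@dataclass(frozen=True)
class SeatConfig:
    """Geometry and loading of one seat configuration.

    Parameters
    ----------
    spa_deg:
        Seat-pan angle from horizontal, degrees, ``0 <= spa_deg < 90``.
    sp2ba_deg:
        Seat-pan-to-backrest included angle, degrees, ``90 < sp2ba_deg < 180``.
    body_weight_N:
        Subject weight force in newtons, positive.
    cof_seat, cof_foot:
        Friction coefficients carried as metadata (they parameterize the
        synthetic force generator, not any analysis step).
    """

    spa_deg: float
    sp2ba_deg: float
    body_weight_N: float
    cof_seat: float = 0.1
    cof_foot: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.spa_deg < 90.0:
            raise ValueError(f"spa_deg must be in [0, 90), got {self.spa_deg}")
        if not 90.0 < self.sp2ba_deg < 180.0:
            raise ValueError(f"sp2ba_deg must be in (90, 180), got {self.sp2ba_deg}")
        if not self.body_weight_N > 0:
            raise ValueError("body_weight_N must be positive")


@dataclass(frozen=True)
class PlanarForce:
    """A sagittal-plane force on one contact surface, in one frame."""

    fx: float
    fz: float
    frame: str
    surface: str

    def __post_init__(self) -> None:
        if self.surface not in SURFACES:
            raise ValueError(f"surface must be one of {SURFACES}, got {self.surface!r}")
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}, got {self.frame!r}")
        if not (math.isfinite(self.fx) and math.isfinite(self.fz)):
            raise ValueError("force components must be finite")

    @property
    def norm(self) -> float:
        return math.hypot(self.fx, self.fz)


def surface_tilt_angle(config: SeatConfig, surface: str) -> float:
    """Tilt (deg, about the lateral axis) of a contact surface's plane.

    Seat pan: SPA.  Backrest: SPA + SP2BA - 90 (tilt from vertical of the
    backrest plane equals the tilt of its local frame).  Footrest: 0.
    """
    if surface == "SP":
        return config.spa_deg
    if surface == "SB":
        return config.spa_deg + config.sp2ba_deg - 90.0
    if surface == "FS":
        return 0.0
    raise ValueError(f"unknown surface tag {surface!r}; expected one of {SURFACES}")


def rotate_global_to_local(f: PlanarForce, angle_deg: float) -> PlanarForce:
    """Rotate a global-frame force into a surface frame tilted by ``angle_deg``.

    fx_L = fx_G cos a + fz_G sin a;  fz_L = -fx_G sin a + fz_G cos a.
    The Euclidean norm is preserved.
    """
    if f.frame != "global":
        raise ValueError("rotate_global_to_local expects a global-frame force")
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return replace(f, fx=f.fx * c + f.fz * s, fz=-f.fx * s + f.fz * c, frame="local")


def rotate_local_to_global(f: PlanarForce, angle_deg: float) -> PlanarForce:
    """Inverse of :func:`rotate_global_to_local`."""
    if f.frame != "local":
        raise ValueError("rotate_local_to_global expects a local-frame force")
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return replace(f, fx=f.fx * c - f.fz * s, fz=f.fx * s + f.fz * c, frame="global")


def force_balance(
    forces: list[PlanarForce], config: SeatConfig
) -> tuple[float, float]:
    """Signed static-balance residuals (Sum_Fx, Sum_Fz) of a global force set.

    The three surface reactions (one per SB/SP/FS, global frame) should
    balance gravity: vertical reactions are negative (body pushing down on
    the surfaces), so the body weight enters the vertical sum with positive
    sign.  Both sums are zero for a perfectly measured equilibrium.
    """
    seen = {f.surface for f in forces}
    if seen != set(SURFACES) or len(forces) != 3:
        missing = set(SURFACES) - seen
        raise ValueError(f"need exactly one global force per surface; missing {sorted(missing)}")
    if any(f.frame != "global" for f in forces):
        raise ValueError("force_balance expects global-frame forces")
    sum_fx = sum(f.fx for f in forces)
    sum_fz = sum(f.fz for f in forces) + config.body_weight_N
    return sum_fx, sum_fz


def balance_magnitudes(forces: list[PlanarForce], config: SeatConfig) -> tuple[float, float]:
    """|Sum_Fx|, |Sum_Fz| — the magnitudes reported in validation tables."""
    sum_fx, sum_fz = force_balance(forces, config)
    return abs(sum_fx), abs(sum_fz)


# ---------------------------------------------------------------------------
# Sim-vs-Exp comparison statistics

#: threshold below which a reference value counts as zero for D%
_DPCT_EPS = 1e-9


def compare_conditions(sim: pd.DataFrame, exp: pd.DataFrame) -> pd.DataFrame:
    """Per-condition differences D = Sim - Exp plus an "All" mean row.

    Both tables are indexed by condition label with one numeric column per
    compared quantity.  The output holds one D row per condition, in the
    input condition order, and a final ``All`` row with the per-quantity
    mean difference over conditions.
    """
    if list(sim.index) != list(exp.index):
        bad = sorted(set(sim.index).symmetric_difference(exp.index)) or list(sim.index)
        raise ValueError(f"condition labels do not match: {bad}")
    if list(sim.columns) != list(exp.columns):
        bad = sorted(set(sim.columns).symmetric_difference(exp.columns))
        raise ValueError(f"quantity columns do not match: {bad}")
    d = sim - exp
    d.loc["All"] = d.mean(axis=0)
    return d


def percent_difference(sim: pd.DataFrame, exp: pd.DataFrame) -> pd.DataFrame:
    """D% = 100 (Sim - Exp) / |Exp|, NaN where the reference is ~0."""
    if list(sim.index) != list(exp.index) or list(sim.columns) != list(exp.columns):
        raise ValueError("sim and exp tables must share index and columns")
    denom = exp.abs().where(exp.abs() >= _DPCT_EPS)
    return 100.0 * (sim - exp) / denom


# ---------------------------------------------------------------------------
# CSV interface: columns condition, surface, frame, fx, fz (N)


def read_force_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format force CSV, normalizing unicode minus signs."""
    text = Path(path).read_text(encoding="utf-8").replace("−", "-")
    from io import StringIO

    df = pd.read_csv(StringIO(text))
    required = {"condition", "surface", "frame", "fx", "fz"}
    if not required.issubset(df.columns):
        raise ValueError(f"force table missing columns {sorted(required - set(df.columns))}")
    df["fx"] = df["fx"].astype(float)
    df["fz"] = df["fz"].astype(float)
    return df


def write_force_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def forces_from_table(df: pd.DataFrame, condition: str, frame: str = "global") -> list[PlanarForce]:
    """Extract one PlanarForce per surface for a condition from a long table."""
    sel = df[(df["condition"] == condition) & (df["frame"] == frame)]
    return [
        PlanarForce(fx=row.fx, fz=row.fz, frame=frame, surface=row.surface)
        for row in sel.itertuples()
    ]


def condition_force_row(
    forces: list[PlanarForce], config: SeatConfig
) -> dict[str, float]:
    """Assemble the 12 per-condition force quantities of a validation table.

    Global Fx/Fz for SB, SP, FS; local Fx/Fz for SB and SP (the footrest is
    horizontal so its local components equal the global ones and are not
    repeated); signed Sum_Fx and Sum_Fz.
    """
    by_surface = {f.surface: f for f in forces}
    row: dict[str, float] = {}
    for s in SURFACES:
        f = by_surface[s]
        row[f"Fx_{s}_G"] = f.fx
        row[f"Fz_{s}_G"] = f.fz
    for s in ("SB", "SP"):
        loc = rotate_global_to_local(by_surface[s], surface_tilt_angle(config, s))
        row[f"Fx_{s}_L"] = loc.fx
        row[f"Fz_{s}_L"] = loc.fz
    sum_fx, sum_fz = force_balance(forces, config)
    row["Sum_Fx"] = sum_fx
    row["Sum_Fz"] = sum_fz
    return row
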