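"""Pressure-mat metrics: correction factor, CA/PP/MP, profiles and regions.

The measurement device is a thin sensor mat (natively 48 x 48 sensors at a
12.7 mm pitch) laid on the seat-pan or backrest cushion, sampling interface
pressure in kPa.  Capacitive mats drift, so a trial-specific multiplicative
correction factor ``fcorr`` rescales each map until its integral equals the
normal force measured by load cells.  All summary metrics (contact area CA,
peak pressure PP, mean pressure MP) are computed on the corrected map.

Fore-aft structure on the seat pan is summarized by the lateral profile
SOC (sum over columns, one value per row) whose peak row marks the ischial
tuberosities; four fore-aft regions (I: rear of the peak, II-IV: successive
halvings toward the thigh end) partition the supported load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_PITCH_MM = 12.7
#: default contact threshold, kPa: below the mat's rated floor, above numeric noise
DEFAULT_THRESHOLD_KPA = 0.1


@dataclass
class PressureGrid:
    """A calibrated pressure-mat frame.

    ``values`` is a rows x cols array in kPa; row index increases rear to
    front (fore-aft axis), column index runs laterally.
    """

    values: np.ndarray
    pitch_mm: float = DEFAULT_PITCH_MM
    surface: str = "SP"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("pressure grid must be 2-D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("pressure values must be finite and non-negative")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")

    @property
    def cell_area_mm2(self) -> float:
        return self.pitch_mm**2

    def integral_N(self) -> float:
        """Map integral as a force: sum(kPa) * mm^2 * 1e-3 = N."""
        return float(self.values.sum() * self.cell_area_mm2 * 1e-3)

    def scaled(self, factor: float) -> "PressureGrid":
        return PressureGrid(self.values * factor, self.pitch_mm, self.surface)


@dataclass(frozen=True)
class PressureSummary:
    ca_mm2: float
    pp_kpa: float
    mp_kpa: float
    fcorr: float

    def __post_init__(self) -> None:
        if self.ca_mm2 < 0 or self.fcorr <= 0:
            raise ValueError("invalid summary: CA >= 0 and fcorr > 0 required")


@dataclass(frozen=True)
class PressureProfiles:
    soc: np.ndarray  # per-row sums (lateral profile)
    sor: np.ndarray  # per-column sums (frontal profile)


@dataclass(frozen=True)
class RegionPartition:
    """Fore-aft seat-pan partition from the lateral profile.

    Row indices: x_beg first active row (rear), x_max peak row, x_end last
    active row (thigh end); x_mid1 midpoint of (x_max, x_end), x_mid2
    midpoint of (x_mid1, x_end).  p_i..p_iv are load proportions (%) in
    regions I=[x_beg,x_max), II=[x_max,x_mid1), III=[x_mid1,x_mid2),
    IV=[x_mid2,x_end].
    """

    x_beg: int
    x_max: int
    x_mid1: int
    x_mid2: int
    x_end: int
    p_i: float
    p_ii: float
    p_iii: float
    p_iv: float
    degenerate: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.x_beg <= self.x_max <= self.x_mid1 <= self.x_mid2 <= self.x_end:
            raise ValueError("partition boundaries must be ordered")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.p_i, self.p_ii, self.p_iii, self.p_iv])


def correction_factor(grid: PressureGrid, normal_force_N: float) -> float:
    """Trial-specific factor making the map integral equal the normal force.

    fcorr = |F| / (sum(p_kPa) * pitch_mm^2 * 1e-3).  Multiplying the grid by
    fcorr makes its integral exactly |F|.
    """
    if normal_force_N == 0:
        raise ValueError("normal force must be nonzero")
    total = grid.integral_N()
    if total <= 0:
        raise ValueError("cannot correct a zero-pressure grid")
    return abs(normal_force_N) / total


def summarize(
    grid: PressureGrid,
    normal_force_N: float,
    threshold_kpa: float = DEFAULT_THRESHOLD_KPA,
) -> PressureSummary:
    """CA, PP and MP of the corrected map.

    CA counts corrected cells above the contact threshold times the cell
    area; PP is the corrected maximum; MP is the mean corrected pressure
    over active cells, i.e. (corrected load on active cells)/CA — equal to
    normal_force/CA when the threshold truncates no load.
    """
    if threshold_kpa < 0:
        raise ValueError("threshold must be >= 0")
    fcorr = correction_factor(grid, normal_force_N)
    corrected = grid.values * fcorr
    active = corrected > threshold_kpa
    n_active = int(active.sum())
    ca = n_active * grid.cell_area_mm2
    pp = float(corrected.max())
    mp = float(corrected[active].mean()) if n_active else float("nan")
    return PressureSummary(ca_mm2=ca, pp_kpa=pp, mp_kpa=mp, fcorr=fcorr)


def profiles(grid: PressureGrid) -> PressureProfiles:
    """Lateral (per-row) and frontal (per-column) pressure profiles."""
    return PressureProfiles(soc=grid.values.sum(axis=1), sor=grid.values.sum(axis=0))


def _round_half_rear(x: float) -> int:
    """Round to nearest integer row, exact halves toward the rear (floor)."""
    import math

    f = math.floor(x)
    return f if x - f <= 0.5 else f + 1


def partition_regions(
    soc: np.ndarray, threshold: float = 0.0
) -> RegionPartition:
    """Partition the lateral profile into the four fore-aft load regions.

    Active rows are those with profile value strictly above ``threshold``;
    the rear-most and front-most active rows bound the partition, the peak
    row (first row of a tied maximum) splits off region I, and two midpoint
    rows (nearest integer, halves toward the rear) split the remainder into
    II/III/IV.  Proportions are percentages of the active-span load and sum
    to 100.  Zero-width regions contribute 0 % and are flagged.
    """
    soc = np.asarray(soc, dtype=float)
    active = np.nonzero(soc > threshold)[0]
    if active.size == 0:
        raise ValueError("no profile row exceeds the contact threshold")
    x_beg, x_end = int(active[0]), int(active[-1])
    span = soc[x_beg : x_end + 1]
    x_max = x_beg + int(np.argmax(span))
    x_mid1 = _round_half_rear((x_max + x_end) / 2.0)
    x_mid2 = _round_half_rear((x_mid1 + x_end) / 2.0)

    # regions: I=[x_beg,x_max) II=[x_max,x_mid1) III=[x_mid1,x_mid2) IV=[x_mid2,x_end]
    bounds = [(x_beg, x_max), (x_max, x_mid1), (x_mid1, x_mid2), (x_mid2, x_end + 1)]
    sums = np.array([soc[a:b].sum() for a, b in bounds])
    total = sums.sum()
    if total <= 0:
        raise ValueError("active span carries no load")
    props = 100.0 * sums / total
    names = ("I", "II", "III", "IV")
    degenerate = tuple(n for (a, b), n in zip(bounds, names) if b <= a)
    return RegionPartition(
        x_beg=x_beg,
        x_max=x_max,
        x_mid1=x_mid1,
        x_mid2=x_mid2,
        x_end=x_end,
        p_i=props[0],
        p_ii=props[1],
        p_iii=props[2],
        p_iv=props[3],
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# I/O: headerless CSV matrices in kPa, row 0 = rear edge


def read_pressure_csv(
    path: str | Path, pitch_mm: float = DEFAULT_PITCH_MM, surface: str = "SP"
) -> PressureGrid:
    values = np.loadtxt(path, delimiter=",", dtype=float)
    return PressureGrid(values=np.atleast_2d(values), pitch_mm=pitch_mm, surface=surface)


def write_pressure_csv(grid: PressureGrid, path: str | Path) -> None:
    np.savetxt(path, grid.values, delimiter=",", fmt="%.6g")
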