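"""Bundled reference dataset: a four-configuration seating validation campaign.

One mid-sized male subject (body weight 784.8 N) seated on a reconfigurable
seat with 50 mm foam cushions, seat-pan angle SPA swept over 0/5/10/15 deg
with the pan-to-backrest angle fixed at 100 deg.  The tables hold the
campaign's experimental (Exp) and simulated (Sim) values:

* contact forces (N) per surface in global and local frames plus the
  balance sums,
* pressure summary parameters (contact area mm^2, peak/mean pressure kPa,
  fore-aft region proportions %, correction factors),
* under-ischium tissue thickness (mm) and ROI volume reduction (%) with
  and without tissue sliding,
* the material parameter sets of the constitutive laws.

These printed values are inputs: demo fixtures, cross-checks for the frame
transforms and comparison statistics, and qualitative anchors for the
tissue metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .frames import SeatConfig
from .materials import FoamParams, OgdenParams, default_foam_loading_curve

CONDITIONS = ("SPA0", "SPA5", "SPA10", "SPA15")
BODY_WEIGHT_N = 784.8
SP2BA_DEG = 100.0

FORCE_COLUMNS = [
    "Fx_SB_G", "Fz_SB_G", "Fx_SP_G", "Fz_SP_G", "Fx_FS_G", "Fz_FS_G",
    "Fx_SB_L", "Fz_SB_L", "Fx_SP_L", "Fz_SP_L", "Sum_Fx", "Sum_Fz",
]

_FORCES_EXP = [
    [-73.5, -32.0, 59.2, -697.0, 7.6, -66.0, -78.0, -18.7, 59.2, -697.0, 6.7, -10.2],
    [-98.8, -37.3, 88.4, -689.2, 8.2, -68.1, -105.1, -10.5, 28.0, -694.3, 2.2, -9.9],
    [-126.2, -72.8, 113.9, -643.0, 9.8, -73.5, -143.5, -25.2, 0.5, -653.0, -2.5, -4.3],
    [-167.8, -109.4, 150.5, -578.2, 17.3, -97.7, -198.3, -28.2, -4.3, -597.4, 0.0, -0.5],
]
_FORCES_SIM = [
    [-76.8, -16.2, 67.8, -705.2, 9.0, -64.1, -78.5, -2.6, 67.8, -705.2, -0.1, -0.7],
    [-118.7, -29.6, 111.3, -694.8, 9.1, -60.9, -122.3, 2.2, 50.3, -701.9, 1.8, -0.5],
    [-157.7, -52.4, 140.3, -661.1, 19.6, -73.9, -166.1, 4.7, 23.3, -675.4, 2.1, -2.6],
    [-202.4, -87.1, 174.7, -608.4, 30.4, -94.4, -220.3, 6.6, 11.2, -632.9, 2.6, -5.1],
]

PRESSURE_COLUMNS = [
    "CA_SB", "PP_SB", "MP_SB", "CA_SP", "PP_SP", "MP_SP",
    "P_I", "P_II", "P_III", "P_IV", "fcorr_SB", "fcorr_SP",
]

_PRESSURE_EXP = [
    [40968, 3.2, 1.9, 168225, 13.4, 4.1, 36.7, 42.4, 13.4, 7.5, 1.76, 1.38],
    [49355, 3.5, 2.1, 165484, 14.1, 4.2, 40.4, 40.9, 12.1, 6.5, 1.69, 1.48],
    [71451, 3.3, 2.0, 165967, 14.7, 3.9, 37.2, 43.1, 13.8, 6.0, 1.81, 1.54],
    [80806, 3.8, 2.5, 158871, 12.1, 3.8, 40.9, 42.5, 11.5, 5.1, 1.67, 1.64],
]
_PRESSURE_SIM = [
    [46935, 4.9, 1.9, 176774, 13.1, 4.2, 39.2, 42.7, 11.3, 6.7, np.nan, np.nan],
    [65968, 5.4, 2.1, 174354, 13.2, 4.2, 39.1, 42.4, 11.5, 6.9, np.nan, np.nan],
    [78387, 5.8, 2.3, 176451, 12.2, 4.0, 42.2, 39.8, 11.4, 6.7, np.nan, np.nan],
    [100322, 6.2, 2.4, 168871, 12.2, 3.9, 43.5, 41.8, 10.4, 4.3, np.nan, np.nan],
]

TISSUE_COLUMNS = [
    "T_preload_20", "T_loaded_20", "R_20", "T_preload_50", "T_loaded_50", "R_50",
]

# rows: (condition, sliding Y/N)
_TISSUE = {
    ("SPA0", "Y"): [38.8, 14.1, 60.8, 41.0, 19.3, 50.8],
    ("SPA0", "N"): [38.9, 16.8, 51.8, 41.2, 22.1, 42.4],
    ("SPA5", "Y"): [38.8, 15.4, 58.5, 41.1, 20.5, 49.1],
    ("SPA5", "N"): [38.8, 17.7, 51.5, 41.0, 23.1, 42.4],
    ("SPA10", "Y"): [38.8, 16.0, 56.1, 41.1, 21.1, 46.3],
    ("SPA10", "N"): [38.9, 18.2, 47.3, 41.2, 23.4, 37.8],
    ("SPA15", "Y"): [38.8, 16.0, 54.8, 41.1, 21.0, 45.3],
    ("SPA15", "N"): [38.9, 18.0, 47.5, 41.2, 23.3, 38.5],
}


def seat_configs() -> dict[str, SeatConfig]:
    """The four campaign seat configurations keyed by condition label."""
    return {
        label: SeatConfig(
            spa_deg=float(label.removeprefix("SPA")),
            sp2ba_deg=SP2BA_DEG,
            body_weight_N=BODY_WEIGHT_N,
        )
        for label in CONDITIONS
    }


def force_table(source: str = "exp") -> pd.DataFrame:
    """Per-condition force quantities (N); source in {'exp', 'sim'}."""
    data = {"exp": _FORCES_EXP, "sim": _FORCES_SIM}[source.lower()]
    return pd.DataFrame(data, index=list(CONDITIONS), columns=FORCE_COLUMNS)


def pressure_table(source: str = "exp") -> pd.DataFrame:
    """Per-condition pressure summary parameters; source in {'exp', 'sim'}."""
    data = {"exp": _PRESSURE_EXP, "sim": _PRESSURE_SIM}[source.lower()]
    return pd.DataFrame(data, index=list(CONDITIONS), columns=PRESSURE_COLUMNS)


def tissue_table() -> pd.DataFrame:
    """ROI thickness/volume-reduction values, indexed by (condition, sliding)."""
    idx = pd.MultiIndex.from_tuples(_TISSUE.keys(), names=["condition", "sliding"])
    return pd.DataFrame(list(_TISSUE.values()), index=idx, columns=TISSUE_COLUMNS)


def soft_tissue_material() -> OgdenParams:
    """Flesh: single-term Ogden (neo-Hookean), mu = 3e-6 GPa = 3 kPa, alpha = 2."""
    return OgdenParams.neo_hookean(mu_kpa=3.0, poisson=0.499, density_kg_mm3=9.0e-7)


def seat_pan_foam(scale: float = 1.15) -> FoamParams:
    """Seat-pan cushion: HU 0.65, SHAPE 8, tensile E 1.04e-4 GPa.

    The tabulated loading curve is a synthetic stand-in with the canonical
    low-density-foam shape (the campaign's measured curve was not published
    numerically); ``scale`` defaults to the 1.15 calibration factor.
    """
    return FoamParams(
        loading_curve=default_foam_loading_curve(),
        hu=0.65,
        shape=8.0,
        scale=scale,
        e_tensile_gpa=1.04e-4,
        density_kg_mm3=5.0e-8,
    )


def backrest_foam(scale: float = 1.15) -> FoamParams:
    """Backrest cushion: HU 0.65, SHAPE 5, tensile E 8.75e-5 GPa."""
    return FoamParams(
        loading_curve=default_foam_loading_curve(stiffness_kpa=4.5),
        hu=0.65,
        shape=5.0,
        scale=scale,
        e_tensile_gpa=8.75e-5,
        density_kg_mm3=4.9e-8,
    )
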