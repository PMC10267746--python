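"""Seeded synthetic inputs: pressure maps, equilibrium force sets, mesh pairs.

The validation pipeline normally consumes a pressure-mat recording, load-cell
force tables and pre/post-loading tissue meshes.  This module fabricates all
three with known ground truth so every analysis stage can be exercised and
checked end to end:

* **Pressure maps** — two ischial-tuberosity Gaussian peaks plus a thigh
  ridge on the seat pan (or a diffuse patch for the backrest), scaled to a
  target normal force, then degraded by a known multiplicative calibration
  error and log-normal sensor noise.
* **Force sets** — global-frame surface reactions constructed to satisfy
  static balance exactly for a given body weight and seat geometry, plus
  noisy "measured" copies.
* **Tissue mesh pairs** — a hexahedral flesh column compressed to the
  stretch that balances the applied stress through the flesh/foam series
  stack, with an optional kinematic "sliding" mode that thins the column
  under the ischium (emulating gluteal tissue escaping laterally from under
  the bone, which raises the ROI volume reduction).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import materials
from .frames import SeatConfig, PlanarForce, surface_tilt_angle
from .pressure import PressureGrid, DEFAULT_PITCH_MM, DEFAULT_THRESHOLD_KPA
from .tissue import SoftTissueMesh, make_box_mesh

GRID_N = 48  # native mat resolution


@dataclass(frozen=True)
class MapRecipe:
    """Recipe for one synthetic seat-pan (or backrest) pressure map.

    ``it_peaks`` are (row, col, amplitude kPa, spread mm) Gaussian blobs,
    where spread may be a scalar or a (fore-aft, lateral) pair;
    ``thigh_ridge`` is ((row_lo, row_hi), amplitude kPa, lateral spread mm).
    The noise-free map is scaled so its true integral equals
    ``target_force_N`` and then divided by ``calibration_error`` so that the
    correction-factor analysis should recover exactly that factor.
    """

    it_peaks: tuple = ((13, 18, 13.5, 30.0), (13, 29, 13.5, 30.0))
    thigh_ridge: tuple = ((19, 44), 10.0, 75.0)
    target_force_N: float = 694.3
    calibration_error: float = 1.48
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.it_peaks:
            spreads = (p[3],) if np.isscalar(p[3]) else tuple(p[3])
            if p[2] <= 0 or any(s <= 0 for s in spreads):
                raise ValueError("peak amplitudes and spreads must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.target_force_N <= 0 or self.calibration_error <= 0:
            raise ValueError("target force and calibration error must be positive")


def gen_pressure_map(
    recipe: MapRecipe,
    shape: tuple[int, int] = (GRID_N, GRID_N),
    pitch_mm: float = DEFAULT_PITCH_MM,
    threshold_kpa: float = DEFAULT_THRESHOLD_KPA,
) -> tuple[PressureGrid, dict]:
    """Synthesize a mat frame; returns (measured grid, ground truth).

    Ground truth reports the calibrated noise-free map's contact area, peak
    pressure, peak row (of the lateral profile) and the injected
    calibration factor.
    """
    rows, cols = shape
    r = np.arange(rows)[:, None] * pitch_mm
    c = np.arange(cols)[None, :] * pitch_mm
    true = np.zeros((rows, cols))
    for pr, pc, amp, spread in recipe.it_peaks:
        s_r, s_c = (spread, spread) if np.isscalar(spread) else spread
        true += amp * np.exp(
            -((r - pr * pitch_mm) ** 2) / (2 * s_r**2)
            - ((c - pc * pitch_mm) ** 2) / (2 * s_c**2)
        )
    (r_lo, r_hi), ridge_amp, ridge_spread = recipe.thigh_ridge
    if ridge_amp > 0:
        mid_col = (cols - 1) / 2.0 * pitch_mm
        in_rows = ((r >= r_lo * pitch_mm) & (r <= r_hi * pitch_mm)).astype(float)
        # pressure under the thighs decays toward the knee (front) end
        frac = np.clip((r / pitch_mm - r_lo) / max(r_hi - r_lo, 1), 0.0, 1.0)
        fore_aft = 1.0 - 0.85 * frac
        lateral = np.exp(-((c - mid_col) ** 2) / (2 * ridge_spread**2))
        true += ridge_amp * in_rows * fore_aft * lateral
    true[true < 0.3] = 0.0  # sensor floor: cells below mat sensitivity read zero
    integral_N = true.sum() * pitch_mm**2 * 1e-3
    true *= recipe.target_force_N / integral_N

    truth = {
        "fcorr": recipe.calibration_error,
        "ca_mm2": float((true > threshold_kpa).sum() * pitch_mm**2),
        "pp_kpa": float(true.max()),
        "peak_row": int(np.argmax(true.sum(axis=1))),
        "force_N": recipe.target_force_N,
    }
    measured = true / recipe.calibration_error
    if recipe.noise_cv > 0:
        rng = np.random.default_rng(recipe.seed)
        sigma = math.sqrt(math.log(1.0 + recipe.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=measured.shape)
        measured = measured * noise
    return PressureGrid(values=measured, pitch_mm=pitch_mm), truth


# ---------------------------------------------------------------------------


def gen_force_set(
    config: SeatConfig,
    load_split: tuple[float, float, float] = (0.12, 0.78, 0.10),
    noise_sd_N: float = 3.0,
    seed: int = 0,
) -> dict[str, list[PlanarForce]]:
    """Statically admissible global force sets for one seat configuration.

    ``load_split`` gives the SB/SP/FS fractions of body weight carried
    vertically.  Horizontal components follow the surface tilt through a
    friction-like coupling (the seat COF), and the backrest shear closes the
    horizontal balance so the noiseless set satisfies sum Fx = 0 and
    sum Fz + W = 0 exactly.  Returns ``truth`` (noiseless) plus two
    independent noisy draws ``exp`` and ``sim``.
    """
    split = np.asarray(load_split, dtype=float)
    if split.shape != (3,) or np.any(split < 0) or not math.isclose(split.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("load_split must be three non-negative fractions summing to 1")
    w = config.body_weight_N
    fz = -split * w  # SB, SP, FS vertical reactions (downward on the surfaces)
    tilt_sp = math.radians(surface_tilt_angle(config, "SP"))
    tilt_fs = math.radians(surface_tilt_angle(config, "FS"))
    fx_sp = config.cof_seat * abs(fz[1]) * math.tan(tilt_sp)
    fx_fs = config.cof_foot * abs(fz[2]) * math.tan(tilt_fs)
    fx_sb = -(fx_sp + fx_fs)
    truth = [
        PlanarForce(fx=fx_sb, fz=fz[0], frame="global", surface="SB"),
        PlanarForce(fx=fx_sp, fz=fz[1], frame="global", surface="SP"),
        PlanarForce(fx=fx_fs, fz=fz[2], frame="global", surface="FS"),
    ]
    rng = np.random.default_rng(seed)

    def noisy() -> list[PlanarForce]:
        return [
            replace(f, fx=f.fx + rng.normal(0, noise_sd_N), fz=f.fz + rng.normal(0, noise_sd_N))
            for f in truth
        ]

    return {"truth": truth, "exp": noisy(), "sim": noisy()}


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnModel:
    """A 1-D tissue-over-foam column under the ischial tuberosity.

    The flesh column (thickness ~40 mm) and the cushion foam (50 mm) carry
    the same nominal stress in series; ``applied_stress_kpa`` is the seated
    load per unit area.  ``sliding_fraction`` in [0, 1] switches on the
    kinematic tissue-sliding mode.
    """

    flesh: materials.OgdenParams
    foam: materials.FoamParams
    flesh_thickness_mm: float = 40.0
    foam_thickness_mm: float = 50.0
    applied_stress_kpa: float = 8.0
    sliding_fraction: float = 0.0
    lateral_size_mm: float = 120.0

    def __post_init__(self) -> None:
        if self.flesh_thickness_mm <= 0 or self.foam_thickness_mm <= 0:
            raise ValueError("thicknesses must be positive")
        if not 0.0 <= self.sliding_fraction <= 1.0:
            raise ValueError("sliding_fraction must lie in [0, 1]")


#: radial spread (mm) of the sliding indentation under the ischium
_SLIDE_SPREAD_MM = 20.0
#: indentation depth as a fraction of the total axial compression at full sliding
_SLIDE_DEPTH_FACTOR = 0.3
#: radial outflow amplitude at full sliding (fraction of local radius)
_SLIDE_OUTFLOW = 0.15


def gen_tissue_pair(
    model: ColumnModel, mesh_density_mm: float = 5.0, seed: int = 0
) -> tuple[SoftTissueMesh, SoftTissueMesh, np.ndarray, dict]:
    """Pre/post-loading flesh meshes plus the ischium landmark.

    The pre mesh is a hexahedral block (lateral_size^2 x flesh thickness)
    whose top-centre node is the ischium point.  The post mesh shares the
    connectivity with a displacement field: uniform axial compression to
    the stretch balancing the applied stress through the Ogden law, plus —
    when sliding is enabled — an extra Gaussian indentation under the
    ischium with a volume-shedding radial outflow.  Returns
    (pre, post, ischium_point, metadata).
    """
    if mesh_density_mm > model.flesh_thickness_mm / 4.0:
        raise ValueError("mesh_density_mm must be <= flesh thickness / 4")
    t = model.flesh_thickness_mm
    L = model.lateral_size_mm
    pre = make_box_mesh(origin=(-L / 2, -L / 2, 0.0), size=(L, L, t), spacing_mm=mesh_density_mm)
    ischium = np.array([0.0, 0.0, t])

    lam = materials.ogden_compressive_stretch(model.flesh, model.applied_stress_kpa)
    foam_strain = materials.equilibrium_strain(model.foam, model.applied_stress_kpa)

    s = model.sliding_fraction
    depth = s * _SLIDE_DEPTH_FACTOR * (1.0 - lam) * t
    if lam - depth / t <= 0:
        raise ValueError(
            f"sliding indentation inverts the column (lambda={lam:.3f}, depth={depth:.1f} mm)"
        )
    nodes = pre.nodes.copy()
    x, y, z = nodes[:, 0], nodes[:, 1], nodes[:, 2]
    r2 = x**2 + y**2
    gauss = np.exp(-r2 / (2 * _SLIDE_SPREAD_MM**2))
    z_new = lam * z - depth * (z / t) * gauss
    radial = 1.0 + s * _SLIDE_OUTFLOW * (z / t) * gauss
    nodes = np.column_stack([x * radial, y * radial, z_new])
    post = SoftTissueMesh(nodes=nodes, hexes=pre.hexes.copy())
    meta = {
        "stretch": lam,
        "foam_strain": foam_strain,
        "foam_settlement_mm": foam_strain * model.foam_thickness_mm,
        "slide_depth_mm": depth,
        "seed": seed,
    }
    return pre, post, ischium, meta
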