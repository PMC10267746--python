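"""Uniaxial material laws for flesh and seat foam.

Two constitutive families drive the seated load path:

* **Flesh** (lumped muscle + adipose tissue) — an incompressible Ogden
  hyperelastic solid.  With a single term and exponent alpha = 2 the law
  reduces to neo-Hookean, sigma = mu (lambda - lambda^-2) in nominal stress
  vs stretch.

* **Cushion foam** — a low-density open-cell foam described by a tabulated
  nominal loading curve (optionally scaled by a calibration factor) and a
  hysteretic unloading branch parameterized by the unloading factor HU in
  (0, 1] and the shape factor SHAPE > 0.  The unloading branch used here
  interpolates between the loading stress and its HU-scaled floor through
  the stored-energy ratio raised to SHAPE:

      sigma_u(e) = sigma_L(e) * [HU + (1 - HU) (W(e)/W(e_max))^SHAPE]

  with W(e) the loading strain energy integral.  This form is this
  package's own definition — solvers that expose HU/SHAPE do not publish
  their internal equations — chosen so that the branch is continuous with
  loading at e_max, collapses to the elastic curve at HU = 1, always lies
  below loading, and dissipates more as SHAPE grows.

Compression strain and stress are positive for foam; the Ogden law is
signed (compressive stress negative).  Everything is quasi-static and
rate-independent (reloading creep decay BETA defaults to 0, reloading
retraces the loading curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize


@dataclass(frozen=True)
class OgdenParams:
    """Incompressible Ogden parameters: terms of (mu_i [kPa], alpha_i)."""

    terms: tuple[tuple[float, float], ...]
    poisson: float = 0.499
    density_kg_mm3: float = 9.0e-7

    def __post_init__(self) -> None:
        if sum(mu * a for mu, a in self.terms) <= 0:
            raise ValueError("sum(mu_i * alpha_i) must be positive")
        if not 0 < self.poisson < 0.5:
            raise ValueError("poisson must lie in (0, 0.5)")

    @classmethod
    def neo_hookean(cls, mu_kpa: float, **kw) -> "OgdenParams":
        return cls(terms=((mu_kpa, 2.0),), **kw)


@dataclass
class FoamParams:
    """Low-density foam: tabulated loading curve + hysteretic unloading.

    loading_curve rows are (nominal strain, nominal stress kPa), strictly
    increasing in strain, passing through (0, 0), non-decreasing in stress.
    ``scale`` multiplies the tabulated stresses (curve calibration factor).
    """

    loading_curve: np.ndarray
    hu: float = 0.65
    shape: float = 8.0
    beta: float = 0.0
    scale: float = 1.0
    e_tensile_gpa: float = 1.04e-4
    density_kg_mm3: float = 5.0e-8

    def __post_init__(self) -> None:
        c = np.asarray(self.loading_curve, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 2:
            raise ValueError("loading_curve must be an (n>=2, 2) array")
        if not (c[0, 0] == 0.0 and c[0, 1] == 0.0):
            raise ValueError("loading curve must pass through (0, 0)")
        if np.any(np.diff(c[:, 0]) <= 0):
            raise ValueError("loading curve strains must be strictly increasing")
        if np.any(np.diff(c[:, 1]) < 0):
            raise ValueError("loading curve stress must be non-decreasing")
        if not 0 < self.hu <= 1:
            raise ValueError("hu must lie in (0, 1]")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        self.loading_curve = c

    @property
    def max_strain(self) -> float:
        return float(self.loading_curve[-1, 0])


@dataclass(frozen=True)
class StressStrainCurve:
    points: np.ndarray  # ordered (strain, stress) pairs
    mode: str  # "loading" | "unloading"

    @property
    def strain(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def stress(self) -> np.ndarray:
        return self.points[:, 1]


# ---------------------------------------------------------------------------
# Ogden / neo-Hookean


def ogden_uniaxial_stress(p: OgdenParams, stretch):
    """Nominal uniaxial stress of an incompressible Ogden solid at stretch(es).

    sigma(l) = sum_i mu_i (l^(a_i - 1) - l^(-a_i/2 - 1)); zero at l = 1,
    negative in compression (l < 1).
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    sigma = np.zeros_like(lam)
    for mu, a in p.terms:
        sigma = sigma + mu * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
    return sigma if sigma.ndim else float(sigma)


def ogden_energy(p: OgdenParams, stretch):
    """Strain energy density W(l) = sum_i (mu_i/a_i)(l^a_i + 2 l^(-a_i/2) - 3)."""
    lam = np.asarray(stretch, dtype=float)
    w = np.zeros_like(lam)
    for mu, a in p.terms:
        w = w + (mu / a) * (lam**a + 2.0 * lam ** (-a / 2.0) - 3.0)
    return w if w.ndim else float(w)


def ogden_compressive_stretch(p: OgdenParams, stress_magnitude_kpa: float) -> float:
    """Stretch l in (0, 1] at which |sigma(l)| equals a compressive load."""
    if stress_magnitude_kpa < 0:
        raise ValueError("stress magnitude must be >= 0")
    if stress_magnitude_kpa == 0:
        return 1.0
    f = lambda lam: ogden_uniaxial_stress(p, lam) + stress_magnitude_kpa
    lo = 1e-6
    if f(lo) > 0:
        raise ValueError("load exceeds the representable compressive range")
    return brentq(f, lo, 1.0, xtol=1e-12, rtol=1e-14)


# ---------------------------------------------------------------------------
# Foam loading / unloading branches


def foam_loading_stress(p: FoamParams, strain):
    """Scaled piecewise-linear loading stress; no extrapolation past the table."""
    e = np.asarray(strain, dtype=float)
    if np.any(e < 0) or np.any(e > p.max_strain + 1e-12):
        raise ValueError(
            f"strain outside tabulated range [0, {p.max_strain}]"
        )
    s = p.scale * np.interp(e, p.loading_curve[:, 0], p.loading_curve[:, 1])
    return s if s.ndim else float(s)


def _loading_energy(p: FoamParams, strains: np.ndarray) -> np.ndarray:
    """Cumulative strain energy W(e) = int_0^e sigma_L de at given strains.

    Exact for the piecewise-linear curve: trapezoid over the union of curve
    knots and the query points.
    """
    knots = p.loading_curve[:, 0]
    grid = np.union1d(knots[knots <= strains.max() + 1e-15], strains)
    sig = p.scale * np.interp(grid, p.loading_curve[:, 0], p.loading_curve[:, 1])
    w_grid = np.concatenate(
        [[0.0], np.cumsum(0.5 * (sig[1:] + sig[:-1]) * np.diff(grid))]
    )
    return np.interp(strains, grid, w_grid)


def foam_unloading_stress(p: FoamParams, strain, strain_max: float):
    """Hysteretic unloading stress after loading to ``strain_max``.

    Continuous with the loading branch at strain_max; bounded below by
    HU * loading stress; equal to loading for HU = 1.
    """
    e = np.atleast_1d(np.asarray(strain, dtype=float))
    scalar = np.ndim(strain) == 0
    if strain_max <= 0 or strain_max > p.max_strain + 1e-12:
        raise ValueError("strain_max must lie in (0, max tabulated strain]")
    if np.any(e < 0) or np.any(e > strain_max + 1e-12):
        raise ValueError("unloading strain must lie in [0, strain_max]")
    sig_l = np.asarray(foam_loading_stress(p, e))
    w = _loading_energy(p, e)
    w_max = _loading_energy(p, np.array([strain_max]))[0]
    if w_max <= 0:
        raise ValueError("loading curve stores no energy up to strain_max")
    ratio = np.clip(w / w_max, 0.0, 1.0)
    sig_u = sig_l * (p.hu + (1.0 - p.hu) * ratio**p.shape)
    return float(sig_u[0]) if scalar else sig_u


def simulate_compression_test(
    p: FoamParams,
    max_strain: float = 0.8,
    strain_step: float = 0.01,
    sample_mm: tuple[float, float, float] = (50.0, 50.0, 50.0),
) -> tuple[StressStrainCurve, StressStrainCurve]:
    """Quasi-static uniaxial compression cycle on a cubic foam sample.

    Load at constant (nominal) strain rate to ``max_strain``, unload back to
    zero.  Rate-independent (beta = 0), so the sample size only sets the
    nominal geometry metadata; returns (loading, unloading) branches.
    """
    if not 0 < max_strain <= p.max_strain:
        raise ValueError("max_strain must lie in (0, max tabulated strain]")
    n = max(2, int(round(max_strain / strain_step)) + 1)
    e = np.linspace(0.0, max_strain, n)
    load = np.column_stack([e, np.asarray(foam_loading_stress(p, e))])
    unload = np.column_stack(
        [e[::-1], np.asarray(foam_unloading_stress(p, e[::-1], max_strain))]
    )
    return (
        StressStrainCurve(points=load, mode="loading"),
        StressStrainCurve(points=unload, mode="unloading"),
    )


def cycle_dissipation(loading: StressStrainCurve, unloading: StressStrainCurve) -> float:
    """Energy dissipated per unit volume over a load-unload cycle (>= 0)."""
    w_load = np.trapezoid(loading.stress, loading.strain)
    # unloading runs strain_max -> 0; integrate in increasing strain
    order = np.argsort(unloading.strain)
    w_unload = np.trapezoid(unloading.stress[order], unloading.strain[order])
    return float(w_load - w_unload)


def equilibrium_strain(p: FoamParams, applied_stress_kpa: float) -> float:
    """Static compression strain at which the loading stress balances a load."""
    if applied_stress_kpa < 0:
        raise ValueError("applied stress must be >= 0")
    if applied_stress_kpa == 0:
        return 0.0
    s_max = foam_loading_stress(p, p.max_strain)
    if applied_stress_kpa > s_max:
        raise ValueError("applied stress exceeds the tabulated curve")
    f = lambda e: foam_loading_stress(p, e) - applied_stress_kpa
    return brentq(f, 0.0, p.max_strain, xtol=1e-12, rtol=1e-14)


# ---------------------------------------------------------------------------
# HU / SHAPE identification

#: hu within this distance of 1 means the data carry no hysteresis and
#: shape cannot be identified
_HU_DEGENERATE_TOL = 1e-3


def identify_unloading_params(
    loading_curve: np.ndarray,
    measured_unloading: StressStrainCurve,
    scale: float = 1.0,
    hu_grid: np.ndarray | None = None,
    shape_grid: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Least-squares fit of (HU, SHAPE) to a measured unloading branch.

    Coarse grid search over hu in (0, 1] x shape in [0.25, 25], then
    Nelder-Mead refinement of the RMSE.  Returns (hu, shape, rmse); when
    the fitted hu is ~1 the data carry no hysteresis, shape is
    unidentifiable and returned as NaN.
    """
    pts = measured_unloading.points
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 strain points on the unloading branch")
    if np.allclose(pts[:, 1], 0.0):
        raise ValueError("degenerate unloading curve (all-zero stresses)")
    e_meas, s_meas = pts[:, 0], pts[:, 1]
    strain_max = float(e_meas.max())

    def rmse(hu: float, shape: float) -> float:
        p = FoamParams(loading_curve=loading_curve, hu=hu, shape=shape, scale=scale)
        pred = np.asarray(foam_unloading_stress(p, e_meas, strain_max))
        return float(np.sqrt(np.mean((pred - s_meas) ** 2)))

    if hu_grid is None:
        hu_grid = np.linspace(0.05, 1.0, 20)
    if shape_grid is None:
        shape_grid = np.concatenate([np.linspace(0.25, 10, 40), np.linspace(10.5, 25, 30)])
    best = min(
        ((rmse(h, s), h, s) for h in hu_grid for s in shape_grid), key=lambda t: t[0]
    )
    _, hu0, shape0 = best

    def objective(x):
        h = float(np.clip(x[0], 1e-3, 1.0))
        s = float(np.clip(x[1], 1e-2, 50.0))
        return rmse(h, s)

    res = minimize(objective, x0=[hu0, shape0], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    hu = float(np.clip(res.x[0], 1e-3, 1.0))
    shape = float(np.clip(res.x[1], 1e-2, 50.0))
    err = objective(res.x)
    if hu >= 1.0 - _HU_DEGENERATE_TOL:
        return 1.0, float("nan"), err
    return hu, shape, err


def default_foam_loading_curve(
    stiffness_kpa: float = 6.0, densification_strain: float = 0.6
) -> np.ndarray:
    """A plausible open-cell polyurethane compression curve, tabulated.

    Linear elastic toe, long plateau, densification upturn — the canonical
    three-regime shape of low-density seat foams, with a plateau of a few
    kPa so that a seated subject compresses a 50 mm cushion substantially.
    """
    e = np.linspace(0.0, 0.8, 33)
    plateau = stiffness_kpa * 0.6
    s = np.where(
        e < 0.1,
        stiffness_kpa * e / 0.1 * 0.6,
        plateau + 0.8 * (e - 0.1),
    )
    dens = e > densification_strain
    s = s + np.where(dens, 200.0 * (e - densification_strain) ** 2, 0.0)
    s[0] = 0.0
    return np.column_stack([e, s])
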