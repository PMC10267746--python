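"""Config-driven orchestration producing the three validation reports.

Three report shapes mirror the validation campaign's summary tables:

* **forces** — per condition, global and local contact forces on seat back
  (SB), seat pan (SP) and foot support (FS), balance sums, Sim - Exp
  differences (D) and their All-row means;
* **pressure** — contact area, peak and mean pressure per surface, fore-aft
  region proportions, correction factors, with D and D% rows;
* **tissue** — under-ischium mean thickness before/after loading and ROI
  volume reduction for the 20 and 50 mm cylinders, with and without
  tissue sliding.

Two input routes exist: the bundled printed reference tables (locals,
sums and statistics recomputed from the printed global values), and a
file-based route reading the CSV/VTK fixture set written by
:func:`write_fixtures`.  Reports are deterministic for fixed inputs;
randomness lives only in the generators.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, reference, synthetic
from .frames import (
    PlanarForce,
    SeatConfig,
    compare_conditions,
    condition_force_row,
    forces_from_table,
    percent_difference,
    read_force_table,
    rotate_global_to_local,
    surface_tilt_angle,
)
from .pressure import (
    DEFAULT_PITCH_MM,
    DEFAULT_THRESHOLD_KPA,
    PressureGrid,
    partition_regions,
    profiles,
    read_pressure_csv,
    summarize,
    write_pressure_csv,
)
from .tissue import SoftTissueMesh, build_roi, roi_stats

log = logging.getLogger("sitpress")

SLIDING_FLAGS = ("Y", "N")


@dataclass
class StudyConfig:
    """Study layout: conditions, input locations, thresholds."""

    data_dir: Path
    conditions: dict[str, SeatConfig]
    threshold_kpa: float = DEFAULT_THRESHOLD_KPA
    pitch_mm: float = DEFAULT_PITCH_MM
    ray_grid_mm: float = 2.0
    roi_diameters_mm: tuple[float, ...] = (20.0, 50.0)
    ischium_point: tuple[float, float, float] = (0.0, 0.0, 40.0)
    seat_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        conditions = {
            label: SeatConfig(
                spa_deg=float(spec["spa_deg"]),
                sp2ba_deg=float(raw.get("sp2ba_deg", reference.SP2BA_DEG)),
                body_weight_N=float(raw.get("body_weight_N", reference.BODY_WEIGHT_N)),
            )
            for label, spec in raw["conditions"].items()
        }
        return cls(
            data_dir=path.parent,
            conditions=conditions,
            threshold_kpa=float(raw.get("threshold_kpa", DEFAULT_THRESHOLD_KPA)),
            pitch_mm=float(raw.get("pitch_mm", DEFAULT_PITCH_MM)),
            ray_grid_mm=float(raw.get("ray_grid_mm", 2.0)),
            roi_diameters_mm=tuple(raw.get("roi_diameters_mm", (20.0, 50.0))),
            ischium_point=tuple(raw.get("ischium_point", (0.0, 0.0, 40.0))),
            seat_normal=tuple(raw.get("seat_normal", (0.0, 0.0, 1.0))),
            seed=int(raw.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "body_weight_N": next(iter(self.conditions.values())).body_weight_N,
            "sp2ba_deg": next(iter(self.conditions.values())).sp2ba_deg,
            "conditions": {k: {"spa_deg": v.spa_deg} for k, v in self.conditions.items()},
            "threshold_kpa": self.threshold_kpa,
            "pitch_mm": self.pitch_mm,
            "ray_grid_mm": self.ray_grid_mm,
            "roi_diameters_mm": list(self.roi_diameters_mm),
            "ischium_point": list(self.ischium_point),
            "seat_normal": list(self.seat_normal),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False), encoding="utf-8")

    def config_hash(self) -> str:
        # hash the scientific configuration only, not the storage location
        items = {k: v for k, v in self.__dict__.items() if k != "data_dir"}
        blob = repr(sorted(items.items(), key=lambda kv: kv[0])).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def surface_normal_force(
    forces: list[PlanarForce], config: SeatConfig, surface: str
) -> float:
    """Magnitude of the normal force on a surface from its global force.

    In the tilted local frames the seat-pan normal is the local z component
    while the near-vertical backrest's normal is the local x component; the
    footrest is horizontal so its normal is the global z component.
    """
    f = next(f for f in forces if f.surface == surface)
    if surface == "FS":
        return abs(f.fz)
    loc = rotate_global_to_local(f, surface_tilt_angle(config, surface))
    return abs(loc.fx) if surface == "SB" else abs(loc.fz)


# ---------------------------------------------------------------------------
# Printed-value route


def printed_forces_report() -> pd.DataFrame:
    """Force report recomputed from the bundled printed global forces.

    Locals and balance sums are recomputed by the package (rotation /
    balance), not copied; D rows and the All means follow.
    """
    configs = reference.seat_configs()
    rows = {}
    for source in ("exp", "sim"):
        printed = reference.force_table(source)
        for cond in reference.CONDITIONS:
            forces = [
                PlanarForce(
                    fx=printed.loc[cond, f"Fx_{s}_G"],
                    fz=printed.loc[cond, f"Fz_{s}_G"],
                    frame="global",
                    surface=s,
                )
                for s in ("SB", "SP", "FS")
            ]
            rows[(source.capitalize(), cond)] = condition_force_row(forces, configs[cond])
    table = pd.DataFrame(rows).T
    exp = table.loc["Exp"]
    sim = table.loc["Sim"]
    d = compare_conditions(sim, exp)
    exp.loc["All"] = exp.mean(axis=0)
    sim.loc["All"] = sim.mean(axis=0)
    return _stack_report({"Exp": exp, "Sim": sim, "D": d})


def printed_pressure_report() -> pd.DataFrame:
    """Pressure report from printed areas/proportions with MP recomputed.

    Mean pressures are recomputed as normal force / contact area, the
    package's uniform MP definition, using normal forces rotated from the
    printed global force pairs; CA, PP, proportions and fcorr are carried
    from the printed tables.  D and D% rows (All D% from the All means)
    complete the report.
    """
    configs = reference.seat_configs()
    out = {}
    for source in ("exp", "sim"):
        printed = reference.pressure_table(source)
        force_tab = reference.force_table(source)
        tab = printed.copy()
        for cond in reference.CONDITIONS:
            forces = [
                PlanarForce(
                    fx=force_tab.loc[cond, f"Fx_{s}_G"],
                    fz=force_tab.loc[cond, f"Fz_{s}_G"],
                    frame="global",
                    surface=s,
                )
                for s in ("SB", "SP", "FS")
            ]
            for surf in ("SB", "SP"):
                fn = surface_normal_force(forces, configs[cond], surf)
                tab.loc[cond, f"MP_{surf}"] = fn / printed.loc[cond, f"CA_{surf}"] * 1e3
        out[source.capitalize()] = tab
    d = compare_conditions(out["Sim"], out["Exp"])
    for tab in out.values():
        tab.loc["All"] = tab.mean(axis=0)
    dpct = percent_difference(out["Sim"], out["Exp"])
    out["D"] = d
    out["D%"] = dpct
    return _stack_report(out)


# ---------------------------------------------------------------------------
# Fixture materialization


def write_fixtures(out_dir: str | Path, seed: int = 0) -> StudyConfig:
    """Materialize a complete demo dataset (4 conditions x Exp/Sim).

    Force CSVs carry the printed global values; pressure maps and tissue
    mesh pairs are synthesized with condition-matched targets (normal
    forces and correction factors from the reference tables, applied
    under-ischium stress scaled from the peak pressures).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs = reference.seat_configs()
    study = StudyConfig(data_dir=out, conditions=configs, seed=seed)

    # force tables, long format (global frame)
    for source in ("exp", "sim"):
        printed = reference.force_table(source)
        recs = []
        for cond in reference.CONDITIONS:
            for s in ("SB", "SP", "FS"):
                recs.append(
                    dict(condition=cond, surface=s, frame="global",
                         fx=printed.loc[cond, f"Fx_{s}_G"], fz=printed.loc[cond, f"Fz_{s}_G"])
                )
        pd.DataFrame(recs).to_csv(out / f"forces_{source}.csv", index=False)

    # pressure maps
    printed_p = reference.pressure_table("exp")
    for i, cond in enumerate(reference.CONDITIONS):
        for j, source in enumerate(("exp", "sim")):
            force_tab = reference.force_table(source)
            forces = forces_from_table(read_force_table(out / f"forces_{source}.csv"), cond)
            for k, surf in enumerate(("SP", "SB")):
                fn = surface_normal_force(forces, configs[cond], surf)
                calib = printed_p.loc[cond, f"fcorr_{surf}"] if source == "exp" else 1.0
                noise = 0.05 if source == "exp" else 0.0
                if surf == "SP":
                    recipe = synthetic.MapRecipe(
                        target_force_N=fn, calibration_error=float(calib),
                        noise_cv=noise, seed=seed + 97 * i + 13 * j + k,
                    )
                else:
                    recipe = synthetic.MapRecipe(
                        it_peaks=((28, 23, 2.8, 60.0),),
                        thigh_ridge=((0, 0), 0.0, 1.0),
                        target_force_N=fn, calibration_error=float(calib),
                        noise_cv=noise, seed=seed + 97 * i + 13 * j + k,
                    )
                grid, _ = synthetic.gen_pressure_map(recipe)
                write_pressure_csv(grid, out / f"pressure_{cond}_{source}_{surf}.csv")

    # tissue mesh pairs: applied stress scaled from the condition's peak pressure
    flesh = reference.soft_tissue_material()
    foam = reference.seat_pan_foam()
    for i, cond in enumerate(reference.CONDITIONS):
        sigma = 0.7 * printed_p.loc[cond, "PP_SP"]
        for flag, s_frac in (("Y", 1.0), ("N", 0.0)):
            model = synthetic.ColumnModel(
                flesh=flesh, foam=foam, applied_stress_kpa=float(sigma),
                sliding_fraction=s_frac,
            )
            pre, post, ischium, _ = synthetic.gen_tissue_pair(model, seed=seed + i)
            pre.save(out / f"tissue_{cond}_{flag}_pre.vtk")
            post.save(out / f"tissue_{cond}_{flag}_post.vtk")
    study.ischium_point = (0.0, 0.0, 40.0)
    study.to_yaml(out / "study.yaml")
    return study


# ---------------------------------------------------------------------------
# File-based runs


def run_forces(study: StudyConfig) -> pd.DataFrame:
    """Assemble the force report from the study's force CSVs."""
    tabs = {}
    for source in ("exp", "sim"):
        path = study.data_dir / f"forces_{source}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing force table {path}")
        long = read_force_table(path)
        missing = [c for c in study.conditions if c not in set(long["condition"])]
        if missing:
            raise ValueError(f"force table {path} lacks conditions {missing}")
        rows = {
            cond: condition_force_row(forces_from_table(long, cond), cfg)
            for cond, cfg in study.conditions.items()
        }
        tabs[source.capitalize()] = pd.DataFrame(rows).T
    d = compare_conditions(tabs["Sim"], tabs["Exp"])
    for tab in tabs.values():
        tab.loc["All"] = tab.mean(axis=0)
    tabs["D"] = d
    return _stack_report(tabs)


def run_pressure(study: StudyConfig) -> pd.DataFrame:
    """Assemble the pressure report from the study's grids and force CSVs."""
    out = {}
    for source in ("exp", "sim"):
        long = read_force_table(study.data_dir / f"forces_{source}.csv")
        rows = {}
        for cond, cfg in study.conditions.items():
            forces = forces_from_table(long, cond)
            row: dict[str, float] = {}
            for surf in ("SB", "SP"):
                path = study.data_dir / f"pressure_{cond}_{source}_{surf}.csv"
                if not path.exists():
                    raise FileNotFoundError(f"missing pressure map {path}")
                grid = read_pressure_csv(path, pitch_mm=study.pitch_mm, surface=surf)
                fn = surface_normal_force(forces, cfg, surf)
                summ = summarize(grid, fn, study.threshold_kpa)
                row[f"CA_{surf}"] = summ.ca_mm2
                row[f"PP_{surf}"] = summ.pp_kpa
                row[f"MP_{surf}"] = summ.mp_kpa
                row[f"fcorr_{surf}"] = summ.fcorr
                if surf == "SP":
                    corrected = grid.scaled(summ.fcorr)
                    part = partition_regions(
                        profiles(corrected).soc, study.threshold_kpa
                    )
                    if part.degenerate:
                        log.warning("%s %s: degenerate regions %s", cond, source, part.degenerate)
                    for name, val in zip(
                        ("P_I", "P_II", "P_III", "P_IV"), part.proportions
                    ):
                        row[name] = val
            rows[cond] = row
        out[source.capitalize()] = pd.DataFrame(rows).T[reference.PRESSURE_COLUMNS]
    d = compare_conditions(out["Sim"], out["Exp"])
    for tab in out.values():
        tab.loc["All"] = tab.mean(axis=0)
    out["D"] = d
    out["D%"] = percent_difference(out["Sim"], out["Exp"])
    return _stack_report(out)


def run_tissue(study: StudyConfig) -> pd.DataFrame:
    """Assemble the tissue report from the study's mesh pairs."""
    rows = {}
    rois = {
        d: build_roi(study.ischium_point, study.seat_normal, d)
        for d in study.roi_diameters_mm
    }
    for cond in study.conditions:
        for flag in SLIDING_FLAGS:
            meshes = {}
            for state in ("pre", "post"):
                path = study.data_dir / f"tissue_{cond}_{flag}_{state}.vtk"
                try:
                    meshes[state] = SoftTissueMesh.load(path)
                except (OSError, ValueError) as exc:
                    raise RuntimeError(f"cannot read mesh {path}: {exc}") from exc
            row = {}
            for d, roi in rois.items():
                tag = f"{d:.0f}"
                s_pre = roi_stats(meshes["pre"], roi, study.ray_grid_mm)
                s_post = roi_stats(meshes["post"], roi, study.ray_grid_mm)
                row[f"T_preload_{tag}"] = s_pre.t_mean_mm
                row[f"T_loaded_{tag}"] = s_post.t_mean_mm
                row[f"R_{tag}"] = (1.0 - s_post.v_mm3 / s_pre.v_mm3) * 100.0
            rows[(cond, flag)] = row
    table = pd.DataFrame(rows).T
    table.index.names = ["condition", "sliding"]
    for flag in SLIDING_FLAGS:
        table.loc[("All", flag), :] = table.xs(flag, level="sliding").mean(axis=0)
    return table


# ---------------------------------------------------------------------------
# Report output


def _stack_report(tabs: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Interleave per-source tables into a condition x source row block."""
    conditions = list(tabs[next(iter(tabs))].index)
    rows = {}
    for cond in conditions:
        for name, tab in tabs.items():
            if cond in tab.index:
                rows[(cond, name)] = tab.loc[cond]
    report = pd.DataFrame(rows).T
    report.index.names = ["condition", "row"]
    return report


_PRECISION = {"CA": 0, "PP": 1, "MP": 1, "P_": 1, "fcorr": 2, "F": 1, "Sum": 1, "T_": 1, "R_": 1}


def _column_precision(col: str) -> int:
    for prefix, dec in _PRECISION.items():
        if col.startswith(prefix):
            return dec
    return 1


def write_report(
    report: pd.DataFrame, path: str | Path, study: StudyConfig | None = None
) -> None:
    """CSV with provenance header plus a fixed-precision text rendering."""
    path = Path(path)
    header = [f"# sitpress {__version__}"]
    if study is not None:
        header.append(f"# config_hash={study.config_hash()} seed={study.seed}")
    body = report.to_csv()
    path.write_text("\n".join(header) + "\n" + body, encoding="utf-8")
    rendered = report.copy()
    for col in rendered.columns:
        rendered[col] = rendered[col].map(
            lambda v, d=_column_precision(col): "" if pd.isna(v) else f"{v:.{d}f}"
        )
    path.with_suffix(".txt").write_text(rendered.to_string() + "\n", encoding="utf-8")


def read_report(path: str | Path, n_index: int = 2) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=list(range(n_index)))
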