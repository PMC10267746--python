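# sitpress

Analysis toolkit for validating seated human–seat interaction models:
contact-force frame transforms and balance checks, pressure-mat summary
metrics, under-ischium soft-tissue compression, and cushion/flesh material
laws — plus seeded synthetic generators that stand in for the measurement
rig and the finite-element solver.

It is written for biomechanics and ergonomics researchers who compare a
simulated sitting human against pressure-mat and load-cell measurements
across seat configurations (seat-pan angle SPA, pan-to-backrest angle
SP2BA) and need the comparison parameters computed reproducibly:

* **Forces** — surface reactions on seat back (SB), seat pan (SP) and foot
  support (FS) rotated between the global frame and tilted surface-local
  frames (`fx_L = fx_G cos a + fz_G sin a`, `fz_L = −fx_G sin a + fz_G cos a`,
  with `a = SPA` for the pan and `a = SPA + SP2BA − 90` for the backrest),
  balance residuals `Σ Fx` and `Σ Fz + W`, and Sim − Exp difference
  statistics.
* **Pressure** — trial-specific correction factor
  `fcorr = F_normal / ∫ p dA`, contact area CA, peak pressure PP, mean
  pressure MP = F/CA, lateral/frontal profiles (SOC/SOR), and the four
  fore-aft seat-pan load regions P_I–P_IV split at the profile peak and two
  midpoint rows.
* **Tissue** — mean thickness and volume reduction
  `R = (1 − V_loaded/V_preload) · 100 %` inside 20 mm and 50 mm cylinder
  ROIs under the ischial tuberosity, by consistent ray-cast quadrature on
  volumetric meshes (VTK legacy ASCII).
* **Materials** — incompressible Ogden/neo-Hookean flesh, tabulated
  low-density-foam loading with hysteretic unloading (HU, SHAPE), virtual
  compression tests and least-squares HU/SHAPE identification.

A reference dataset from a four-configuration validation campaign (one
mid-sized male, 784.8 N, SPA 0–15°, SP2BA 100°) is bundled and doubles as
the demo input and cross-check fixture.  See `docs/methods.md` for the
model details and assumptions.

## Worked example

```sh
$ sitpress all --out study_out --seed 1
all reports written under study_out/reports
```

This materializes a synthetic fixture set (force CSVs, pressure maps,
tissue mesh pairs for 4 conditions × Exp/Sim) and writes five reports.
The same steps are available as narrative scripts under `analysis/`
(`01_generate_fixtures.py` … `05_foam_identification.py`), which print
their findings, e.g.:

```
printed-value force report -> results/forces_printed.csv
  mean Sim-Exp differences (N): backrest Fx -22.3, seat-pan Fz -15.5, seat-pan shear (local) 17.3
printed-value pressure report -> results/pressure_printed.csv
  recomputed Exp seat-pan MP (kPa): 4.1, 4.2, 3.9, 3.8
  backrest contact-area mean error: 20.2 %
synthetic-fixture pressure report -> results/pressure_synthetic.csv
  recovered seat-pan calibration factors: 1.38, 1.48, 1.54, 1.64
  ROI 20 mm: mean R with sliding 61.4 % vs without 47.9 %
  ROI 50 mm: mean R with sliding 58.4 % vs without 47.9 %
seat_pan: recovered HU=0.650 SHAPE=8.00 (true 0.65, 8.0)
```

Reading: the simulated model over-predicts backrest horizontal force by
22.3 N on average (small against the 785 N body weight); mean seat-pan
pressure recomputed as force/area reproduces the measured 4.1–3.8 kPa;
the injected mat calibration errors are recovered exactly by the
correction-factor analysis; and enabling tissue sliding raises the
under-ischium volume reduction in both ROIs, the qualitative signature the
tissue metric is designed to detect.

As a library:

```python
from sitpress import SeatConfig, PlanarForce, rotate_global_to_local, surface_tilt_angle

cfg = SeatConfig(spa_deg=5, sp2ba_deg=100, body_weight_N=784.8)
f = PlanarForce(fx=88.4, fz=-689.2, frame="global", surface="SP")
local = rotate_global_to_local(f, surface_tilt_angle(cfg, "SP"))
print(f"{local.fx:.1f}")   # 28.0  (seat-pan shear, N)
```

## Layout

```
src/sitpress/      frames, pressure, tissue, materials, synthetic,
                   reference (bundled campaign tables), pipeline, cli, vtkio
analysis/          numbered narrative drivers writing under results/
tests/             pytest suite (unit, property and validation-level tests)
scripts/           acceptance.py
docs/methods.md    models, assumptions, numerical choices, limitations
```
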