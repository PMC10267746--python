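# Methods

`sitpress` implements the analysis side of a seating-comfort validation
campaign: given contact-force tables, pressure-mat recordings and
pre/post-loading soft-tissue meshes for a set of seat configurations, it
computes the comparison parameters used to judge a seated human-body model
against measurements.  Because the finite-element solver and the
instrumented seat are not desk-reproducible, a synthetic-data module
generates statistically structured stand-ins for all three input kinds with
known ground truth, so that every analysis stage is testable end to end.

## Seat geometry and force frames

A configuration is described by the seat-pan angle SPA (tilt from
horizontal, 0–15° in the bundled campaign), the pan-to-backrest included
angle SP2BA (fixed at 100°), and the subject weight W (784.8 N).  Forces
live in the sagittal plane: global x forward-horizontal, z upward,
right-handed about the lateral y axis.  Each contact surface (seat back SB,
seat pan SP, foot support FS) carries a local frame obtained by rotating
the global frame about y by the surface tilt:

* seat pan: `tilt = SPA`
* backrest: `tilt = SPA + SP2BA − 90` (its tilt from vertical)
* footrest: `tilt = 0`

with `fx_L = fx_G cos a + fz_G sin a`, `fz_L = −fx_G sin a + fz_G cos a`.
The sign convention of the positive x direction is not uniquely fixed by
the campaign tables alone; the one above reproduces every bundled local
value from its global pair to within the 0.1 N printing precision, which is
the criterion by which it was chosen.  A consequence worth noting: in the
seat-pan frame the normal force is the local z component, while for the
near-vertical backrest it is the local x component (checked against
mean-pressure × area consistency for all four conditions).

Static balance residuals are `Sum_Fx = Σ fx` and `Sum_Fz = Σ fz + W` (the
vertical reactions are negative, so W enters positively).  The bundled
table prints the SPA0 horizontal residual with the opposite sign to the
column arithmetic; the package therefore reports signed residuals and
compares magnitudes where the reference sign is unreliable.

Sim-vs-Exp statistics are per-condition differences `D = Sim − Exp`, their
per-quantity means over conditions (the "All" row), and
`D% = 100 (Sim − Exp)/|Exp|`, flagged undefined when `|Exp| < 1e−9`.  The
All-row D% is computed from the All-row means, not as the mean of
per-condition percentages (this is what makes the backrest contact-area
figure 20.2 %).

## Pressure maps

Mats are 48 × 48 capacitive sensors at 12.7 mm pitch reporting kPa.  The
trial-specific correction factor is

    fcorr = |F_normal| / (Σ p_ij · pitch² · 10⁻³),

making the corrected map integrate exactly to the load-cell normal force.
On the corrected map: CA counts cells above a contact threshold times the
cell area; PP is the maximum; MP is the mean over active cells, equal to
F/CA whenever the threshold truncates no load.  MP is defined this way
uniformly for measured and simulated maps, since the alternative
definitions cannot be distinguished from the bundled values.

The contact threshold defaults to 0.1 kPa — below the mat's 1.4 kPa rated
floor but above floating-point noise; it is configurable, and no claim is
made that the campaign used the same value.

The lateral profile SOC (per-row sums) and frontal profile SOR (per-column
sums) conserve the grid total.  The fore-aft partition takes `x_beg`/`x_end`
as the first/last active profile rows, `x_max` as the profile peak (first
row on ties), `x_mid1 = mid(x_max, x_end)` and `x_mid2 = mid(x_mid1,
x_end)` rounded to the nearest row with exact halves toward the rear (the
deterministic choice consistent with the worked partition example used in
the tests), and regions `I=[x_beg,x_max)`, `II=[x_max,x_mid1)`,
`III=[x_mid1,x_mid2)`, `IV=[x_mid2,x_end]`.  Proportions are percentages of
the active-span load and sum to 100; zero-width regions contribute 0 % and
are flagged.

## Tissue ROI metrics

Two cylinders (20 and 50 mm diameter, default height 200 mm) quantify
tissue compression under the ischial tuberosity.  The cylinder axis is the
seat-pan normal through the ischium point closest to the seat; the upper
face plane contains that point, so the rim circle touches the ischium, and
the body extends seat-ward.  The ROI is frozen in the seat frame — built
from the unloaded landmark and applied identically to the pre- and
post-loading meshes — which makes the preload thickness equal the full
tissue column and the loaded thickness the compressed one.

Thickness and volume come from one ray sweep: axis-parallel rays on a
square grid (default 0.5 mm, 2 mm in the batch pipeline for speed) over the
cross-section; each ray's chord is the length of its intersection with the
union of volumetric elements (the elements are the tissue, so unmeshed bone
is excluded by construction), clipped to the cylinder.  Mean thickness
averages chords over hitting rays; volume sums chord × cell area, making
`V = t_mean × A_hit` hold to rounding.  Hexahedra are split into six
tetrahedra sharing a body diagonal; ray–tet intersection uses half-space
clipping, with a coarse 2-D bucket index keeping the per-ray candidate set
small.  Accuracy is controlled purely by the grid: the analytic cylinder
volume of a slab is matched within 1 % at the 0.5 mm grid, and refining the
grid 2× moves smooth-fixture volumes by < 0.5 %.

Volume reduction is `R = (1 − V_loaded/V_preload) · 100 %`.  For uniform
axial compression to stretch λ with no lateral escape, R = (1 − λ)·100
exactly; rigid motions applied jointly to mesh pair and ROI leave R
unchanged to machine precision (exercised on slab fixtures, where the
result is grid-independent).

## Material laws

**Flesh** is an incompressible Ogden solid,
`σ(λ) = Σ μ_i (λ^{α_i−1} − λ^{−α_i/2−1})` in nominal stress; the bundled
parameter set (μ = 3 kPa, α = 2, i.e. neo-Hookean; Poisson 0.499 carried as
metadata) represents lumped muscle and adipose tissue.  Stress is verified
against numeric differentiation of the strain energy to 1e−8 relative.

**Cushion foam** follows a tabulated nominal loading curve (strictly
increasing strain through the origin), multiplied by a calibration scale
factor (1.15 for the bundled cushions).  The hysteretic unloading branch is

    σ_u(ε) = σ_L(ε) · [HU + (1 − HU) (W(ε)/W(ε_max))^SHAPE],

with `W` the loading strain-energy integral (exact trapezoid on the
piecewise-linear curve).  This functional form is this package's own
definition: the solver family that exposes HU and SHAPE does not publish
its unloading equations, so the form was chosen to satisfy the behaviors
those parameters are documented to control — continuity with loading at
ε_max, collapse to the elastic curve at HU = 1, σ_u ≤ σ_L everywhere, and
dissipation growing with SHAPE — and no numerical equivalence with any
solver's internals is claimed.  Reloading retraces the loading curve
(creep decay constant BETA = 0); everything is quasi-static and
rate-independent.  Identification of (HU, SHAPE) from a measured unloading
branch is least squares via coarse grid search plus Nelder–Mead
refinement; noise-free synthetic branches are recovered within 1 %, 2 %
multiplicative noise widens this to within 10 %, and HU ≈ 1 data flag
SHAPE as unidentifiable (NaN).

The bundled loading curve itself is a synthetic stand-in with the
canonical three-regime shape of low-density polyurethane (linear toe to
~10 % strain, plateau of a few kPa, quadratic densification above 60 %),
since the campaign's measured curve was not published numerically.  The
tensile moduli and densities are carried as metadata only.

## Synthetic data: what it emulates and what it does not

**Pressure maps** are sums of anisotropic Gaussian blobs: two
ischial-tuberosity peaks plus a laterally-spread, forward-tapering thigh
ridge (or one broad patch for the backrest), with cells below 0.3 kPa
zeroed (sensor floor).  The noise-free map is scaled to a target normal
force, divided by a known calibration error (so the correction-factor
analysis must recover it — round-trips hold to 1e−6), and degraded by
multiplicative log-normal noise, default cv = 0.05 in line with a mat
accuracy of ±10 % of scale.  Default targets follow the bundled campaign:
seat-pan normal forces of 660–700 N and the per-condition calibration
factors.  The default shape yields CA ≈ 1.6e5 mm² and PP ≈ 19 kPa —
realistic for an 80 kg adult — but its fore-aft load split differs from
the single campaign subject's print (less load rear of the peak), so
region proportions are exercised qualitatively, not numerically.

**Force sets** distribute the body weight over SB/SP/FS (default split
0.12/0.78/0.10), derive shear from surface tilt through a friction-like
coupling, and close the horizontal balance through the backrest, so the
noiseless set balances exactly (residuals < 1e−9 N); Gaussian component
noise (default 3 N) produces "measured" copies.

**Tissue pairs** are hexahedral flesh columns (40 mm thick, the modelling
default for the under-IT column) compressed to the stretch at which the
Ogden stress balances the applied load; the cushion foam shares that
stress in series and its settlement is reported as metadata, but the
column base stays fixed in the seat frame so the ROI bookkeeping is exact.
The sliding mode adds a Gaussian indentation under the ischium (spread
20 mm, depth 0.3 × total compression at full sliding) with a mild radial
outflow — a kinematic emulation of gluteal tissue escaping from under the
bone, sufficient to exercise the metric's discriminating power
(R(sliding) > R(no sliding) in both ROIs for every condition) but not a
contact-mechanics model.  Fixture applied stresses are scaled from each
condition's peak pressure (0.7 × PP), giving stretches around 0.5 and
volume reductions in the 45–65 % range observed in seated-MRI studies.

All generators are pure functions of (parameters, seed); repeated calls
are bit-identical, and reports re-run on unchanged inputs byte-identical
(randomness lives only in generators, never in analysis).

What passing tests show is therefore internal consistency — transforms,
balance, metric definitions, parameter recovery — on inputs with the
campaign's magnitudes and structure; they do not show that a particular
body model reproduces a particular subject, nor do the synthetic maps and
meshes carry real inter-subject variability.

## Problem sizes and numerical choices

Batch runs use 48 × 48 maps, 120 × 120 × 40 mm columns at 5 mm element
size, and a 2 mm ray grid (the 0.5 mm grid is used where the 1 % analytic
comparisons are made); a full fixture-generation-plus-reports run takes a
few seconds on one core.  Root finding (equilibrium stretch/strain) uses
bracketed Brent iterations at 1e−12 tolerance; interval unions in the ray
caster merge with a 1e−9 mm glue tolerance; report CSVs store full
precision with a fixed-precision text rendering alongside (0.1 N, 0.1 kPa,
1 mm², 0.1 mm, 0.1 %).

## Known limitations

* The unloading law is a behavioral model of HU/SHAPE, not a solver
  re-implementation; identified parameters transfer only in that sense.
* MP for simulated maps is force/area by definition here; reference tables
  produced with a different simulated-MP convention will differ at the
  0.1 kPa level.
* The ROI volume-reduction anchors from the campaign (e.g. 57.6 % vs
  49.5 % with/without sliding in the 20 mm ROI) are reproduced as an
  ordering, not as values: the printed thickness tables do not determine
  the volumes, so quantitative agreement is not claimed.
* Only sagittal-plane forces are treated; no lateral components, moments,
  backrest region partition, or map registration between trials.
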