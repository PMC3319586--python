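# Methods

## Model

The upper-extremity circulation is represented as a network of lumped
(0D) segments — the electrical analog of a linearized 1D pulse-wave model.
Twenty named vessels form the computational domain: the ascending aorta,
aortic arch (two pieces), thoracic aorta, innominate, both carotids, both
subclavians, vertebral, the access-side axillary/brachial, radial,
proximal/distal ulnar and interosseus arteries, and the venous outflow
trajectories (distal/proximal cephalic, median cubital, basilic,
axillary/subclavian vein). Each vessel is divided into segments of at most
5 cm (ceiling rule, equal lengths), and each segment becomes a Π-element
evaluated at its midpoint diameter:

- viscous resistance `R = 8μℓ/(πr⁴)` (Poiseuille),
- blood inertance `L = ρℓ/(πr²)` (plug flow),
- wall compliance `C = 3πr³ℓ/(2Eh)` (thin-wall, incompressible),

with half of `C` lumped at each segment end. Blood is Newtonian with
ρ = 1000 kg/m³ and μ = 3·10⁻³ Pa·s. Venous segments carry a leakage
resistor `R_L = 100 × R` from their distal node to the central venous
pressure, standing in for unmodeled small tributaries; the multiplier is
exposed to the uncertainty layer (±50 %) because it is weakly known.
Element values are SI internally; all interfaces use clinical units
(mmHg, ml/min, mm, kPa) through one conversion module.

**Anastomosis.** The artery–vein junction is two nonlinear resistors: a
venous limb into the vein and a distal limb continuing down the host
artery. Each produces a Borda–Carnot-type junction loss
`Δp = K(θ)·ρ·q|q|/(2A²)`, odd in the flow and linear in the loss
coefficient. `K(θ)` interpolates linearly between endpoints at 30° and 60°
(venous limb 3.0 → 5.0, distal limb 1.0 → 1.5; floored at 0.05 outside the
range). These endpoints are a documented modeling choice — the published
description fixes only the dependencies (angle, flow), not the
coefficients. A short-segment Poiseuille term on each limb keeps the
branch well-posed at q = 0. The default angle is 45° (surgical range
30–60°), the site 5 cm proximal to the wrist (RC) or to the elbow
bifurcation (BC/BB).

**Boundary conditions.** A prescribed periodic flow is injected at the
aortic root; the subclavian-vein outflow node is held at the central
venous pressure (default 10 mmHg). Arterial branches not modeled
segment-by-segment end in three-element windkessels whose far side drains
to the same venous reference. The preoperative domain carries no venous
segments — the veins only become hemodynamically relevant through the
fistula.

## Personalization

- **Diameters.** Arm arteries and veins use the patient's duplex stations,
  interpolated linearly along the vessel, extrapolated by continuing the
  end slope, floored at 0.5 mm; a single station extrapolates as a
  constant. Station positions run along the flow direction (from the
  central end for arteries, from the peripheral end for veins).
- **Lengths and central geometry.** Vessel lengths and the aorta/primary
  branch diameters come from a packaged generic adult table; central
  diameters are scaled by the measured-to-generic subclavian diameter
  ratio. Venous lengths equal the arterial lengths at the same anatomical
  level.
- **Wall thickness.** h/r = 15 % (subclavian/axillary/brachial), 20 %
  (radial/ulnar/interosseus), 10 % (veins), generic values elsewhere.
- **Stiffness.** One arm-wide arterial Young's modulus from brachial
  distensibility, `D = ΔA/(A·Δp)` out of the wall-tracking and finger
  pressure waveforms and `E = 3/(2·D·(h/r))` (thin-wall). Aorta and veins
  use generic moduli.
- **Windkessels.** Terminal mean-flow targets come from the MR
  measurements: radial and ulnar terminals take their measured flows, the
  interosseus terminal absorbs the brachial remainder (conservation), and
  the non-arm remainder is split by fixed fractions (thoracic aorta 0.62,
  carotids 0.10 each, vertebral 0.03, contralateral subclavian 0.15).
  Marching mean pressures down the preoperative tree from MAP gives each
  terminal's total resistance `(p_node − p_ven)/q̄`; it is split
  Z_wk : R_wk = 10 : 90 with `R_wk·C_wk = 1.5 s`. Negative residual
  resistance raises an inconsistent-measurements error.
- **Screening.** A vessel is caliber-adequate iff its minimum station
  strictly exceeds 2 mm (conservative: the worst station governs).

## Numerics

The network equations are assembled in modified nodal analysis form (free
node pressures, one internal windkessel node per terminal, one flow
unknown per branch) and integrated with trapezoidal companion models at a
fixed step of `T/1000` — A-stable on the stiff RC ladder and
bit-reproducible. The run starts at the DC operating point of the network
under the mean inflow and marches cycle by cycle until the mean aortic
pressure and mean brachial flow change by < 10⁻³ relative between
consecutive cycles (max 50 cycles; runs that fail to settle are flagged,
not raised). The two anastomosis resistors are resolved inside every step
by Newton linearization of the quadratic loss, entering the prefactorized
LU system through a rank-2 Woodbury correction (refresh tolerance 10⁻⁶ on
the flow iterate), so a whole run costs one LU factorization and one
back-substitution per step. Veins are linear compliant segments — venous
collapse is not modeled.

**Baroreflex.** Postoperative inflow is the preoperative waveform scaled
by `s`, found by a bracketed secant iteration on `s ∈ [1, 5]` until the
mean aortic pressure matches the preoperative value within 10⁻³ relative;
all other personalized parameters stay fixed. The MAP is close to linear
in `s`, so the iteration typically needs 3–6 simulations (warm-started
from the previous state).

## Uncertainty propagation

Each uncertain input is uniform over nominal ± half-width: arterial
diameters ±10 %, venous diameters ±20 %, lengths ±10 %, Young's moduli
±20 %, windkessel resistances ±20 % (peripheral time constant fixed, so
C_wk moves inversely), leakage resistance ±50 %, anastomosis angle
30–60°, venous pressure ±5 mmHg. These bands are measurement-precision
scale defaults, overridable per patient. A Latin-Hypercube design
(scipy `qmc`) places exactly one sample in each of the n equal-probability
strata per parameter; each sample is one full prediction run.
Non-converged runs are counted and excluded; percentiles (median, 25th,
75th) interpolate linearly between order statistics. The library default
is 256 runs; the tests and the acceptance script use 2–16 runs per
configuration, which is enough for the properties they check while keeping
a full cohort pass at desk scale.

## Synthetic cohort

The generator emulates the preoperative measurement record of a dialysis
access work-up: duplex diameters at three stations per arm vessel with
distal taper (radial 1.9–3.3 mm, brachial 3.6–5.4 mm, distal cephalic
1.6–3.4 mm, so the default 25-patient cohort spans both caliber-adequate
and inadequate vessels), MAP 70–120 mmHg, cardiac period 0.7–1.2 s,
cardiac output 3.5–7 l/min with 1.5–4 % to the arm, a two-phase aortic
waveform (systolic half-sine over a diastolic plateau, peak/mean 2.5–3.5),
and a distension/pressure waveform pair constructed from a known brachial
modulus of 400–1200 kPa so the stiffness inversion is exact by
construction. Degraded variants reproduce the documented failure modes
(thrombosed cephalic vein, small radial artery, sparse stations).

What it does **not** emulate: stenoses, curvature or kinking, accessory
and deep veins, vascular adaptation/maturation, flow-mediated dilatation,
measurement noise correlated across stations. Passing tests therefore
demonstrate the internal consistency and the stated physics of the
pipeline on realistic magnitudes — not clinical accuracy on real patients,
which requires a measured cohort.

## Design choices and limitations

- The interosseus terminal flow is derived by conservation
  (brachial − radial − ulnar) instead of an arbitrary split fraction.
- The decision statistic is the Monte-Carlo median; window bounds 400 and
  1500 ml/min are inclusive; interval-overlap tests use closed intervals.
- The maturation projection (immediate flow ≈ 60–70 % of matured flow at
  the wrist, 90–100 % at the elbow) is reported as context only and never
  enters eligibility.
- Prosthetic grafts, MRA-based geometry, frequency-domain/wave-reflection
  analysis and 1D PDE propagation are out of scope.
- Degenerate inputs: zero-length segments yield zero elements; zero wall
  distension raises a rigid-vessel error; a missing vein raises an
  incomplete-domain error naming the vessel; ties at the 2 mm caliber
  threshold are inadequate (strict inequality).
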