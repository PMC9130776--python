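# Methods

`myoloop` simulates beat-to-beat hemodynamics and regional myocardial
mechanics of a closed human circulation with a two-compartment description
of ischemic wall segments, and estimates the severity of regional
contractile dysfunction from 18-segment longitudinal strain. This note
documents the model, its numerical treatment, the parameterization, and
the limits of what the synthetic experiments demonstrate.

## Myofiber model

Each wall patch carries a three-element Hill myofiber. The contractile
element of length `Lsi` sits in series with an elastic element
`Lse = Ls − Lsi`; active stress is

    sigma_act = Sf_act · C(t, Lsi) · (Lsi − Lsi0_act) · Lse / Lse_iso

with `Sf_act` in kPa/µm so the product carries kPa. The parallel passive
stress is the sum of an extracellular-matrix power law

    sigma_ECM = Sf_pas · ((Ls / Ls0_pas)^k_ECM − 1)

and a titin term `Sf_act · k1_tit · ((Ls/Ls0_pas)^k2_tit − 1)`. Because
titin scales with `Sf_act`, a fully noncontractile fiber (`Sf_act = 0`)
is described by the ECM term alone. `sigma_ECM` is signed: below the
zero-stress length `Ls0_pas` it is negative (buckling is permitted); no
clamping proved necessary for solver stability.

The contractility `C` is an algebraic single twitch per beat — the
product of a rise factor `tanh((t_act/τ_r)²)` (exactly zero before
activation, C¹-smooth at onset) and a sigmoid decay centred at a
length-dependent duration `T_dur = CD · (0.29 + 0.30·Lsi)` with
`τ_r = 0.20·CD`, `τ_d = 0.15·CD`. `CD` (s) is therefore an explicit
first-class duration multiplier, which the estimation pipeline fits.
An algebraic twitch (rather than an ODE state) keeps one state per patch;
any smooth unimodal twitch with these monotonicities gives equivalent
behavior at this level of description.

Series-element kinetics follow the sliding-velocity law
`dLsi/dt = v_max · (Lse/Lse_iso − 1)`: zero at the isovolumetric
reference extension, positive (contractile element yielding) beyond it.

## Two-compartment patch

An ischemic patch of wall volume `V_patch` is split into a contractile
compartment `V_C = (1 − NCVF)·V_patch` and a noncontractile compartment
`V_NC = NCVF·V_patch` in series. NCVF ∈ [0, 1] is the noncontractile
volume fraction — the single severity parameter (0 healthy, 1 fully
noncontractile). Serial coupling is enforced exactly: at every
evaluation the compartments carry equal fiber stress, and the patch
sarcomere length is the volume-weighted average
`Ls = (1−NCVF)·Ls_C + NCVF·Ls_NC`. Given the composite `Ls` and the
contractile state `(Lsi, C)`, the noncontractile length solves the
scalar monotone equation `sigma_ECM,NC(Ls_NC) = sigma_C(Ls_C)` by
safeguarded Newton (relative stress tolerance 1e−10, bracket
[0.3, 4.8] µm). The composite stiffness follows the series law
`1/k = (1−NCVF)/k_C + NCVF/k_NC`. The noncontractile compartment has its
own `Ls0_pas` and `k_ECM` (the stiffness parameters calibrated per
scenario); its `Sf_pas` defaults to the contractile value.

## Ventricles, walls, circulation

Cardiac walls are thick-walled spherical shells of myofibers. The LV
free wall, septum and RV free wall form a three-segment assembly:
spherical caps joined at a ring of radius `ym`, with the septal cap
volume `VS` and `ym` solved quasi-statically at every evaluation so that
the axial and radial components of the three wall tensions balance
(2-D damped Newton, numerical Jacobian, relative tolerance 1e−7). Wall
tension maps to cavity pressure through the thick-shell one-fiber
relation `p = 2 Tm Cm`, `Tm = σ_f · Vw/(2Am) · (1 + z²/3 + z⁴/5)`,
`z = 3 Cm Vw/(2Am)`; fiber strain follows the midwall area,
`Ls = Ls_ref · sqrt(Am/Am_ref)` with `Ls_ref = 2.0 µm`. Walls subdivide
into patches that share one tension; each patch contributes a linearized
area–tension relation `Am_i(T) = Am0_i + (dA/dT)_i · T` rebuilt every
evaluation from its sarcomere stiffness (floored at 0.2 kPa/µm), so
subdividing a wall into identical patches leaves hemodynamics unchanged
to solver tolerance. Atria are single spherical shells with a weaker,
shorter twitch activated one AV delay (0.16 s) before the ventricles.

The circulation closes through four elastic vessel compartments
(systemic/pulmonary, arterial/venous; linear pressure–volume relations)
joined by peripheral resistances, and four valves modelled as diode +
Bernoulli orifice + inertance (`L dq/dt = Δp − B q|q| − R q`, flow
clamped at zero when closed). Aortic valve closure — ejection flow
returning to zero — is the default end-systole marker; a maximal
`P/(V−V0)` elastance detector is available behind a flag.

Homeostatic pressure–flow regulation acts between beats: peripheral
resistance moves toward the MAP target (`R ← R·(MAP*/MAP)^0.5`) and
circulating volume toward the SV target (3 ml venous volume per ml SV
error), with a dead band of 0.3 units so a converged model is a fixed
point of the beat map. Regulation is disabled during afterload
manipulations.

## Numerics

All states integrate on a fixed ≤2 ms output grid (the grid divides the
cycle exactly). Each grid step is one or more Heun (explicit
trapezoidal) substeps; the embedded Euler/Heun difference provides a
local-error estimate, and a failing step retries with doubled substeps
(scales: 100 ml for volumes, 2000 ml/s for valve flows, 2 µm for
sarcomere lengths; relative tolerance 5e−4 by default, 2e−3 inside the
estimation forward model where thousands of runs are needed). The
geometry solves (TriSeg, patch tension, compartment split) are algebraic
and warm-started from the previous evaluation; their linearization uses
the previous evaluation's lengths, the standard quasi-static treatment
for this model family. The core loop is compiled with numba; identical
inputs give bit-identical trajectories.

## Reference parameterization

`defaults.py` holds one versioned reference parameterization of a
resting adult, calibrated so the regulated baseline (HR 71 bpm, SV
72 ml, MAP 92 mmHg) shows a healthy resting LV: EDV ≈ 149 ml, EF ≈ 49%,
peak LV pressure ≈ 114 mmHg, end-systolic elastance ≈ 2.3 mmHg/ml.
Key values: `Sf_act = 290 kPa/µm`, `Sf_pas = 1.5 kPa`,
`Ls0_pas = 1.75 µm`, `k_ECM = 10`, `k1_tit = 0.012`, `k2_tit = 4`,
`Lsi0_act = 1.51 µm`, `Lse_iso = 0.04 µm`, `v_max = 7 µm/s`,
`CD = 0.45 s`; LV free wall 125 ml / 139 cm², septum 64 / 72, RV free
wall 42 / 168, systemic resistance 1.03 mmHg·s/ml, arterial compliance
1.3 ml/mmHg. The split of passive stress between the ECM power law and
the titin term matters for the ischemia experiments: titin (scaling with
`Sf_act`) softens along with contractile loss in a one-compartment
simulation, while the noncontractile compartment of a two-compartment
patch, being titin-free, keeps its full ECM stiffness.

## Scenario protocols

*Global function (ESPVR).* Baseline regulated at HR 71 / SV 72 /
MAP 92. Two-compartment ischemia: NCVF = 0.2 in the LV free wall and
septum, noncontractile stiffness at baseline values. One-compartment
ischemia: a uniform `Sf_act` scale on LV + septum found by bisection
until steady-state EDV matches the two-compartment run (the bisection
runs to interval collapse, so the match lands far inside the 0.5 ml
acceptance). For each variant, regulation is then frozen and arterial
resistance set to 0.8/1.0/1.2 of reference; the end-systolic (V, P)
points at aortic valve closure are fitted with a least-squares line
`P = Emax (V − V0)`.

*Acute ischemia/reperfusion.* Baseline recalibrated to HR 105, SV 49 ml
and peak LV pressure 84 mmHg (the MAP target is tuned by a secant loop).
A region of 30% of the total LV wall volume — split proportionally into
one LV-free-wall and one septal patch — sweeps NCVF through
1 → 0.8 → … → 0 with noncontractile stiffness `Ls0_pas = 2.21 µm`,
`k_ECM = 17`. Strain and segment length are reported for the
dysfunctional free-wall patch; sarcomere length maps affinely to segment
length through the baseline end-diastolic calibration point
(`SL = Ls · SL_exp,ED/Ls_ED`; default `SL_exp,ED = 19.8 mm`). Reported
stage metrics: systolic stretch amplitude (peak strain over the ejection
window relative to end-diastole), the LV pressure–segment length loop
area, and end-diastolic segment length. The patch stress–strain loop
area is also recorded; note that over a reperfusion sweep it saturates
near baseline about one NCVF step before the pressure–length loop area
does, because the composite strain reference shifts with NCVF.

*Prolonged ischemia.* Baseline at HR 111 / SV 41 / peak 91 mmHg; the
region stays at NCVF = 1 while the noncontractile stiffness walks
through (`Ls0_pas`, `k_ECM`) = (2.01, 26) → (2.19, 70) → (2.03, 120),
emulating edema-driven stiffening and subsequent compaction.

## Estimation pipeline

The estimated vector has 39 entries: per-segment NCVF (18, domain
[0, 1]) and noncontractile `k_ECM` (18, domain [10, 120] spanning the
calibrated scenario range), plus global LV wall area, contraction
duration `CD` and stroke volume, each ±30% of reference. Heart rate is
fixed to the measured value; MAP stays at the 92 mmHg default (no
pressure measurement is assumed). The 18 echo segments map one-to-one
onto 18 LV patches (12 free wall, 6 septal) with basal/mid/apical volume
weights 1.2 : 1.0 : 0.7.

The objective sums four components, each normalized by an expected
measurement uncertainty and by its number of contributing samples, so
one uncertainty-unit of white noise contributes ≈1 per sample: segmental
strain (2 percentage points), segmental strain rate (20 %/s; first-order
finite difference), EDV (10 ml) and EF (3 points). Simulated strains
are first rescaled by one global factor matching the peak |GLS| of
simulation and measurement (absorbing the systematic offset between
one-fiber strain in a spherical wall and longitudinal STE strain).
Strain and strain-rate sums stop at an early-diastolic cutoff: 10% of
the cycle after the moment |GLS| first falls below 90% of its peak
amplitude; late-diastolic strain is ignored.

Optimization: 1000 scrambled-Sobol draws (a power-of-two block is drawn
and truncated) evaluated through the forward model; 40 initial particles
= the 20 best draws by objective + 20 recombinations whose per-segment
(NCVF, k_ECM) pairs come from that segment's 20 best draws by segmental
error and whose globals come from the global top 20; then multi-swarm
PSO — 5 subswarms × 8 particles, constriction updates
(χ = 0.7298, c₁ = c₂ = 2.05), velocity clamped at 30% of the domain,
membership reshuffled every 40 iterations — stopping when every
particle's normalized energy (mean squared step as a fraction of domain
width) falls below 1e−4, or at 1000 iterations. A failed forward run
costs +∞ for that evaluation. All randomness flows from the run seed.

The forward model inside the fit restarts from one cached regulated
steady state of the segment model and advances 7 beats after applying
the candidate parameters — enough for regulation to re-settle to within
a few ml of EDV; the residual transient bias is small against the 10 ml
EDV uncertainty but is shared by every candidate.

## Virtual patients

The generator runs the same forward model at a known parameter vector to
full steady state, samples strain on the 2 ms grid, and adds independent
Gaussian noise per strain sample (2 points) plus one Gaussian
perturbation each to EDV (10 ml) and EF (3 points) — the same scales
the objective normalizes by. Two preset infarct morphologies are
provided (transmural anteroseptal, nontransmural apical), and a
follow-up generator shifts segmental NCVF by a prescribed delta
(clipped to [0, 1] with a warning) to emulate functional recovery.

What this does and does not show: white per-sample noise at 2 ms makes
the strain-rate component an essentially constant noise floor (its
per-sample derivative noise is ~70 uncertainty units), so recovery is
driven by the strain, EDV and EF terms; real speckle-tracking noise is
temporally correlated and frame-rate limited, and real data add drift,
segment misregistration, afterload uncertainty and model-form error that
these experiments cannot probe. Recovery experiments therefore validate
the estimator's identifiability and implementation, not its clinical
accuracy.

Reduced problem sizes used by the validation suite (chosen to keep the
full suite in the tens of minutes on one CPU): 200 MC draws, 40
particles, 50 PSO iterations, 7 forward beats; two virtual patients
whose baseline exams are fitted with two optimizer seeds each and whose
follow-up exams are fitted once for the longitudinal sign check.

A practical identifiability limit shows up at these noise levels:
moderately dysfunctional segments lie on a flat (NCVF, k_ECM) ridge — a
fully noncontractile compartment with a stiff ECM (k_ECM ≈ 25–30)
produces nearly the same strain trace as a half-noncontractile one with
the compliant baseline ECM — and the objective separates the ridge ends
by only a few cost units on the large strain-rate noise floor, so the
recovered NCVF of such segments depends partly on the noise
realization. Severely dysfunctional and healthy segments recover
robustly. This is a property of the data and noise model, not of the
optimizer; larger search budgets do not remove it.

## Known limitations

- No pericardium, no baroreflex dynamics beyond between-beat regulation,
  simultaneous ventricular activation (narrow-QRS assumption); activation
  timing is present in the configuration but not estimated.
- Calcium handling and cross-bridge kinetics are not modelled; stunning
  is represented functionally through NCVF alone.
- The one-fiber spherical geometry maps all deformation onto one fiber
  strain; regional longitudinal strain is represented only up to the
  global amplitude rescaling described above.
- `Emax`/`V0` from three afterload points are extrapolation-sensitive:
  small slope changes move V0 by many ml, which is why protocol
  tolerances (steady-state and EDV-match) are kept tight.
- The segment-length map uses the dimensionally consistent orientation
  of the affine calibration (`SL = Ls · SL_exp,ED/Ls_ED`); the
  alternative orientation printed in some descriptions of this
  calibration is dimensionally inconsistent and is not used.
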