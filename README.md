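# myoloop

Lumped-parameter, closed-loop simulation of the human heart and
circulation with a **two-compartment model of ischemic myocardium**, and
strain-based estimation of regional contractile dysfunction.

## The problem

After a myocardial infarction, part of a ventricular wall segment stops
generating force while the rest keeps working. How severe is that
regional dysfunction, and what does it do to the pump? Global indices
(ejection fraction, the end-systolic pressure–volume relation) and
regional deformation (segmental longitudinal strain from speckle-tracking
echocardiography) both carry the signature, but reading severity off
them needs a mechanistic model.

`myoloop` represents each ischemic wall patch as two serially coupled
compartments: a contractile compartment and a noncontractile one with
zero active stress. The **noncontractile volume fraction**

    NCVF = V_NC / V_patch              (0 = healthy, 1 = fully passive)

is the single severity parameter. Myofibers follow a three-element Hill
model — active stress
`σ_act = Sf_act · C(t) · (Lsi − Lsi0) · Lse/Lse_iso` in series with a
passive ECM power law `σ_ECM = Sf_pas ((Ls/Ls0,pas)^k_ECM − 1)` and a
titin term — inside thick-walled spherical wall segments; the LV, septum
and RV interact through a three-wall tension balance, and the loop closes
through windkessel vessels and inertial valves with between-beat
regulation of mean arterial pressure and stroke volume. At every time
point the two compartments of a patch carry equal fiber stress and the
patch sarcomere length is their volume-weighted average,
`Ls = (1−NCVF)·Ls_C + NCVF·Ls_NC`; segmental strain is engineering
strain `ε = (Ls/Ls_ref − 1)·100%`.

On top of the simulator sits an estimation pipeline that recovers
per-segment NCVF and noncontractile stiffness (k_ECM), plus global wall
area, contraction duration and stroke volume, from an 18-segment strain
dataset with EDV and EF: quasi-random Monte Carlo initialization, 40
candidate particles (20 global best + 20 per-segment recombinations),
then multi-swarm particle swarm optimization with an energy-based stop.
A virtual-patient generator closes the loop for validation without
clinical data.

Audience: researchers in computational cardiac mechanics and
deformation-imaging-based diagnostics.

## Worked example

```python
from myoloop.protocols import run_two_vs_one_compartment_espvr
res = run_two_vs_one_compartment_espvr()
for name in ("baseline", "two_compartment", "one_compartment"):
    e = getattr(res, name)
    print(f"{name:16s} Emax={e.Emax:5.2f} mmHg/ml  V0={e.V0:7.1f} ml")
```

prints

```
baseline         Emax= 2.30 mmHg/ml  V0=   28.2 ml
two_compartment  Emax= 1.05 mmHg/ml  V0=   45.8 ml
one_compartment  Emax= 0.45 mmHg/ml  V0=  -89.1 ml
```

Reading: 20% regional ischemia modelled with the two-compartment patch
shifts the end-systolic pressure–volume relation rightward (V0 up by
~18 ml) while moderately reducing its slope — the stretched passive
compartment holds extra volume at end-systole. Forcing the same
end-diastolic volume with a *one-compartment* global weakening of active
stress instead collapses the slope to 0.45 mmHg/ml and drives V0 to an
unphysiological −89 ml. Regional ischemia is series mechanics, not a
uniform loss of contractility.

More scripts live in `examples/`: baseline hemodynamics, the acute
ischemia/reperfusion strain sweep (NCVF 1 → 0 with systolic stretch and
work-loop areas per stage), and an end-to-end virtual-patient
estimation. A thin CLI mirrors them:

```bash
myoloop simulate --beats 5
myoloop scenario acute
myoloop synth --pattern anteroseptal_transmural --seed 1 --out runs/p1
myoloop fit runs/p1/dataset.tsv --seed 1 --mc-n 200 --max-iter 40
```

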