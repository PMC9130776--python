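"""Compare ESPVRs: healthy baseline vs two- and one-compartment ischemia.

Reproduces the global pump-function experiment: 20% of the LV wall
(free wall + septum) is made noncontractile either by a serial
two-compartment subdivision (NCVF = 0.2) or by uniformly reducing active
stress until the end-diastolic volume matches.  Each variant is probed
with arterial resistance at 80%, 100% and 120% of reference and a line is
fitted through the end-systolic pressure-volume points.
"""

from myoloop.protocols import run_two_vs_one_compartment_espvr

res = run_two_vs_one_compartment_espvr()

print("model variant          Emax (mmHg/ml)   V0 (ml)")
for label, e in [("baseline", res.baseline),
                 ("two-compartment", res.two_compartment),
                 ("one-compartment", res.one_compartment)]:
    print(f"{label:22s} {e.Emax:10.2f} {e.V0:12.1f}")
print(f"\none-compartment active-stress scale: {res.sf_act_scale:.3f} "
      f"(EDV matched to {res.edv_two_compartment:.1f} ml)")
print()
print("The two-compartment model shifts the ESPVR rightward (V0 up) with")
print("a moderate slope reduction; the one-compartment model collapses the")
print("slope and drives V0 far negative — unphysiological for regional")
print("ischemia, which is why the two-compartment form is preferred.")
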