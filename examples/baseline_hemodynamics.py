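"""Run the reference closed-loop heart to its regulated steady state.

Builds the default model (71 bpm, regulated to MAP 92 mmHg and stroke
volume 72 ml), converges it, and prints the per-beat hemodynamic summary:
end-diastolic and end-systolic LV volume, ejection fraction, mean arterial
pressure, and peak systolic LV pressure.  These are the numbers every
scenario in this package starts from.
"""

from myoloop import HeartModel

model = HeartModel()
beat = model.run_to_steady_state()

s = beat.summary()
print("converged reference steady state:")
print(f"  EDV      {s['EDV']:7.1f} ml   (end-diastolic LV volume)")
print(f"  ESV      {s['ESV']:7.1f} ml   (end-systolic LV volume)")
print(f"  EF       {s['EF']:7.1f} %    (ejection fraction)")
print(f"  SV       {s['SV']:7.1f} ml   (aortic stroke volume)")
print(f"  MAP      {s['MAP']:7.1f} mmHg (mean arterial pressure)")
print(f"  peak LVP {s['peak_p_LV']:7.1f} mmHg")
print()
print("A healthy LV at rest: EF about 50%, peak pressure near 115 mmHg,")
print("with MAP and SV pinned at their homeostatic targets.")
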