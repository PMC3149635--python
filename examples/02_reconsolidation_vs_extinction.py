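"""Reexposure duration decides between retrieval, reconsolidation and extinction.

Sweeps the duration t of a single nonreinforced reexposure under vehicle
and under anisomycin (Hebbian synthesis blocked, S = 0), then prints mean
freezing at the final test.  Watch for three regimes: short t (drug has no
effect), intermediate t (drug causes amnesia: reconsolidation blockade),
long t (controls extinguish, drug preserves fear: extinction blockade).
"""

from reconsim import extinction_onset, reexposure_sweep

curve = reexposure_sweep(
    range(11),
    {"vehicle": {}, "anisomycin": {"S_reexposure": 0.0}},
    n_replicates=100,
    seed=0,
)

print(f"{'t':>3} {'vehicle':>9} {'anisomycin':>11}")
for t in sorted(set(curve.t)):
    veh = curve[(curve.t == t) & (curve.arm == "vehicle")].mean_freezing.iloc[0]
    ani = curve[(curve.t == t) & (curve.arm == "anisomycin")].mean_freezing.iloc[0]
    print(f"{t:3.0f} {veh:9.1f} {ani:11.1f}")

print(f"\nextinction onset in controls: t = {extinction_onset(curve, arm='vehicle'):.0f}")
print("The anisomycin column is V-shaped: amnesia deepens with t until "
      "extinction takes over in controls, after which the drug protects "
      "the original memory instead.")
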