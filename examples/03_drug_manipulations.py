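"""Pharmacology presets: degradation blockade rescues reconsolidation.

Runs the four-arm intermediate-reexposure preset: vehicle, anisomycin
(S = 0), degradation blockade (D = 0), and both drugs together.  Blocking
mismatch-induced degradation has no effect on its own but cancels the
amnestic effect of anisomycin — the signature that amnesia requires active
degradation of the retrieved trace.
"""

from reconsim import run_preset

df = run_preset("fig6a", seed=0, n_replicates=100)
final = df[df.session_label == "after reexposure"]

print(f"{'condition':>28} {'freezing %':>10}")
for _, row in final.iterrows():
    print(f"{row.arm:>28} {row.mean_freezing:10.1f}")

print("\nAnisomycin alone collapses freezing to baseline (10%); adding "
      "degradation blockade restores it to vehicle levels (~90%).")
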