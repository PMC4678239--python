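"""Simulate the two built-in demo pathways and describe their dynamics.

The steady-state demo is a JAK-STAT-style responder: its nuclear
transcription-factor dimer peaks and relaxes to a plateau while the
SOCS-type inhibitor accumulates.  The oscillator demo is an NF-κB-style
two-feedback network whose nuclear factor oscillates with a ~2 h period.
"""

from kinfault import (SamplingSpec, build_demo_oscillator, build_demo_steady,
                      oscillation_features, simulate)

steady = build_demo_steady()
traj = simulate(steady, SamplingSpec(steady.default_horizon_h, 6))
dimer = traj.column("stat3_dimer_nuc")
socs = traj.column("socs3")
i_peak = dimer.argmax()
print(f"{steady.name}: {len(traj.times)} samples over "
      f"{traj.times[-1]:.0f} h")
print(f"  nuclear dimer peaks at {dimer.max():.1f} nM "
      f"(t = {traj.times[i_peak]:.2f} h), settles at {dimer[-1]:.1f} nM")
print(f"  inhibitor rises to a {socs[-1]:.0f} nM plateau")
print("  -> single transient peak + plateau: the signature this model is "
      "tuned for\n")

oscillator = build_demo_oscillator()
traj = simulate(oscillator, SamplingSpec(oscillator.default_horizon_h, 6))
feat = oscillation_features(traj)
print(f"{oscillator.name}: output oscillates with")
print(f"  amplitude H = {feat.H:.1f} nM, period P = {feat.P:.0f} s "
      f"({feat.P / 3600:.2f} h), N = {feat.N} complete peak-pairs")
print(f"  steepness R = 2H/P = {feat.R:.5f} nM/s, "
      f"aggregate A = HPN = {feat.A:.2f} nM*s*1e6")
print("  -> sustained oscillation driven by the two negative feedback loops")
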