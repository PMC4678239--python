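"""Stress the method: rising noise and sparser sampling.

Measurement noise lowers the similarity of the true fault but, within a
wide range, not its rank; thinning the sampling grid from six points per
hour to one leaves the identification intact.
"""

from kinfault import (Perturbation, SamplingSpec, SimulationCache,
                      build_demo_oscillator, build_demo_steady,
                      density_sweep, noise_sweep)

model = build_demo_steady()
spec = SamplingSpec(model.default_horizon_h, 6)
cache = SimulationCache(model, spec)  # perturbed sims shared across scans
truth = Perturbation("rate_up", "r5", 1000.0)

runs, agg = noise_sweep(model, truth, fractions=[0.2, 0.4, 0.6, 0.8],
                        seeds=range(10), spec=spec, cache=cache)
print(f"noise sweep ({truth.target} x{truth.fold:g}, 10 seeds per level):")
print(agg.to_string(index=False))
print("-> median S decays with noise; the rank-1 identification does not\n")

oscillator = build_demo_oscillator()
truth_o = Perturbation("molecule_up", "ikba_nfkb", 10.0)
df = density_sweep(oscillator, truth_o, densities=[6, 3, 1], seed=0)
print(f"density sweep ({truth_o.target} x{truth_o.fold:g}):")
print(df.to_string(index=False))
print("-> the fault is still ranked first at one sample per hour, though "
      "the oscillation features degrade with the sparser grid")
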