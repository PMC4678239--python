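"""Localize a fault: scan every candidate perturbation and rank by S.

The scanner re-simulates the model under every candidate single-target
fault over the default fold grid (x5..x1000 up, reciprocals down), scores
each against the clinical data with the similarity S, and ranks candidates
by their best fold's S.  The top-ranked candidate is the inferred fault.
"""

from kinfault import (Perturbation, SamplingSpec, build_demo_steady,
                      generate_clinical, scan)

model = build_demo_steady()
spec = SamplingSpec(model.default_horizon_h, 6)
truth = Perturbation("rate_up", "r2", 1000.0)
dataset = generate_clinical(model, truth, noise_fraction=0.2, spec=spec,
                            seed=1)

table = scan(model, dataset, "rate_up", spec=spec)
print(f"scanned {len(table.rows)} reactions for upregulation; top 5 by S:")
df = table.to_dataframe().head(5)
print(df[["rank", "candidate", "best_fold", "S",
          "S_stat3_dimer_nuc", "S_socs3"]].to_string(index=False))
top = table.rows[0]
print(f"\ninferred fault: {top.candidate} (true fault: {truth.target}) — "
      f"S = {top.S:.3f} at best fold x{top.best_fold:g}")
print("S near 1 separates the true fault cleanly from the next candidates; "
      "the best fold is a fit, not an estimate of the true regulation level.")
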