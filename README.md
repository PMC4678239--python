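# kinfault

Kinetic-model-based localization of malfunctioning reactions and molecules
in signal transduction pathways from noisy time-course data.

## The problem

Many diseases trace back to a single defective step in a signaling
pathway: one reaction whose catalyzing enzyme is inhibited or
overexpressed, or one preexisting molecule (a receptor, a kinase pool, an
inhibitor–factor complex) present in deficit or excess before stimulation.
Given a measured time-course of one or more pathway outputs — a "clinical"
profile — and a validated kinetic (ODE) model of the pathway, which single
component is broken, and in which direction?

`kinfault` answers this by *model-based fault diagnosis*: it perturbs every
candidate component of the model over a grid of fold changes, re-simulates,
and ranks candidates by how similar their predicted output profiles are to
the clinical data. It is aimed at systems biologists with a trusted ODE
model of a pathway and time-course measurements of a few outputs.

## The method

The pathway is an ODE system dx/dt = f(x, p, u) with state vector x
(concentrations, nM), parameters p (rate constants) and a constant stimulus
u switched on at t = 0. A fault is a single multiplicative change: one rate
constant × fold (reaction fault) or one nonzero initial concentration ×
fold (preexisting-molecule fault), giving four abnormal-condition kinds:
`rate_up`, `rate_down`, `molecule_up`, `molecule_down`.

The sampled profiles of all measured outputs are concatenated into single
column vectors Y_clinical and Y_model and compared with the similarity

    S = (Y_clinicalᵀ·Y_model) / (‖Y_clinical‖·‖Y_model‖)
        × 1 / ((m_c/m_m + m_m/m_c)/2)

where m_c, m_m are the two profile means. The first factor measures shape
(cosine), the second magnitude; S ∈ [0, 1] for nonnegative profiles and
S = 1 exactly for identical ones. For each candidate the scanner keeps the
fold maximizing S and ranks candidates by that S.

For oscillatory outputs, two confirmatory factors are extracted from the
detected peaks (after dropping a window-dependent leading minimum and
trailing maximum): mean amplitude H (nM), mean period P (s), and the
number of complete peak-pairs N, combined as

    R = 2H/P   (nM/s, steepness of the oscillation)
    A = H·P·N  (reported in nM·s·10⁶, aggregate oscillation magnitude)

S decides the ranking; R and A re-order only near-ties in S (|ΔS| < 0.01
by default), so a clear S winner is never demoted.

Two reduced demo models ship with the package: a JAK-STAT/SOCS-style
steady-state responder (10 states; outputs: nuclear STAT3 dimer and SOCS3)
and a TNF-α/NF-κB-style oscillator with IκBα and A20 negative feedback
loops (12 states; output: nuclear NF-κB, ~2 h period). User models can be
imported from SBML L3V1.

Since clinical time-courses for defined single faults do not exist, the
package generates artificial clinical data: the model is simulated under a
ground-truth fault, sampled on a regular grid (six points per hour by
default), and each point is replaced by a Gaussian draw whose mean is the
clean value and whose standard deviation is a stated fraction of it (20%
by default). This makes ground truth available, so recovery rates are
measurable.

## Worked example

```python
from kinfault import (Perturbation, SamplingSpec, build_demo_steady,
                      generate_clinical, scan)

model = build_demo_steady()
spec = SamplingSpec(model.default_horizon_h, 6)
truth = Perturbation("rate_up", "r2", 1000.0)    # STAT3 activation x1000
data = generate_clinical(model, truth, noise_fraction=0.2, spec=spec, seed=1)
table = scan(model, data, "rate_up", spec=spec)
print(table.to_dataframe().head(5))
```

prints

```
 rank candidate  best_fold        S  S_stat3_dimer_nuc  S_socs3
    1        r2      300.0 0.985964           0.984213 0.985983
    2        r7       10.0 0.917867           0.190988 0.898961
    3        r6       10.0 0.917867           0.190988 0.898961
    4       r11     1000.0 0.820307           0.809655 0.820924
    5        r4     1000.0 0.548072           0.505575 0.552263
```

The true fault r2 is ranked first with S ≈ 0.99 despite 20% noise; the
per-output columns show it matches *both* measured profiles, while r6/r7
match only the inhibitor. The best fold (×300 here) is the best fit on the
scan grid, not an estimate of the true regulation level — identifying the
level is outside what the ranking can do.

The `examples/` directory has one short script per capability: simulation,
clinical-data generation, scanning, R/A confirmation, noise/density
robustness, SBML round trip. A thin CLI mirrors the library
(`kinfault simulate|generate|scan|sweep-noise|sweep-density|export-sbml`).

## Layout

- `src/kinfault/models.py` — model abstraction, demo models, perturbations
- `src/kinfault/simulate.py` — stiff integration, regular-grid sampling
- `src/kinfault/clinical.py` — artificial clinical data, thinning
- `src/kinfault/similarity.py` — the similarity score S
- `src/kinfault/oscillation.py` — peak detection, H/P/N and R/A factors
- `src/kinfault/faultscan.py` — the scanner, ranking, experiment sweeps
- `src/kinfault/sbml.py` — SBML L3V1 import/export
- `docs/methods.md` — model equations, parameter choices, design notes
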