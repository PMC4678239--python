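# Methods

## Scope and model class

The package implements model-based fault localization for signal
transduction pathways. The model class is deterministic mass-action ODE
systems dx/dt = f(x, p, u) with nonnegative concentrations (nM), per-second
rate constants and a single constant stimulus u applied as a step at t = 0.
Three assumptions carry the whole method:

1. **Rest before stimulation.** Without stimulus the initial state is a
   rest point (checked at construction to |dx/dt| < 1e-9 nM/s), so every
   post-stimulation feature is attributable to the stimulus plus the fault.
2. **Single multiplicative fault.** Exactly one rate constant or one
   preexisting (nonzero-initial) concentration differs from nominal by a
   fold factor. Simultaneous faults are out of scope.
3. **Trusted model.** The nominal model is taken as correct; the method
   localizes which of its numbers changed, it does not criticize the model.

Time is seconds internally; user-facing horizons and sampling densities are
hours and samples/hour, converted in one place (`simulate.SECONDS_PER_HOUR`).

## Demo models

The two built-in models are reduced stand-ins with the feedback
architecture of well-studied pathways; they are not reductions of any
published large model, and their parameter values are package fixtures
tuned once to meet the qualitative targets below, then committed.

**Steady-state responder (jakstat_demo, 10 states, 12 mass-action
reactions).** IL-6-like stimulus (10 nM) activates a receptor (10 nM);
the active receptor activates cytoplasmic STAT3 (300 nM); activated STAT3
dimerizes, the dimer enters the nucleus (output 1) and is recycled to the
precursor by a preexisting phosphatase (50 nM); the dimer drives
transcription/translation of a SOCS3-like inhibitor (output 2) that
reversibly sequesters the active receptor. Tuning targets: output 1 rises
to a single interior peak (~61 nM at 0.8 h) and relaxes to a nonzero
plateau (~29 nM) within the 10 h default horizon; output 2 rises
monotonically to a plateau (~287 nM). The STAT moiety
(stat3c + stat3c_p + 2·dimers) is conserved by construction, which the
tests use as an integration check.

**Two-feedback oscillator (nfkb_demo, 12 states, 16 reactions).**
TNF-like stimulus activates a preexisting adapter (10 nM) which activates
a neutral kinase pool (200 nM); active kinase liberates NF-κB from a
preexisting 120 nM IκBα|NF-κB complex; nuclear NF-κB (the single output)
induces both IκBα (which re-sequesters NF-κB in cytoplasm and nucleus) and
A20 (which inactivates the kinase). Tuning targets: sustained oscillation
with ≥ 3 complete peak-pairs within 15 h at roughly constant amplitude.
The committed parameters give period ≈ 2.0 h and amplitude ≈ 60 nM; the
NF-κB moiety (complex + cytoplasmic + nuclear) is conserved. The
parameters were found by a coarse random search around hand-chosen
timescales, then rounded to two significant digits and re-verified.

Stimulus dose (10 nM) and the steady-model horizon (10 h) are package
choices — long enough to reach the plateau; the oscillator uses the 15 h
analysis window its features are defined on.

## Numerical integration

LSODA (stiff-capable, via `scipy.integrate.solve_ivp`) with rtol = 1e-8,
atol = 1e-10 nM; sample grids are evaluated through the solver's dense
interpolant, never by re-integration. These tolerances keep solver error
(checked by tolerance-halving, < 1e-5 relative) far below the profile
differences the similarity metric resolves. Tiny negative overshoot is
clipped to zero in reported trajectories only, not in solver state.
Extreme perturbations (folds up to 1000, down to 1e-4) change stiffness
substantially; LSODA's automatic method switching handles the whole
default grid without tuning.

## Artificial clinical data

Each sampled clean value y is replaced by an independent draw from
Normal(y, σ·y) with σ the noise fraction (default 0.2); zero values stay
zero. Draws are clamped at zero by default (concentrations are
nonnegative); the flag is recorded on the dataset and the unclamped
variant remains available, since clamping slightly biases near-zero points
upward. Noise is white across time points and outputs; correlated or
parameter-level noise (cell-to-cell variability) is not modeled.

The *representative* fault of a condition kind — used as ground truth in
the experiment suites — is the candidate whose noise-free profile is least
similar (lowest S, i.e. largest 1 − S) to the normal profile at the kind's
representative fold magnitude (steady model: ×1000, ×0.001, ×100, ×0.01;
oscillator: ×100, ×0.0001, ×10, ×0.01 for rate_up/rate_down/molecule_up/
molecule_down). One dissimilarity rule (1 − S) covers both steady-state
and oscillatory models rather than separate steady-state-change and
amplitude/period rules; ties break by candidate order, then smaller fold.

What passing these synthetic-data tests shows: the ranking recovers a
single multiplicative fault from signal-proportional white noise at the
stated sampling density, *when the generating model is the scanned model*.
What it does not show: robustness to model mismatch, correlated noise,
missing samples, or multi-fault pathologies — real clinical profiles
differ in all four ways.

## Similarity and ranking

S is the product of a cosine shape term and the mean-ratio magnitude term
2·m_c·m_m/(m_c² + m_m²). Outputs are concatenated raw, so a
large-magnitude output dominates the combined S; per-output S values are
reported alongside to surface this. All-zero or nonpositive-mean profiles
make S undefined: the similarity function raises, and the scanner maps the
error to S = 0 with a logged warning (a silent zero would hide modeling
bugs). Identical arrays short-circuit to S = 1 exactly, making the
noise-free self-match criterion exact rather than within-epsilon.

The scanner keeps, per candidate, the fold maximizing S over the grid
(up: 5..100 by 5 then 200..1000 by 100; down: reciprocals of the up grid
plus decades 1e-1..1e-4 — the down grid mirrors the up grid since only
representative decade levels are quoted for inhibition). The generating
fold need not lie on the grid; the reported best fold is a fit, not a
regulation-level estimate. Ranking is by descending S. Within groups whose
S values differ by less than tie_epsilon (default 0.01, transitively
chained), candidates carrying oscillation annotations are re-ordered by
ascending RA_distance

    |R_m − R_c| / max(R_c, ε) + |A_m − A_c| / max(A_c, ε),  ε = 1e-12,

then candidate id; groups without R/A annotations keep their S order — an
alphabetical re-order there would demote strictly better candidates on
no evidence. `confirm_with_RA` applies the same rule to the top k rows and
never demotes a clear S winner.

## Oscillation features

Peaks are strict interior local extrema with prominence ≥ 5% of the
series' global range (scipy `find_peaks`); plateaus collapse to their
midpoint; endpoints are never peaks. Where prominence filtering leaves two
same-type extrema adjacent, the more extreme survives, so detection output
alternates max/min. Trimming removes a *leading* minimum and a *trailing*
maximum — edge extrema whose defining rise or fall lies outside the
analysis window — and preserves alternation. H is mean(maxima) −
mean(minima); P averages the mean gap between adjacent maxima and adjacent
minima, converted to seconds; N counts adjacent (max, min) pairs among the
surviving entries; a result is defined only when at least two maxima and
two minima survive (otherwise all features are zero and flagged).

R = 2H/P is reported in nM/s and A = H·P·N is divided by 10⁶ for
reporting (nM·s·10⁶): with H of order 10 nM, P of order 10³–10⁴ s and N of
order 10, the raw product is of order 10⁶. The raw value is stored too.

Noisy clinical series are smoothed with a centered 5-sample moving average
before peak detection (prominence and window are exposed in `PeakConfig`).
The smoother attenuates amplitude — about 25% for a 2 h period sampled at
6/h — so when the clinical side was smoothed, the model-side profile is
passed through the identical pipeline before computing RA_distance; the
attenuation then cancels instead of biasing the distance against the true
fault.

## Performance

A fault scan is dominated by the candidate × fold simulations, which do
not depend on the noise realization: a `SimulationCache` built once per
(model, sampling grid) is shared across seeds, noise levels and repeated
scans. The full default grids cost ~900 simulations for the steady demo
and ~1100 for the oscillator (about one and two minutes respectively on
one core); every subsequent scan at the same grid is milliseconds. The
experiment suites (`noise_sweep`, `density_sweep`) and the acceptance
script use ten seeds per condition and these problem sizes throughout.

## SBML

Export writes SBML L3V1 core with mass-action kinetic laws in MathML and a
small package-namespace annotation for outputs, oscillatory flag and
default horizon (concepts SBML core lacks). Import accepts arithmetic
MathML (times, plus, minus, divide, power, ci, cn), requires exactly one
boundary-condition species (the stimulus) and one parameter per reaction,
and rejects events, rules, constraints, function definitions, initial
assignments and delays by name. Imported models are re-validated against
the rest-point contract.

## Known limitations

- Single faults only; the scan cannot represent compensating double faults.
- The best fold is not an estimate of the true regulation level, and
  structurally redundant candidates (e.g. a binding step and its reverse)
  can tie within noise — more measured outputs would be needed to separate
  them.
- The magnitude term compares means over the whole window; faults whose
  effect is confined to a short transient are penalized less than shape
  intuition suggests.
- At one sample per hour the oscillation features of a ~2 h period are
  undefined (too few resolvable peaks); ranking then rests on S alone.
- Molecule faults apply only to species with nonzero pre-stimulation
  concentration; a fault in a species synthesized only after stimulation
  must be expressed as a fault of its producing/consuming reactions.
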