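"""Kinetic-model abstraction, built-in demo pathways, and fault perturbations.

A :class:`KineticModel` is a deterministic ODE system ``dx/dt = f(x, k, u)``
over named species, with named rate constants ``k`` and a single constant
stimulus ``u`` switched on at t = 0.  Before stimulation the model sits at a
rest point, so every post-stimulation feature of the dynamics is attributable
to the stimulus and to whatever fault is being simulated.

Two reduced demo models ship with the package:

* :func:`build_demo_steady` — a JAK-STAT-style responder with a SOCS-type
  transcriptional negative feedback; its nuclear transcription-factor dimer
  peaks and relaxes to a nonzero plateau.
* :func:`build_demo_oscillator` — an NF-κB-style network with two negative
  feedback loops (an IκB-type sequestering inhibitor and an A20-type kinase
  inactivator); its nuclear factor oscillates with a period of about two
  hours under sustained stimulation.

A fault is a :class:`Perturbation`: one rate constant or one preexisting
molecule's initial concentration multiplied by a fold change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import (ModelValidationError, NotPreexistingError,
                     UnknownTargetError)

__all__ = [
    "Reaction", "ReactionNetwork", "KineticModel", "Perturbation",
    "PERTURBATION_KINDS", "preexisting_set", "apply_perturbation",
    "build_demo_steady", "build_demo_oscillator", "model_summary",
]

#: The four fault taxonomy kinds: a single reaction rate up/down-regulated,
#: or a single preexisting molecule in excess/deficit.
PERTURBATION_KINDS = ("rate_up", "rate_down", "molecule_up", "molecule_down")

#: Default tolerance for the rest-point check (nM/s).
REST_POINT_TOL = 1e-9


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``reactants`` and ``products`` are ``(species, stoichiometry)`` pairs;
    a species appearing on both sides with equal stoichiometry acts as a
    catalyst (it enters the rate law but has zero net production).  The
    stimulus may appear by name like any species; its concentration is the
    model input ``u``.
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    description: str = ""


class ReactionNetwork:
    """A list of mass-action reactions compiled to a fast RHS.

    The rate of reaction *j* is ``k[j] * prod_i c_i^s_ij`` over its
    reactant entries.  The network pre-computes index arrays so the RHS is
    a handful of vectorized numpy operations per call.
    """

    def __init__(self, species: Sequence[str], stimulus_name: str,
                 reactions: Sequence[Reaction]):
        self.species = tuple(species)
        self.stimulus_name = stimulus_name
        self.reactions = tuple(reactions)
        if stimulus_name in self.species:
            raise ModelValidationError(
                f"stimulus {stimulus_name!r} must not be a state variable")
        n_s, n_r = len(self.species), len(self.reactions)
        index = {s: i for i, s in enumerate(self.species)}
        # augmented concentration vector: states + [u, 1.0]
        stim_idx, one_idx = n_s, n_s + 1
        max_order = max(
            (sum(st for _, st in rx.reactants) for rx in self.reactions),
            default=1)
        if max_order > 2:
            raise ModelValidationError(
                "mass-action networks here support reaction order <= 2")
        ridx = np.full((n_r, 2), one_idx, dtype=np.intp)
        stoich = np.zeros((n_s, n_r))
        for j, rx in enumerate(self.reactions):
            slot = 0
            for name, st in rx.reactants:
                i = stim_idx if name == self.stimulus_name else index[name]
                for _ in range(st):
                    ridx[j, slot] = i
                    slot += 1
                if i < n_s:
                    stoich[i, j] -= st
            for name, st in rx.products:
                if name == self.stimulus_name:
                    continue
                stoich[index[name], j] += st
        self._ridx = ridx
        self.stoichiometry = stoich

    @property
    def reaction_names(self) -> tuple[str, ...]:
        return tuple(rx.name for rx in self.reactions)

    def rhs(self, x: np.ndarray, k: np.ndarray, u: float) -> np.ndarray:
        xf = np.empty(len(self.species) + 2)
        xf[:-2] = x
        xf[-2] = u
        xf[-1] = 1.0
        v = k * xf[self._ridx[:, 0]] * xf[self._ridx[:, 1]]
        return self.stoichiometry @ v

    def rates(self, x: np.ndarray, k: np.ndarray, u: float) -> np.ndarray:
        """Per-reaction fluxes at state ``x`` (for diagnostics)."""
        xf = np.concatenate([x, [u, 1.0]])
        return k * xf[self._ridx[:, 0]] * xf[self._ridx[:, 1]]


@dataclass(frozen=True)
class KineticModel:
    """An ODE signaling model with designated measured outputs.

    Concentrations are in nM and time is in seconds internally; user-facing
    horizons and sampling densities are in hours (conversion is centralized
    in :mod:`kinfault.simulate`).
    """

    name: str
    state_names: tuple[str, ...]
    initial_state: np.ndarray
    rate_constant_names: tuple[str, ...]
    rate_constants: np.ndarray
    stimulus_name: str
    stimulus: float
    output_names: tuple[str, ...]
    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    oscillatory: bool = False
    default_horizon_h: float = 10.0
    network: ReactionNetwork | None = field(default=None, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "initial_state",
                           np.asarray(self.initial_state, dtype=float))
        object.__setattr__(self, "rate_constants",
                           np.asarray(self.rate_constants, dtype=float))
        if len(self.initial_state) != len(self.state_names):
            raise ModelValidationError(
                f"{len(self.state_names)} state names but "
                f"{len(self.initial_state)} initial values")
        if len(self.rate_constants) != len(self.rate_constant_names):
            raise ModelValidationError(
                f"{len(self.rate_constant_names)} rate-constant names but "
                f"{len(self.rate_constants)} values")
        if np.any(self.initial_state < 0) or np.any(self.rate_constants < 0):
            raise ModelValidationError(
                "initial concentrations and rate constants must be >= 0")
        if not self.output_names:
            raise ModelValidationError("output_names must be nonempty")
        seen = set()
        for o in self.output_names:
            if o not in self.state_names:
                raise ModelValidationError(f"output {o!r} is not a state")
            if o in seen:
                raise ModelValidationError(f"output {o!r} listed twice")
            seen.add(o)

    # -- index helpers -----------------------------------------------------
    def state_index(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError:
            raise UnknownTargetError(
                f"model {self.name!r} has no state {name!r}") from None

    def rate_index(self, name: str) -> int:
        try:
            return self.rate_constant_names.index(name)
        except ValueError:
            raise UnknownTargetError(
                f"model {self.name!r} has no rate constant {name!r}") from None

    @property
    def output_indices(self) -> tuple[int, ...]:
        return tuple(self.state_names.index(o) for o in self.output_names)

    def validate_rest_point(self, tol: float = REST_POINT_TOL) -> float:
        """Check the unstimulated initial state is a rest point.

        Returns the max absolute RHS component; raises if it exceeds *tol*.
        """
        drift = float(np.max(np.abs(
            self.rhs(self.initial_state, self.rate_constants, 0.0))))
        if drift > tol:
            raise ModelValidationError(
                f"initial state of {self.name!r} is not at rest without "
                f"stimulus (max |dx/dt| = {drift:.3g} > {tol:g})")
        return drift


def preexisting_set(model: KineticModel) -> tuple[str, ...]:
    """Species with strictly positive concentration before stimulation.

    These are the admissible targets of molecule_up / molecule_down faults.
    """
    return tuple(s for s, c in zip(model.state_names, model.initial_state)
                 if c > 0)


@dataclass(frozen=True)
class Perturbation:
    """A single-target fault: one number of the model multiplied by ``fold``."""

    kind: str
    target: str
    fold: float

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}; "
                             f"expected one of {PERTURBATION_KINDS}")
        if not self.fold > 0:
            raise ValueError(f"fold must be positive, got {self.fold}")
        if self.kind.endswith("_up") and self.fold < 1:
            raise ValueError(f"{self.kind} requires fold >= 1, got {self.fold}")
        if self.kind.endswith("_down") and self.fold > 1:
            raise ValueError(f"{self.kind} requires fold <= 1, got {self.fold}")

    @property
    def is_rate(self) -> bool:
        return self.kind.startswith("rate")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "target": self.target, "fold": self.fold}


def apply_perturbation(model: KineticModel, p: Perturbation) -> KineticModel:
    """Return a copy of *model* with exactly one number changed.

    For ``rate_*`` kinds the targeted rate constant is multiplied by
    ``p.fold``; for ``molecule_*`` kinds the targeted initial concentration
    is.  Molecule faults require a preexisting (nonzero-initial) target.
    """
    if p.is_rate:
        j = model.rate_index(p.target)
        k = model.rate_constants.copy()
        k[j] *= p.fold
        return replace(model, rate_constants=k)
    i = model.state_index(p.target)
    if not model.initial_state[i] > 0:
        raise NotPreexistingError(
            f"{p.target!r} has zero initial concentration in {model.name!r}; "
            "molecule faults apply only to preexisting molecules (nonzero "
            "concentration before stimulation)")
    x0 = model.initial_state.copy()
    x0[i] *= p.fold
    return replace(model, initial_state=x0)


# ---------------------------------------------------------------------------
# Built-in demo models
# ---------------------------------------------------------------------------

def _network_model(name, species, x0, stimulus_name, stimulus, reactions,
                   rate_constants, outputs, oscillatory, horizon_h):
    net = ReactionNetwork(species, stimulus_name, reactions)
    model = KineticModel(
        name=name,
        state_names=tuple(species),
        initial_state=np.asarray(x0, dtype=float),
        rate_constant_names=net.reaction_names,
        rate_constants=np.asarray(rate_constants, dtype=float),
        stimulus_name=stimulus_name,
        stimulus=stimulus,
        output_names=tuple(outputs),
        rhs=net.rhs,
        oscillatory=oscillatory,
        default_horizon_h=horizon_h,
        network=net,
    )
    model.validate_rest_point()
    return model


def build_demo_steady() -> KineticModel:
    """Reduced JAK-STAT/SOCS responder (10 states, 12 reactions).

    IL-6-like stimulus activates a receptor; the active receptor activates a
    cytoplasmic STAT3-type precursor, which dimerizes and enters the nucleus
    (the nuclear dimer is output 1).  A preexisting phosphatase recycles the
    nuclear dimer back to precursor.  The dimer drives transcription and
    translation of a SOCS3-type inhibitor (output 2) that reversibly
    sequesters the active receptor — the negative feedback loop.  mRNA and
    inhibitor decay first-order.

    Parameter values are package fixtures tuned once so that, under nominal
    stimulus, output 1 rises to a single peak near 0.75 h and relaxes to a
    nonzero plateau within 10 h, while output 2 rises monotonically to a
    plateau.
    """
    species = ["receptor", "receptor_active", "stat3c", "stat3c_p",
               "stat3_dimer_cyt", "stat3_dimer_nuc", "pp2",
               "socs3_mrna", "socs3", "receptor_socs3"]
    x0 = [10.0, 0.0, 300.0, 0.0, 0.0, 0.0, 50.0, 0.0, 0.0, 0.0]
    rx = [
        Reaction("r1", (("receptor", 1), ("il6", 1)),
                 (("receptor_active", 1), ("il6", 1)),
                 "receptor activation by stimulus"),
        Reaction("r2", (("stat3c", 1), ("receptor_active", 1)),
                 (("stat3c_p", 1), ("receptor_active", 1)),
                 "STAT3 activation by active receptor"),
        Reaction("r3", (("stat3c_p", 2),), (("stat3_dimer_cyt", 1),),
                 "dimerization of activated STAT3"),
        Reaction("r4", (("stat3_dimer_cyt", 1),), (("stat3_dimer_nuc", 1),),
                 "nuclear import of the dimer"),
        Reaction("r5", (("stat3_dimer_nuc", 1), ("pp2", 1)),
                 (("stat3c", 2), ("pp2", 1)),
                 "phosphatase-mediated recycling of the nuclear dimer"),
        Reaction("r6", (("stat3_dimer_nuc", 1),),
                 (("stat3_dimer_nuc", 1), ("socs3_mrna", 1)),
                 "dimer-driven transcription of the inhibitor"),
        Reaction("r7", (("socs3_mrna", 1),),
                 (("socs3_mrna", 1), ("socs3", 1)),
                 "translation of the inhibitor"),
        Reaction("r8", (("socs3_mrna", 1),), (), "mRNA decay"),
        Reaction("r9", (("socs3", 1),), (), "inhibitor decay"),
        Reaction("r10", (("receptor_active", 1), ("socs3", 1)),
                 (("receptor_socs3", 1),),
                 "inhibitor sequesters the active receptor (feedback)"),
        Reaction("r11", (("receptor_socs3", 1),),
                 (("receptor_active", 1), ("socs3", 1)),
                 "release of the sequestered receptor"),
        Reaction("r12", (("receptor_active", 1),), (("receptor", 1),),
                 "receptor deactivation"),
    ]
    k = [2e-4, 1e-4, 1e-3, 5e-3, 2e-5, 1e-3, 5e-4, 5e-4, 1e-4,
         1e-5, 1e-3, 1e-4]
    return _network_model(
        "jakstat_demo", species, x0, "il6", 10.0, rx, k,
        ["stat3_dimer_nuc", "socs3"], oscillatory=False, horizon_h=10.0)


def build_demo_oscillator() -> KineticModel:
    """Reduced TNF-α/NF-κB-style oscillator (12 states, 16 reactions).

    TNF-like stimulus activates a preexisting TRADD-type adapter, which
    activates a neutral IKK-type kinase.  Active kinase liberates NF-κB from
    a preexisting cytoplasmic IκBα|NF-κB complex; free NF-κB enters the
    nucleus (the single output).  Nuclear NF-κB drives transcription and
    translation of (i) IκBα, which re-sequesters NF-κB in both compartments,
    and (ii) A20, which inactivates the active kinase — the two negative
    feedback loops responsible for sustained oscillation.  mRNAs, A20 and
    free IκBα decay first-order.

    Parameter values are package fixtures tuned once so that the nominal
    output oscillates with a period near 2 h and roughly constant amplitude
    (~60 nM), giving at least three complete peak-pairs within 15 h.
    """
    species = ["tradd", "tradd_active", "ikk_neutral", "ikk_active",
               "ikba_nfkb", "nfkb_cyt", "nfkb_nuc", "ikba_mrna",
               "ikba_cyt", "ikba_nuc", "a20_mrna", "a20"]
    x0 = [10.0, 0.0, 200.0, 0.0, 120.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    rx = [
        Reaction("r1", (("tradd", 1), ("tnf", 1)),
                 (("tradd_active", 1), ("tnf", 1)),
                 "adapter activation by stimulus"),
        Reaction("r2", (("ikk_neutral", 1), ("tradd_active", 1)),
                 (("ikk_active", 1), ("tradd_active", 1)),
                 "kinase activation by the active adapter"),
        Reaction("r3", (("ikba_nfkb", 1), ("ikk_active", 1)),
                 (("nfkb_cyt", 1), ("ikk_active", 1)),
                 "kinase-driven liberation of NF-κB from the complex"),
        Reaction("r4", (("nfkb_cyt", 1),), (("nfkb_nuc", 1),),
                 "nuclear import of free NF-κB"),
        Reaction("r5", (("nfkb_nuc", 1),),
                 (("nfkb_nuc", 1), ("ikba_mrna", 1)),
                 "NF-κB-driven transcription of the inhibitor"),
        Reaction("r6", (("ikba_mrna", 1),),
                 (("ikba_mrna", 1), ("ikba_cyt", 1)),
                 "translation of the inhibitor"),
        Reaction("r7", (("ikba_cyt", 1), ("nfkb_cyt", 1)),
                 (("ikba_nfkb", 1),),
                 "cytoplasmic re-sequestration of NF-κB"),
        Reaction("r8", (("ikba_cyt", 1),), (("ikba_nuc", 1),),
                 "nuclear import of the inhibitor"),
        Reaction("r9", (("ikba_nuc", 1), ("nfkb_nuc", 1)),
                 (("ikba_nfkb", 1),),
                 "nuclear capture and export of NF-κB as complex"),
        Reaction("r10", (("nfkb_nuc", 1),),
                 (("nfkb_nuc", 1), ("a20_mrna", 1)),
                 "NF-κB-driven transcription of the second regulator"),
        Reaction("r11", (("a20_mrna", 1),),
                 (("a20_mrna", 1), ("a20", 1)),
                 "translation of the second regulator"),
        Reaction("r12", (("ikk_active", 1), ("a20", 1)),
                 (("ikk_neutral", 1), ("a20", 1)),
                 "kinase inactivation by the second regulator (feedback)"),
        Reaction("r13", (("ikba_mrna", 1),), (), "inhibitor mRNA decay"),
        Reaction("r14", (("a20_mrna", 1),), (), "regulator mRNA decay"),
        Reaction("r15", (("a20", 1),), (), "regulator decay"),
        Reaction("r16", (("ikba_cyt", 1),), (), "free inhibitor decay"),
    ]
    k = [2e-4, 1e-4, 1.7e-5, 3e-3, 1.4e-3, 1.9e-3, 2.5e-3, 3.4e-3,
         2.3e-3, 2e-4, 5e-3, 1.1e-4, 2.9e-4, 5e-4, 1.1e-3, 7.6e-5]
    return _network_model(
        "nfkb_demo", species, x0, "tnf", 10.0, rx, k,
        ["nfkb_nuc"], oscillatory=True, horizon_h=15.0)


def model_summary(model: KineticModel) -> dict:
    """JSON-serializable summary of a model's structure and parameters."""
    return {
        "name": model.name,
        "states": {s: float(c) for s, c in
                   zip(model.state_names, model.initial_state)},
        "rate_constants": {r: float(k) for r, k in
                           zip(model.rate_constant_names,
                               model.rate_constants)},
        "stimulus": {"name": model.stimulus_name,
                     "value": float(model.stimulus)},
        "outputs": list(model.output_names),
        "preexisting": list(preexisting_set(model)),
        "oscillatory": model.oscillatory,
        "default_horizon_h": model.default_horizon_h,
    }


def write_model_summary(model: KineticModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_summary(model), fh, indent=1)
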