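"""SBML Level 3 Version 1 (core) import and export of kinetic models.

Export writes any network-backed model (the demo models, or an imported
one) as a single-compartment SBML document with mass-action kinetic laws in
MathML.  The designated outputs, the oscillatory flag and the default
horizon — concepts SBML core does not carry — travel in a small annotation
element under the package's own namespace.

Import maps a document back onto the model contract: species become states,
the unique boundary-condition species becomes the constant stimulus, global
parameters become rate constants (one per reaction), and each reaction's
kinetic-law MathML is compiled to a rate function.  The MathML subset
accepted is arithmetic only — times, plus, minus, divide, power, ci, cn —
which covers mass-action and rational kinetic laws.  Constructs outside the
ODE contract (events, rules, constraints, function definitions, delays,
initial assignments) are rejected with an error naming the element.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from lxml import etree

from .errors import SbmlImportError
from .models import KineticModel, ReactionNetwork, Reaction

__all__ = ["write_sbml", "read_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
KF_NS = "https://github.com/kinfault/schema"

_UNSUPPORTED = ("listOfEvents", "listOfRules", "listOfConstraints",
                "listOfFunctionDefinitions", "listOfInitialAssignments")


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _mathml_mass_action(parent, rate_name: str,
                        reactants: tuple[tuple[str, int], ...]) -> None:
    math = etree.SubElement(parent, _q(MATHML_NS, "math"))
    apply_ = etree.SubElement(math, _q(MATHML_NS, "apply"))
    etree.SubElement(apply_, _q(MATHML_NS, "times"))
    etree.SubElement(apply_, _q(MATHML_NS, "ci")).text = rate_name
    for species, stoich in reactants:
        for _ in range(stoich):
            etree.SubElement(apply_, _q(MATHML_NS, "ci")).text = species


def write_sbml(model: KineticModel, path) -> None:
    """Write a network-backed model as SBML L3V1 core."""
    if model.network is None:
        raise ValueError(
            f"model {model.name!r} has no reaction network; only "
            "network-backed models can be exported")
    net = model.network
    root = etree.Element(_q(SBML_NS, "sbml"),
                         nsmap={None: SBML_NS}, level="3", version="1")
    mdl = etree.SubElement(root, _q(SBML_NS, "model"), id=model.name)

    ann = etree.SubElement(mdl, _q(SBML_NS, "annotation"))
    kf = etree.SubElement(ann, _q(KF_NS, "modelInfo"), nsmap={"kf": KF_NS})
    kf.set("outputs", " ".join(model.output_names))
    kf.set("oscillatory", str(model.oscillatory).lower())
    kf.set("defaultHorizonHours", repr(model.default_horizon_h))

    comps = etree.SubElement(mdl, _q(SBML_NS, "listOfCompartments"))
    etree.SubElement(comps, _q(SBML_NS, "compartment"), id="cell",
                     size="1", spatialDimensions="3", constant="true")

    sps = etree.SubElement(mdl, _q(SBML_NS, "listOfSpecies"))
    for name, c0 in zip(model.state_names, model.initial_state):
        etree.SubElement(
            sps, _q(SBML_NS, "species"), id=name, compartment="cell",
            initialConcentration=repr(float(c0)),
            hasOnlySubstanceUnits="false", boundaryCondition="false",
            constant="false")
    etree.SubElement(
        sps, _q(SBML_NS, "species"), id=model.stimulus_name,
        compartment="cell", initialConcentration=repr(float(model.stimulus)),
        hasOnlySubstanceUnits="false", boundaryCondition="true",
        constant="true")

    pars = etree.SubElement(mdl, _q(SBML_NS, "listOfParameters"))
    for name, k in zip(model.rate_constant_names, model.rate_constants):
        etree.SubElement(pars, _q(SBML_NS, "parameter"), id=name,
                         value=repr(float(k)), constant="true")

    rxns = etree.SubElement(mdl, _q(SBML_NS, "listOfReactions"))
    for rx, rate_name in zip(net.reactions, model.rate_constant_names):
        el = etree.SubElement(rxns, _q(SBML_NS, "reaction"), id=rx.name,
                              reversible="false", fast="false")
        if rx.reactants:
            lo = etree.SubElement(el, _q(SBML_NS, "listOfReactants"))
            for species, stoich in rx.reactants:
                etree.SubElement(lo, _q(SBML_NS, "speciesReference"),
                                 species=species, stoichiometry=str(stoich),
                                 constant="true")
        if rx.products:
            lo = etree.SubElement(el, _q(SBML_NS, "listOfProducts"))
            for species, stoich in rx.products:
                etree.SubElement(lo, _q(SBML_NS, "speciesReference"),
                                 species=species, stoichiometry=str(stoich),
                                 constant="true")
        kl = etree.SubElement(el, _q(SBML_NS, "kineticLaw"))
        _mathml_mass_action(kl, rate_name, rx.reactants)

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


# ---------------------------------------------------------------------------
# Import
# ---------------------------------------------------------------------------

def _compile_mathml(node, names: dict[str, int]):
    """Compile a MathML expression to ``f(xf) -> float`` over an augmented
    value vector indexed by *names* (species, stimulus, parameters)."""
    tag = etree.QName(node).localname
    if tag == "ci":
        ident = node.text.strip()
        if ident not in names:
            raise SbmlImportError(f"unknown identifier {ident!r} in "
                                  "kinetic law")
        i = names[ident]
        return lambda xf: xf[i]
    if tag == "cn":
        val = float(node.text.strip())
        return lambda xf: val
    if tag == "apply":
        children = [c for c in node
                    if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_compile_mathml(c, names) for c in children[1:]]
        if op == "times":
            return lambda xf: np.prod([a(xf) for a in args])
        if op == "plus":
            return lambda xf: sum(a(xf) for a in args)
        if op == "minus":
            if len(args) == 1:
                return lambda xf: -args[0](xf)
            return lambda xf: args[0](xf) - args[1](xf)
        if op == "divide":
            return lambda xf: args[0](xf) / args[1](xf)
        if op == "power":
            return lambda xf: args[0](xf) ** args[1](xf)
        if op == "csymbol" or op == "delay":
            raise SbmlImportError("delay constructs are not supported")
        raise SbmlImportError(f"unsupported MathML operator <{op}>")
    raise SbmlImportError(f"unsupported MathML element <{tag}>")


def read_sbml(path) -> KineticModel:
    """Read an SBML L3V1 document into a :class:`KineticModel`.

    Requirements beyond validity: exactly one boundary-condition species
    (the stimulus); one global parameter per reaction appearing in its
    kinetic law (the reaction's rate constant, in document order).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such SBML file: {p}")
    try:
        tree = etree.parse(str(p))
    except etree.XMLSyntaxError as exc:
        raise SbmlImportError(f"cannot parse {p}: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise SbmlImportError(f"{p} is not an SBML document "
                              f"(root <{etree.QName(root).localname}>)")
    ns = etree.QName(root).namespace
    mdl = root.find(_q(ns, "model"))
    if mdl is None:
        raise SbmlImportError("document has no <model> element")
    for bad in _UNSUPPORTED:
        found = mdl.find(_q(ns, bad))
        if found is not None and len(found):
            raise SbmlImportError(
                f"unsupported SBML construct <{bad}> "
                f"(first child <{etree.QName(found[0]).localname}>)")

    state_names, x0 = [], []
    stimulus_name, stimulus = None, None
    for sp in mdl.iterfind(f"{_q(ns, 'listOfSpecies')}/{_q(ns, 'species')}"):
        sid = sp.get("id")
        conc = float(sp.get("initialConcentration", "0"))
        if sp.get("boundaryCondition") == "true":
            if stimulus_name is not None:
                raise SbmlImportError(
                    "more than one boundary-condition species; cannot "
                    "identify the stimulus")
            stimulus_name, stimulus = sid, conc
        else:
            state_names.append(sid)
            x0.append(conc)
    if stimulus_name is None:
        raise SbmlImportError("no boundary-condition species to serve as "
                              "the stimulus")

    param_names, param_vals = [], []
    for par in mdl.iterfind(
            f"{_q(ns, 'listOfParameters')}/{_q(ns, 'parameter')}"):
        param_names.append(par.get("id"))
        param_vals.append(float(par.get("value", "0")))

    # augmented vector layout: states + [stimulus] + parameters
    names = {s: i for i, s in enumerate(state_names)}
    names[stimulus_name] = len(state_names)
    for j, pn in enumerate(param_names):
        names[pn] = len(state_names) + 1 + j

    reactions, rate_fns, rx_names = [], [], []
    for rx in mdl.iterfind(f"{_q(ns, 'listOfReactions')}/{_q(ns, 'reaction')}"):
        rx_names.append(rx.get("id"))
        def refs(tag):
            lo = rx.find(_q(ns, tag))
            if lo is None:
                return ()
            return tuple(
                (r.get("species"), int(float(r.get("stoichiometry", "1"))))
                for r in lo.iterfind(_q(ns, "speciesReference")))
        reactants, products = refs("listOfReactants"), refs("listOfProducts")
        kl = rx.find(_q(ns, "kineticLaw"))
        if kl is None:
            raise SbmlImportError(f"reaction {rx.get('id')!r} has no "
                                  "kinetic law")
        math = kl.find(_q(MATHML_NS, "math"))
        if math is None or not len(math):
            raise SbmlImportError(f"reaction {rx.get('id')!r} has an empty "
                                  "kinetic law")
        rate_fns.append(_compile_mathml(math[0], names))
        reactions.append((reactants, products))
    if len(rx_names) != len(param_names):
        raise SbmlImportError(
            f"{len(rx_names)} reactions but {len(param_names)} parameters; "
            "expected one rate constant per reaction")

    n_s, n_r = len(state_names), len(reactions)
    stoich = np.zeros((n_s, n_r))
    for j, (reactants, products) in enumerate(reactions):
        for s, st in reactants:
            if s in names and names[s] < n_s:
                stoich[names[s], j] -= st
        for s, st in products:
            if s in names and names[s] < n_s:
                stoich[names[s], j] += st

    def rhs(x, k, u):
        xf = np.concatenate([x, [u], k])
        v = np.array([f(xf) for f in rate_fns])
        return stoich @ v

    # package annotation: outputs, oscillatory flag, horizon
    outputs, oscillatory, horizon = None, False, 10.0
    info = mdl.find(f"{_q(ns, 'annotation')}/{_q(KF_NS, 'modelInfo')}")
    if info is not None:
        outputs = tuple(info.get("outputs", "").split())
        oscillatory = info.get("oscillatory") == "true"
        horizon = float(info.get("defaultHorizonHours", "10"))
    if not outputs:
        outputs = (state_names[-1],)  # fallback: last declared species

    # rebuild a ReactionNetwork when every kinetic law is mass-action so the
    # imported model stays exportable; otherwise keep the compiled RHS only
    network = None
    try:
        rx_objs = [Reaction(nm, reactants, products)
                   for nm, (reactants, products) in zip(rx_names, reactions)]
        network = ReactionNetwork(state_names, stimulus_name, rx_objs)
    except Exception:
        network = None

    model = KineticModel(
        name=mdl.get("id", p.stem),
        state_names=tuple(state_names),
        initial_state=np.asarray(x0),
        rate_constant_names=tuple(param_names),
        rate_constants=np.asarray(param_vals),
        stimulus_name=stimulus_name,
        stimulus=float(stimulus),
        output_names=outputs,
        rhs=rhs,
        oscillatory=oscillatory,
        default_horizon_h=horizon,
        network=network,
    )
    model.validate_rest_point(tol=1e-6)
    return model
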