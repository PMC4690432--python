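"""Read/write the supported SBML subset and expose the base set of values.

Supported subset: compartments, species (amounts), global parameters,
reactions with kinetic laws, rate rules and assignment rules.  Events,
delays, algebraic rules, function definitions, constraints and initial
assignments are rejected with :class:`~paramdag.errors.UnsupportedFeature`
rather than silently dropped.

Species are stored internally as amounts; a model declaring
``initialConcentration`` is converted via its compartment size at load.
Output is always SBML Level 3 Version 1.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from xml.etree import ElementTree as ET

from . import expressions as ex
from .errors import SBMLParseError, UnknownKey, UnsupportedFeature

L3_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"
DELAY_CSYMBOL = "http://www.sbml.org/sbml/symbols/delay"

GLOBAL_QUANTITY = "GLOBAL_QUANTITY"
SPECIES_INITIAL = "SPECIES_INITIAL"
COMPARTMENT_SIZE = "COMPARTMENT_SIZE"


@dataclass(frozen=True)
class Compartment:
    id: str
    size: float
    constant: bool = True


@dataclass(frozen=True)
class Species:
    id: str
    compartment_id: str
    initial_amount: float
    boundary: bool = False


@dataclass(frozen=True)
class GlobalQuantity:
    id: str
    value: float
    constant: bool = True


@dataclass(frozen=True)
class SpeciesRef:
    species_id: str
    stoichiometry: float = 1.0


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[SpeciesRef, ...]
    products: tuple[SpeciesRef, ...]
    modifiers: tuple[str, ...]
    kinetic_law: ex.MathExpr


@dataclass(frozen=True)
class Rule:
    """A rate or assignment rule; ``target_id`` is the variable it drives."""

    target_id: str
    math: ex.MathExpr


@dataclass(frozen=True)
class BaseModel:
    model_id: str
    compartments: tuple[Compartment, ...] = ()
    species: tuple[Species, ...] = ()
    global_quantities: tuple[GlobalQuantity, ...] = ()
    reactions: tuple[Reaction, ...] = ()
    rate_rules: tuple[Rule, ...] = ()
    assignment_rules: tuple[Rule, ...] = ()


@dataclass(frozen=True)
class BaseSet:
    """The assignable quantities of a model and their initial values."""

    values: dict[str, float] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)


def validate_model(model: BaseModel) -> None:
    """Check the BaseModel invariants; raise :class:`SBMLParseError`."""
    ids: set[str] = set()
    for coll in (model.compartments, model.species, model.global_quantities,
                 model.reactions):
        for item in coll:
            if item.id in ids:
                raise SBMLParseError(f"duplicate id {item.id!r}")
            ids.add(item.id)
    comp_ids = {c.id for c in model.compartments}
    for sp in model.species:
        if sp.compartment_id not in comp_ids:
            raise SBMLParseError(
                f"species {sp.id!r} references unknown compartment "
                f"{sp.compartment_id!r}"
            )
    sp_ids = {s.id for s in model.species}
    known = ids
    for rxn in model.reactions:
        for ref in rxn.reactants + rxn.products:
            if ref.species_id not in sp_ids:
                raise SBMLParseError(
                    f"reaction {rxn.id!r} references unknown species "
                    f"{ref.species_id!r}"
                )
            if not ref.stoichiometry > 0:
                raise SBMLParseError(
                    f"reaction {rxn.id!r}: stoichiometry must be positive"
                )
        for key, node in ex.references(rxn.kinetic_law):
            if node is not None or key not in known:
                raise SBMLParseError(
                    f"kinetic law of {rxn.id!r} references undeclared id "
                    f"{key!r}"
                )
    for rule in model.rate_rules + model.assignment_rules:
        if rule.target_id not in known:
            raise SBMLParseError(
                f"rule targets undeclared id {rule.target_id!r}"
            )
        for key, node in ex.references(rule.math):
            if node is not None or key not in known:
                raise SBMLParseError(
                    f"rule for {rule.target_id!r} references undeclared id "
                    f"{key!r}"
                )


# ---------------------------------------------------------------------------
# reading


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _bool(value: str | None, default: bool = False) -> bool:
    if value is None:
        return default
    return value.strip().lower() in ("true", "1")


def _math_to_ast(elem: ET.Element) -> ex.MathExpr:
    tag = _strip_ns(elem.tag)
    if tag == "math":
        children = list(elem)
        if len(children) != 1:
            raise SBMLParseError("<math> must hold exactly one expression")
        return _math_to_ast(children[0])
    if tag == "cn":
        text = (elem.text or "").strip()
        if elem.get("type") == "e-notation":
            parts = [t for t in [text] + [
                (c.tail or "").strip() for c in elem
            ] if t]
            if len(parts) != 2:
                raise SBMLParseError("malformed e-notation <cn>")
            return ex.Num(float(f"{parts[0]}e{parts[1]}"))
        if elem.get("type") == "rational":
            parts = [t for t in [text] + [
                (c.tail or "").strip() for c in elem
            ] if t]
            if len(parts) != 2:
                raise SBMLParseError("malformed rational <cn>")
            return ex.BinOp("/", ex.Num(float(parts[0])),
                            ex.Num(float(parts[1])))
        return ex.Num(float(text))
    if tag == "ci":
        return ex.Ref((elem.text or "").strip(), ex.BARE)
    if tag == "csymbol":
        url = elem.get("definitionURL", "")
        if url == TIME_CSYMBOL:
            return ex.Time()
        if url == DELAY_CSYMBOL:
            raise UnsupportedFeature("delay")
        raise UnsupportedFeature(f"csymbol {url}")
    if tag == "pi":
        return ex.Num(3.141592653589793)
    if tag == "exponentiale":
        return ex.Num(2.718281828459045)
    if tag == "apply":
        children = list(elem)
        op = _strip_ns(children[0].tag)
        args = [_math_to_ast(c) for c in children[1:]]
        if op == "plus":
            if not args:
                return ex.Num(0.0)
            out = args[0]
            for a in args[1:]:
                out = ex.BinOp("+", out, a)
            return out
        if op == "minus":
            if len(args) == 1:
                return ex.Neg(args[0])
            out = args[0]
            for a in args[1:]:
                out = ex.BinOp("-", out, a)
            return out
        if op == "times":
            if not args:
                return ex.Num(1.0)
            out = args[0]
            for a in args[1:]:
                out = ex.BinOp("*", out, a)
            return out
        if op == "divide":
            if len(args) != 2:
                raise SBMLParseError("<divide> takes two operands")
            return ex.BinOp("/", args[0], args[1])
        if op == "power":
            if len(args) != 2:
                raise SBMLParseError("<power> takes two operands")
            return ex.BinOp("^", args[0], args[1])
        if op in ("exp", "ln", "log", "abs", "root"):
            if op == "root":  # default degree-2 root
                if len(args) == 1:
                    return ex.Call("sqrt", tuple(args))
                raise UnsupportedFeature("root with explicit degree")
            return ex.Call(op, tuple(args))
        if op == "csymbol":
            return _math_to_ast(children[0])
        raise UnsupportedFeature(f"MathML operator <{op}>")
    raise UnsupportedFeature(f"MathML element <{tag}>")


def _substitute(e: ex.MathExpr, mapping: dict[str, ex.MathExpr]) -> ex.MathExpr:
    if isinstance(e, ex.Ref) and e.node is ex.BARE and e.key in mapping:
        return mapping[e.key]
    if isinstance(e, ex.Neg):
        return ex.Neg(_substitute(e.operand, mapping))
    if isinstance(e, ex.BinOp):
        return ex.BinOp(e.op, _substitute(e.left, mapping),
                        _substitute(e.right, mapping))
    if isinstance(e, ex.Call):
        return ex.Call(e.name, tuple(_substitute(a, mapping) for a in e.args))
    return e


def parse_sbml_string(text: str) -> BaseModel:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise SBMLParseError(f"not well-formed XML: {exc}") from exc
    if _strip_ns(root.tag) != "sbml":
        raise SBMLParseError("root element is not <sbml>")
    ns = root.tag[1:].rsplit("}", 1)[0] if root.tag.startswith("{") else ""
    if "level3" in ns and "version1" not in ns:
        raise UnsupportedFeature(f"SBML namespace {ns}")
    model_elem = next((c for c in root if _strip_ns(c.tag) == "model"), None)
    if model_elem is None:
        raise SBMLParseError("no <model> element")

    def kids(parent: ET.Element, tag: str) -> list[ET.Element]:
        lst = next(
            (c for c in parent if _strip_ns(c.tag) == tag), None
        )
        return list(lst) if lst is not None else []

    for feature, tag in [
        ("events", "listOfEvents"),
        ("function definitions", "listOfFunctionDefinitions"),
        ("constraints", "listOfConstraints"),
        ("initial assignments", "listOfInitialAssignments"),
    ]:
        if kids(model_elem, tag):
            raise UnsupportedFeature(feature)

    compartments = []
    for c in kids(model_elem, "listOfCompartments"):
        size = c.get("size", c.get("volume", "1"))
        compartments.append(Compartment(
            id=c.get("id") or c.get("name") or "",
            size=float(size),
            constant=_bool(c.get("constant"), True),
        ))
    comp_size = {c.id: c.size for c in compartments}

    species = []
    for s in kids(model_elem, "listOfSpecies"):
        sid = s.get("id") or s.get("name") or ""
        comp = s.get("compartment", "")
        if s.get("initialAmount") is not None:
            amount = float(s.get("initialAmount"))
        elif s.get("initialConcentration") is not None:
            if comp not in comp_size:
                raise SBMLParseError(
                    f"species {sid!r} references unknown compartment {comp!r}"
                )
            amount = float(s.get("initialConcentration")) * comp_size[comp]
        else:
            amount = 0.0
        species.append(Species(
            id=sid, compartment_id=comp, initial_amount=amount,
            boundary=_bool(s.get("boundaryCondition")),
        ))

    quantities = []
    for p in kids(model_elem, "listOfParameters"):
        quantities.append(GlobalQuantity(
            id=p.get("id") or p.get("name") or "",
            value=float(p.get("value", "0")),
            constant=_bool(p.get("constant"), True),
        ))

    reactions = []
    for r in kids(model_elem, "listOfReactions"):
        rid = r.get("id") or r.get("name") or ""

        def refs(tag: str) -> tuple[SpeciesRef, ...]:
            return tuple(
                SpeciesRef(
                    species_id=sr.get("species", ""),
                    stoichiometry=float(sr.get("stoichiometry", "1")),
                )
                for sr in kids(r, tag)
            )

        modifiers = tuple(
            m.get("species", "") for m in kids(r, "listOfModifiers")
        )
        kl = next((c for c in r if _strip_ns(c.tag) == "kineticLaw"), None)
        if kl is None:
            raise SBMLParseError(f"reaction {rid!r} has no kinetic law")
        math_elem = next(
            (c for c in kl if _strip_ns(c.tag) == "math"), None
        )
        if math_elem is None:
            raise SBMLParseError(f"kinetic law of {rid!r} has no <math>")
        law = _math_to_ast(math_elem)
        # inline numeric values of reaction-local parameters
        local_params: dict[str, ex.MathExpr] = {}
        for tag in ("listOfLocalParameters", "listOfParameters"):
            for lp in kids(kl, tag):
                local_params[lp.get("id") or lp.get("name") or ""] = ex.Num(
                    float(lp.get("value", "0"))
                )
        if local_params:
            law = _substitute(law, local_params)
        reactions.append(Reaction(
            id=rid,
            reactants=refs("listOfReactants"),
            products=refs("listOfProducts"),
            modifiers=modifiers,
            kinetic_law=law,
        ))

    rate_rules, assignment_rules = [], []
    for rule in kids(model_elem, "listOfRules"):
        tag = _strip_ns(rule.tag)
        if tag == "algebraicRule":
            raise UnsupportedFeature("algebraic rules")
        math_elem = next(
            (c for c in rule if _strip_ns(c.tag) == "math"), None
        )
        if math_elem is None:
            raise SBMLParseError(f"<{tag}> has no <math>")
        target = rule.get("variable", "")
        rec = Rule(target_id=target, math=_math_to_ast(math_elem))
        if tag == "rateRule":
            rate_rules.append(rec)
        elif tag == "assignmentRule":
            assignment_rules.append(rec)
        else:
            raise UnsupportedFeature(f"rule <{tag}>")

    model = BaseModel(
        model_id=model_elem.get("id") or model_elem.get("name") or "model",
        compartments=tuple(compartments),
        species=tuple(species),
        global_quantities=tuple(quantities),
        reactions=tuple(reactions),
        rate_rules=tuple(rate_rules),
        assignment_rules=tuple(assignment_rules),
    )
    validate_model(model)
    return model


def load_sbml(path: str | Path) -> BaseModel:
    """Load an SBML L2 or L3V1 file into a :class:`BaseModel`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return parse_sbml_string(path.read_text())


# ---------------------------------------------------------------------------
# base set / value application


def base_set(model: BaseModel) -> BaseSet:
    """One entry per global quantity, non-boundary species initial amount
    and compartment size."""
    values: dict[str, float] = {}
    category: dict[str, str] = {}
    for q in model.global_quantities:
        values[q.id] = q.value
        category[q.id] = GLOBAL_QUANTITY
    for sp in model.species:
        if not sp.boundary:
            values[sp.id] = sp.initial_amount
            category[sp.id] = SPECIES_INITIAL
    for c in model.compartments:
        values[c.id] = c.size
        category[c.id] = COMPARTMENT_SIZE
    return BaseSet(values=values, category=category)


def apply_values(model: BaseModel, resolved: dict[str, float]) -> BaseModel:
    """Return a copy of *model* with the initial values in *resolved*
    substituted; structure (reactions, math) untouched."""
    bs = base_set(model)
    for key in resolved:
        if key not in bs.values:
            raise UnknownKey(f"{key!r} is not an assignable quantity")
    quantities = tuple(
        replace(q, value=float(resolved[q.id])) if q.id in resolved else q
        for q in model.global_quantities
    )
    species = tuple(
        replace(s, initial_amount=float(resolved[s.id]))
        if s.id in resolved else s
        for s in model.species
    )
    compartments = tuple(
        replace(c, size=float(resolved[c.id])) if c.id in resolved else c
        for c in model.compartments
    )
    return replace(
        model,
        global_quantities=quantities,
        species=species,
        compartments=compartments,
    )


# ---------------------------------------------------------------------------
# writing


def _ast_to_mathml(e: ex.MathExpr) -> ET.Element:
    if isinstance(e, ex.Num):
        el = ET.Element("cn")
        v = e.value
        if v == int(v) and abs(v) < 1e16:
            el.set("type", "integer")
            el.text = f" {int(v)} "
        else:
            el.text = f" {v!r} "
        return el
    if isinstance(e, ex.Ref):
        if e.node is not None:
            raise ValueError("node-qualified reference in SBML math")
        el = ET.Element("ci")
        el.text = f" {e.key} "
        return el
    if isinstance(e, ex.Time):
        el = ET.Element("csymbol")
        el.set("encoding", "text")
        el.set("definitionURL", TIME_CSYMBOL)
        el.text = " time "
        return el
    if isinstance(e, ex.Neg):
        app = ET.Element("apply")
        app.append(ET.Element("minus"))
        app.append(_ast_to_mathml(e.operand))
        return app
    if isinstance(e, ex.BinOp):
        op = {"+": "plus", "-": "minus", "*": "times", "/": "divide",
              "^": "power"}[e.op]
        app = ET.Element("apply")
        app.append(ET.Element(op))
        app.append(_ast_to_mathml(e.left))
        app.append(_ast_to_mathml(e.right))
        return app
    if isinstance(e, ex.Call):
        name = {"sqrt": "root"}.get(e.name, e.name)
        app = ET.Element("apply")
        app.append(ET.Element(name))
        for a in e.args:
            app.append(_ast_to_mathml(a))
        return app
    raise TypeError(f"not a MathExpr node: {e!r}")


def _math_element(e: ex.MathExpr) -> ET.Element:
    math = ET.Element("math")
    math.set("xmlns", MATHML_NS)
    math.append(_ast_to_mathml(e))
    return math


def sbml_string(model: BaseModel) -> str:
    """Serialize *model* as SBML Level 3 Version 1."""
    validate_model(model)
    root = ET.Element("sbml")
    root.set("xmlns", L3_NS)
    root.set("level", "3")
    root.set("version", "1")
    m = ET.SubElement(root, "model")
    m.set("id", model.model_id)

    if model.compartments:
        loc = ET.SubElement(m, "listOfCompartments")
        for c in model.compartments:
            el = ET.SubElement(loc, "compartment")
            el.set("id", c.id)
            el.set("size", repr(c.size))
            el.set("constant", "true" if c.constant else "false")
    if model.species:
        los = ET.SubElement(m, "listOfSpecies")
        for s in model.species:
            el = ET.SubElement(los, "species")
            el.set("id", s.id)
            el.set("compartment", s.compartment_id)
            el.set("initialAmount", repr(s.initial_amount))
            el.set("hasOnlySubstanceUnits", "true")
            el.set("boundaryCondition", "true" if s.boundary else "false")
            el.set("constant", "false")
    if model.global_quantities:
        lop = ET.SubElement(m, "listOfParameters")
        for q in model.global_quantities:
            el = ET.SubElement(lop, "parameter")
            el.set("id", q.id)
            el.set("value", repr(q.value))
            el.set("constant", "true" if q.constant else "false")
    if model.rate_rules or model.assignment_rules:
        lor = ET.SubElement(m, "listOfRules")
        for rule in model.assignment_rules:
            el = ET.SubElement(lor, "assignmentRule")
            el.set("variable", rule.target_id)
            el.append(_math_element(rule.math))
        for rule in model.rate_rules:
            el = ET.SubElement(lor, "rateRule")
            el.set("variable", rule.target_id)
            el.append(_math_element(rule.math))
    if model.reactions:
        lorx = ET.SubElement(m, "listOfReactions")
        for rxn in model.reactions:
            el = ET.SubElement(lorx, "reaction")
            el.set("id", rxn.id)
            el.set("reversible", "false")
            if rxn.reactants:
                lst = ET.SubElement(el, "listOfReactants")
                for ref in rxn.reactants:
                    sr = ET.SubElement(lst, "speciesReference")
                    sr.set("species", ref.species_id)
                    sr.set("stoichiometry", repr(ref.stoichiometry))
                    sr.set("constant", "true")
            if rxn.products:
                lst = ET.SubElement(el, "listOfProducts")
                for ref in rxn.products:
                    sr = ET.SubElement(lst, "speciesReference")
                    sr.set("species", ref.species_id)
                    sr.set("stoichiometry", repr(ref.stoichiometry))
                    sr.set("constant", "true")
            if rxn.modifiers:
                lst = ET.SubElement(el, "listOfModifiers")
                for mid in rxn.modifiers:
                    mr = ET.SubElement(lst, "modifierSpeciesReference")
                    mr.set("species", mid)
            kl = ET.SubElement(el, "kineticLaw")
            kl.append(_math_element(rxn.kinetic_law))
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def write_sbml(model: BaseModel, path: str | Path) -> None:
    Path(path).write_text(sbml_string(model))


def copy_model(model: BaseModel) -> BaseModel:
    return copy.deepcopy(model)
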