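"""Test and demo inputs: toy SBML models, the three worked-example
projects, seeded random DAG projects, and an independent brute-force
resolution oracle.

The oracle recomputes resolution directly from its definition — no
memoization and no shared logic with :mod:`paramdag.graph` — so the two
routes can be compared on randomized hierarchies.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from . import expressions as ex
from .graph import BASE, LOCAL, ConfigGraph, Opaque
from .project import Project
from .sbml_model import (
    BaseModel,
    Compartment,
    GlobalQuantity,
    Reaction,
    Species,
    SpeciesRef,
)

DECAY = "DECAY"
CONVERSION = "CONVERSION"
OSCILLATOR = "OSCILLATOR"
RANDOM_DAG = "RANDOM_DAG"


@dataclass(frozen=True)
class FixtureSpec:
    kind: str = RANDOM_DAG
    seed: int = 0
    n_nodes: int = 6
    n_keys: int = 4
    max_parents: int = 3
    p_local: float = 0.4

    def __post_init__(self):
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if not 0 <= self.p_local <= 1:
            raise ValueError("p_local must be in [0, 1]")


# ---------------------------------------------------------------------------
# toy models


def make_model(kind: str) -> BaseModel:
    """DECAY: A -> 0 (law k*A).  CONVERSION: A <-> B mass action.
    OSCILLATOR: 3-species mass-action hypercycle (conserves X+Y+Z)."""
    if kind == DECAY:
        return BaseModel(
            model_id="decay",
            compartments=(Compartment("cell", 1.0),),
            species=(Species("A", "cell", 1.0),),
            global_quantities=(GlobalQuantity("k", 1.0),),
            reactions=(Reaction(
                id="deg",
                reactants=(SpeciesRef("A"),),
                products=(),
                modifiers=(),
                kinetic_law=ex.parse("k*A"),
            ),),
        )
    if kind == CONVERSION:
        return BaseModel(
            model_id="conversion",
            compartments=(Compartment("cell", 1.0),),
            species=(Species("A", "cell", 1.0), Species("B", "cell", 0.0)),
            global_quantities=(
                GlobalQuantity("kf", 1.0), GlobalQuantity("kr", 0.5),
            ),
            reactions=(
                Reaction("fwd", (SpeciesRef("A"),), (SpeciesRef("B"),), (),
                         ex.parse("kf*A")),
                Reaction("rev", (SpeciesRef("B"),), (SpeciesRef("A"),), (),
                         ex.parse("kr*B")),
            ),
        )
    if kind == OSCILLATOR:
        return BaseModel(
            model_id="oscillator",
            compartments=(Compartment("cell", 1.0),),
            species=(
                Species("X", "cell", 2.0),
                Species("Y", "cell", 1.0),
                Species("Z", "cell", 1.0),
            ),
            global_quantities=(
                GlobalQuantity("k1", 1.0),
                GlobalQuantity("k2", 1.0),
                GlobalQuantity("k3", 1.0),
            ),
            reactions=(
                Reaction("r1", (SpeciesRef("X"), SpeciesRef("Y")),
                         (SpeciesRef("Y", 2.0),), (), ex.parse("k1*X*Y")),
                Reaction("r2", (SpeciesRef("Y"), SpeciesRef("Z")),
                         (SpeciesRef("Z", 2.0),), (), ex.parse("k2*Y*Z")),
                Reaction("r3", (SpeciesRef("Z"), SpeciesRef("X")),
                         (SpeciesRef("X", 2.0),), (), ex.parse("k3*Z*X")),
            ),
        )
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# the worked-example projects


def _mdt_model() -> BaseModel:
    model = make_model(DECAY)
    return BaseModel(
        model_id="wt_model",
        compartments=model.compartments,
        species=model.species,
        global_quantities=model.global_quantities
        + (GlobalQuantity("mdt", 80.0),),
        reactions=model.reactions,
    )


def make_mdt_project() -> Project:
    """Two-node hierarchy: WT_glucose (root, all base values) and
    WT_galactose, which overrides mdt 80 -> 150."""
    project = Project.new(_mdt_model())
    g = project.param_graph
    g.create_root("WT_glucose")
    g.create_child("WT_galactose", ["WT_glucose"])
    g.set_local("WT_galactose", "mdt", 150.0)
    return project


def make_fig3_project() -> Project:
    """Time-course graph 'short' (duration 500) / 'long' (duration 1000);
    short applies to WT and WT_galactose, long only to WT_galactose."""
    project = Project.new(_mdt_model())
    g = project.param_graph
    g.create_root("WT")
    g.create_child("WT_galactose", ["WT"])
    g.set_local("WT_galactose", "mdt", 150.0)
    tc = project.tc_graph
    short = tc.create_root("short")
    tc.set_local("short", "duration", 500.0)
    tc.set_local("short", "interval_size", 1.0)
    short.applies_to = ["WT", "WT_galactose"]
    long_ = tc.create_child("long", ["short"])
    tc.set_local("long", "duration", 1000.0)
    long_.applies_to = ["WT_galactose"]
    return project


def make_conflict_project() -> Project:
    """WT1 and WT2 locally assign k1 = 2 and 4; M is a child of both, so
    k1 conflicts at M.  The base model carries k1 = 1."""
    model = BaseModel(
        model_id="conflict_demo",
        compartments=(Compartment("cell", 1.0),),
        species=(Species("A", "cell", 1.0),),
        global_quantities=(GlobalQuantity("k1", 1.0),),
        reactions=(Reaction("deg", (SpeciesRef("A"),), (), (),
                            ex.parse("k1*A")),),
    )
    project = Project.new(model)
    g = project.param_graph
    g.create_root("WT1")
    g.set_local("WT1", "k1", 2.0)
    g.create_root("WT2")
    g.set_local("WT2", "k1", 4.0)
    g.create_child("M", ["WT1", "WT2"])
    return project


def make_paper_examples() -> tuple[Project, Project, Project]:
    """(mdt two-node project, Fig 3 settings project, Fig 4 conflict
    project)."""
    return make_mdt_project(), make_fig3_project(), make_conflict_project()


# ---------------------------------------------------------------------------
# random projects


def _random_model(rng: random.Random, n_keys: int) -> BaseModel:
    quantities = tuple(
        GlobalQuantity(f"q{i}", round(rng.uniform(0.5, 5.0), 6))
        for i in range(n_keys)
    )
    law = ex.parse("q0*S0") if n_keys else ex.parse("S0")
    return BaseModel(
        model_id="random_model",
        compartments=(Compartment("cell", 1.0),),
        species=(Species("S0", "cell", 1.0),),
        global_quantities=quantities,
        reactions=(Reaction("deg", (SpeciesRef("S0"),), (), (), law),),
    )


def _random_expr(rng: random.Random, key: str, keys: list[str],
                 ancestors: list[str]) -> str:
    """An occasional ancestor-reference expression; division only by
    constants so arithmetic errors cannot occur."""
    c = round(rng.uniform(0.5, 3.0), 3)
    if not ancestors:
        return rng.choice([f"{c}", f"{key}@BASE", f"{c}*{key}@BASE"])
    anc = rng.choice(ancestors)
    other = rng.choice(keys)
    anc2 = rng.choice(ancestors)
    return rng.choice([
        f"{key}@{anc}",
        f"{c}*{key}@{anc}",
        f"{key}@{anc} + {c}",
        f"{key}@{anc} / {max(c, 0.5)}",
        f"{c}*{key}",  # bare: scale the inherited value
        f"{key}@{anc} + {other}@{anc2}",
        f"{key}@BASE",
    ])


def make_random_project(spec: FixtureSpec) -> Project:
    """Seed-deterministic random DAG project.

    Topological wiring (node *i* draws parents among nodes ``< i``),
    random numeric locals with probability ``p_local`` (a third of them
    expressions over ancestors / BASE), and — on roughly a third of seeds
    — one forced node deletion to exercise dangling references.
    """
    rng = random.Random(spec.seed)
    model = _random_model(rng, spec.n_keys)
    project = Project.new(model)
    g = project.param_graph
    keys = [q.id for q in model.global_quantities] or ["S0"]

    names = [f"N{i}" for i in range(spec.n_nodes)]
    for i, name in enumerate(names):
        if i == 0 or rng.random() < 0.25:
            g.create_root(name)
        else:
            k = rng.randint(1, min(spec.max_parents, i))
            parents = rng.sample(names[:i], k)
            g.create_child(name, parents)
        ancestors = sorted(g.ancestors(name))
        for key in keys:
            if rng.random() < spec.p_local:
                if rng.random() < 0.33:
                    g.set_local(name, key,
                                _random_expr(rng, key, keys, ancestors))
                else:
                    g.set_local(name, key, round(rng.uniform(0.5, 8.0), 4))

    if spec.n_nodes > 2 and rng.random() < 0.33:
        victim = rng.choice(names[: spec.n_nodes - 1])
        g.delete_node(victim, force=True)
    return project


# ---------------------------------------------------------------------------
# the brute-force oracle


class _Sentinel:
    def __init__(self, label: str):
        self.label = label

    def __repr__(self):
        return self.label


CONFLICT = _Sentinel("CONFLICT")
DANGLING = _Sentinel("DANGLING")

_ORACLE_ABS = 1e-15
_ORACLE_REL = 1e-12


def _o_distinct(a: float, b: float) -> bool:
    return abs(a - b) > max(_ORACLE_ABS, _ORACLE_REL * max(abs(a), abs(b)))


def _o_refs(e) -> list[tuple[str, str | None]]:
    if isinstance(e, ex.Ref):
        return [(e.key, e.node)]
    if isinstance(e, ex.Neg):
        return _o_refs(e.operand)
    if isinstance(e, ex.BinOp):
        return _o_refs(e.left) + _o_refs(e.right)
    return []


def _o_arith(e, env):
    if isinstance(e, ex.Num):
        return e.value
    if isinstance(e, ex.Ref):
        return env[(e.key, e.node)]
    if isinstance(e, ex.Neg):
        return -_o_arith(e.operand, env)
    if isinstance(e, ex.BinOp):
        a, b = _o_arith(e.left, env), _o_arith(e.right, env)
        return {"+": lambda: a + b, "-": lambda: a - b,
                "*": lambda: a * b, "/": lambda: a / b,
                "^": lambda: a**b}[e.op]()
    raise TypeError(f"oracle cannot evaluate {e!r}")


def oracle_resolve_graph(graph: ConfigGraph, base, name: str, key: str):
    """Definitional, cache-free resolution; returns a float or one of the
    :data:`CONFLICT` / :data:`DANGLING` sentinels."""

    def value_of(n: str, k: str):
        node = graph.nodes[n]
        lv = node.locals.get(k)
        if lv is None:
            inh = inherit(n, k)
            return inh if isinstance(inh, _Sentinel) else inh[0]
        if isinstance(lv, Opaque):
            return lv.value
        env = {}
        for rk, rn in _o_refs(lv):
            if (rk, rn) in env:
                continue
            if rn == ex.BASE_NODE:
                env[(rk, rn)] = base[rk]
            elif rn is None:
                inh = inherit(n, rk)
                if isinstance(inh, _Sentinel):
                    return inh
                env[(rk, rn)] = inh[0]
            else:
                if rn not in graph.nodes:
                    return DANGLING
                sub = value_of(rn, rk)
                if isinstance(sub, _Sentinel):
                    return sub
                env[(rk, rn)] = sub
        return _o_arith(lv, env)

    def inherit(n: str, k: str):
        """(value, origin-or-None) by definition, or a sentinel."""
        node = graph.nodes[n]
        if not node.parents:
            return (base[k], None)
        deliveries = []
        for p in node.parents:
            pv = value_of(p, k)
            if isinstance(pv, _Sentinel):
                return pv
            deliveries.append((p, pv, origin(p, k)))
        changes = [(p, v, o) for p, v, o in deliveries if o is not None]
        if not changes:
            return (base[k], None)
        for i in range(len(changes)):
            for j in range(i + 1, len(changes)):
                if _o_distinct(changes[i][1], changes[j][1]):
                    return CONFLICT
        chosen = min(changes, key=lambda t: t[2])
        return (chosen[1], chosen[2])

    def origin(n: str, k: str):
        """Name of the ancestor-or-self holding the governing local
        assignment delivered by node *n*, or None for the base set."""
        if k in graph.nodes[n].locals:
            return n
        inh = inherit(n, k)
        if isinstance(inh, _Sentinel):
            return inh  # unreachable in callers that pre-check value_of
        return inh[1]

    if name not in graph.nodes:
        raise KeyError(name)
    return value_of(name, key)


def oracle_resolve(project: Project, name: str, key: str):
    return oracle_resolve_graph(
        project.param_graph, project.base_values(), name, key
    )


__all__ = [
    "FixtureSpec", "DECAY", "CONVERSION", "OSCILLATOR", "RANDOM_DAG",
    "make_model", "make_mdt_project", "make_fig3_project",
    "make_conflict_project", "make_paper_examples", "make_random_project",
    "oracle_resolve", "oracle_resolve_graph", "CONFLICT", "DANGLING",
    "BASE", "LOCAL",
]
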