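"""Reaction-network-to-ODE construction and deterministic time courses.

dx/dt = S·v(x, p, t) for non-boundary species, with rate rules appended as
extra state equations (a rate-rule target — species or global quantity —
is governed solely by its rule).  Assignment rules are applied before each
rate evaluation.  Integration uses scipy's stiff-capable adaptive LSODA,
sampled on the uniform output grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from scipy.integrate import solve_ivp

from . import expressions as ex
from .errors import (
    BlockedByConflict,
    BlockedByInconsistency,
    ConflictError,
    DanglingReference,
    IntegrationFailure,
)
from .graph import CONFLICTED, INCONSISTENT
from .sbml_model import BaseModel, apply_values
from .settings import DEFAULT_TIMECOURSE, TimeCourseSpec, applicable_settings

if TYPE_CHECKING:  # pragma: no cover
    from .project import Project


def _compile(expr: ex.MathExpr):
    """Compile an AST into ``f(env, t) -> float`` closures (tiny models;
    a plain recursive walk per call would do, this just hoists dispatch)."""
    if isinstance(expr, ex.Num):
        v = expr.value
        return lambda env, t: v
    if isinstance(expr, ex.Ref):
        key = expr.key
        return lambda env, t: env[key]
    if isinstance(expr, ex.Time):
        return lambda env, t: t
    if isinstance(expr, ex.Neg):
        f = _compile(expr.operand)
        return lambda env, t: -f(env, t)
    if isinstance(expr, ex.BinOp):
        fl, fr = _compile(expr.left), _compile(expr.right)
        op = expr.op
        if op == "+":
            return lambda env, t: fl(env, t) + fr(env, t)
        if op == "-":
            return lambda env, t: fl(env, t) - fr(env, t)
        if op == "*":
            return lambda env, t: fl(env, t) * fr(env, t)
        if op == "/":
            return lambda env, t: fl(env, t) / fr(env, t)
        return lambda env, t: fl(env, t) ** fr(env, t)
    if isinstance(expr, ex.Call):
        fns = {"exp": math.exp, "ln": math.log, "log": math.log10,
               "abs": abs, "sqrt": math.sqrt,
               "floor": math.floor, "ceil": math.ceil}
        fn = fns[expr.name]
        fargs = [_compile(a) for a in expr.args]
        return lambda env, t: fn(*(f(env, t) for f in fargs))
    raise TypeError(f"cannot compile {expr!r}")


@dataclass
class ODESystem:
    model: BaseModel
    state_ids: list[str]          # non-boundary species, then rule quantities
    species_state_ids: list[str]  # the species slice of state_ids
    stoichiometry: np.ndarray     # len(species_state_ids) x n_reactions
    _rates: list = field(repr=False, default_factory=list)
    _rules: dict = field(repr=False, default_factory=dict)   # id -> closure
    _assign: list = field(repr=False, default_factory=list)  # (id, closure)
    _constants: dict = field(repr=False, default_factory=dict)

    def initial_state(self) -> np.ndarray:
        by_id = {sp.id: sp.initial_amount for sp in self.model.species}
        by_id.update({q.id: q.value for q in self.model.global_quantities})
        return np.array([by_id[i] for i in self.state_ids], dtype=float)

    def _env(self, y: np.ndarray, t: float) -> dict[str, float]:
        env = dict(self._constants)
        env.update(zip(self.state_ids, y))
        for target, fn in self._assign:
            env[target] = fn(env, t)
        return env

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        env = self._env(y, t)
        v = np.array([f(env, t) for f in self._rates], dtype=float)
        dy = np.zeros(len(self.state_ids))
        ns = len(self.species_state_ids)
        if self._rates:
            dy[:ns] = self.stoichiometry @ v
        for i, sid in enumerate(self.state_ids):
            if sid in self._rules:
                dy[i] = self._rules[sid](env, t)
        return dy


def build_ode(model: BaseModel) -> ODESystem:
    rule_targets = {r.target_id for r in model.rate_rules}
    species_states = [sp.id for sp in model.species if not sp.boundary]
    quantity_states = [
        q.id for q in model.global_quantities if q.id in rule_targets
    ]
    state_ids = species_states + quantity_states
    n_s, n_r = len(species_states), len(model.reactions)
    stoich = np.zeros((n_s, n_r))
    idx = {sid: i for i, sid in enumerate(species_states)}
    for j, rxn in enumerate(model.reactions):
        for ref in rxn.reactants:
            if ref.species_id in idx:
                stoich[idx[ref.species_id], j] -= ref.stoichiometry
        for ref in rxn.products:
            if ref.species_id in idx:
                stoich[idx[ref.species_id], j] += ref.stoichiometry

    constants: dict[str, float] = {}
    for c in model.compartments:
        constants[c.id] = c.size
    for sp in model.species:
        if sp.boundary and sp.id not in rule_targets:
            constants[sp.id] = sp.initial_amount
    for q in model.global_quantities:
        if q.id not in rule_targets:
            constants[q.id] = q.value

    sys = ODESystem(
        model=model,
        state_ids=state_ids,
        species_state_ids=species_states,
        stoichiometry=stoich,
        _rates=[_compile(r.kinetic_law) for r in model.reactions],
        _rules={r.target_id: _compile(r.math) for r in model.rate_rules},
        _assign=[(r.target_id, _compile(r.math))
                 for r in model.assignment_rules],
        _constants=constants,
    )
    return sys


@dataclass
class TimeSeries:
    times: np.ndarray
    values: np.ndarray  # len(times) x len(labels)
    labels: list[str]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("time," + ",".join(self.labels) + "\n")
            for t, row in zip(self.times, self.values):
                cells = [f"{t:.10g}"] + [f"{v:.10g}" for v in row]
                fh.write(",".join(cells) + "\n")


def output_grid(spec: TimeCourseSpec) -> np.ndarray:
    n = int(math.floor(
        (spec.duration - spec.output_start) / spec.interval_size + 1e-9
    ))
    return spec.output_start + np.arange(n + 1) * spec.interval_size


def run_timecourse(sys: ODESystem,
                   spec: TimeCourseSpec = DEFAULT_TIMECOURSE) -> TimeSeries:
    """Integrate and sample on the uniform grid; all species and global
    quantities are emitted as columns (constants as constant columns)."""
    times = output_grid(spec)
    y0 = sys.initial_state()
    t_end = float(max(times[-1], spec.duration))
    try:
        sol = solve_ivp(
            sys.rhs, (0.0, t_end), y0, method="LSODA", t_eval=times,
            rtol=spec.rel_tol, atol=spec.abs_tol,
        )
    except (ArithmeticError, ValueError) as exc:
        raise IntegrationFailure(str(exc)) from exc
    if not sol.success:
        raise IntegrationFailure(sol.message)
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationFailure("non-finite state encountered")

    labels = ([sp.id for sp in sys.model.species]
              + [q.id for q in sys.model.global_quantities])
    values = np.empty((len(times), len(labels)))
    state_index = {sid: i for i, sid in enumerate(sys.state_ids)}
    init = {sp.id: sp.initial_amount for sp in sys.model.species}
    init.update({q.id: q.value for q in sys.model.global_quantities})
    for j, label in enumerate(labels):
        if label in state_index:
            values[:, j] = sol.y[state_index[label]]
        else:
            values[:, j] = init[label]
    return TimeSeries(times=times, values=values, labels=labels)


@dataclass
class EnsembleResult:
    """Per-(parameter node, time-course node) outcomes of a batch run."""

    runs: dict[tuple[str, str], TimeSeries] = field(default_factory=dict)
    failures: dict[tuple[str, str], str] = field(default_factory=dict)

    def keys(self):
        return set(self.runs) | set(self.failures)


def run_ensemble(project: "Project",
                 selection: list[str]) -> EnsembleResult:
    """Run every (selected node x applicable time-course spec) pair.

    Selected nodes must have status OK; integration failures are recorded
    per pair without aborting the batch.
    """
    pg = project.param_graph
    base = project.base_values()
    for name in selection:
        st = pg.status(base, name)
        if st == CONFLICTED:
            raise BlockedByConflict(name)
        if st == INCONSISTENT:
            raise BlockedByInconsistency(name)

    result = EnsembleResult()
    for name in selection:
        try:
            resolved = pg.resolve_all(base, name)
        except ConflictError:
            raise BlockedByConflict(name)
        except DanglingReference:
            raise BlockedByInconsistency(name)
        flat = apply_values(
            project.model, {k: rv.value for k, rv in resolved.items()}
        )
        sys = build_ode(flat)
        for tc_name in applicable_settings(project.tc_graph, pg, name):
            try:
                spec = project.timecourse_for(tc_name)
            except ConflictError:
                raise BlockedByConflict(tc_name)
            except DanglingReference:
                raise BlockedByInconsistency(tc_name)
            try:
                result.runs[(name, tc_name)] = run_timecourse(sys, spec)
            except IntegrationFailure as exc:
                result.failures[(name, tc_name)] = str(exc)
    return result
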