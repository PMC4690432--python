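"""The inheritance engine: a DAG of named configurations over a key space.

Each :class:`ConfigNode` carries an ordered parent list and a map of local
assignments.  Resolving ``(node, key)`` yields a value plus provenance:

* ``LOCAL`` — the node assigns the key itself (number or expression);
* ``INHERITED`` — exactly one effective change is delivered through the
  parents; the recorded ``origin`` is the ancestor holding the governing
  local assignment;
* ``BASE`` — nothing in the ancestry redefines the key.

A *conflict* is a ``(node, key)`` where two or more parents deliver
*distinct effective values* (numeric tolerance below) and the node has no
local assignment.  Parents that deliver the untouched base value carry no
change and never conflict.  Conflicts are never silently tie-broken:
resolution raises :class:`~paramdag.errors.ConflictError`.

Values are floats driven by the expression language, or — for settings
graphs — opaque values (:class:`Opaque`) that inherit wholesale and are
compared by equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import expressions as ex
from .errors import (
    ConflictError,
    CycleError,
    DanglingReference,
    DuplicateName,
    NoLocalAssignment,
    NonAncestorReference,
    NoSuchConflict,
    ReferenceCycleError,
    UnknownKey,
    UnknownNode,
    UnknownParent,
)

OK = "OK"
CONFLICTED = "CONFLICTED"
INCONSISTENT = "INCONSISTENT"

BASE = "BASE"
LOCAL = "LOCAL"
INHERITED = "INHERITED"

#: |v_i - v_j| > max(ABS_TOL, REL_TOL * max(|v_i|, |v_j|))  =>  distinct
CONFLICT_ABS_TOL = 1e-15
CONFLICT_REL_TOL = 1e-12


@dataclass(frozen=True)
class Opaque:
    """A non-numeric local value (enum/string/list); inherits wholesale."""

    value: object


@dataclass
class ConfigNode:
    name: str
    parents: list[str] = field(default_factory=list)
    locals: dict[str, object] = field(default_factory=dict)  # MathExpr|Opaque
    color: str | None = None
    applies_to: list[str] | None = None  # settings graphs only


@dataclass(frozen=True)
class ResolvedValue:
    value: object
    provenance: str  # BASE | LOCAL | INHERITED
    origin: str | None = None  # ancestor name when provenance == INHERITED

    def describe(self) -> str:
        if self.provenance == LOCAL:
            return "Local change"
        if self.provenance == INHERITED:
            return f"@{self.origin}"
        return "Base set"


@dataclass(frozen=True)
class Conflict:
    node: str
    key: str
    candidates: dict[str, object]  # parent name -> effective value delivered

    def __post_init__(self):
        assert len(self.candidates) >= 2


@dataclass(frozen=True)
class ImpactReport:
    deleted: str
    affected_descendants: list[str]
    newly_inconsistent: list[tuple[str, str]]  # (node, key)


def _values_distinct(a: object, b: object) -> bool:
    if isinstance(a, (int, float)) and isinstance(b, (int, float)):
        return abs(a - b) > max(
            CONFLICT_ABS_TOL, CONFLICT_REL_TOL * max(abs(a), abs(b))
        )
    return a != b


class ConfigGraph:
    """A DAG of configurations with memoized, provenance-tracked resolution.

    *key_space* restricts the assignable keys (``None`` = unrestricted);
    *opaque_keys* names keys whose locals must be :class:`Opaque` values.
    """

    def __init__(self, key_space: Iterable[str] | None = None,
                 opaque_keys: Iterable[str] = ()):
        self.key_space: set[str] | None = (
            set(key_space) if key_space is not None else None
        )
        self.opaque_keys = set(opaque_keys)
        self.nodes: dict[str, ConfigNode] = {}
        self._cache: dict[tuple[str, str], tuple[str, object]] = {}
        self._active: set[tuple[str, str]] = set()

    # -- structure ---------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, name: str) -> ConfigNode:
        try:
            return self.nodes[name]
        except KeyError:
            raise UnknownNode(f"no node named {name!r}") from None

    def ancestors(self, name: str) -> set[str]:
        """Strict ancestors of *name*."""
        self.node(name)
        seen: set[str] = set()
        stack = list(self.nodes[name].parents)
        while stack:
            cur = stack.pop()
            if cur in seen or cur not in self.nodes:
                continue
            seen.add(cur)
            stack.extend(self.nodes[cur].parents)
        return seen

    def descendants(self, name: str) -> set[str]:
        """Strict descendants of *name*."""
        self.node(name)
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for n, rec in self.nodes.items():
            for p in rec.parents:
                if p in children:
                    children[p].append(n)
        seen: set[str] = set()
        stack = children[name][:]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(children[cur])
        return seen

    def roots(self) -> list[str]:
        return [n for n, rec in self.nodes.items() if not rec.parents]

    def _check_name(self, name: str) -> None:
        if name in self.nodes:
            raise DuplicateName(f"node name {name!r} already in use")
        if not ex.IDENT_RE.match(name):
            raise DuplicateName(f"invalid node name {name!r}")
        if name == ex.BASE_NODE:
            raise DuplicateName(f"{name!r} is a reserved node name")

    def create_root(self, name: str) -> ConfigNode:
        self._check_name(name)
        node = ConfigNode(name=name)
        self.nodes[name] = node
        self._cache.clear()  # a re-created name can cure dangling references
        return node

    def create_child(self, name: str, parents: list[str]) -> ConfigNode:
        self._check_name(name)
        for p in parents:
            if p not in self.nodes:
                raise UnknownParent(f"no node named {p!r}")
        if len(set(parents)) != len(parents):
            raise UnknownParent("duplicate parent names")
        node = ConfigNode(name=name, parents=list(parents))
        self.nodes[name] = node
        self._cache.clear()
        return node

    def set_parents(self, name: str, parents: list[str]) -> None:
        """Rewire *name*'s parent list, preserving acyclicity."""
        node = self.node(name)
        for p in parents:
            if p not in self.nodes:
                raise UnknownParent(f"no node named {p!r}")
            if p == name or name in self.ancestors(p):
                raise CycleError(
                    f"making {p!r} a parent of {name!r} would create a cycle"
                )
        node.parents = list(parents)
        self._cache.clear()

    # -- local assignments -------------------------------------------------

    def _coerce_local(self, key: str, value) -> object:
        if key in self.opaque_keys:
            if not isinstance(value, Opaque):
                value = Opaque(value)
            return value
        if isinstance(value, Opaque):
            raise UnknownKey(f"key {key!r} does not take opaque values")
        if isinstance(value, (int, float)):
            v = float(value)
            return ex.Neg(ex.Num(-v)) if v < 0 else ex.Num(v)
        if isinstance(value, str):
            return ex.parse(value)
        return value  # assume MathExpr

    def set_local(self, name: str, key: str, value) -> None:
        node = self.node(name)
        if self.key_space is not None and key not in self.key_space:
            raise UnknownKey(f"{key!r} is not in the key space")
        expr = self._coerce_local(key, value)
        if not isinstance(expr, Opaque):
            anc = self.ancestors(name)
            for rkey, rnode in ex.references(expr):
                if self.key_space is not None and rkey not in self.key_space:
                    raise UnknownKey(
                        f"expression references unknown key {rkey!r}"
                    )
                if rnode is None or rnode == ex.BASE_NODE:
                    continue
                if rnode not in anc:
                    raise NonAncestorReference(
                        f"{rkey}@{rnode}: {rnode!r} is not an ancestor of "
                        f"{name!r}"
                    )
        node.locals[key] = expr
        self._invalidate(name)

    def clear_local(self, name: str, key: str) -> None:
        node = self.node(name)
        if key not in node.locals:
            raise NoLocalAssignment(
                f"node {name!r} has no local assignment for {key!r}"
            )
        del node.locals[key]
        self._invalidate(name)

    # -- cache -------------------------------------------------------------

    def _invalidate(self, name: str) -> None:
        cone = self.descendants(name) | {name}
        for k in [k for k in self._cache if k[0] in cone]:
            del self._cache[k]

    # -- resolution --------------------------------------------------------

    def resolve(self, base: Mapping[str, object], name: str,
                key: str) -> ResolvedValue:
        """Resolve *key* at node *name* against the *base* mapping."""
        self.node(name)
        if self.key_space is not None and key not in self.key_space:
            raise UnknownKey(f"{key!r} is not in the key space")
        ck = (name, key)
        hit = self._cache.get(ck)
        if hit is not None:
            status, payload = hit
            if status == "ok":
                return payload
            raise payload
        if ck in self._active:
            raise ReferenceCycleError(
                f"reference cycle while resolving {key!r} at {name!r}"
            )
        self._active.add(ck)
        try:
            rv = self._resolve(base, name, key)
        except (ConflictError, DanglingReference, UnknownKey,
                ReferenceCycleError) as exc:
            self._cache[ck] = ("err", exc)
            raise
        finally:
            self._active.discard(ck)
        self._cache[ck] = ("ok", rv)
        return rv

    def _base_value(self, base: Mapping[str, object], key: str) -> object:
        try:
            return base[key]
        except KeyError:
            raise UnknownKey(
                f"{key!r} is not in the base set"
            ) from None

    def _resolve(self, base, name, key) -> ResolvedValue:
        node = self.nodes[name]
        lv = node.locals.get(key)
        if lv is None:
            return self._inherited(base, name, key)
        if isinstance(lv, Opaque):
            return ResolvedValue(lv.value, LOCAL)
        env: dict[tuple[str, str | None], float] = {}
        for rkey, rnode in ex.iter_references(lv):
            pair = (rkey, rnode)
            if pair in env:
                continue
            if rnode == ex.BASE_NODE:
                env[pair] = self._base_value(base, rkey)
            elif rnode is None:
                env[pair] = self._inherited(base, name, rkey).value
            else:
                if rnode not in self.nodes:
                    raise DanglingReference(rnode)
                env[pair] = self.resolve(base, rnode, rkey).value
        return ResolvedValue(ex.evaluate(lv, env), LOCAL)

    def _inherited(self, base, name, key) -> ResolvedValue:
        """The value *name* would inherit for *key*, ignoring its locals."""
        node = self.nodes[name]
        if not node.parents:
            return ResolvedValue(self._base_value(base, key), BASE)
        deliveries = [
            (p, self.resolve(base, p, key)) for p in node.parents
        ]
        changes = [(p, rv) for p, rv in deliveries if rv.provenance != BASE]
        if not changes:
            return ResolvedValue(self._base_value(base, key), BASE)
        for i in range(len(changes)):
            for j in range(i + 1, len(changes)):
                if _values_distinct(changes[i][1].value, changes[j][1].value):
                    raise ConflictError(Conflict(
                        node=name,
                        key=key,
                        candidates={p: rv.value for p, rv in changes},
                    ))

        def origin_of(p: str, rv: ResolvedValue) -> str:
            return p if rv.provenance == LOCAL else rv.origin

        chosen = min(changes, key=lambda pr: origin_of(*pr))
        return ResolvedValue(
            chosen[1].value, INHERITED, origin_of(*chosen)
        )

    def resolve_all(self, base: Mapping[str, object],
                    name: str) -> dict[str, ResolvedValue]:
        """Pointwise :meth:`resolve` over the full key space.

        Raises :class:`ConflictError` naming every conflicted key if the
        node is CONFLICTED, and propagates dangling-reference errors.
        """
        keys = self._all_keys(base)
        conflicts = self.detect_conflicts(base, name)
        if conflicts:
            exc = ConflictError(conflicts[0])
            exc.conflicts = conflicts  # every conflicted key, not just one
            exc.args = (
                f"node {name!r} conflicted on keys "
                f"{sorted(c.key for c in conflicts)}",
            )
            raise exc
        return {key: self.resolve(base, name, key) for key in keys}

    def _all_keys(self, base: Mapping[str, object]) -> list[str]:
        if self.key_space is not None:
            return sorted(self.key_space)
        return sorted(base.keys())

    # -- conflicts / status ------------------------------------------------

    def detect_conflicts(self, base: Mapping[str, object],
                         name: str) -> list[Conflict]:
        node = self.node(name)
        out: list[Conflict] = []
        for key in self._all_keys(base):
            if key in node.locals:
                continue
            try:
                self.resolve(base, name, key)
            except ConflictError as exc:
                if exc.conflict.node == name:
                    out.append(exc.conflict)
            except (DanglingReference, UnknownKey, ReferenceCycleError):
                pass  # reported through status/resolve, not as a conflict
        return out

    def inconsistencies(self, base: Mapping[str, object],
                        name: str) -> list[tuple[str, str]]:
        """(key, missing thing) pairs for locals that no longer resolve."""
        node = self.node(name)
        out = []
        for key, lv in node.locals.items():
            if key not in base:
                out.append((key, f"key {key!r} removed from base set"))
                continue
            if isinstance(lv, Opaque):
                continue
            for rkey, rnode in ex.references(lv):
                if rnode not in (None, ex.BASE_NODE) \
                        and rnode not in self.nodes:
                    out.append((key, f"references deleted node {rnode!r}"))
        return out

    def status(self, base: Mapping[str, object], name: str) -> str:
        if self.inconsistencies(base, name):
            return INCONSISTENT
        if self.detect_conflicts(base, name):
            return CONFLICTED
        return OK

    def resolve_conflict(self, base: Mapping[str, object], name: str,
                         key: str, *, from_parent: str | None = None,
                         from_base: bool = False,
                         expression=None) -> None:
        """Clear the conflict at ``(name, key)`` via a local assignment.

        Exactly one of *from_parent* / *from_base* / *expression* must be
        given (the paper's options a/b/c).
        """
        conflicts = {c.key: c for c in self.detect_conflicts(base, name)}
        if key not in conflicts:
            raise NoSuchConflict(f"no conflict at ({name!r}, {key!r})")
        given = [from_parent is not None, from_base, expression is not None]
        if sum(given) != 1:
            raise ValueError(
                "give exactly one of from_parent, from_base, expression"
            )
        if from_parent is not None:
            if from_parent not in self.nodes[name].parents:
                raise UnknownParent(
                    f"{from_parent!r} is not a parent of {name!r}"
                )
            self.set_local(name, key, ex.Ref(key, from_parent))
        elif from_base:
            self.set_local(name, key, ex.Ref(key, ex.BASE_NODE))
        else:
            self.set_local(name, key, expression)

    # -- deletion ----------------------------------------------------------

    def delete_node(self, name: str, force: bool = False) -> ImpactReport:
        self.node(name)
        affected = sorted(self.descendants(name))
        newly_inconsistent = []
        for d in affected:
            for key, lv in self.nodes[d].locals.items():
                if isinstance(lv, Opaque):
                    continue
                if any(rn == name for _, rn in ex.references(lv)):
                    newly_inconsistent.append((d, key))
        report = ImpactReport(
            deleted=name,
            affected_descendants=affected,
            newly_inconsistent=sorted(newly_inconsistent),
        )
        if force:
            del self.nodes[name]
            for rec in self.nodes.values():
                if name in rec.parents:
                    rec.parents = [p for p in rec.parents if p != name]
            self._cache.clear()
        return report
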