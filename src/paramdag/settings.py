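"""Time-course and plot settings as inheritance graphs.

Both settings kinds reuse :class:`~paramdag.graph.ConfigGraph` verbatim:
numeric fields (duration, interval size, tolerances) admit the expression
language including ancestor references; enum/structured fields (method,
plot series) inherit as opaque values.

Every settings node carries an ``applies_to`` list of parameter-node
names; an empty list means the node applies to all parameter sets.  With
no settings nodes defined at all, every parameter node maps to the single
built-in default spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .errors import UnknownNode
from .graph import ConfigGraph, Opaque

if TYPE_CHECKING:  # pragma: no cover
    from .sbml_model import BaseModel

DETERMINISTIC_STIFF = "DETERMINISTIC_STIFF"
TIME = "TIME"

#: name used for the implicit spec when a settings graph is empty
DEFAULT_NODE = "default"

TIMECOURSE_NUMERIC_KEYS = (
    "duration", "interval_size", "output_start", "rel_tol", "abs_tol",
)
TIMECOURSE_OPAQUE_KEYS = ("method",)

PLOT_OPAQUE_KEYS = ("x", "series", "title", "x_label", "y_label")


@dataclass(frozen=True)
class TimeCourseSpec:
    duration: float = 100.0
    interval_size: float = 1.0
    output_start: float = 0.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12
    method: str = DETERMINISTIC_STIFF
    applies_to: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not 0 < self.interval_size <= self.duration:
            raise ValueError("interval_size must be in (0, duration]")
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ValueError("tolerances must be > 0")
        if self.method != DETERMINISTIC_STIFF:
            raise ValueError(f"unsupported method {self.method!r}")


@dataclass(frozen=True)
class PlotSeries:
    id: str
    color: str = "C0"
    width: float = 1.5
    symbol: str = "none"
    stride: int = 1

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be a positive integer")


@dataclass(frozen=True)
class PlotSpec:
    x: str = TIME  # TIME or a variable id (phase plane)
    y: tuple[PlotSeries, ...] = ()
    title: str = ""
    x_label: str = "time"
    y_label: str = "value"
    applies_to: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.y:
            raise ValueError("a plot needs at least one y series")


DEFAULT_TIMECOURSE = TimeCourseSpec()


def timecourse_base() -> dict[str, object]:
    """Base-set mapping for the time-course settings graph (the paper's
    'basic default configuration')."""
    d = DEFAULT_TIMECOURSE
    return {
        "duration": d.duration,
        "interval_size": d.interval_size,
        "output_start": d.output_start,
        "rel_tol": d.rel_tol,
        "abs_tol": d.abs_tol,
        "method": d.method,
    }


def make_timecourse_graph() -> ConfigGraph:
    return ConfigGraph(
        key_space=TIMECOURSE_NUMERIC_KEYS + TIMECOURSE_OPAQUE_KEYS,
        opaque_keys=TIMECOURSE_OPAQUE_KEYS,
    )


def make_settings_graph(key_space, opaque_keys=()) -> ConfigGraph:
    """Generic constructor mirroring the parameter-graph semantics."""
    return ConfigGraph(key_space=key_space, opaque_keys=opaque_keys)


def plot_base(model: "BaseModel") -> dict[str, object]:
    """Default plot settings: every non-boundary species against time."""
    series = [
        {"id": sp.id, "color": f"C{i % 10}", "width": 1.5,
         "symbol": "none", "stride": 1}
        for i, sp in enumerate(model.species) if not sp.boundary
    ]
    return {
        "x": TIME,
        "series": series,
        "title": model.model_id,
        "x_label": "time",
        "y_label": "value",
    }


def make_plot_graph() -> ConfigGraph:
    return ConfigGraph(key_space=PLOT_OPAQUE_KEYS,
                       opaque_keys=PLOT_OPAQUE_KEYS)


def timecourse_spec(graph: ConfigGraph, base: dict, name: str) -> TimeCourseSpec:
    """Materialize the fully resolved TimeCourseSpec of settings node *name*."""
    resolved = graph.resolve_all(base, name)
    node = graph.node(name)
    return TimeCourseSpec(
        duration=float(resolved["duration"].value),
        interval_size=float(resolved["interval_size"].value),
        output_start=float(resolved["output_start"].value),
        rel_tol=float(resolved["rel_tol"].value),
        abs_tol=float(resolved["abs_tol"].value),
        method=str(resolved["method"].value),
        applies_to=tuple(node.applies_to or ()),
    )


def plot_spec(graph: ConfigGraph, base: dict, name: str) -> PlotSpec:
    resolved = graph.resolve_all(base, name)
    node = graph.node(name)
    series = tuple(
        PlotSeries(
            id=s["id"], color=s.get("color", "C0"),
            width=float(s.get("width", 1.5)),
            symbol=s.get("symbol", "none"), stride=int(s.get("stride", 1)),
        )
        for s in resolved["series"].value
    )
    return PlotSpec(
        x=str(resolved["x"].value),
        y=series,
        title=str(resolved["title"].value),
        x_label=str(resolved["x_label"].value),
        y_label=str(resolved["y_label"].value),
        applies_to=tuple(node.applies_to or ()),
    )


def applicable_settings(settings_graph: ConfigGraph,
                        param_graph: ConfigGraph,
                        param_node: str) -> list[str]:
    """Settings nodes applying to *param_node*, in insertion order.

    A node with an empty/unset ``applies_to`` applies to every parameter
    node.  An empty settings graph yields ``[DEFAULT_NODE]``.
    """
    if param_node not in param_graph.nodes:
        raise UnknownNode(f"no parameter node named {param_node!r}")
    if not settings_graph.nodes:
        return [DEFAULT_NODE]
    return [
        name for name, rec in settings_graph.nodes.items()
        if not rec.applies_to or param_node in rec.applies_to
    ]


def dangling_applies_to(settings_graph: ConfigGraph,
                        param_graph: ConfigGraph) -> list[tuple[str, str]]:
    """(settings node, missing parameter node) pairs."""
    out = []
    for name, rec in settings_graph.nodes.items():
        for target in rec.applies_to or ():
            if target not in param_graph.nodes:
                out.append((name, target))
    return out
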