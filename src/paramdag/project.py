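"""Whole-project persistence and export.

A project bundles the embedded base SBML model with three inheritance
graphs (parameter values, time-course settings, plot settings) in a JSON
file (format_version "1.0")::

    {
      "format_version": "1.0",
      "model_sbml": "<sbml ...>...",
      "parameter_graph":  {"nodes": [{"name", "parents", "locals", ...}]},
      "timecourse_graph": {"nodes": [...]},
      "plot_graph":       {"nodes": [...]}
    }

Locals are stored as canonical expression strings for numeric keys and as
raw JSON values for opaque keys; nodes are stored in insertion order so a
load replays the original construction.  Conflicted or inconsistent graphs
round-trip unchanged — they block simulation and export, not saving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import expressions as ex
from . import settings as st
from .errors import (
    BlockedByConflict,
    BlockedByInconsistency,
    ConflictError,
    DanglingReference,
    FormatVersionError,
    SchemaError,
    UnknownKey,
)
from .graph import CONFLICTED, INCONSISTENT, ConfigGraph, Conflict, Opaque
from .sbml_model import (
    BaseModel,
    apply_values,
    base_set,
    load_sbml,
    parse_sbml_string,
    sbml_string,
    write_sbml,
)
from .simulator import EnsembleResult

FORMAT_VERSION = "1.0"

PARAMS = "params"
TIMECOURSE = "timecourse"
PLOT = "plot"


@dataclass
class Project:
    model: BaseModel
    model_sbml: str
    param_graph: ConfigGraph
    tc_graph: ConfigGraph
    plot_graph: ConfigGraph
    format_version: str = FORMAT_VERSION

    # -- construction ------------------------------------------------------

    @classmethod
    def new(cls, model: BaseModel, model_sbml: str | None = None) -> "Project":
        bs = base_set(model)
        return cls(
            model=model,
            model_sbml=model_sbml or sbml_string(model),
            param_graph=ConfigGraph(key_space=bs.values.keys()),
            tc_graph=st.make_timecourse_graph(),
            plot_graph=st.make_plot_graph(),
        )

    @classmethod
    def from_sbml(cls, path: str | Path) -> "Project":
        model = load_sbml(path)
        return cls.new(model, Path(path).read_text())

    # -- access helpers ----------------------------------------------------

    def base_values(self) -> dict[str, float]:
        return base_set(self.model).values

    def graph(self, which: str) -> ConfigGraph:
        try:
            return {PARAMS: self.param_graph, TIMECOURSE: self.tc_graph,
                    PLOT: self.plot_graph}[which]
        except KeyError:
            raise UnknownKey(f"no graph named {which!r}") from None

    def graph_base(self, which: str) -> dict[str, object]:
        if which == PARAMS:
            return self.base_values()
        if which == TIMECOURSE:
            return st.timecourse_base()
        return st.plot_base(self.model)

    def timecourse_for(self, name: str) -> st.TimeCourseSpec:
        if name == st.DEFAULT_NODE and name not in self.tc_graph.nodes:
            return st.DEFAULT_TIMECOURSE
        return st.timecourse_spec(self.tc_graph, st.timecourse_base(), name)

    def plot_for(self, name: str) -> st.PlotSpec:
        base = st.plot_base(self.model)
        if name == st.DEFAULT_NODE and name not in self.plot_graph.nodes:
            series = tuple(
                st.PlotSeries(**s) for s in base["series"]
            )
            return st.PlotSpec(
                x=base["x"], y=series, title=base["title"],
                x_label=base["x_label"], y_label=base["y_label"],
            )
        return st.plot_spec(self.plot_graph, base, name)

    def applicable_timecourses(self, param_node: str) -> list[str]:
        return st.applicable_settings(
            self.tc_graph, self.param_graph, param_node
        )

    def applicable_plots(self, param_node: str) -> list[str]:
        return st.applicable_settings(
            self.plot_graph, self.param_graph, param_node
        )


# ---------------------------------------------------------------------------
# save / load


_GRAPH_KEYS = {
    PARAMS: "parameter_graph",
    TIMECOURSE: "timecourse_graph",
    PLOT: "plot_graph",
}


def _serialize_local(graph: ConfigGraph, value) -> object:
    if isinstance(value, Opaque):
        return value.value
    return ex.to_string(value)


def _graph_to_json(graph: ConfigGraph) -> dict:
    nodes = []
    for name, rec in graph.nodes.items():
        entry: dict[str, object] = {
            "name": name,
            "parents": list(rec.parents),
            "locals": {
                key: _serialize_local(graph, lv)
                for key, lv in rec.locals.items()
            },
        }
        if rec.color is not None:
            entry["color"] = rec.color
        if rec.applies_to is not None:
            entry["applies_to"] = list(rec.applies_to)
        nodes.append(entry)
    return {"nodes": nodes}


def save(project: Project, path: str | Path) -> None:
    doc = {
        "format_version": project.format_version,
        "model_sbml": project.model_sbml,
    }
    for which, json_key in _GRAPH_KEYS.items():
        doc[json_key] = _graph_to_json(project.graph(which))
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _require(cond: bool, message: str, pointer: str) -> None:
    if not cond:
        raise SchemaError(message, pointer)


def _graph_from_json(doc: object, pointer: str,
                     graph: ConfigGraph) -> ConfigGraph:
    _require(isinstance(doc, dict), "graph must be an object", pointer)
    nodes = doc.get("nodes", [])
    _require(isinstance(nodes, list), "'nodes' must be a list",
             pointer + "/nodes")
    for i, entry in enumerate(nodes):
        p = f"{pointer}/nodes/{i}"
        _require(isinstance(entry, dict), "node must be an object", p)
        name = entry.get("name")
        _require(isinstance(name, str) and bool(name),
                 "node needs a string 'name'", p + "/name")
        parents = entry.get("parents", [])
        _require(
            isinstance(parents, list)
            and all(isinstance(x, str) for x in parents),
            "'parents' must be a list of strings", p + "/parents",
        )
        for par in parents:
            _require(par in graph.nodes,
                     f"parent {par!r} not defined before {name!r}",
                     p + "/parents")
        if parents:
            rec = graph.create_child(name, parents)
        else:
            rec = graph.create_root(name)
        locals_doc = entry.get("locals", {})
        _require(isinstance(locals_doc, dict), "'locals' must be an object",
                 p + "/locals")
        for key, raw in locals_doc.items():
            if key in graph.opaque_keys:
                rec.locals[key] = Opaque(raw)
            else:
                _require(isinstance(raw, str),
                         f"local {key!r} must be an expression string",
                         p + f"/locals/{key}")
                try:
                    rec.locals[key] = ex.parse(raw)
                except Exception as exc:
                    raise SchemaError(str(exc), p + f"/locals/{key}")
        color = entry.get("color")
        if color is not None:
            _require(isinstance(color, str), "'color' must be a string",
                     p + "/color")
            rec.color = color
        applies = entry.get("applies_to")
        if applies is not None:
            _require(
                isinstance(applies, list)
                and all(isinstance(x, str) for x in applies),
                "'applies_to' must be a list of strings", p + "/applies_to",
            )
            rec.applies_to = list(applies)
    return graph


def load(path: str | Path) -> Project:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}", "")
    _require(isinstance(doc, dict), "project must be a JSON object", "")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise FormatVersionError(
            f"unsupported format_version {version!r} "
            f"(expected {FORMAT_VERSION!r})"
        )
    sbml = doc.get("model_sbml")
    _require(isinstance(sbml, str) and bool(sbml),
             "'model_sbml' must be an embedded SBML string", "/model_sbml")
    model = parse_sbml_string(sbml)
    project = Project.new(model, sbml)
    for which, json_key in _GRAPH_KEYS.items():
        if json_key in doc:
            _graph_from_json(doc[json_key], "/" + json_key,
                             project.graph(which))
    return project


# ---------------------------------------------------------------------------
# consistency


@dataclass
class ConsistencyReport:
    conflicts: list[tuple[str, Conflict]] = field(default_factory=list)
    inconsistent: list[tuple[str, str, str]] = field(default_factory=list)
    dangling_applies_to: list[tuple[str, str, str]] = field(
        default_factory=list
    )

    @property
    def ok(self) -> bool:
        return not (self.conflicts or self.inconsistent
                    or self.dangling_applies_to)

    def lines(self) -> list[str]:
        out = []
        for which, c in self.conflicts:
            cands = ", ".join(
                f"{p}={v!r}" for p, v in sorted(c.candidates.items())
            )
            out.append(
                f"CONFLICT [{which}] node {c.node!r} key {c.key!r}: {cands}"
            )
        for which, node, why in self.inconsistent:
            out.append(f"INCONSISTENT [{which}] node {node!r}: {why}")
        for which, node, target in self.dangling_applies_to:
            out.append(
                f"DANGLING applies_to [{which}] node {node!r} -> "
                f"missing parameter node {target!r}"
            )
        return out


def check_consistency(project: Project) -> ConsistencyReport:
    """List every conflicted key, inconsistent node and dangling
    applies_to name; an empty report permits simulation/export."""
    report = ConsistencyReport()
    for which in (PARAMS, TIMECOURSE, PLOT):
        graph = project.graph(which)
        base = project.graph_base(which)
        for name in graph.nodes:
            for key, why in graph.inconsistencies(base, name):
                report.inconsistent.append((which, name, f"{key}: {why}"))
            for conflict in graph.detect_conflicts(base, name):
                report.conflicts.append((which, conflict))
    for which in (TIMECOURSE, PLOT):
        for node, target in st.dangling_applies_to(
            project.graph(which), project.param_graph
        ):
            report.dangling_applies_to.append((which, node, target))
    return report


# ---------------------------------------------------------------------------
# export


def _require_ok(project: Project, name: str) -> None:
    status = project.param_graph.status(project.base_values(), name)
    if status == CONFLICTED:
        raise BlockedByConflict(name)
    if status == INCONSISTENT:
        raise BlockedByInconsistency(name)


def flatten_node(project: Project, name: str) -> BaseModel:
    """The base model with node *name*'s fully resolved values applied."""
    _require_ok(project, name)
    try:
        resolved = project.param_graph.resolve_all(
            project.base_values(), name
        )
    except ConflictError:
        raise BlockedByConflict(name)
    except DanglingReference:
        raise BlockedByInconsistency(name)
    return apply_values(
        project.model, {k: rv.value for k, rv in resolved.items()}
    )


def export_node_sbml(project: Project, name: str,
                     path: str | Path) -> Path:
    """Write the flattened SBML L3V1 for node *name*, plus a sidecar JSON
    carrying the applicable time-course/plot specs (SBML cannot hold them).
    """
    from dataclasses import replace as _replace

    flat = flatten_node(project, name)
    flat = _replace(flat, model_id=f"{flat.model_id}_{name}")
    path = Path(path)
    write_sbml(flat, path)
    sidecar = {
        "node": name,
        "timecourse": [
            _spec_json(project.timecourse_for(tc))
            for tc in project.applicable_timecourses(name)
        ],
        "plots": [
            _plot_json(project.plot_for(p))
            for p in project.applicable_plots(name)
        ],
    }
    sidecar_path = path.with_suffix(".settings.json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def _spec_json(spec: st.TimeCourseSpec) -> dict:
    return {
        "duration": spec.duration, "interval_size": spec.interval_size,
        "output_start": spec.output_start, "rel_tol": spec.rel_tol,
        "abs_tol": spec.abs_tol, "method": spec.method,
        "applies_to": list(spec.applies_to),
    }


def _plot_json(spec: st.PlotSpec) -> dict:
    return {
        "x": spec.x,
        "y": [
            {"id": s.id, "color": s.color, "width": s.width,
             "symbol": s.symbol, "stride": s.stride} for s in spec.y
        ],
        "title": spec.title, "x_label": spec.x_label,
        "y_label": spec.y_label, "applies_to": list(spec.applies_to),
    }


def export_ensemble(project: Project, outdir: str | Path) -> Path:
    """One flattened SBML per OK node plus a manifest CSV; conflicted or
    inconsistent nodes are listed as skipped."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = project.base_values()
    rows = []
    for name in project.param_graph.nodes:
        status = project.param_graph.status(base, name)
        if status == "OK":
            fname = f"{project.model.model_id}_{name}.xml"
            try:
                export_node_sbml(project, name, outdir / fname)
                rows.append((name, fname, "OK"))
            except (BlockedByConflict, BlockedByInconsistency) as exc:
                rows.append((name, "", type(exc).__name__))
        else:
            rows.append((name, "", status))
    manifest = outdir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write("node,file,status\n")
        for name, fname, status in rows:
            fh.write(f"{name},{fname},{status}\n")
    return manifest


def export_graph_dot(project: Project, which: str = PARAMS) -> str:
    """Graphviz DOT text: edges run child -> parent; every in-edge of a
    CONFLICTED child is dashed.  Output is byte-stable (sorted emission).
    """
    graph = project.graph(which)
    base = project.graph_base(which)
    lines = ["digraph configurations {", "  rankdir=BT;"]
    statuses = {name: graph.status(base, name) for name in graph.nodes}
    for name in sorted(graph.nodes):
        attrs = [f'label="{name}"']
        rec = graph.nodes[name]
        if rec.color:
            attrs.append("style=filled")
            attrs.append(f'fillcolor="{rec.color}"')
        if statuses[name] == CONFLICTED:
            attrs.append('color="red"')
        elif statuses[name] == INCONSISTENT:
            attrs.append('color="orange"')
        lines.append(f'  "{name}" [{", ".join(attrs)}];')
    edges = []
    for name in sorted(graph.nodes):
        for parent in graph.nodes[name].parents:
            style = ' [style=dashed]' if statuses[name] == CONFLICTED else ""
            edges.append(f'  "{name}" -> "{parent}"{style};')
    lines.extend(sorted(edges))
    lines.append("}")
    return "\n".join(lines) + "\n"


def render_plots(project: Project, result: EnsembleResult,
                 outdir: str | Path, images: bool = False) -> list[Path]:
    """Per (parameter node x time-course node x applicable plot spec):
    a CSV of the plotted columns and optionally a PNG honoring
    color/width/symbol/stride."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (pnode, tcnode), ts in sorted(result.runs.items()):
        for plot_name in project.applicable_plots(pnode):
            spec = project.plot_for(plot_name)
            series = [s for s in spec.y if s.id in ts.labels]
            if not series:
                continue
            if spec.x == st.TIME:
                x = ts.times
                x_name = "time"
            else:
                if spec.x not in ts.labels:
                    continue
                x = ts.column(spec.x)
                x_name = spec.x
            csv_path = outdir / f"plot_{pnode}_{tcnode}_{plot_name}.csv"
            with open(csv_path, "w") as fh:
                fh.write(x_name + "," + ",".join(s.id for s in series) + "\n")
                cols = [ts.column(s.id) for s in series]
                for i in range(len(x)):
                    cells = [f"{x[i]:.10g}"] + [
                        f"{c[i]:.10g}" for c in cols
                    ]
                    fh.write(",".join(cells) + "\n")
            written.append(csv_path)
            if images:
                written.append(_render_png(
                    csv_path.with_suffix(".png"), spec, x, x_name, ts, series
                ))
    return written


_MARKERS = {"none": "", "circle": "o", "square": "s", "diamond": "D",
            "triangle": "^", "cross": "x", "plus": "+"}


def _render_png(path, spec, x, x_name, ts, series):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s in series:
        ax.plot(
            x, ts.column(s.id), label=s.id, color=s.color,
            linewidth=s.width, marker=_MARKERS.get(s.symbol, ""),
            markevery=s.stride,
        )
    ax.set_xlabel(spec.x_label or x_name)
    ax.set_ylabel(spec.y_label)
    if spec.title:
        ax.set_title(spec.title)
    ax.legend(loc="best", fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
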