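# paramdag

Hierarchical management, simulation and export of SBML model
parameterizations.

A systems-biology model rarely lives as a single parameter set: mutants,
growth conditions and experiment-specific settings produce dozens or
hundreds of variants of one base model. `paramdag` keeps them all in one
project as **inheritance DAGs**:

* **Parameter graph** — each node ("mutant") names a configuration that
  inherits every value from its parents and overrides a few locally.
  Local values may be numbers or algebraic expressions over ancestor
  values (`2*k1@parent_name + 4*k2@grandparent_name`) or the base set
  (`k1@BASE`); a bare identifier (`2*k1`) scales the inherited value.
  Assignable keys are the model's global quantities, species initial
  amounts and compartment sizes.
* **Conflict detection** — a child of multiple parents inherits the union
  of their changes; if two parents redefine the same key to different
  values the node is CONFLICTED and cannot be simulated or exported until
  the conflict is resolved (pick a parent, pick the base value, or type
  an expression). Deleting a node that others reference marks them
  INCONSISTENT; both states survive save/load so no work is lost.
* **Settings graphs** — time-course settings (duration, interval size,
  solver tolerances) and plot settings inherit through the same engine,
  and each settings node declares which parameter nodes it applies to.
* **Simulation & export** — any OK node can be flattened (resolved values
  substituted into a copy of the base model), integrated with a
  stiff-capable adaptive ODE solver (scipy LSODA), written as CSV/PNG, or
  exported as standalone SBML L3V1 (plus a sidecar JSON carrying the
  applicable simulation/plot settings). Graphs render to Graphviz DOT
  with conflicted in-edges dashed.

SBML reading accepts Level 2 and Level 3 Version 1 (compartments,
species, parameters, reactions with kinetic laws, rate/assignment rules);
events, delays, algebraic rules and function definitions are rejected
explicitly. Output is always L3V1.

## CLI quick tour

```bash
paramdag fixtures DECAY --out .                 # write a toy SBML model
paramdag init --sbml decay.xml --project p.json
paramdag node add WT --project p.json
paramdag node add MUT --parents WT --project p.json
paramdag node set MUT k 0.5 --project p.json
paramdag node show MUT --project p.json         # values + provenance notes
paramdag conflicts --project p.json             # list (exit 2 if any)
paramdag conflicts --fix M k1 --from-parent WT1 --project p.json
paramdag run --project p.json --outdir out      # CSVs (+ --images for PNG)
paramdag export sbml --project p.json --outdir out
paramdag export dot --project p.json            # Graphviz text
paramdag check --project p.json                 # consistency report
```

Exit codes: `0` ok, `1` user error, `2` blocked by conflict/inconsistency,
`3` internal error. Add `--json` for machine-readable output.

The same operations are available as a library:

```python
from paramdag import Project, load_sbml, run_ensemble, save

project = Project.from_sbml("decay.xml")
g = project.param_graph
g.create_root("WT")
g.create_child("MUT", ["WT"])
g.set_local("MUT", "k", "2*k@WT")
result = run_ensemble(project, ["WT", "MUT"])
```

## Layout

| Path | Contents |
| --- | --- |
| `src/paramdag/sbml_model.py` | SBML subset reader/writer, base set, value substitution |
| `src/paramdag/expressions.py` | expression language (parser, printer, evaluator) |
| `src/paramdag/graph.py` | the inheritance engine (resolution, conflicts, deletion impact) |
| `src/paramdag/settings.py` | time-course / plot settings graphs and applicability |
| `src/paramdag/simulator.py` | ODE construction, time courses, ensemble runs |
| `src/paramdag/project.py` | project JSON persistence, consistency report, SBML/DOT/plot export |
| `src/paramdag/fixtures.py` | toy models, worked-example projects, random DAGs, brute-force oracle |
| `src/paramdag/cli.py` | `paramdag` command-line interface |
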