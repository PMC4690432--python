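import json

import pytest

from paramdag import fixtures as fx
from paramdag import project as pj
from paramdag.errors import (
    BlockedByConflict,
    ConflictError,
    DanglingReference,
    FormatVersionError,
    SchemaError,
)
from paramdag.graph import CONFLICTED
from paramdag.sbml_model import base_set, load_sbml
from paramdag.simulator import run_ensemble


def _outcomes(project):
    out = {}
    for which in (pj.PARAMS, pj.TIMECOURSE, pj.PLOT):
        g = project.graph(which)
        base = project.graph_base(which)
        for name in g.nodes:
            out[(which, name, "status")] = g.status(base, name)
            for key in sorted(base):
                try:
                    rv = g.resolve(base, name, key)
                    out[(which, name, key)] = (
                        "ok", rv.value, rv.provenance, rv.origin
                    )
                except ConflictError:
                    out[(which, name, key)] = ("conflict",)
                except DanglingReference as exc:
                    out[(which, name, key)] = ("dangling", exc.node)
    return out


class TestSaveLoad:
    def test_conflicted_project_round_trips(self, conflict_project,
                                            tmp_path):
        path = tmp_path / "p.json"
        pj.save(conflict_project, path)
        loaded = pj.load(path)
        assert _outcomes(loaded) == _outcomes(conflict_project)
        assert loaded.param_graph.status(
            loaded.base_values(), "M"
        ) == CONFLICTED

    def test_empty_project_round_trips(self, decay_model, tmp_path):
        project = pj.Project.new(decay_model)
        path = tmp_path / "p.json"
        pj.save(project, path)
        loaded = pj.load(path)
        assert loaded.model == decay_model
        assert len(loaded.param_graph) == 0

    def test_truncated_file_is_schema_error(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text('{"format_version": "1.0", "model_sb')
        with pytest.raises(SchemaError):
            pj.load(path)

    def test_wrong_version(self, conflict_project, tmp_path):
        path = tmp_path / "p.json"
        pj.save(conflict_project, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = "9.9"
        path.write_text(json.dumps(doc))
        with pytest.raises(FormatVersionError):
            pj.load(path)

    def test_schema_error_carries_pointer(self, conflict_project, tmp_path):
        path = tmp_path / "p.json"
        pj.save(conflict_project, path)
        doc = json.loads(path.read_text())
        doc["parameter_graph"]["nodes"][0]["parents"] = "oops"
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError) as err:
            pj.load(path)
        assert "parameter_graph" in err.value.pointer

    @pytest.mark.parametrize("seed", range(12))
    def test_randomized_round_trip_fixpoint(self, seed, tmp_path):
        project = fx.make_random_project(fx.FixtureSpec(
            seed=seed, n_nodes=7, n_keys=4, p_local=0.5,
        ))
        path = tmp_path / "p.json"
        pj.save(project, path)
        loaded = pj.load(path)
        assert _outcomes(loaded) == _outcomes(project)

    def test_dangling_reference_round_trips(self, mdt_project, tmp_path):
        g = mdt_project.param_graph
        g.set_local("WT_galactose", "mdt", "2*mdt@WT_glucose")
        g.delete_node("WT_glucose", force=True)
        path = tmp_path / "p.json"
        pj.save(mdt_project, path)
        loaded = pj.load(path)
        assert loaded.param_graph.status(
            loaded.base_values(), "WT_galactose"
        ) == "INCONSISTENT"


class TestCheckConsistency:
    def test_conflict_reported(self, conflict_project):
        report = pj.check_consistency(conflict_project)
        assert not report.ok
        assert len(report.conflicts) == 1
        which, conflict = report.conflicts[0]
        assert (which, conflict.node, conflict.key) == (pj.PARAMS, "M", "k1")

    def test_clean_project_empty_report(self, mdt_project):
        assert pj.check_consistency(mdt_project).ok

    def test_dangling_applies_to_reported(self, fig3_project):
        fig3_project.param_graph.delete_node("WT_galactose", force=True)
        report = pj.check_consistency(fig3_project)
        assert any(
            target == "WT_galactose"
            for _, _, target in report.dangling_applies_to
        )


class TestExportNode:
    def test_galactose_export_carries_mdt_150(self, mdt_project, tmp_path):
        path = tmp_path / "gal.xml"
        pj.export_node_sbml(mdt_project, "WT_galactose", path)
        flat = load_sbml(path)
        assert flat.model_id == "wt_model_WT_galactose"
        mdt = next(q for q in flat.global_quantities if q.id == "mdt")
        assert mdt.value == 150.0
        sidecar = json.loads(
            path.with_suffix(".settings.json").read_text()
        )
        assert sidecar["node"] == "WT_galactose"

    def test_root_export_value_identical_to_base(self, mdt_project,
                                                 tmp_path):
        path = tmp_path / "root.xml"
        pj.export_node_sbml(mdt_project, "WT_glucose", path)
        flat = load_sbml(path)
        assert base_set(flat).values == mdt_project.base_values()

    def test_conflicted_export_blocked(self, conflict_project, tmp_path):
        with pytest.raises(BlockedByConflict):
            pj.export_node_sbml(conflict_project, "M", tmp_path / "m.xml")

    @pytest.mark.parametrize("seed", range(10))
    def test_export_reimport_fixpoint(self, seed, tmp_path):
        """A flattened node re-imported as a fresh base with one root
        resolves identically to the original node."""
        project = fx.make_random_project(fx.FixtureSpec(
            seed=seed + 500, n_nodes=6, n_keys=4, p_local=0.5,
        ))
        g, base = project.param_graph, project.base_values()
        for name in list(g.nodes):
            if g.status(base, name) != "OK":
                continue
            try:
                resolved = g.resolve_all(base, name)
            except (ConflictError, DanglingReference):
                continue
            path = tmp_path / f"{seed}_{name}.xml"
            pj.export_node_sbml(project, name, path)
            fresh = pj.Project.new(load_sbml(path))
            fresh.param_graph.create_root("root")
            re_resolved = fresh.param_graph.resolve_all(
                fresh.base_values(), "root"
            )
            for key, rv in resolved.items():
                assert re_resolved[key].value == pytest.approx(
                    rv.value, rel=1e-12
                )


class TestExportEnsemble:
    def test_clean_project(self, fig3_project, tmp_path):
        manifest = pj.export_ensemble(fig3_project, tmp_path)
        rows = manifest.read_text().splitlines()
        assert rows[0] == "node,file,status"
        assert len(rows) == 3  # WT + WT_galactose
        files = list(tmp_path.glob("*.xml"))
        assert len(files) == 2

    def test_conflicted_node_skipped(self, conflict_project, tmp_path):
        manifest = pj.export_ensemble(conflict_project, tmp_path)
        rows = dict(
            (line.split(",")[0], line.split(",")[2])
            for line in manifest.read_text().splitlines()[1:]
        )
        assert rows["M"] == "CONFLICTED"
        assert rows["WT1"] == "OK"
        assert len(list(tmp_path.glob("*.xml"))) == 2

    def test_empty_graph_manifest_only(self, decay_model, tmp_path):
        project = pj.Project.new(decay_model)
        manifest = pj.export_ensemble(project, tmp_path)
        assert manifest.read_text().splitlines() == ["node,file,status"]


class TestDot:
    def test_conflicted_edges_dashed(self, conflict_project):
        dot = pj.export_graph_dot(conflict_project)
        assert dot.count("style=dashed") == 2
        assert '"M" -> "WT1" [style=dashed];' in dot

    def test_resolution_restores_solid_edges(self, conflict_project):
        g = conflict_project.param_graph
        g.resolve_conflict(conflict_project.base_values(), "M", "k1",
                           from_parent="WT1")
        dot = pj.export_graph_dot(conflict_project)
        assert "dashed" not in dot

    def test_single_root(self, decay_model):
        project = pj.Project.new(decay_model)
        project.param_graph.create_root("only")
        dot = pj.export_graph_dot(project)
        assert dot.count('label=') == 1
        assert "->" not in dot

    def test_byte_stable(self, conflict_project):
        assert pj.export_graph_dot(conflict_project) == \
            pj.export_graph_dot(conflict_project)


class TestRenderPlots:
    def test_default_plot_csv(self, mdt_project, tmp_path):
        result = run_ensemble(mdt_project, ["WT_glucose"])
        written = pj.render_plots(mdt_project, result, tmp_path)
        assert len(written) == 1
        lines = written[0].read_text().splitlines()
        assert lines[0] == "time,A"
        assert len(lines) == 102  # default duration 100, interval 1

    def test_omitted_species_column_absent(self, conversion_model,
                                           tmp_path):
        from paramdag.graph import Opaque

        project = pj.Project.new(conversion_model)
        project.param_graph.create_root("WT")
        pg = project.plot_graph
        pg.create_root("onlyA")
        pg.set_local("onlyA", "series",
                     Opaque([{"id": "A"}]))  # omit B from the plot
        result = run_ensemble(project, ["WT"])
        written = pj.render_plots(project, result, tmp_path)
        header = written[0].read_text().splitlines()[0]
        assert header == "time,A"

    def test_phase_plane_csv(self, conversion_model, tmp_path):
        from paramdag.graph import Opaque

        project = pj.Project.new(conversion_model)
        project.param_graph.create_root("WT")
        pg = project.plot_graph
        pg.create_root("phase")
        pg.set_local("phase", "x", Opaque("A"))
        pg.set_local("phase", "series", Opaque([{"id": "B"}]))
        result = run_ensemble(project, ["WT"])
        written = pj.render_plots(project, result, tmp_path)
        header = written[0].read_text().splitlines()[0]
        assert header == "A,B"

    def test_images_written(self, mdt_project, tmp_path):
        result = run_ensemble(mdt_project, ["WT_glucose"])
        written = pj.render_plots(mdt_project, result, tmp_path,
                                  images=True)
        assert any(p.suffix == ".png" for p in written)
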