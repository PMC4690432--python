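import pytest

from paramdag import fixtures as fx
from paramdag import settings as st
from paramdag.errors import UnknownKey, UnknownNode
from paramdag.graph import LOCAL, ConfigGraph, Opaque


@pytest.fixture
def tc_graph():
    return st.make_timecourse_graph()


TC_BASE = st.timecourse_base()


class TestTimeCourseGraph:
    def test_short_long_durations(self, tc_graph):
        tc_graph.create_root("short")
        tc_graph.set_local("short", "duration", 500.0)
        tc_graph.create_child("long", ["short"])
        tc_graph.set_local("long", "duration", 1000.0)
        assert tc_graph.resolve(TC_BASE, "short", "duration").value == 500.0
        assert tc_graph.resolve(TC_BASE, "long", "duration").value == 1000.0

    def test_duration_as_ancestor_expression(self, tc_graph):
        tc_graph.create_root("short")
        tc_graph.set_local("short", "duration", 500.0)
        tc_graph.create_child("long", ["short"])
        tc_graph.set_local("long", "duration", "2*duration@short")
        assert tc_graph.resolve(TC_BASE, "long", "duration").value == 1000.0

    def test_interval_inherited(self, tc_graph):
        tc_graph.create_root("short")
        tc_graph.set_local("short", "interval_size", 2.5)
        tc_graph.create_child("long", ["short"])
        rv = tc_graph.resolve(TC_BASE, "long", "interval_size")
        assert (rv.value, rv.origin) == (2.5, "short")

    def test_enum_field_is_opaque_not_expression(self, tc_graph):
        tc_graph.create_root("s")
        tc_graph.set_local("s", "method", "DETERMINISTIC_STIFF")
        rv = tc_graph.resolve(TC_BASE, "s", "method")
        assert rv.value == "DETERMINISTIC_STIFF"
        assert rv.provenance == LOCAL
        with pytest.raises(UnknownKey):
            tc_graph.set_local("s", "duration", Opaque("not numeric"))

    def test_spec_materialization(self, tc_graph):
        tc_graph.create_root("short")
        tc_graph.set_local("short", "duration", 500.0)
        spec = st.timecourse_spec(tc_graph, TC_BASE, "short")
        assert spec.duration == 500.0
        assert spec.interval_size == st.DEFAULT_TIMECOURSE.interval_size
        assert spec.method == st.DETERMINISTIC_STIFF

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            st.TimeCourseSpec(duration=-1)
        with pytest.raises(ValueError):
            st.TimeCourseSpec(duration=10, interval_size=20)
        with pytest.raises(ValueError):
            st.TimeCourseSpec(rel_tol=0)


class TestApplicability:
    def test_fig3_mapping(self, fig3_project):
        assert fig3_project.applicable_timecourses("WT_galactose") == \
            ["short", "long"]
        assert fig3_project.applicable_timecourses("WT") == ["short"]

    def test_empty_applies_to_means_all(self, mdt_project):
        tc = mdt_project.tc_graph
        tc.create_root("any")
        for node in mdt_project.param_graph.nodes:
            assert mdt_project.applicable_timecourses(node) == ["any"]

    def test_no_settings_graph_maps_to_default(self, mdt_project):
        assert mdt_project.applicable_timecourses("WT_glucose") == \
            [st.DEFAULT_NODE]
        assert mdt_project.timecourse_for(st.DEFAULT_NODE) == \
            st.DEFAULT_TIMECOURSE

    def test_unknown_parameter_node(self, fig3_project):
        with pytest.raises(UnknownNode):
            fig3_project.applicable_timecourses("ghost")

    def test_dangling_applies_to_reported(self, fig3_project):
        fig3_project.param_graph.delete_node("WT_galactose", force=True)
        dangling = st.dangling_applies_to(
            fig3_project.tc_graph, fig3_project.param_graph
        )
        assert ("short", "WT_galactose") in dangling
        assert ("long", "WT_galactose") in dangling


class TestDefaults:
    def test_documented_default_values(self):
        d = st.DEFAULT_TIMECOURSE
        assert (d.duration, d.interval_size) == (100.0, 1.0)
        assert (d.rel_tol, d.abs_tol) == (1e-8, 1e-12)

    def test_plot_base_covers_species(self, fig3_project):
        base = st.plot_base(fig3_project.model)
        assert [s["id"] for s in base["series"]] == ["A"]
        assert base["x"] == st.TIME


def test_settings_graph_satisfies_inheritance_oracle():
    """The config-graph oracle suite, run over the time-course key space."""
    import random

    keys = list(st.TIMECOURSE_NUMERIC_KEYS)
    for seed in range(20):
        rng = random.Random(seed + 1000)
        g = st.make_timecourse_graph()
        names = [f"s{i}" for i in range(6)]
        for i, name in enumerate(names):
            if i == 0 or rng.random() < 0.3:
                g.create_root(name)
            else:
                k = rng.randint(1, min(2, i))
                g.create_child(name, rng.sample(names[:i], k))
            for key in keys:
                if rng.random() < 0.4:
                    anc = sorted(g.ancestors(name))
                    if anc and rng.random() < 0.4:
                        g.set_local(name, key,
                                    f"2*{key}@{rng.choice(anc)}")
                    else:
                        g.set_local(name, key, rng.uniform(1, 50))
        from paramdag.errors import ConflictError, DanglingReference

        for name in names:
            for key in keys:
                try:
                    got = g.resolve(TC_BASE, name, key).value
                except ConflictError:
                    got = fx.CONFLICT
                except DanglingReference:
                    got = fx.DANGLING
                expected = fx.oracle_resolve_graph(g, TC_BASE, name, key)
                if isinstance(expected, float):
                    assert got == pytest.approx(expected, rel=1e-12)
                else:
                    assert got is expected
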