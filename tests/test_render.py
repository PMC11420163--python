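"""SVG rendering: frames, animation, legend, popups."""

import json
import random
import xml.etree.ElementTree as ET

import pytest

from metapaint import (
    Breakpoints,
    ChannelState,
    MultiOmicsExperiment,
    build_frames,
    compute_histogram,
    layout_network,
    make_color_scale,
    render_animation,
    render_frame,
    render_legend,
    render_popup,
    resolve_targets,
    toy_quinate_network,
    value_to_color,
    value_to_thickness,
)
from metapaint.mapping import MISSING_COLOR, default_channel_state
from metapaint.render import NoDataError, RenderConfigError, sanitize_id

from conftest import make_dataset

NS = {"svg": "http://www.w3.org/2000/svg"}


def states_for(experiment, network):
    out = {}
    for ds in experiment.datasets:
        res = resolve_targets(ds, network, n_frames=experiment.n_frames)
        vals = [v for s in res for v in s.values if v is not None] or [0.0]
        out[ds.spec.target_channel] = default_channel_state(
            ds.spec.target_channel, vals, ds.spec.signed
        )
    return out


@pytest.fixture(scope="module")
def quinate_setup():
    net = toy_quinate_network()
    diagram = layout_network(net)
    exp = MultiOmicsExperiment(
        [
            make_dataset(
                dataset_id="tx", data_type="gene", channel="edge_color",
                rows=(
                    ("quiA", [1.0, 2.0, 3.0, 4.0]),
                    ("pcaG", [5.0, -6.0, 2.0, 0.5]),
                    ("pcaH", [-1.0, -7.0, 1.0, 0.25]),
                ),
                n_columns=4,
                labels=["3 h", "11.75 h", "13 h", "15 h"],
            ),
            make_dataset(
                dataset_id="prot", data_type="protein", channel="edge_thickness",
                rows=(("quiA", [0.5, 1.5, 2.5, 3.5]), ("pheA", [1.0, None, 2.0, 4.0])),
                n_columns=4, signed=False,
            ),
            make_dataset(
                dataset_id="met", data_type="compound", channel="node_color",
                rows=(("quinate", [5.5]), ("L-phenylalanine", [-2.0])),
            ),
        ]
    )
    return net, diagram, exp


class TestBuildFrames:
    def test_four_frames_with_static_node_colors(self, quinate_setup):
        """The single-column metabolomics layer holds constant while the
        four-column layers animate."""
        net, diagram, exp = quinate_setup
        fs = build_frames(diagram, exp, states_for(exp, net), net)
        assert fs.n_frames == 4
        for f in range(4):
            assert fs.frames[f]["quinate"]["fill"] == fs.frames[0]["quinate"]["fill"]
            assert fs.frames[f]["phe"]["fill"] == fs.frames[0]["phe"]["fill"]
        # edge colors do change between frames for pcaGH (5.0 vs -6.0 extremes)
        assert fs.frames[0]["r-pcaGH"]["stroke"] != fs.frames[1]["r-pcaGH"]["stroke"]

    def test_single_dataset_single_column_gives_one_frame(self, quinate_setup):
        net, diagram, _ = quinate_setup
        exp = MultiOmicsExperiment(
            [make_dataset(data_type="compound", channel="node_color",
                          rows=(("quinate", [1.0]),))]
        )
        fs = build_frames(diagram, exp, states_for(exp, net), net)
        assert fs.n_frames == 1

    def test_styles_equal_independent_recomputation(self, quinate_setup):
        net, diagram, exp = quinate_setup
        states = states_for(exp, net)
        fs = build_frames(diagram, exp, states, net)
        for ds in exp.datasets:
            res = resolve_targets(ds, net, n_frames=exp.n_frames)
            st = states[ds.spec.target_channel]
            for s in res:
                for f, v in enumerate(s.values):
                    style = fs.frames[f][s.target_id]
                    if st.is_color:
                        key = "fill" if st.channel.startswith("node") else "stroke"
                        assert style[key] == value_to_color(v, st)
                    else:
                        assert float(style["stroke-width"]) == pytest.approx(
                            value_to_thickness(v, st), abs=5e-4
                        )

    def test_missing_channel_state_is_config_error(self, quinate_setup):
        net, diagram, exp = quinate_setup
        states = states_for(exp, net)
        del states["node_color"]
        with pytest.raises(RenderConfigError, match="node_color"):
            build_frames(diagram, exp, states, net)


class TestRenderFrame:
    def test_empty_diagram_is_membrane_only_xml(self):
        from metapaint.network import MetabolicNetwork

        d = layout_network(MetabolicNetwork())
        root = ET.fromstring(render_frame(d, {}, 2))
        assert root.tag.endswith("svg")
        shapes = [e for e in root.iter() if not e.tag.endswith("svg")]
        assert len(shapes) == 1 and shapes[0].get("id") == "membrane"

    def test_each_reaction_id_once_at_tier2(self, quinate_setup):
        net, diagram, exp = quinate_setup
        fs = build_frames(diagram, exp, states_for(exp, net), net)
        root = ET.fromstring(render_frame(diagram, fs.frames[0], 2, net))
        ids = [e.get("id") for e in root.iter() if e.get("id")]
        for rid in net.reactions:
            assert ids.count(sanitize_id(rid)) == 1

    def test_painted_stroke_matches_frame_style_exactly(self, quinate_setup):
        net, diagram, exp = quinate_setup
        fs = build_frames(diagram, exp, states_for(exp, net), net)
        root = ET.fromstring(render_frame(diagram, fs.frames[0], 2, net))
        by_ref = {}
        for e in root.iter():
            if e.get("data-ref"):
                by_ref.setdefault(e.get("data-ref"), []).append(e)
        for tid, style in fs.frames[0].items():
            for e in by_ref[tid]:
                if "stroke" in style and e.tag.endswith("polyline"):
                    assert e.get("stroke") == style["stroke"]
                if "fill" in style and not e.tag.endswith("polyline"):
                    assert e.get("fill") == style["fill"]

    def test_missing_value_edge_gets_missing_style(self, quinate_setup):
        net, diagram, _ = quinate_setup
        exp = MultiOmicsExperiment(
            [make_dataset(rows=(("quiA", [None]), ("quiB", [2.0])))]
        )
        states = states_for(exp, net)
        fs = build_frames(diagram, exp, states, net)
        assert fs.frames[0]["r-quiA"]["stroke"] == MISSING_COLOR

    def test_tier_filters_detail(self, quinate_setup):
        net, diagram, exp = quinate_setup
        fs = build_frames(diagram, exp, states_for(exp, net), net)
        t0 = render_frame(diagram, fs.frames[0], 0, net)
        t2 = render_frame(diagram, fs.frames[0], 2, net)
        assert "polyline" in t0  # membrane
        assert ET.fromstring(t0) is not None
        assert len(t2) > len(t0)
        assert "circle" not in t0 and "circle" in t2

    def test_tier3_replaces_shapes_with_colored_names(self, quinate_setup):
        net, diagram, exp = quinate_setup
        states = states_for(exp, net)
        fs = build_frames(diagram, exp, states, net)
        root = ET.fromstring(render_frame(diagram, fs.frames[0], 3, net))
        texts = {
            e.get("data-ref"): e
            for e in root.iter()
            if e.tag.endswith("text") and e.get("data-ref")
        }
        assert texts["quinate"].text == "quinate"
        assert texts["quinate"].get("fill") == fs.frames[0]["quinate"]["fill"]
        # no shape element remains for that compound
        for e in root.iter():
            if e.get("data-ref") == "quinate":
                assert e.tag.endswith("text")

    def test_tooltip_titles_present(self, quinate_setup):
        net, diagram, exp = quinate_setup
        fs = build_frames(diagram, exp, states_for(exp, net), net)
        root = ET.fromstring(render_frame(diagram, fs.frames[0], 2, net))
        titles = [t.text for t in root.iter() if t.tag.endswith("title")]
        assert "quinate" in titles
        assert any("quinate dehydrogenase" in t for t in titles)


class TestRenderAnimation:
    def test_geometry_identical_across_frames(self, quinate_setup, tmp_path):
        net, diagram, exp = quinate_setup
        fs = build_frames(diagram, exp, states_for(exp, net), net)
        names = render_animation(diagram, fs, 2, tmp_path, network=net)
        assert len(names) == 4
        geoms = []
        for n in names:
            root = ET.fromstring((tmp_path / n).read_text())
            geoms.append(
                [
                    (e.tag, e.get("points"), e.get("cx"), e.get("cy"), e.get("x"),
                     e.get("y"))
                    for e in root.iter()
                ]
            )
        assert all(g == geoms[0] for g in geoms[1:])

    def test_index_lists_frames_in_order_with_labels(self, quinate_setup, tmp_path):
        net, diagram, exp = quinate_setup
        fs = build_frames(diagram, exp, states_for(exp, net), net)
        render_animation(diagram, fs, 2, tmp_path, network=net)
        index = json.loads((tmp_path / "index.json").read_text())
        assert index["n_frames"] == 4
        assert [f["label"] for f in index["frames"]] == ["3 h", "11.75 h", "13 h", "15 h"]
        assert [f["file"] for f in index["frames"]] == [
            f"frame_{i:03d}.svg" for i in range(4)
        ]

    def test_single_frame_set(self, quinate_setup, tmp_path):
        net, diagram, _ = quinate_setup
        exp = MultiOmicsExperiment(
            [make_dataset(data_type="compound", channel="node_color",
                          rows=(("quinate", [1.0]),), labels=["score"])]
        )
        fs = build_frames(diagram, exp, states_for(exp, net), net)
        names = render_animation(diagram, fs, 2, tmp_path / "one", network=net)
        index = json.loads((tmp_path / "one" / "index.json").read_text())
        assert len(names) == 1 and len(index["frames"]) == 1
        assert index["frames"][0]["label"] == "score"


class TestStyleFidelity:
    def test_1000_random_value_state_pairs_round_trip_through_svg(self):
        """Colors and widths extracted from rendered SVG equal the mapping
        module's own outputs for the same values."""
        from metapaint import CompoundNode, MetabolicNetwork, Reaction

        rng = random.Random(17)
        n = 1000
        comps = [CompoundNode(f"c{i}") for i in range(n + 1)]
        rxns = [Reaction(f"r{i:04d}", [f"c{i}"], [f"c{i+1}"], [f"g{i}"]) for i in range(n)]
        net = MetabolicNetwork(comps, rxns, [])
        diagram = layout_network(net)
        values = [
            None if rng.random() < 0.05 else rng.uniform(-12, 12) for _ in range(n)
        ]
        rows = tuple((f"r{i:04d}", [v]) for i, v in enumerate(values))
        exp = MultiOmicsExperiment(
            [
                make_dataset(dataset_id="col", data_type="reaction",
                             channel="edge_color", rows=rows),
                make_dataset(dataset_id="thk", data_type="reaction",
                             channel="edge_thickness", rows=rows, signed=False),
            ]
        )
        states = states_for(exp, net)
        fs = build_frames(diagram, exp, states, net)
        root = ET.fromstring(render_frame(diagram, fs.frames[0], 2, net))
        stroke = {}
        width = {}
        for e in root.iter():
            ref = e.get("data-ref")
            if ref and e.tag.endswith("polyline"):
                stroke[ref] = e.get("stroke")
                width[ref] = float(e.get("stroke-width"))
        for i, v in enumerate(values):
            rid = f"r{i:04d}"
            assert stroke[rid] == value_to_color(v, states["edge_color"])
            assert width[rid] == pytest.approx(
                value_to_thickness(v, states["edge_thickness"]), abs=5e-4
            )


class TestLegend:
    def _hist_and_state(self):
        from metapaint.mapping import EntityValueSeries

        series = [EntityValueSeries(f"t{i}", [float(i)]) for i in range(-3, 4)]
        bp = Breakpoints((-4.0, -2.0, 0.0, 2.0, 4.0, 6.0))
        state = ChannelState(
            channel="edge_color", breakpoints=bp,
            color_scale=make_color_scale("green-red", 5),
        )
        return compute_histogram(series, 0, bp), state

    def test_five_bins_give_five_regions(self):
        hist, state = self._hist_and_state()
        root = ET.fromstring(render_legend(hist, state))
        regions = [e for e in root.iter() if e.get("class") == "legend-bin"]
        assert len(regions) == 5
        assert [r.get("fill") for r in regions] == list(
            reversed(state.color_scale.colors)
        )

    def test_boundary_labels_two_decimals(self):
        hist, state = self._hist_and_state()
        root = ET.fromstring(render_legend(hist, state))
        labels = [e.text for e in root.iter() if e.get("class") == "boundary-label"]
        assert labels == ["-4.00", "-2.00", "0.00", "2.00", "4.00", "6.00"]

    def test_counts_match_histogram(self):
        hist, state = self._hist_and_state()
        root = ET.fromstring(render_legend(hist, state))
        counts = [int(e.text) for e in root.iter() if e.get("class") == "bin-count"]
        assert counts == list(reversed(hist.bin_counts))

    def test_bin_count_mismatch_rejected(self):
        hist, state = self._hist_and_state()
        bad = ChannelState(
            channel="edge_color",
            breakpoints=Breakpoints((0.0, 1.0, 2.0)),
            color_scale=make_color_scale("green-red", 2),
        )
        with pytest.raises(ValueError, match="bins"):
            render_legend(hist, bad)


class TestPopup:
    def test_reaction_popup_shows_each_contributing_gene_series(self, quinate_setup):
        """Two genes x one transcriptomics dataset -> two separate series,
        pre-aggregation (isozymes stay distinguishable)."""
        net, _, exp = quinate_setup
        root = ET.fromstring(render_popup("r-pcaGH", exp, net))
        labels = [e.get("data-label") for e in root.iter() if e.get("data-label")]
        assert sorted(labels) == ["tx: pcaG", "tx: pcaH"]

    def test_two_datasets_two_genes_four_series(self, quinate_setup):
        net, _, _ = quinate_setup
        exp = MultiOmicsExperiment(
            [
                make_dataset(dataset_id="tx", channel="edge_color",
                             rows=(("pcaG", [1.0, 2.0]), ("pcaH", [3.0, 4.0])),
                             n_columns=2),
                make_dataset(dataset_id="prot", data_type="protein",
                             channel="edge_thickness",
                             rows=(("pcaG", [5.0, 6.0]), ("pcaH", [7.0, 8.0])),
                             n_columns=2, signed=False),
            ]
        )
        root = ET.fromstring(render_popup("r-pcaGH", exp, net))
        series = [e for e in root.iter() if e.get("data-label")]
        assert len(series) == 4

    def test_single_point_series_rendered_as_marker(self, quinate_setup):
        net, _, _ = quinate_setup
        exp = MultiOmicsExperiment(
            [make_dataset(data_type="compound", channel="node_color",
                          rows=(("quinate", [5.5]),))]
        )
        root = ET.fromstring(render_popup("quinate", exp, net))
        markers = [e for e in root.iter() if e.get("data-value")]
        assert len(markers) == 1
        assert float(markers[0].get("data-value")) == 5.5

    def test_plotted_values_equal_parsed_table_values(self, quinate_setup):
        net, _, exp = quinate_setup
        root = ET.fromstring(render_popup("r-quiA", exp, net))
        by_series = {}
        for g in root.iter():
            if g.get("data-label"):
                vals = [
                    (int(c.get("data-column")), float(c.get("data-value")))
                    for c in g.iter() if c.get("data-value")
                ]
                by_series[g.get("data-label")] = [v for _, v in sorted(vals)]
        assert by_series["tx: quiA"] == [1.0, 2.0, 3.0, 4.0]
        assert by_series["prot: quiA"] == [0.5, 1.5, 2.5, 3.5]

    def test_axis_labeled_with_column_labels(self, quinate_setup):
        net, _, exp = quinate_setup
        root = ET.fromstring(render_popup("r-quiA", exp, net))
        xlabels = [e.text for e in root.iter() if e.get("class") == "x-label"]
        assert xlabels == ["3 h", "11.75 h", "13 h", "15 h"]

    def test_untouched_entity_is_no_data_error(self, quinate_setup):
        net, _, exp = quinate_setup
        with pytest.raises(NoDataError):
            render_popup("r-sdh", exp, net)
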