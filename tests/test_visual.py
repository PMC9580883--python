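"""Visual channel maps, compartment-box layout, and graph export round-trips."""

import itertools
import json
import math

import pytest
from lxml import etree

from phytonet import (
    AnnotatedNetwork,
    DEFAULT_GEOMETRY,
    StyleMap,
    compute_style,
    layout_compartments,
    network_summary,
    write_graph,
)
from phytonet.annotate import assign_ligand_locations, assign_protein_locations
from phytonet.errors import LayoutError, StyleError
from phytonet.tables import PKAnnotation
from phytonet.visual import CompartmentGeometry, read_graphml, write_legend


def styled_toy(toy_network):
    from phytonet import annotate_pharmacokinetics, annotate_protein_function

    net = assign_protein_locations(
        toy_network.copy(),
        {"A": "nucleus", "B": "plasma membrane"},
        {"C": "cytoplasm", "D": "mitochondrion"},
    )
    assign_ligand_locations(net)
    annotate_pharmacokinetics(
        net,
        [
            PKAnnotation("l1", 0.85, "high", 5.0),
            PKAnnotation("l2", 0.55, "low", -1.0),
            PKAnnotation("l3", 0.11, "high", 2.0),
            PKAnnotation("l4", 0.17, "low", 0.0),
        ],
    )
    annotate_protein_function(net, {"A": "oncogene", "B": "tumor suppressor"})
    return compute_style(net)


class TestStyle:
    def test_probability_one_gets_maximum_width(self, toy_network):
        net = styled_toy(toy_network)
        widths = {
            d["probability"]: d["width"]
            for _, _, d in net.graph.edges(data=True)
            if d["edge_type"] in ("PCPI", "DPI")
        }
        assert widths[1.0] == StyleMap().edge_width_range[1]
        probs = sorted(widths)
        assert [widths[p] for p in probs] == sorted(widths[p] for p in probs)

    def test_ppi_edge_colors(self, toy_network):
        net = styled_toy(toy_network)
        colors = {d["edge_type"]: d["color"] for _, _, d in net.graph.edges(data=True)}
        assert colors["PPI-up"] == "#2ca02c"  # green
        assert colors["PPI-down"] == "#d62728"  # red
        assert colors["PCPI"] == colors["DPI"] == "#1f77b4"  # blue

    def test_glycoside_edges_dashed(self, toy_network):
        net = styled_toy(toy_network)
        styles = {d["edge_type"]: d["line_style"] for _, _, d in net.graph.edges(data=True)}
        assert styles["glycoside-aglycone"] == "dashed"
        assert styles["PCPI"] == "solid"

    def test_lowest_logp_gets_minimum_opacity(self, toy_network):
        net = styled_toy(toy_network)
        nodes = net.graph.nodes
        lo, hi = StyleMap().node_opacity_range
        assert nodes["l2"]["opacity"] == lo  # logp -1.0 is the observed minimum
        assert nodes["l1"]["opacity"] == hi  # logp 5.0 is the maximum
        # monotone in log P
        pairs = [(nodes[n]["logp"], nodes[n]["opacity"]) for n in ("l1", "l2", "l3", "l4")]
        pairs.sort()
        assert [o for _, o in pairs] == sorted(o for _, o in pairs)

    def test_missing_pk_maps_to_channel_minimum_with_marker(self, toy_network):
        net = styled_toy(toy_network)  # l5 has no PK record
        node = net.graph.nodes["l5"]
        assert node["pk_missing"] is True
        assert node["opacity"] == StyleMap().node_opacity_range[0]
        assert node["size"] == min(StyleMap().node_size_map.values())

    def test_gi_absorption_sizes_and_bioavailability_borders(self, toy_network):
        net = styled_toy(toy_network)
        nodes = net.graph.nodes
        assert nodes["l1"]["size"] > nodes["l2"]["size"]
        assert nodes["l1"]["border_color"] == "#2ca02c"  # 0.85 -> high/green
        assert nodes["l2"]["border_color"] == "#ff7f0e"  # 0.55 -> medium/orange
        assert nodes["l3"]["border_color"] == "#d62728"  # 0.11 -> low/red

    def test_protein_styling(self, toy_network):
        net = styled_toy(toy_network)
        nodes = net.graph.nodes
        assert nodes["A"]["shape"] == "square"
        assert nodes["A"]["fill"] == "#ffc0cb"
        assert nodes["A"]["label_color"] == "#d62728"  # oncogene
        assert nodes["B"]["label_color"] == "#2ca02c"  # tumor suppressor
        assert nodes["C"]["label_color"] == "#000000"  # other
        assert nodes["l1"]["shape"] == "circle"

    def test_unknown_edge_type_raises(self):
        net = AnnotatedNetwork()
        net.graph.add_node("a", node_kind="ligand")
        net.graph.add_node("b", node_kind="ligand")
        net.graph.add_edge("a", "b", edge_type="mystery")
        with pytest.raises(StyleError):
            compute_style(net)


class TestLayout:
    def _inside(self, point, rect):
        x, y, w, h = rect
        return x <= point[0] <= x + w and y <= point[1] <= y + h

    def test_single_node_centered(self):
        net = AnnotatedNetwork()
        net.graph.add_node("n", node_kind="protein", compartment="nucleus")
        coords = layout_compartments(net, seed=1)
        x, y, w, h = DEFAULT_GEOMETRY.rect("nucleus")
        assert coords["n"] == (x + w / 2, y + h / 2)

    def test_same_seed_identical_coordinates(self, toy_network):
        net = styled_toy(toy_network)
        assert layout_compartments(net, seed=5) == layout_compartments(net, seed=5)

    def test_fifty_nodes_inside_rectangle_with_min_separation(self):
        net = AnnotatedNetwork()
        for i in range(50):
            net.graph.add_node(f"n{i:02d}", node_kind="protein", compartment="cytoplasm")
        coords = layout_compartments(net, seed=3, jitter_frac=0.2)
        rect = DEFAULT_GEOMETRY.rect("cytoplasm")
        assert all(self._inside(p, rect) for p in coords.values())
        # grid pitch minus jitter bounds the pairwise separation
        ncol = math.ceil(math.sqrt(50))
        nrow = math.ceil(50 / ncol)
        cell_w = rect[2] * 0.8 / ncol
        cell_h = rect[3] * 0.8 / nrow
        min_sep = (1 - 2 * 0.2) * min(cell_w, cell_h)
        for a, b in itertools.combinations(coords.values(), 2):
            assert math.dist(a, b) >= min_sep - 1e-9

    def test_missing_rectangle_raises(self):
        net = AnnotatedNetwork()
        net.graph.add_node("n", node_kind="protein", compartment="vacuole")
        with pytest.raises(LayoutError, match="vacuole"):
            layout_compartments(net, seed=1)

    def test_custom_geometry(self):
        geom = CompartmentGeometry(rectangles={"vacuole": (0.0, 0.0, 10.0, 10.0)})
        net = AnnotatedNetwork()
        net.graph.add_node("n", node_kind="protein", compartment="vacuole")
        assert layout_compartments(net, geometry=geom, seed=1)["n"] == (5.0, 5.0)


class TestExport:
    def test_graphml_round_trip_preserves_attributes(self, toy_network, tmp_path):
        net = styled_toy(toy_network)
        coords = layout_compartments(net, seed=2)
        path = tmp_path / "net.graphml"
        write_graph(net, coords, path, fmt="graphml")
        back = read_graphml(path)
        assert back.n_nodes == net.n_nodes
        assert back.n_edges == net.n_edges
        for n, d in net.graph.nodes(data=True):
            round_tripped = back.graph.nodes[str(n)]
            for key, value in d.items():
                if value is not None:
                    assert round_tripped[key] == value
        original_edges = sorted(
            (u, v, tuple(sorted((k, v2) for k, v2 in d.items() if v2 is not None)))
            for u, v, d in net.graph.edges(data=True)
        )
        returned_edges = sorted(
            (u, v, tuple(sorted(d.items()))) for u, v, d in back.graph.edges(data=True)
        )
        assert returned_edges == original_edges

    def test_graphml_is_schema_shaped_xml(self, toy_network, tmp_path):
        net = styled_toy(toy_network)
        path = tmp_path / "net.graphml"
        write_graph(net, layout_compartments(net, seed=2), path, fmt="graphml")
        tree = etree.parse(str(path))
        root = tree.getroot()
        assert root.tag == "{http://graphml.graphdrawing.org/xmlns}graphml"
        keys = {k.get("attr.name") for k in root.iter("{http://graphml.graphdrawing.org/xmlns}key")}
        assert {"node_kind", "edge_type", "x", "y"} <= keys

    def test_empty_network_writes_valid_file(self, tmp_path):
        path = tmp_path / "empty.graphml"
        write_graph(AnnotatedNetwork(), {}, path, fmt="graphml")
        assert read_graphml(path).n_nodes == 0

    def test_json_export_matches_summary_counts(self, toy_network, tmp_path):
        net = styled_toy(toy_network)
        path = tmp_path / "net.cyjs"
        write_graph(net, layout_compartments(net, seed=2), path, fmt="cytoscape-json")
        payload = json.loads(path.read_text())
        totals = network_summary(net).set_index(["category", "value"])["count"]
        assert len(payload["elements"]["nodes"]) == totals[("total", "nodes")]
        assert len(payload["elements"]["edges"]) == totals[("total", "edges")]

    def test_csv_export_matches_summary_counts(self, toy_network, tmp_path):
        import pandas as pd

        net = styled_toy(toy_network)
        write_graph(net, layout_compartments(net, seed=2), tmp_path / "net", fmt="csv")
        totals = network_summary(net).set_index(["category", "value"])["count"]
        assert len(pd.read_csv(tmp_path / "net.nodes.csv")) == totals[("total", "nodes")]
        assert len(pd.read_csv(tmp_path / "net.edges.csv")) == totals[("total", "edges")]

    def test_legend_mentions_every_edge_type(self, tmp_path):
        style = StyleMap()
        write_legend(style, tmp_path / "legend.txt")
        text = (tmp_path / "legend.txt").read_text()
        for edge_type in style.edge_colors:
            assert edge_type in text
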