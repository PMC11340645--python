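import math
import xml.etree.ElementTree as ET

import numpy as np
import pytest

import celltree as ct
from celltree.cluster_tree import ClusterNode, ClusterTree
from celltree.render import ConfigValidationError, overlay_color_scale

SVG_NS = "{http://www.w3.org/2000/svg}"


def balanced_tree(n_leaves):
    def grow(k, base):
        node = ClusterNode(-1)
        if k == 1:
            node.cells = [f"{base}_{i}" for i in range(3)]
            return node
        node.distance = 0.3
        node.children = [grow(k // 2, base + "L"), grow(k - k // 2, base + "R")]
        return node

    from celltree.cluster_tree import renumber_bfs
    return ClusterTree(renumber_bfs(grow(n_leaves, "c")))


class TestRadialLayout:
    def test_two_leaf_tree_leaves_opposite(self):
        t = balanced_tree(2)
        layout = ct.radial_layout(t)
        l1, l2 = (layout[leaf.node_id] for leaf in t.leaves())
        assert l1.angular_span == pytest.approx((0, math.pi))
        assert l2.angular_span == pytest.approx((math.pi, 2 * math.pi))
        assert abs(l1.angle - l2.angle) == pytest.approx(math.pi)

    def test_four_leaf_balanced_uniform_steps(self):
        t = balanced_tree(4)
        layout = ct.radial_layout(t, scale_by_distance=False)
        for leaf in t.leaves():
            ln = layout[leaf.node_id]
            assert ln.radius == 2
            span = ln.angular_span[1] - ln.angular_span[0]
            assert span == pytest.approx(math.pi / 2)

    def test_single_leaf_at_origin(self):
        t = ct.simulate_random_tree(1, seed=0)
        layout = ct.radial_layout(t)
        assert layout[0].radius == 0 and layout[0].parent_id is None

    def test_root_spans_full_circle_radius_zero(self, random_tree):
        layout = ct.radial_layout(random_tree)
        root = layout[random_tree.root.node_id]
        assert root.radius == 0
        assert root.angular_span == (0, 2 * math.pi)

    def test_leaf_spans_sum_to_two_pi(self, random_tree):
        layout = ct.radial_layout(random_tree)
        total = sum(layout[l.node_id].angular_span[1] - layout[l.node_id].angular_span[0]
                    for l in random_tree.leaves())
        assert total == pytest.approx(2 * math.pi, abs=1e-9)

    def test_sibling_spans_partition_parent(self, random_tree):
        layout = ct.radial_layout(random_tree)
        for node in random_tree.nodes():
            if node.is_leaf:
                continue
            spans = [layout[c.node_id].angular_span for c in node.children]
            parent = layout[node.node_id].angular_span
            assert spans[0][0] == pytest.approx(parent[0])
            assert spans[0][1] == pytest.approx(spans[1][0])
            assert spans[1][1] == pytest.approx(parent[1])

    def test_distance_scaling_uses_split_distance(self):
        t = balanced_tree(2)
        t.root.distance = 0.5
        layout = ct.radial_layout(t, scale_by_distance=True)
        for leaf in t.leaves():
            assert layout[leaf.node_id].radius == pytest.approx(0.5)

    def test_zero_distance_edges_get_epsilon_floor(self):
        t = balanced_tree(4)
        t.root.children[0].distance = 0.0
        t.root.distance = 1.0
        layout = ct.radial_layout(t, scale_by_distance=True)
        child = t.root.children[0]
        grandchild = child.children[0]
        assert layout[grandchild.node_id].radius > layout[child.node_id].radius


class TestBranchWidths:
    def test_root_gets_max(self, random_tree):
        widths = ct.compute_branch_widths(random_tree, (1.0, 10.0))
        assert widths[random_tree.root.node_id] == 10.0

    def test_all_widths_above_min(self, random_tree):
        widths = ct.compute_branch_widths(random_tree, (1.0, 10.0))
        assert all(w > 1.0 for w in widths.values())

    def test_equal_size_siblings_equal_width(self):
        t = balanced_tree(4)
        widths = ct.compute_branch_widths(t, (0.5, 4.0))
        c1, c2 = t.root.children
        assert widths[c1.node_id] == widths[c2.node_id]


class TestRenderSvg:
    def render(self, t, **kw):
        layout = ct.radial_layout(t)
        return ct.render_svg(t, layout, ct.RenderConfig(), **kw)

    def test_element_counts_match_tree_size(self):
        for n_leaves in (2, 3, 5):
            t = balanced_tree(n_leaves)
            doc = self.render(t)
            root = ET.fromstring(doc.xml)
            glyphs = root.findall(f".//{SVG_NS}g[@class='node']")
            links = root.findall(f".//{SVG_NS}path[@class='link']")
            assert len(glyphs) == 2 * n_leaves - 1
            assert len(links) == 2 * n_leaves - 2

    def test_output_parses_as_xml_with_lxml(self):
        lxml_etree = pytest.importorskip("lxml.etree")
        doc = self.render(balanced_tree(3))
        lxml_etree.fromstring(doc.xml.encode())

    def test_glyphs_carry_node_ids(self):
        t = balanced_tree(3)
        doc = self.render(t)
        root = ET.fromstring(doc.xml)
        ids = {g.get("data-node-id") for g in root.findall(f".//{SVG_NS}g[@class='node']")}
        assert ids == {str(n.node_id) for n in t.nodes()}

    def test_legend_color_is_verbatim_hex(self):
        t = balanced_tree(2)
        labels = ct.LabelMap({b: "x" for b in t.barcodes()}, {"x": "#ABCDEF"})
        doc = self.render(t, labels=labels)
        assert "#ABCDEF" in doc.xml
        root = ET.fromstring(doc.xml)
        legend = root.find(f".//{SVG_NS}g[@class='legend']")
        rect = legend.find(f"{SVG_NS}rect")
        assert rect.get("fill") == "#ABCDEF"

    def test_overlay_missing_node_rejected(self):
        t = balanced_tree(3)
        layout = ct.radial_layout(t)
        bad = ct.NodeOverlay({0: 1.0}, ct.OverlayKind.MEAN_FEATURE)
        with pytest.raises(ValueError, match="overlay missing"):
            ct.render_svg(t, layout, ct.RenderConfig(), overlays=bad)

    def test_color_scale_monotone(self):
        ov = ct.NodeOverlay({i: float(i) for i in range(5)},
                            ct.OverlayKind.MEAN_FEATURE)
        colors = overlay_color_scale(ov, "#000000", "#FF0000")
        reds = [int(colors[i][1:3], 16) for i in range(5)]
        assert reds == sorted(reds)


class TestRenderPng:
    def test_png_header_and_width(self):
        t = balanced_tree(3)
        doc = ct.render_svg(t, ct.radial_layout(t), ct.RenderConfig())
        png = ct.render_png(doc, 200)
        assert png[:8] == b"\x89PNG\r\n\x1a\n"
        from PIL import Image
        import io
        img = Image.open(io.BytesIO(png))
        assert img.width == 200
        assert img.height == 200  # square config preserves aspect

    def test_deterministic_bytes(self):
        t = balanced_tree(4)
        labels = ct.LabelMap({b: ("a" if "L" in b else "b") for b in t.barcodes()})
        doc = ct.render_svg(t, ct.radial_layout(t), ct.RenderConfig(), labels=labels)
        assert ct.render_png(doc, 150) == ct.render_png(doc, 150)


class TestRenderConfig:
    def test_default_round_trips(self):
        cfg = ct.RenderConfig()
        back = ct.config_from_json(ct.config_to_json(cfg))
        assert back == cfg

    def test_full_round_trip_with_history(self):
        cfg = ct.RenderConfig(
            scale_by_distance=True, global_scale=1.5,
            branch_width_range=(0.5, 6.0), color_map={"a": "#112233"},
            feature_overlays=[{"feature": "g1", "hi": 2.0, "lo": 0.5}],
            prune_history=ct.PruneHistory([
                ct.PruneStep(ct.PruneKind.MIN_CELLS, 10),
                ct.PruneStep(ct.PruneKind.MIN_DISTANCE_SEARCH, 0.019),
            ]),
            export="png", width_px=640, height_px=480,
            show_legend=False, seed=7,
        )
        back = ct.config_from_json(ct.config_to_json(cfg))
        assert back == cfg

    def test_unknown_key_rejected_with_path(self):
        text = ct.config_to_json(ct.RenderConfig()).replace(
            '"seed"', '"sneed"')
        with pytest.raises(ConfigValidationError, match="sneed"):
            ct.config_from_json(text)

    def test_wrong_type_rejected(self):
        obj = ct.RenderConfig().to_obj()
        obj["width_px"] = "wide"
        with pytest.raises(ConfigValidationError, match="width_px"):
            from celltree.render import RenderConfig
            RenderConfig.from_obj(obj)

    def test_version_required(self):
        obj = ct.RenderConfig().to_obj()
        del obj["version"]
        with pytest.raises(ConfigValidationError, match="version"):
            from celltree.render import RenderConfig
            RenderConfig.from_obj(obj)

    def test_embedded_history_replays_identically(self, random_tree, tmp_path):
        cfg = ct.RenderConfig(prune_history=ct.PruneHistory(
            [ct.PruneStep(ct.PruneKind.MIN_CELLS, 8)]))
        back = ct.config_from_json(ct.config_to_json(cfg))
        t1 = ct.apply_history(random_tree, cfg.prune_history)
        t2 = ct.apply_history(random_tree, back.prune_history)
        ct.write_tree_json(t1, tmp_path / "1.json")
        ct.write_tree_json(t2, tmp_path / "2.json")
        assert (tmp_path / "1.json").read_text() == (tmp_path / "2.json").read_text()

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigValidationError):
            ct.RenderConfig(global_scale=0)
        with pytest.raises(ConfigValidationError):
            ct.RenderConfig(export="pdf")
        with pytest.raises(ConfigValidationError):
            ct.RenderConfig(feature_overlays=[{}, {}, {}])
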