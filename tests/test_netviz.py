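import math

import numpy as np
import pandas as pd
import pytest

from mirtarnet import (
    InteractionTable,
    build_network,
    common_targets,
    fold_change_color,
    layout_network,
    load_case_study_tables,
    treemap_layout,
)
from mirtarnet.netviz import LAYOUT_METHODS


def table_from_edges(edges):
    rows = [{"mirna_id": m, "mrna_id": g, "correlation": True} for m, g in edges]
    return InteractionTable.from_frame(pd.DataFrame(rows))


def star(n_leaves, hub="m1"):
    return build_network(table_from_edges([(hub, f"g{i}") for i in range(n_leaves)]))


def random_network(rng, n_mirna=4, n_mrna=12):
    edges = set()
    for g in range(n_mrna):
        for m in rng.choice(n_mirna, size=rng.integers(1, 3), replace=False):
            edges.add((f"m{m}", f"g{g}"))
    return build_network(table_from_edges(sorted(edges)))


class TestBuildNetwork:
    def test_star_counts(self):
        net = star(3)
        assert len(net.mirna_nodes) == 1 and len(net.mrna_nodes) == 3
        assert len(net.edges) == 3

    def test_support_counts_true_flags(self):
        rows = [
            {
                "mirna_id": "m",
                "mrna_id": "g",
                "correlation": True,
                "genmir": True,
                "mine": True,
                "targetscan": True,
                "microrna_org": False,
            }
        ]
        net = build_network(InteractionTable.from_frame(pd.DataFrame(rows)))
        assert net.edges[0][2] == 4

    def test_empty_table_rejected(self):
        empty = InteractionTable(
            frame=pd.DataFrame(columns=["mirna_id", "mrna_id", "correlation"]),
            algorithms=["correlation"],
        )
        with pytest.raises(ValueError):
            build_network(empty)


class TestNodeLinkLayouts:
    def test_circular_equal_angular_gaps(self):
        net = star(6)
        lay = layout_network(net, "circular", seed=0)
        center = np.mean(list(lay.positions.values()), axis=0)
        angles = sorted(
            math.atan2(y - center[1], x - center[0]) for x, y in lay.positions.values()
        )
        gaps = np.diff(angles + [angles[0] + 2 * math.pi])
        assert np.allclose(gaps, 2 * math.pi / net.n_nodes)

    @pytest.mark.parametrize("method", LAYOUT_METHODS)
    def test_deterministic_given_seed_and_distinct_positions(self, method):
        net = random_network(np.random.default_rng(0))
        a = layout_network(net, method, seed=5)
        b = layout_network(net, method, seed=5)
        assert a.positions == b.positions
        pts = list(a.positions.values())
        assert len({tuple(np.round(p, 12)) for p in pts}) == len(pts)

    def test_post_pass_guarantees_separation_regardless_of_core_embedding(self):
        # the core embedding may crowd or coincide structurally equivalent
        # leaves; after the post-pass they are always strictly separated
        for seed in range(5):
            net = star(12)
            lay = layout_network(net, "isom_modified", seed=seed)
            pts = np.array(list(lay.positions.values()))
            dists = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(dists, np.inf)
            assert dists.min() > 0

    def test_modified_isom_scatters_star_leaves_evenly(self):
        net = star(6)
        lay = layout_network(net, "isom_modified", seed=1)
        c = np.array(lay.positions["m1"])
        leaves = [np.array(lay.positions[f"g{i}"]) for i in range(6)]
        radii = [np.linalg.norm(p - c) for p in leaves]
        assert np.allclose(radii, radii[0])
        angles = sorted(math.atan2(*(p - c)[::-1]) for p in leaves)
        gaps = np.diff(angles + [angles[0] + 2 * math.pi])
        assert np.allclose(gaps, 2 * math.pi / 6, atol=1e-9)

    def test_multi_star_leaves_stay_attached_to_their_hub(self):
        net = build_network(
            table_from_edges(
                [("m1", f"g{i}") for i in range(4)]
                + [("m2", f"h{i}") for i in range(3)]
                + [("m1", "shared"), ("m2", "shared")]
            )
        )
        lay = layout_network(net, "isom_modified", seed=2)
        for hub, prefix, count in (("m1", "g", 4), ("m2", "h", 3)):
            c = np.array(lay.positions[hub])
            radii = [
                np.linalg.norm(np.array(lay.positions[f"{prefix}{i}"]) - c)
                for i in range(count)
            ]
            assert np.allclose(radii, radii[0])
            assert radii[0] > 0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            layout_network(star(2), "sunflower", seed=0)


class TestTreemap:
    def test_single_pair_fills_canvas(self):
        net = star(1)
        tm = treemap_layout(net, 400, 300)
        (node, parent, x, y, w, h, depth) = tm.parents()[0]
        assert (x, y, w, h) == (0.0, 0.0, 400.0, 300.0)
        assert len(tm.leaves()) == 1

    def test_parent_area_proportional_to_target_count(self):
        net = build_network(
            table_from_edges([("A", f"g{i}") for i in range(3)] + [("B", "g9")])
        )
        tm = treemap_layout(net, 400, 300)
        areas = {r[0]: r[4] * r[5] for r in tm.parents()}
        assert areas["A"] == pytest.approx(3 * areas["B"])
        assert sum(areas.values()) == pytest.approx(120000)

    def test_shared_target_duplicated_under_each_parent(self):
        net = build_network(table_from_edges([("A", "g"), ("B", "g"), ("A", "h")]))
        tm = treemap_layout(net, 100, 100)
        assert sum(1 for r in tm.leaves() if r[0] == "g") == 2

    def test_area_conservation_and_leaf_count_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            net = random_network(rng)
            tm = treemap_layout(net, 640, 480)
            assert len(tm.leaves()) == len(net.edges)
            parents = {r[0]: r[4] * r[5] for r in tm.parents()}
            assert sum(parents.values()) == pytest.approx(640 * 480, rel=1e-9)
            leaf_acc = {}
            for r in tm.leaves():
                leaf_acc[r[1]] = leaf_acc.get(r[1], 0.0) + r[4] * r[5]
            for m, area in parents.items():
                assert leaf_acc[m] == pytest.approx(area, rel=1e-6)

    def test_nonpositive_canvas_rejected(self):
        with pytest.raises(ValueError):
            treemap_layout(star(2), 0, 100)


class TestCommonTargetsAndColor:
    def test_common_target_intersection(self):
        net = build_network(
            table_from_edges([("m1", "g1"), ("m1", "g2"), ("m2", "g2"), ("m2", "g3")])
        )
        assert common_targets(net, {"m1", "m2"}) == {"g2"}
        assert common_targets(net, {"m1"}) == {"g1", "g2"}

    def test_disjoint_mirnas_share_nothing(self):
        net = build_network(table_from_edges([("m1", "g1"), ("m2", "g2")]))
        assert common_targets(net, {"m1", "m2"}) == set()

    def test_unknown_mirna_is_lookup_error(self):
        with pytest.raises(KeyError):
            common_targets(star(2), {"mX"})

    def test_fold_change_color_saturation(self):
        assert fold_change_color(1.0) == (1.0, 1.0, 1.0)
        assert fold_change_color(4.0, cap=4.0) == (1.0, 0.0, 0.0)
        assert fold_change_color(-4.0, cap=4.0) == (0.0, 0.0, 1.0)
        # stronger up-regulation is more saturated red
        weak = fold_change_color(1.5, cap=4.0)
        strong = fold_change_color(3.0, cap=4.0)
        assert strong[1] < weak[1]

    def test_case_study_network_renders(self, tmp_path):
        non, _ = load_case_study_tables()
        net = build_network(non)
        lay = layout_network(net, "kk", seed=0)
        from mirtarnet.netviz import export_graphml, export_tsv, render_node_link

        export_graphml(net, tmp_path / "n.graphml")
        export_tsv(net, tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
        render_node_link(net, lay, tmp_path / "n.svg")
        assert (tmp_path / "n.svg").stat().st_size > 0
        assert len((tmp_path / "edges.tsv").read_text().splitlines()) == 46
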