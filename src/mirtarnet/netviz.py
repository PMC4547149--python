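"""Bipartite miRNA-target network construction, layouts and static export.

Node-link layouts come in four flavours: circular, force-directed
(Fruchterman-Reingold), Kamada-Kawai stress minimization, and a modified
inverted self-organizing-map (ISOM) embedding.  A plain topology-aware
embedding places all mRNAs that hang off one miRNA by a single link at the
same point; the modification re-places every degree-1 mRNA at equal angular
spacing on a circle around its miRNA, which is what makes the layout usable
for the hub-and-spoke structure typical of miRNA regulation.

The Treemap view converts the network into a two-level hierarchy (each miRNA
tile encloses one equal-area tile per target; shared targets are duplicated
under each parent) tiled with the squarified algorithm, so a miRNA's area is
proportional to its number of targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .interactions import InteractionTable

logger = logging.getLogger(__name__)

LAYOUT_METHODS = ("isom_modified", "kk", "force_directed", "circular")

#: fixed node colors for multisample data (no fold change to encode)
MULTISAMPLE_MIRNA_COLOR = (1.0, 0.65, 0.0)  # orange
MULTISAMPLE_MRNA_COLOR = (0.0, 0.0, 0.55)  # dark blue


@dataclass
class BipartiteNetwork:
    mirna_nodes: set[str]
    mrna_nodes: set[str]
    edges: list[tuple[str, str, int, frozenset]]  # (mirna, mrna, support, algorithms)
    node_fc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(m, g) for m, g, _, _ in self.edges]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate edge")
        for m, g, support, algos in self.edges:
            if m not in self.mirna_nodes or g not in self.mrna_nodes:
                raise ValueError(f"edge ({m}, {g}) does not connect miRNA to mRNA")
            if support != len(algos) or support < 1:
                raise ValueError("edge support must equal its algorithm count (>= 1)")

    def neighbors_of_mirna(self, mirna_id: str) -> set[str]:
        if mirna_id not in self.mirna_nodes:
            raise KeyError(f"unknown miRNA node {mirna_id!r}")
        return {g for m, g, _, _ in self.edges if m == mirna_id}

    def targets_per_mirna(self) -> dict[str, int]:
        counts = {m: 0 for m in self.mirna_nodes}
        for m, _, _, _ in self.edges:
            counts[m] += 1
        return counts

    def mrna_degree(self) -> dict[str, int]:
        deg = {g: 0 for g in self.mrna_nodes}
        for _, g, _, _ in self.edges:
            deg[g] += 1
        return deg

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for m in self.mirna_nodes:
            g.add_node(m, kind="miRNA", fc=self.node_fc.get(m, float("nan")))
        for t in self.mrna_nodes:
            g.add_node(t, kind="mRNA", fc=self.node_fc.get(t, float("nan")))
        for m, t, support, algos in self.edges:
            g.add_edge(m, t, support=support, algorithms=",".join(sorted(algos)))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.mirna_nodes) + len(self.mrna_nodes)


@dataclass
class NodeLayout:
    positions: dict[str, tuple[float, float]]
    method: str
    seed: int

    def __post_init__(self) -> None:
        for node, (x, y) in self.positions.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite position for {node!r}")


@dataclass
class TreemapLayout:
    # (node id, parent id or None, x, y, w, h, depth)
    rects: list[tuple[str, Optional[str], float, float, float, float, int]]
    canvas: tuple[float, float]

    def parents(self):
        return [r for r in self.rects if r[6] == 0]

    def leaves(self):
        return [r for r in self.rects if r[6] == 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rects, columns=["node", "parent", "x", "y", "w", "h", "depth"]
        )


def build_network(table: InteractionTable) -> BipartiteNetwork:
    """One edge per interaction row; support = number of TRUE flags."""
    if len(table) == 0:
        raise ValueError("cannot build a network from an empty interaction table")
    edges = []
    node_fc: dict[str, float] = {}
    for row in table.frame.itertuples():
        algos = frozenset(a for a in table.algorithms if getattr(row, a))
        edges.append((row.mirna_id, row.mrna_id, len(algos), algos))
        fc_m = getattr(row, "fc_mirna", None)
        if fc_m is not None and not pd.isna(fc_m):
            node_fc[row.mirna_id] = float(fc_m)
        fc_g = getattr(row, "fc_mrna", None)
        if fc_g is not None and not pd.isna(fc_g):
            node_fc[row.mrna_id] = float(fc_g)
    return BipartiteNetwork(
        mirna_nodes=table.mirna_ids(),
        mrna_nodes=table.mrna_ids(),
        edges=edges,
        node_fc=node_fc,
    )


# --------------------------------------------------------------------------
# node-link layouts


def _isom_embedding(g: nx.Graph, seed: int, epochs: int = 1500) -> dict:
    """Inverted self-organizing-map graph embedding.

    Each epoch draws a random stimulus point in the plane, finds the nearest
    node and pulls it plus its graph neighbourhood (BFS within the current
    radius) toward the stimulus, with learning rate and radius cooling over
    time.  Purely topology-driven, so structurally equivalent nodes collapse
    onto each other - by design; the caller's post-pass separates them.
    """
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    pos = {n: rng.uniform(0, 1, size=2) for n in nodes}
    r0, r1 = 3, 0
    lr0, lr1 = 0.8, 0.05
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        radius = int(round(r0 + (r1 - r0) * frac))
        lr = lr0 * (lr1 / lr0) ** frac
        stimulus = rng.uniform(0, 1, size=2)
        winner = min(nodes, key=lambda n: float(np.sum((pos[n] - stimulus) ** 2)))
        layers = {winner: 0}
        frontier = [winner]
        for depth in range(1, radius + 1):
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in layers:
                        layers[v] = depth
                        nxt.append(v)
            frontier = nxt
        for n, depth in layers.items():
            pos[n] = pos[n] + lr * 2.0**-depth * (stimulus - pos[n])
    return pos


def _normalize_unit_square(pos: dict, margin: float = 0.05) -> dict:
    pts = np.array(list(pos.values()), dtype=float)
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    span[span == 0] = 1.0
    return {
        n: tuple(margin + (1 - 2 * margin) * (np.asarray(p) - lo) / span)
        for n, p in pos.items()
    }


def _pack_components(g: nx.Graph, layout_one, seed: int) -> dict:
    """Lay out each connected component separately and pack them on a grid."""
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    k = len(comps)
    if k == 1:
        return _normalize_unit_square(layout_one(g.subgraph(comps[0]), seed))
    cols = math.ceil(math.sqrt(k))
    rows = math.ceil(k / cols)
    pos: dict = {}
    for i, comp in enumerate(comps):
        sub = _normalize_unit_square(layout_one(g.subgraph(comp), seed + i))
        r, c = divmod(i, cols)
        for n, (x, y) in sub.items():
            pos[n] = (c / cols + x / cols, r / rows + y / rows)
    return _normalize_unit_square(pos)


def _separate_duplicates(pos: dict, min_gap: float = 1e-9) -> dict:
    """Nudge exactly coincident core positions apart, deterministically."""
    seen: dict[tuple[float, float], int] = {}
    out = {}
    for n in sorted(pos):
        key = (round(pos[n][0], 12), round(pos[n][1], 12))
        count = seen.get(key, 0)
        seen[key] = count + 1
        if count == 0:
            out[n] = tuple(pos[n])
        else:
            angle = 2 * math.pi * (count % 8) / 8
            eps = 1e-4 * count
            out[n] = (pos[n][0] + eps * math.cos(angle), pos[n][1] + eps * math.sin(angle))
    return out


def layout_network(network: BipartiteNetwork, method: str, seed: int = 0) -> NodeLayout:
    """Compute one of the four node-link layouts, normalized to the unit square.

    Coordinates use the screen convention (origin top-left, y downward).
    Disconnected components are laid out separately and packed on a grid,
    except for the circular layout which spaces all nodes equally on one
    circle.
    """
    if method not in LAYOUT_METHODS:
        raise ValueError(f"unknown layout method {method!r}; choose from {LAYOUT_METHODS}")
    g = network.to_graph()
    nodes = sorted(g.nodes)

    if method == "circular":
        n = len(nodes)
        pos = {
            node: (0.5 + 0.45 * math.cos(2 * math.pi * i / n),
                   0.5 + 0.45 * math.sin(2 * math.pi * i / n))
            for i, node in enumerate(nodes)
        }
        return NodeLayout(positions=pos, method=method, seed=seed)

    if method == "force_directed":
        def one(sub, s):
            return nx.spring_layout(sub, seed=s, dim=2)
    elif method == "kk":
        def one(sub, s):
            if len(sub) == 1:
                return {next(iter(sub.nodes)): (0.5, 0.5)}
            return nx.kamada_kawai_layout(sub)
    else:  # isom_modified
        def one(sub, s):
            return _isom_embedding(sub, s)

    pos = _separate_duplicates(_pack_components(g, one, seed))

    if method == "isom_modified":
        pos = _scatter_single_link_targets(network, pos)
    return NodeLayout(positions={n: tuple(map(float, p)) for n, p in pos.items()},
                      method=method, seed=seed)


def _scatter_single_link_targets(network: BipartiteNetwork, pos: dict) -> dict:
    """Re-place every degree-1 mRNA on a circle around its only miRNA.

    Radius is 0.35x the distance to the nearest other miRNA (floor 0.02 in
    unit coordinates; 0.1 when the network has a single miRNA); the d
    targets sit at angles 0, 2*pi/d, ..., so gaps are exactly equal.
    """
    deg = network.mrna_degree()
    mirna_pos = {m: np.asarray(pos[m], dtype=float) for m in network.mirna_nodes}
    out = dict(pos)
    for m in sorted(network.mirna_nodes):
        singles = sorted(g for g in network.neighbors_of_mirna(m) if deg[g] == 1)
        if not singles:
            continue
        center = mirna_pos[m]
        others = [np.linalg.norm(center - q) for o, q in mirna_pos.items() if o != m]
        r = max(0.35 * min(others), 0.02) if others else 0.1
        d = len(singles)
        for i, g_id in enumerate(singles):
            angle = 2 * math.pi * i / d
            out[g_id] = (float(center[0] + r * math.cos(angle)),
                         float(center[1] + r * math.sin(angle)))
    return out


def common_targets(network: BipartiteNetwork, mirna_ids: Iterable[str]) -> set[str]:
    """mRNAs targeted by every one of the given miRNAs."""
    ids = list(mirna_ids)
    if not ids:
        return set()
    sets = [network.neighbors_of_mirna(m) for m in ids]
    return set.intersection(*sets)


# --------------------------------------------------------------------------
# treemap


def _squarify(sizes: list[float], x: float, y: float, w: float, h: float) -> list[tuple]:
    """Squarified tiling of ``sizes`` (already scaled to sum to w*h).

    Returns (x, y, w, h) per size, in input order.  Classic worst-aspect-ratio
    row packing; rows are laid along the shorter side of the remaining space.
    """
    out: list[Optional[tuple]] = [None] * len(sizes)
    order = sorted(range(len(sizes)), key=lambda i: (-sizes[i], i))
    remaining = [(order[i], sizes[order[i]]) for i in range(len(order))]

    def worst(row: list[float], side: float) -> float:
        total = sum(row)
        if total <= 0 or side <= 0:
            return math.inf
        mx, mn = max(row), min(row)
        return max(side**2 * mx / total**2, total**2 / (side**2 * mn))

    def place(row: list[tuple[int, float]], x, y, w, h):
        total = sum(s for _, s in row)
        if w >= h:  # row is a vertical strip of width total/h
            strip = total / h if h > 0 else 0
            cy = y
            for idx, s in row:
                rh = s / strip if strip > 0 else 0
                out[idx] = (x, cy, strip, rh)
                cy += rh
            return x + strip, y, w - strip, h
        strip = total / w if w > 0 else 0
        cx = x
        for idx, s in row:
            rw = s / strip if strip > 0 else 0
            out[idx] = (cx, y, rw, strip)
            cx += rw
        return x, y + strip, w, h - strip

    row: list[tuple[int, float]] = []
    while remaining:
        side = min(w, h)
        nxt = remaining[0]
        if not row or worst([s for _, s in row + [nxt]], side) <= worst(
            [s for _, s in row], side
        ):
            row.append(nxt)
            remaining.pop(0)
        else:
            x, y, w, h = place(row, x, y, w, h)
            row = []
    if row:
        x, y, w, h = place(row, x, y, w, h)
    return [r for r in out]  # type: ignore[return-value]


def treemap_layout(
    network: BipartiteNetwork, width: float = 400.0, height: float = 300.0
) -> TreemapLayout:
    """Two-level treemap: miRNA tiles (area proportional to target count)
    each enclosing equal-area tiles for their targets.

    An mRNA targeted by several miRNAs appears once under each parent, so the
    leaf count equals the network's edge count.
    """
    if width <= 0 or height <= 0:
        raise ValueError("canvas dimensions must be positive")
    counts = network.targets_per_mirna()
    mirnas = sorted(m for m in counts if counts[m] > 0)
    total = sum(counts[m] for m in mirnas)
    if total == 0:
        raise ValueError("network has no edges to lay out")
    area = width * height
    parent_sizes = [counts[m] / total * area for m in mirnas]
    parent_rects = _squarify(parent_sizes, 0.0, 0.0, width, height)

    rects: list[tuple] = []
    for m, (px, py, pw, ph) in zip(mirnas, parent_rects):
        rects.append((m, None, px, py, pw, ph, 0))
        targets = sorted(network.neighbors_of_mirna(m))
        leaf_sizes = [pw * ph / len(targets)] * len(targets)
        for g_id, (lx, ly, lw, lh) in zip(targets, _squarify(leaf_sizes, px, py, pw, ph)):
            rects.append((g_id, m, lx, ly, lw, lh, 1))
    return TreemapLayout(rects=rects, canvas=(width, height))


# --------------------------------------------------------------------------
# colors and export


def fold_change_color(fc: float, cap: float = 4.0) -> tuple[float, float, float]:
    """White-to-red for up-regulation, white-to-blue for down-regulation.

    Saturation grows linearly from 0 at |fc| = 1 to full at |fc| = cap
    (clamped), so a stronger fold change shows as a darker color.
    """
    if cap <= 1:
        raise ValueError("cap must exceed 1")
    s = min(max((abs(fc) - 1) / (cap - 1), 0.0), 1.0)
    if fc >= 0:
        return (1.0, 1.0 - s, 1.0 - s)
    return (1.0 - s, 1.0 - s, 1.0)


def export_graphml(network: BipartiteNetwork, path) -> None:
    nx.write_graphml(network.to_graph(), path)


def export_tsv(network: BipartiteNetwork, nodes_path, edges_path) -> None:
    nodes = [
        {"id": n, "kind": kind, "fc": network.node_fc.get(n, "")}
        for kind, group in (("miRNA", sorted(network.mirna_nodes)),
                            ("mRNA", sorted(network.mrna_nodes)))
        for n in group
    ]
    pd.DataFrame(nodes).to_csv(nodes_path, sep="\t", index=False)
    edges = [
        {"mirna_id": m, "mrna_id": g, "support": s, "algorithms": ",".join(sorted(a))}
        for m, g, s, a in sorted(network.edges)
    ]
    pd.DataFrame(edges).to_csv(edges_path, sep="\t", index=False)


def render_node_link(
    network: BipartiteNetwork,
    layout: NodeLayout,
    path,
    fc_cap: float = 4.0,
    base_width: float = 0.6,
) -> None:
    """Static node-link render; link width scales with algorithm support."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    for m, g, support, _ in network.edges:
        x0, y0 = layout.positions[m]
        x1, y1 = layout.positions[g]
        ax.plot([x0, x1], [y0, y1], color="0.6", lw=base_width * support, zorder=1)
    for n, (x, y) in layout.positions.items():
        if n in network.node_fc:
            color = fold_change_color(network.node_fc[n], cap=fc_cap)
        else:
            color = (
                MULTISAMPLE_MIRNA_COLOR if n in network.mirna_nodes else MULTISAMPLE_MRNA_COLOR
            )
        marker = "s" if n in network.mirna_nodes else "o"
        ax.scatter([x], [y], s=80, c=[color], marker=marker, edgecolors="black", zorder=2)
        ax.annotate(n, (x, y), fontsize=6, xytext=(2, 2), textcoords="offset points")
    ax.set_axis_off()
    ax.invert_yaxis()  # screen convention: origin top-left, y downward
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def render_treemap(
    network: BipartiteNetwork, layout: TreemapLayout, path, fc_cap: float = 4.0
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    w, h = layout.canvas
    fig, ax = plt.subplots(figsize=(8, 8 * h / w))
    for node, parent, x, y, rw, rh, depth in layout.rects:
        if depth == 0:
            ax.add_patch(Rectangle((x, y), rw, rh, fill=False, lw=2, edgecolor="black"))
            ax.annotate(node, (x + 2, y + 10), fontsize=7, weight="bold")
        else:
            if node in network.node_fc:
                color = fold_change_color(network.node_fc[node], cap=fc_cap)
            else:
                color = MULTISAMPLE_MRNA_COLOR
            ax.add_patch(
                Rectangle((x, y), rw, rh, facecolor=color, lw=0.5, edgecolor="0.4")
            )
            ax.annotate(node, (x + rw / 2, y + rh / 2), fontsize=5, ha="center", va="center")
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)  # y downward
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
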