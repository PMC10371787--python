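"""Stage B: guide-schematic layout of the domain-level graph.

The domain graph D is embedded in 2-D (or 3-D) with a Kamada-Kawai layout
whose target edge lengths are the physical domain lengths in bases, starting
from a deterministic circular arrangement of the scaffold nodes. An optional
force-refinement pass locally relaxes edge lengths. Layout quality is
measured by scale-optimal stress (the embedding is only a *guide* schematic:
topology is exact, geometry is approximate).

Exports are self-contained HTML files (inline SVG plus a small vanilla
JavaScript controller, no external assets) with three views: staple
colouring, scaffold routing, and junction ambiguity.
"""

from __future__ import annotations

import html
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .ambig import JunctionReport
from .contactmap import (
    DS_SCAFFOLD,
    SCAFFOLD_EDGE_KINDS,
    SS_SCAFFOLD,
    DomainGraph,
)
from .seqio import Design

log = logging.getLogger(__name__)


def _target_length(attrs: dict) -> float:
    """Ideal drawn length of one edge: base count for scaffold runs, one
    base-equivalent for point-like connections (nicks, crossovers), the
    unpaired base count plus one for loop-outs and dangles."""
    if attrs["kind"] in SCAFFOLD_EDGE_KINDS:
        return float(max(attrs["length"], 1))
    return float(1 + attrs.get("length", 0))


def _simple_graph(d: DomainGraph) -> nx.Graph:
    """Collapse the multigraph to a simple weighted graph for the layout;
    parallel edges keep the smallest target length (tightest constraint)."""
    g = nx.Graph()
    g.add_nodes_from(d.graph.nodes(data=True))
    for u, v, attrs in d.graph.edges(data=True):
        t = _target_length(attrs)
        if g.has_edge(u, v):
            g[u][v]["target"] = min(g[u][v]["target"], t)
        else:
            g.add_edge(u, v, target=t)
    return g


def _circular_init(nodes: list, g: nx.Graph, dimension: int, rng: np.random.Generator) -> dict:
    """Deterministic starting positions: nodes on a circle ordered by their
    scaffold position (synthetic nodes interleave by name at the end), which
    matches the scaffold's own cyclic order and avoids crossing-heavy
    random starts. 3-D adds a small seeded jitter on the extra axis."""

    def order_key(node):
        pos = g.nodes[node].get("scaffold_pos")
        return (0, pos, "") if pos is not None else (1, 0, str(node))

    ordered = sorted(nodes, key=order_key)
    m = len(ordered)
    radius = max(m / (2 * np.pi), 1.0)
    init = {}
    for k, node in enumerate(ordered):
        theta = 2 * np.pi * k / m
        xy = [radius * np.cos(theta), radius * np.sin(theta)]
        if dimension == 3:
            xy.append(float(rng.uniform(-0.1, 0.1) * radius))
        init[node] = np.asarray(xy, dtype=float)
    return init


def embed(d: DomainGraph, dimension: int = 2, seed: int = 0) -> dict:
    """Kamada-Kawai embedding of the domain graph, per connected component.

    Deterministic for a given (graph, dimension, seed). Components beyond
    the first (e.g. dangle-only fragments cannot occur, but defensive) are
    offset horizontally so they do not overlap.
    """
    if dimension not in (2, 3):
        raise ValueError("dimension must be 2 or 3")
    g = _simple_graph(d)
    rng = np.random.default_rng(seed)
    coords: dict = {}
    x_offset = 0.0
    for comp in sorted(nx.connected_components(g), key=lambda c: -len(c)):
        sub = g.subgraph(comp)
        nodes = list(comp)
        if len(nodes) == 1:
            pos = {nodes[0]: np.zeros(dimension)}
        else:
            init = _circular_init(nodes, g, dimension, rng)
            pos = nx.kamada_kawai_layout(
                sub, pos={k: v.tolist() for k, v in init.items()},
                weight="target", dim=dimension,
            )
            # restore physical scale (kamada_kawai normalises to [-1, 1])
            lens, targets = [], []
            for u, v, attrs in sub.edges(data=True):
                lens.append(float(np.linalg.norm(pos[u] - pos[v])))
                targets.append(attrs["target"])
            if lens and sum(lens) > 0:
                factor = sum(targets) / sum(lens)
                pos = {k: v * factor for k, v in pos.items()}
        arr = np.array([pos[nd] for nd in nodes], dtype=float)
        arr[:, 0] += x_offset - arr[:, 0].min()
        x_offset = arr[:, 0].max() + max(np.ptp(arr[:, 1]) if len(nodes) > 1 else 1.0, 1.0) * 0.2
        for nd, row in zip(nodes, arr):
            coords[nd] = row
    return coords


def stress(coords: dict, d: DomainGraph) -> float:
    """Scale-optimal normalised stress of an embedding.

    For graph distances d_ij (shortest paths over target edge lengths) and
    embedded distances e_ij, the reported value is
    ``min_s sum_ij ((s * e_ij - d_ij) / d_ij)^2 / n_pairs`` with the optimal
    scale in closed form, so it is invariant to uniform scaling. 0 is a
    perfect (usually unreachable) embedding.
    """
    g = _simple_graph(d)
    num = den = 0.0
    terms = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nodes = sorted(comp, key=str)
        dist = dict(nx.all_pairs_dijkstra_path_length(sub, weight="target"))
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                dij = dist[u][v]
                if dij <= 0:
                    continue
                eij = float(np.linalg.norm(coords[u] - coords[v]))
                num += eij / dij
                den += (eij / dij) ** 2
                terms.append((eij, dij))
    if not terms or den == 0:
        return 0.0
    s = num / den
    return float(sum(((s * e - dd) / dd) ** 2 for e, dd in terms) / len(terms))


def _edge_rms_error(coords: dict, g: nx.Graph) -> float:
    errs = []
    for u, v, attrs in g.edges(data=True):
        t = attrs["target"]
        e = float(np.linalg.norm(coords[u] - coords[v]))
        errs.append(((e - t) / t) ** 2)
    return float(np.sqrt(np.mean(errs))) if errs else 0.0


def refine(coords: dict, d: DomainGraph, iterations: int = 50, seed: int = 0,
           step: float = 0.05) -> dict:
    """Local force refinement: springs pull every edge toward its target
    length while a weak short-range repulsion separates non-adjacent nodes.

    ``iterations == 0`` returns a copy of the input. Deterministic. If the
    relative edge-length error worsens (repulsion can fight tight layouts),
    the pre-refinement coordinates are returned unchanged.
    """
    out = {k: np.array(v, dtype=float) for k, v in coords.items()}
    if iterations == 0:
        return out
    g = _simple_graph(d)
    nodes = sorted(g.nodes, key=str)
    index = {nd: i for i, nd in enumerate(nodes)}
    x = np.array([out[nd] for nd in nodes], dtype=float)
    edges = [(index[u], index[v], attrs["target"]) for u, v, attrs in g.edges(data=True)]
    adj = {(min(i, j), max(i, j)) for i, j, _ in edges}
    mean_t = float(np.mean([t for _, _, t in edges])) if edges else 1.0
    before = _edge_rms_error(out, g)
    for _ in range(iterations):
        force = np.zeros_like(x)
        for i, j, t in edges:
            delta = x[j] - x[i]
            dist = float(np.linalg.norm(delta)) or 1e-9
            f = (dist - t) / dist * delta  # spring toward target length
            force[i] += f
            force[j] -= f
        # weak repulsion between non-adjacent close pairs
        diff = x[:, None, :] - x[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        near = (dist < mean_t) & (dist > 0)
        for i, j in zip(*np.nonzero(near)):
            if i < j and (i, j) not in adj:
                push = (mean_t - dist[i, j]) / dist[i, j] * diff[i, j] * 0.25
                force[i] += push
                force[j] -= push
        x = x + step * force
    refined = {nd: x[index[nd]] for nd in nodes}
    after = _edge_rms_error(refined, g)
    if after > before:
        log.info("refinement rejected (edge error %.3f -> %.3f); keeping layout", before, after)
        return {k: np.array(v, dtype=float) for k, v in coords.items()}
    log.info("refinement accepted (edge error %.3f -> %.3f)", before, after)
    return refined


@dataclass
class GuideSchematic:
    """An embedded domain graph ready for export."""

    domain_graph: DomainGraph
    coords: dict
    dimension: int = 2
    stress: float = 0.0
    meta: dict = field(default_factory=dict)


def build_schematic(d: DomainGraph, dimension: int = 2, seed: int = 0,
                    refine_iterations: int = 50) -> GuideSchematic:
    """Embed, refine, and score the domain graph."""
    coords = embed(d, dimension=dimension, seed=seed)
    coords = refine(coords, d, iterations=refine_iterations, seed=seed)
    s = stress(coords, d)
    log.info("guide schematic: %d nodes, %d edges, stress %.4f",
             d.graph.number_of_nodes(), d.graph.number_of_edges(), s)
    return GuideSchematic(d, coords, dimension, s)


# ---------------------------------------------------------------------------
# HTML export
# ---------------------------------------------------------------------------

VIEWS = ("staples", "scaffold", "ambiguity")


def _staple_colour(sid: int) -> str:
    return f"hsl({(sid * 137.508) % 360:.0f},70%,45%)"


_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>__TITLE__</title>
<style>
 body { font-family: sans-serif; margin: 1em; }
 .edge { stroke-linecap: round; }
 .edge.scaffold-only { stroke: #888 !important; }
 .node { fill: #333; }
 .junction-ok { fill: #1a9641; }
 .junction-ambiguous { fill: #d7191c; }
 #info { margin-top: .5em; color: #333; min-height: 1.2em; font-size: 90%; }
 button.active { font-weight: bold; }
</style>
</head>
<body>
<h2>__TITLE__</h2>
<div id="controls">__BUTTONS__</div>
<svg id="canvas" viewBox="__VIEWBOX__" width="900" height="700"
     xmlns="http://www.w3.org/2000/svg">__SVG__</svg>
<div id="info">hover an element for details</div>
<script>
const DATA = __DATA__;
function setView(view) {
  for (const el of document.querySelectorAll('.edge'))
    el.classList.toggle('scaffold-only', view === 'scaffold');
  for (const el of document.querySelectorAll('.junction'))
    el.style.display = view === 'ambiguity' ? '' : 'none';
  for (const b of document.querySelectorAll('#controls button'))
    b.classList.toggle('active', b.dataset.view === view);
}
document.querySelectorAll('#controls button').forEach(b =>
  b.addEventListener('click', () => setView(b.dataset.view)));
document.querySelectorAll('[data-info]').forEach(el => {
  el.addEventListener('mouseenter', () =>
    document.getElementById('info').textContent = el.dataset.info);
  el.addEventListener('mouseleave', () =>
    document.getElementById('info').textContent = '');
});
setView('__VIEW__');
</script>
</body>
</html>
"""


def export_html(
    schematic: GuideSchematic,
    path: str | Path,
    view: str = "staples",
    design: Design | None = None,
    junctions: list[JunctionReport] | None = None,
    title: str = "Guide schematic",
) -> None:
    """Write a self-contained interactive HTML guide schematic.

    Views (switchable in the page, ``view`` picks the initial one):

    * ``staples`` -- double-stranded domains coloured per staple, tooltips
      with staple id (and sequence when ``design`` is given);
    * ``scaffold`` -- staple colouring suppressed, scaffold routing only;
    * ``ambiguity`` -- junction markers, green immovable / red ambiguous
      (requires ``junctions``; without them the view shows no markers).
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}")
    coords = {k: np.asarray(v, dtype=float)[:2] for k, v in schematic.coords.items()}
    xs = np.array([c[0] for c in coords.values()])
    ys = np.array([c[1] for c in coords.values()])
    pad = 0.05 * max(np.ptp(xs), np.ptp(ys), 1.0)
    viewbox = (f"{xs.min() - pad:.2f} {ys.min() - pad:.2f} "
               f"{np.ptp(xs) + 2 * pad:.2f} {np.ptp(ys) + 2 * pad:.2f}")
    scale = max(np.ptp(xs), np.ptp(ys), 1.0)
    stroke_ds = 0.012 * scale
    stroke_ss = 0.006 * scale
    r_node = 0.008 * scale
    r_junction = 0.014 * scale

    parts: list[str] = []
    for u, v, attrs in schematic.domain_graph.graph.edges(data=True):
        (x1, y1), (x2, y2) = coords[u], coords[v]
        kind = attrs["kind"]
        sid = attrs.get("staple_id")
        if kind == DS_SCAFFOLD:
            colour, width, dash = _staple_colour(sid), stroke_ds, ""
            info = f"staple {sid}: ds domain, {attrs['length']} bp at scaffold {attrs['start']}"
            if design is not None:
                info += f" | staple sequence {design.staples[sid].sequence}"
        elif kind == SS_SCAFFOLD:
            colour, width, dash = "#555", stroke_ss, ""
            info = f"ss scaffold, {attrs['length']} nt at scaffold {attrs['start']}"
        else:
            colour, width = ("#999", stroke_ss) if sid is None else (_staple_colour(sid), stroke_ss)
            dash = f' stroke-dasharray="{stroke_ss * 2:.3f}"'
            info = kind.replace("_", " ") + ("" if sid is None else f", staple {sid}")
        parts.append(
            f'<line class="edge" x1="{x1:.3f}" y1="{y1:.3f}" x2="{x2:.3f}" y2="{y2:.3f}"'
            f' stroke="{colour}" stroke-width="{width:.3f}"{dash}'
            f' data-info="{html.escape(info, quote=True)}"><title>'
            f"{html.escape(info)}</title></line>"
        )
    for nd, (x, y) in coords.items():
        parts.append(
            f'<circle class="node" cx="{x:.3f}" cy="{y:.3f}" r="{r_node:.3f}"'
            f' data-info="node {html.escape(str(nd), quote=True)}"/>'
        )
    n = schematic.domain_graph.n
    for rep in junctions or []:
        node = (rep.junction[1]) % n  # right domain's start node marks the boundary
        if node not in coords:
            continue
        x, y = coords[node]
        cls = "junction-ambiguous" if rep.ambiguous else "junction-ok"
        info = (f"junction at scaffold {rep.junction}: "
                f"{'ambiguous' if rep.ambiguous else 'immovable'} "
                f"(slack {rep.slack_left}+{rep.slack_right}), "
                f"staples {rep.staple_left}/{rep.staple_right}")
        parts.append(
            f'<circle class="junction {cls}" cx="{x:.3f}" cy="{y:.3f}"'
            f' r="{r_junction:.3f}" data-info="{html.escape(info, quote=True)}"/>'
        )

    data = {
        "stress": schematic.stress,
        "n": n,
        "view": view,
        "n_junctions": len(junctions or []),
    }
    buttons = "".join(
        f'<button data-view="{v}">{v}</button>' for v in VIEWS
    )
    page = (
        _HTML_TEMPLATE
        .replace("__TITLE__", html.escape(title))
        .replace("__BUTTONS__", buttons)
        .replace("__VIEWBOX__", viewbox)
        .replace("__SVG__", "\n".join(parts))
        .replace("__DATA__", json.dumps(data))
        .replace("__VIEW__", view)
    )
    Path(path).write_text(page)
    log.info("wrote guide schematic (%s view) to %s", view, path)
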