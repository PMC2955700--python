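"""File I/O and SVG rendering.

Networks travel as two-column TSV edge lists or Pajek ``.net`` files; labeled
square matrices as TSV/CSV with vertex ids in the first row and column;
layouts as TSV with full float precision.  Rendering writes a plain SVG with
one circle per vertex (solid/hollow by display class), intra-component edges
as line segments, optional background component-similarity lines, and one
label per component.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graph import validate_square_matrix

__all__ = [
    "read_network",
    "write_network",
    "read_vertex_class",
    "read_matrix",
    "write_matrix",
    "read_layout",
    "write_layout",
    "write_iteration_log",
    "RenderSpec",
    "render_svg",
]

_HEADER_TOKENS = {
    "source", "target", "from", "to", "node1", "node2",
    "vertex1", "vertex2", "v1", "v2", "id1", "id2",
}


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    if path.suffix.lower() == ".net":
        return "pajek"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "pajek" if line.lstrip().startswith("*") else "tsv"
    raise ValueError(f"empty file: {path}")


def read_network(path: str | Path, fmt: str = "auto") -> nx.Graph:
    """Read a network from a TSV edge list or a Pajek .net file.

    Pajek vertex numbering (1-based) is mapped back to the declared labels.
    TSV headers are detected by common column names in the first line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    if fmt == "pajek":
        multi = nx.read_pajek(path)
        graph = nx.Graph()
        graph.add_nodes_from(multi.nodes)
        graph.add_edges_from((u, v) for u, v in multi.edges() if u != v)
        return graph
    graph = nx.Graph()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty file: {path}")
    start = 0
    first = lines[0].replace(",", "\t").split("\t")
    if len(first) >= 2 and first[0].strip().lower() in _HEADER_TOKENS:
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = [f.strip() for f in line.replace(",", "\t").split("\t") if f.strip()]
        if len(fields) == 1:
            graph.add_node(fields[0])
            continue
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two vertex ids")
        u, v = fields[0], fields[1]  # optional third column (weight) is ignored
        if u != v:
            graph.add_edge(u, v)
        else:
            graph.add_node(u)
    if graph.number_of_nodes() == 0:
        raise ValueError(f"no vertices parsed from {path}")
    return graph


def write_network(path: str | Path, graph: nx.Graph, fmt: str = "pajek") -> None:
    """Write a network; Pajek preserves isolated vertices, TSV lists edges
    (and isolated vertices as single-field lines)."""
    path = Path(path)
    if fmt == "pajek":
        nx.write_pajek(graph, path)
        return
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u}\t{v}\n")
        for v, deg in graph.degree():
            if deg == 0:
                fh.write(f"{v}\n")


def read_vertex_class(path: str | Path) -> dict[str, int]:
    """Read an (id, 0/1) TSV mapping vertices to a binary display class."""
    classes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.replace(",", "\t").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>0/1'")
            flag = fields[1].strip()
            if flag not in {"0", "1"}:
                if lineno == 1:
                    continue  # header
                raise ValueError(f"{path}:{lineno}: class must be 0 or 1")
            classes[fields[0].strip()] = int(flag)
    return classes


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled square symmetric matrix from TSV/CSV."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    matrix.index = matrix.index.map(str)
    matrix.columns = matrix.columns.map(str)
    return validate_square_matrix(matrix)


def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    """Write a labeled matrix at full float precision (round-trip exact)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.to_csv(path, sep=sep, float_format="%.17g")


def write_layout(
    path: str | Path,
    layout: dict[str, np.ndarray],
    component_of: dict[str, int] | None = None,
) -> None:
    """Write a layout as TSV: vertex_id, component_index, x, y."""
    component_of = component_of or {}
    with open(path, "w") as fh:
        fh.write("vertex_id\tcomponent_index\tx\ty\n")
        for v, pos in layout.items():
            k = component_of.get(v, 0)
            fh.write(f"{v}\t{k}\t{float(pos[0])!r}\t{float(pos[1])!r}\n")


def read_layout(path: str | Path) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Read a layout TSV back; returns (coords, component index per vertex)."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"vertex_id": str}, float_precision="round_trip"
    )
    coords = {
        str(row.vertex_id): np.array([row.x, row.y], dtype=float)
        for row in frame.itertuples()
    }
    comp = {str(row.vertex_id): int(row.component_index) for row in frame.itertuples()}
    return coords, comp


def write_iteration_log(
    path: str | Path, log: list[tuple[int, float, float]]
) -> None:
    """Write a simulation convergence log as TSV (iteration, max_force,
    total_stress), e.g. for convergence plots."""
    with open(path, "w") as fh:
        fh.write("iteration\tmax_force\ttotal_stress\n")
        for it, max_force, stress in log:
            fh.write(f"{it}\t{float(max_force)!r}\t{float(stress)!r}\n")


@dataclass
class RenderSpec:
    """Visual conventions for the SVG rendering."""

    vertex_radius: float = 4.0
    show_similarity_lines: bool = True
    similarity_line_color: str = "#4a6fb5"
    similarity_line_width: float = 6.0  # width at weight 1
    label_components: bool = True
    width: int = 800
    height: int = 600
    margin: float = 40.0
    vertex_class: dict[str, int] = field(default_factory=dict)


def render_svg(
    path: str | Path,
    layout: dict[str, np.ndarray],
    network: nx.Graph,
    spec: RenderSpec | None = None,
    links: list[tuple[int, int, float]] | None = None,
    components: list[list[str]] | None = None,
) -> None:
    """Render the layout to an SVG file.

    Vertices are circles — solid for class 1, hollow for class 0/unknown —
    edges are segments within components, and optional background lines join
    similar components with width proportional to their similarity weight.
    Output is deterministic for fixed input.
    """
    spec = spec or RenderSpec()
    ids = list(layout)
    pts = np.asarray([layout[v] for v in ids], dtype=float)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    usable = np.array([spec.width - 2 * spec.margin, spec.height - 2 * spec.margin])
    scale = float(usable.min() / span.max())

    def to_px(p: np.ndarray) -> tuple[float, float]:
        x = spec.margin + (p[0] - lo[0]) * scale
        y = spec.height - spec.margin - (p[1] - lo[1]) * scale  # y grows upward
        return round(x, 2), round(y, 2)

    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=str(spec.width),
        height=str(spec.height),
        viewBox=f"0 0 {spec.width} {spec.height}",
    )
    centroids = {}
    if components:
        for k, block in enumerate(components):
            centroids[k] = np.mean([layout[v] for v in block], axis=0)
    if links and spec.show_similarity_lines and components:
        back = ET.SubElement(svg, "g", attrib={"class": "similarity-links"})
        for k, l, weight in links:
            (x1, y1), (x2, y2) = to_px(centroids[k]), to_px(centroids[l])
            ET.SubElement(
                back,
                "line",
                x1=str(x1), y1=str(y1), x2=str(x2), y2=str(y2),
                stroke=spec.similarity_line_color,
                attrib={
                    "stroke-width": f"{max(spec.similarity_line_width * weight, 0.5):.2f}",
                    "stroke-opacity": "0.5",
                },
            )
    edges = ET.SubElement(svg, "g", attrib={"class": "edges"})
    for u, v in network.edges():
        (x1, y1), (x2, y2) = to_px(layout[u]), to_px(layout[v])
        ET.SubElement(
            edges, "line",
            x1=str(x1), y1=str(y1), x2=str(x2), y2=str(y2),
            stroke="#555555", attrib={"stroke-width": "1"},
        )
    vertices = ET.SubElement(svg, "g", attrib={"class": "vertices"})
    for v in ids:
        x, y = to_px(layout[v])
        solid = spec.vertex_class.get(v, 0) == 1
        ET.SubElement(
            vertices, "circle",
            cx=str(x), cy=str(y), r=str(spec.vertex_radius),
            fill="#000000" if solid else "#ffffff",
            stroke="#000000", attrib={"stroke-width": "1"},
        )
    if spec.label_components and components:
        labels = ET.SubElement(svg, "g", attrib={"class": "component-labels"})
        for k in sorted(centroids):
            x, y = to_px(centroids[k])
            text = ET.SubElement(
                labels, "text", x=str(x), y=str(round(y - 3 * spec.vertex_radius, 2)),
                attrib={"text-anchor": "middle", "font-size": "10"},
            )
            text.text = f"C{k}"
    ET.ElementTree(svg).write(path, xml_declaration=True, encoding="unicode")
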