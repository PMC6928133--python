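"""Construction of the five virtual ablation lesion sets.

Protocols (clinical nomenclature):

1. ``CPVI``            — circumferential pulmonary-vein isolation: one closed
   ring around each ipsilateral PV pair.
2. ``CPVI+POBI``       — adds posterior box isolation: a roof line between the
   superior-PV rings plus an inferior posterior line between the inferior-PV
   rings, closing a box with the CPVI rings.
3. ``CPVI+POBI+AL``    — adds an anterior line from the anterior mitral
   annulus to the roof/right-superior-PV ring.
4. ``CPVI+RL+LLI``     — CPVI plus roof line and a left lateral isthmus line
   from the left-inferior-PV ring to the lateral mitral annulus.
5. ``CPVI+CFAE``       — CPVI plus electrogram-guided ablation of the
   shortest-cycle-length regions (CL < 120 ms, at most 5% of atrial area).

CPVI rings are geodesic distance bands around the PV antra: every surface
path from the veins to the atrial body must cross the band, so ring closure
holds by construction and is additionally verified by graph separation.
Linear lesions are widened graph geodesics anchored on the rings and the
annulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

from .cfae import CfaeMap
from .geometry import MonolayerMesh

PROTOCOL_NAMES = ("CPVI", "CPVI+POBI", "CPVI+POBI+AL", "CPVI+RL+LLI", "CPVI+CFAE")

DEFAULT_LESION_WIDTH_MM = 4.0
DEFAULT_ANTRAL_MARGIN_MM = 3.0
DEFAULT_CFAE_CL_THRESHOLD_MS = 120.0
DEFAULT_CFAE_AREA_CAP = 0.05


class LesionConstructionError(RuntimeError):
    """Raised when a lesion set cannot be realised on the mesh."""


@dataclass
class LesionSet:
    """A named ablation lesion: node set plus bookkeeping.

    ``area_mm2`` is always the sum of the member nodes' lumped areas.
    """

    protocol: str
    nodes: np.ndarray
    width_mm: float
    area_mm2: float

    @classmethod
    def from_nodes(
        cls, mesh: MonolayerMesh, protocol: str, nodes: np.ndarray, width_mm: float
    ) -> "LesionSet":
        nodes = np.unique(np.asarray(nodes, dtype=np.int64))
        nodes = nodes[~mesh.nonconductive_mask[nodes]]
        return cls(protocol, nodes, width_mm, float(mesh.node_area[nodes].sum()))

    def union(self, other: "LesionSet", protocol: str, mesh: MonolayerMesh) -> "LesionSet":
        return LesionSet.from_nodes(
            mesh, protocol, np.union1d(self.nodes, other.nodes), self.width_mm
        )

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "width_mm": self.width_mm,
            "area_mm2": self.area_mm2,
            "nodes": self.nodes.tolist(),
        }


# ---------------------------------------------------------------------------
# graph helpers
# ---------------------------------------------------------------------------


def _conduction_graph(mesh: MonolayerMesh, removed: np.ndarray | None = None) -> sp.csr_matrix:
    """Edge-length graph restricted to conductive (and non-removed) nodes."""
    g = mesh.surface.adjacency_graph().tolil(copy=True)
    blocked = np.flatnonzero(mesh.nonconductive_mask)
    if removed is not None and len(removed):
        blocked = np.union1d(blocked, removed)
    g[blocked, :] = 0.0
    g[:, blocked] = 0.0
    return g.tocsr()


def _multi_source_distance(graph: sp.csr_matrix, sources: np.ndarray) -> np.ndarray:
    d = dijkstra(graph, directed=False, indices=sources, min_only=True)
    return d


def separates(
    mesh: MonolayerMesh, lesion_nodes: np.ndarray, inside: np.ndarray, outside: np.ndarray
) -> bool:
    """True if removing the lesion disconnects every inside node from every outside node."""
    g = _conduction_graph(mesh, removed=lesion_nodes)
    _, labels = connected_components(g, directed=False)
    ins = np.setdiff1d(inside, lesion_nodes)
    outs = np.setdiff1d(outside, lesion_nodes)
    if len(ins) == 0 or len(outs) == 0:
        return True
    # nodes zeroed out of the graph become singletons; compare only real components
    return len(np.intersect1d(labels[ins], labels[outs])) == 0


def _geodesic_band(
    mesh: MonolayerMesh, sources: np.ndarray, inner_mm: float, outer_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nodes at geodesic distance [inner, outer) from the source set.

    Returns (band nodes, distances to all nodes).  Because graph distance
    changes by at most one edge length per hop, a band wider than the longest
    edge is a closed separating curve around the sources.
    """
    g = _conduction_graph(mesh)
    d = _multi_source_distance(g, sources)
    band = np.flatnonzero((d >= inner_mm) & (d < outer_mm) & ~mesh.nonconductive_mask)
    return band, d


def _widen_path(mesh: MonolayerMesh, path: list[int], half_width_mm: float) -> np.ndarray:
    g = _conduction_graph(mesh)
    d = _multi_source_distance(g, np.asarray(path, dtype=np.int64))
    return np.flatnonzero(np.isfinite(d) & (d <= half_width_mm))


def _landmark_centroid(mesh: MonolayerMesh, name: str) -> np.ndarray:
    idx = mesh.surface.landmark_sets[name]
    return mesh.surface.vertices[idx].mean(axis=0)


def _nearest_in_set(mesh: MonolayerMesh, nodes: np.ndarray, point: np.ndarray) -> int:
    v = mesh.surface.vertices[nodes]
    return int(nodes[np.argmin(np.linalg.norm(v - point, axis=1))])


def _nearest_conductive(mesh: MonolayerMesh, point: np.ndarray) -> int:
    free = mesh.conductive_nodes
    return _nearest_in_set(mesh, free, point)


def _shortest_path(mesh: MonolayerMesh, src: int, dst: int) -> list[int]:
    g = _conduction_graph(mesh)
    dist, pred = dijkstra(g, directed=False, indices=src, return_predecessors=True)
    if not np.isfinite(dist[dst]):
        raise LesionConstructionError(f"no conductive path between nodes {src} and {dst}")
    path = [int(dst)]
    while path[-1] != src:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def _max_edge_length(mesh: MonolayerMesh) -> float:
    e = mesh.surface.edges()
    v = mesh.surface.vertices
    return float(np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1).max())


# ---------------------------------------------------------------------------
# CPVI
# ---------------------------------------------------------------------------


def build_cpvi(
    mesh: MonolayerMesh,
    width_mm: float = DEFAULT_LESION_WIDTH_MM,
    antral_margin_mm: float = DEFAULT_ANTRAL_MARGIN_MM,
    verify: bool = True,
) -> LesionSet:
    """Two closed rings, each encircling an ipsilateral PV pair.

    Each ring is the geodesic band [margin, margin + width) around the union
    of the pair's PV node sets, which guarantees closure when the band is
    wider than the longest mesh edge; closure is re-verified by graph
    separation of the veins from the atrial body.
    """
    width = max(width_mm, 1.05 * _max_edge_length(mesh))
    nodes = []
    lm = mesh.surface.landmark_sets
    for pair in (("LSPV", "LIPV"), ("RSPV", "RIPV")):
        sources = np.union1d(lm[pair[0]], lm[pair[1]])
        sources = sources[~mesh.nonconductive_mask[sources]]
        band, dist = _geodesic_band(mesh, sources, antral_margin_mm, antral_margin_mm + width)
        if len(band) == 0:
            raise LesionConstructionError(f"empty CPVI ring for pair {pair}")
        if verify:
            inside = np.flatnonzero(np.isfinite(dist) & (dist < antral_margin_mm))
            body = np.array([int(np.nanargmax(np.where(np.isfinite(dist), dist, -1)))])
            if not separates(mesh, band, inside, body):
                raise LesionConstructionError(f"CPVI ring around {pair} is not closed")
            if len(np.setdiff1d(inside, band)) == 0:
                raise LesionConstructionError(f"CPVI ring around {pair} left no PV-side nodes")
        nodes.append(band)
    return LesionSet.from_nodes(mesh, "CPVI", np.concatenate(nodes), width)


# ---------------------------------------------------------------------------
# Linear lesions
# ---------------------------------------------------------------------------

LINEAR_LESION_NAMES = ("POBI", "AL", "RL", "LLI")


def _ring_node_sets(mesh: MonolayerMesh, cpvi: LesionSet) -> dict[str, np.ndarray]:
    """Split the CPVI node set into per-PV rings by nearest PV centroid."""
    out = {}
    cents = {n: _landmark_centroid(mesh, n) for n in ("LSPV", "LIPV", "RSPV", "RIPV")}
    v = mesh.surface.vertices[cpvi.nodes]
    names = list(cents)
    dmat = np.stack([np.linalg.norm(v - cents[n], axis=1) for n in names])
    nearest = np.argmin(dmat, axis=0)
    for k, n in enumerate(names):
        out[n] = cpvi.nodes[nearest == k]
    return out


def linear_lesion_paths(
    mesh: MonolayerMesh,
    which: str,
    cpvi: LesionSet | None = None,
    width_mm: float = DEFAULT_LESION_WIDTH_MM,
) -> list[list[int]]:
    """Centre path(s) of a linear lesion as ordered node lists.

    ``POBI`` returns two paths (roof line, inferior posterior line); the
    other lesions return one.
    """
    if which not in LINEAR_LESION_NAMES:
        raise ValueError(f"unknown linear lesion '{which}'")
    for name in ("LSPV", "LIPV", "RSPV", "RIPV", "mitral_annulus", "roof_apex"):
        if name not in mesh.surface.landmark_sets:
            raise LesionConstructionError(f"missing landmark '{name}'")
    if cpvi is None:
        cpvi = build_cpvi(mesh, width_mm)
    rings = _ring_node_sets(mesh, cpvi)
    roof_c = _landmark_centroid(mesh, "roof_apex")
    ann_c = _landmark_centroid(mesh, "mitral_annulus")

    def roof_line() -> list[int]:
        a = _nearest_in_set(mesh, rings["LSPV"], roof_c)
        b = _nearest_in_set(mesh, rings["RSPV"], roof_c)
        return _shortest_path(mesh, a, b)

    if which == "RL":
        return [roof_line()]
    if which == "POBI":
        # inferior posterior line between the annulus-facing sides of the
        # inferior-PV rings closes the box together with the roof line
        a = _nearest_in_set(mesh, rings["LIPV"], ann_c)
        b = _nearest_in_set(mesh, rings["RIPV"], ann_c)
        return [roof_line(), _shortest_path(mesh, a, b)]
    if which == "AL":
        ann_anterior = mesh.surface.vertices[
            _nearest_in_set(
                mesh,
                mesh.surface.landmark_sets["mitral_annulus"],
                _landmark_centroid(mesh, "bachmann_site"),
            )
        ]
        a = _nearest_conductive(mesh, ann_anterior)
        b = _nearest_in_set(mesh, rings["RSPV"], roof_c)
        return [_shortest_path(mesh, a, b)]
    # LLI
    lipv_c = _landmark_centroid(mesh, "LIPV")
    a = _nearest_in_set(mesh, rings["LIPV"], ann_c)
    ann_lateral = mesh.surface.vertices[
        _nearest_in_set(mesh, mesh.surface.landmark_sets["mitral_annulus"], lipv_c)
    ]
    b = _nearest_conductive(mesh, ann_lateral)
    return [_shortest_path(mesh, a, b)]


def build_linear_lesions(
    mesh: MonolayerMesh,
    which: str,
    cpvi: LesionSet | None = None,
    width_mm: float = DEFAULT_LESION_WIDTH_MM,
) -> LesionSet:
    """One of the four linear lesions: ``POBI``, ``AL``, ``RL`` or ``LLI``.

    * ``RL``   — roof line between the superior-PV sides of the two CPVI rings.
    * ``POBI`` — roof line plus an inferior posterior line between the
      inferior-PV sides (the posterior box closes with the CPVI rings).
    * ``AL``   — anterior mitral annulus to the roof/right-superior ring.
    * ``LLI``  — left-inferior ring to the lateral mitral annulus.

    Paths are graph geodesics on the conductive mesh, widened to the full
    lesion width (nodes within width/2 of the centre path).
    """
    paths = linear_lesion_paths(mesh, which, cpvi, width_mm)
    width = max(width_mm, 1.05 * _max_edge_length(mesh))
    half = 0.5 * width
    nodes = np.unique(np.concatenate([_widen_path(mesh, p, half) for p in paths]))
    if len(nodes) == 0:
        raise LesionConstructionError(f"linear lesion '{which}' is empty")
    return LesionSet.from_nodes(mesh, which, nodes, width)


# ---------------------------------------------------------------------------
# CFAE-guided lesions
# ---------------------------------------------------------------------------


def build_cfae_lesions(
    mesh: MonolayerMesh,
    cfae_map: CfaeMap,
    cl_threshold: float = DEFAULT_CFAE_CL_THRESHOLD_MS,
    area_cap_fraction: float = DEFAULT_CFAE_AREA_CAP,
) -> LesionSet:
    """Greedy shortest-cycle-length ablation under the area cap.

    Nodes with CL below ``cl_threshold`` are taken in ascending CL order
    (ties broken by node index) for as long as the cumulative ablated area
    stays strictly below ``area_cap_fraction`` of the total conductive area.
    May return an empty set.
    """
    cl = cfae_map.cycle_length
    conductive = mesh.conductive_nodes
    total_area = float(mesh.node_area[conductive].sum())
    cap = area_cap_fraction * total_area
    cand = conductive[np.isfinite(cl[conductive]) & (cl[conductive] < cl_threshold)]
    order = cand[np.lexsort((cand, cl[cand]))]
    chosen = []
    cum = 0.0
    eps = 1e-9 * max(cap, 1.0)  # guard float accumulation at the cap boundary
    for i in order:
        a = float(mesh.node_area[i])
        if cum + a >= cap - eps:
            break
        chosen.append(int(i))
        cum += a
    return LesionSet.from_nodes(
        mesh, "CFAE", np.asarray(chosen, dtype=np.int64), DEFAULT_LESION_WIDTH_MM
    )


# ---------------------------------------------------------------------------
# Protocol assembly
# ---------------------------------------------------------------------------


def build_protocol_lesions(
    mesh: MonolayerMesh,
    protocol: str,
    cfae_map: CfaeMap | None = None,
    width_mm: float = DEFAULT_LESION_WIDTH_MM,
    cl_threshold: float = DEFAULT_CFAE_CL_THRESHOLD_MS,
    area_cap_fraction: float = DEFAULT_CFAE_AREA_CAP,
) -> LesionSet:
    """Full lesion set of one of the five named ablation protocols."""
    if protocol not in PROTOCOL_NAMES:
        raise ValueError(f"unknown protocol '{protocol}'; choose from {PROTOCOL_NAMES}")
    cpvi = build_cpvi(mesh, width_mm)
    out = LesionSet(protocol, cpvi.nodes, cpvi.width_mm, cpvi.area_mm2)
    if protocol == "CPVI":
        return out
    if protocol in ("CPVI+POBI", "CPVI+POBI+AL"):
        out = out.union(build_linear_lesions(mesh, "POBI", cpvi, width_mm), protocol, mesh)
        if protocol == "CPVI+POBI+AL":
            out = out.union(build_linear_lesions(mesh, "AL", cpvi, width_mm), protocol, mesh)
        return out
    if protocol == "CPVI+RL+LLI":
        out = out.union(build_linear_lesions(mesh, "RL", cpvi, width_mm), protocol, mesh)
        out = out.union(build_linear_lesions(mesh, "LLI", cpvi, width_mm), protocol, mesh)
        return out
    # CPVI+CFAE
    if cfae_map is None:
        raise ValueError("protocol CPVI+CFAE needs a CFAE cycle-length map")
    return out.union(
        build_cfae_lesions(mesh, cfae_map, cl_threshold, area_cap_fraction), protocol, mesh
    )
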