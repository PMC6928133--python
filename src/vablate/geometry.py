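"""Left-atrial surface geometry: synthetic generation, monolayer extrusion, geodesics.

The simulator represents the atrial wall as a triangulated surface carrying a
monolayer of excitable tissue.  Each surface node owns a barycentric patch of
area (one third of every incident triangle) and a constant wall thickness, so
prism volumes enter the diffusion discretization without storing a volumetric
mesh.  All coordinates are millimetres; node indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import ConvexHull

LANDMARK_NAMES = (
    "RSPV",
    "RIPV",
    "LSPV",
    "LIPV",
    "mitral_annulus",
    "laa_ostium",
    "bachmann_site",
    "roof_apex",
)

PV_NAMES = ("RSPV", "RIPV", "LSPV", "LIPV")


class MeshValidationError(ValueError):
    """Raised when a surface mesh violates a structural requirement."""


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangulated atrial surface with named anatomical landmark node sets.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array of vertex indices
    landmark_sets : mapping from landmark name to integer node-index array.
        The canonical names are the four PV ostia (``RSPV``, ``RIPV``,
        ``LSPV``, ``LIPV``), ``mitral_annulus``, ``laa_ostium``,
        ``bachmann_site`` and ``roof_apex``.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    landmark_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.landmark_sets = {
            k: np.unique(np.asarray(v, dtype=np.int64))
            for k, v in self.landmark_sets.items()
        }

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    # -- derived quantities -------------------------------------------------

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (k, 2) sorted-index array."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cr = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric node areas: each triangle contributes one third per vertex."""
        areas = self.triangle_areas()
        va = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(va, self.triangles[:, k], areas / 3.0)
        return va

    def adjacency_graph(self) -> sp.csr_matrix:
        """Symmetric sparse matrix of edge lengths (mm) for path computations."""
        e = self.edges()
        d = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        g = sp.coo_matrix(
            (np.concatenate([d, d]), (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n),
        )
        return g.tocsr()

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_triangles

    def boundary_edges(self) -> np.ndarray:
        """Edges referenced by exactly one triangle (hole rims)."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    # -- validation ---------------------------------------------------------

    def validate(self, require_landmarks: bool = True) -> None:
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= self.n_vertices:
            raise MeshValidationError("triangle refers to an out-of-range vertex index")
        # edge-manifold: no edge shared by more than two triangles
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        if (counts > 2).any():
            raise MeshValidationError(
                f"mesh is not edge-manifold: {(counts > 2).sum()} edges shared by >2 triangles"
            )
        if require_landmarks:
            missing = [n for n in LANDMARK_NAMES if n not in self.landmark_sets]
            if missing:
                raise MeshValidationError(f"missing landmark sets: {missing}")
            graph = self.adjacency_graph()
            for name, idx in self.landmark_sets.items():
                if len(idx) == 0:
                    raise MeshValidationError(f"landmark set '{name}' is empty")
                if idx.min() < 0 or idx.max() >= self.n_vertices:
                    raise MeshValidationError(f"landmark set '{name}' has invalid indices")
                if len(idx) > 1:
                    sub = graph[np.ix_(idx, idx)]
                    ncomp, _ = connected_components(sub, directed=False)
                    if ncomp != 1:
                        raise MeshValidationError(
                            f"landmark set '{name}' is not connected on the mesh graph"
                        )


@dataclass
class MonolayerMesh:
    """Surface mesh extruded to a constant-thickness tissue monolayer.

    One prism per surface triangle; membrane state lives on surface nodes.
    ``adjacency`` holds the clamped cotangent edge weights used by the
    diffusion operator; ``nonconductive_mask`` marks nodes excluded from
    conduction (the mitral annulus by default).
    """

    surface: SurfaceMesh
    thickness: float
    node_area: np.ndarray
    adjacency: sp.csr_matrix
    nonconductive_mask: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.surface.n_vertices

    @property
    def n_prisms(self) -> int:
        return self.surface.n_triangles

    @property
    def conductive_nodes(self) -> np.ndarray:
        return np.flatnonzero(~self.nonconductive_mask)

    def total_area(self) -> float:
        return float(self.node_area.sum())

    def shell_volume(self) -> float:
        return self.total_area() * self.thickness


@dataclass
class SyntheticLAParams:
    """Parameters of the synthetic left-atrium generator.

    Defaults give a chamber comparable to a mildly dilated human LA
    (antero-posterior diameter ~45 mm): an ellipsoidal shell with four
    pulmonary-vein tubes on the posterior wall, a mitral-annulus opening and
    an appendage bulge.
    """

    semi_axes: tuple[float, float, float] = (33.0, 28.0, 26.0)
    pv_tube_radius: float = 5.5
    pv_tube_length: float = 9.0
    annulus_radius: float = 12.0
    target_node_count: int = 2500
    random_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0 or min(
            self.pv_tube_radius, self.pv_tube_length, self.annulus_radius
        ) <= 0:
            raise ValueError("all lengths must be positive")
        if self.target_node_count < 500:
            raise ValueError("target_node_count must be >= 500")


# ---------------------------------------------------------------------------
# Synthetic LA generation
# ---------------------------------------------------------------------------

# Unit directions on the reference sphere.  Convention: +z superior (roof),
# +y posterior, +x patient-left; the mitral annulus opens antero-inferiorly.
_FEATURE_DIRS = {
    "LSPV": (0.72, 0.50, 0.48),
    "LIPV": (0.78, 0.54, -0.33),
    "RSPV": (-0.72, 0.50, 0.48),
    "RIPV": (-0.78, 0.54, -0.33),
    "mitral_annulus": (0.0, -0.52, -0.85),
    "laa": (0.72, -0.58, 0.38),
    "bachmann_site": (-0.42, -0.62, 0.66),
    "roof_apex": (0.0, 0.12, 0.99),
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _fibonacci_sphere(n: int, offset: float) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=np.float64)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * ((i / phi + offset) % 1.0)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _orient_outward(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Flip hull triangles so normals point away from the centroid."""
    c = points.mean(axis=0)
    p0, p1, p2 = points[simplices[:, 0]], points[simplices[:, 1]], points[simplices[:, 2]]
    n = np.cross(p1 - p0, p2 - p0)
    flip = np.einsum("ij,ij->i", n, p0 - c) < 0
    out = simplices.copy()
    out[flip] = out[flip][:, [0, 2, 1]]
    return out


def _smooth_bump(s: np.ndarray) -> np.ndarray:
    """C1 bump: 1 at s=0, 0 for s>=1."""
    out = np.zeros_like(s)
    m = s < 1.0
    out[m] = 0.5 * (1.0 + np.cos(np.pi * s[m]))
    return out


def generate_synthetic_la(params: SyntheticLAParams | None = None) -> SurfaceMesh:
    """Build a synthetic landmarked left-atrial surface.

    The shell is a golden-spiral sphere triangulated by its convex hull,
    scaled to the ellipsoidal semi-axes, with smooth outward protrusions for
    the four pulmonary veins and the appendage.  PV tube tips and the
    mitral-annulus cap are opened (faces removed), so the result is a sphere
    with five boundary holes (Euler characteristic 2 - 5 = -3).  Deterministic
    for a fixed ``random_seed``; the seed perturbs the lattice phase, the
    semi-axes and the PV directions to emulate anatomical variability.
    """
    if params is None:
        params = SyntheticLAParams()
    rng = np.random.default_rng(params.random_seed)

    offset = rng.uniform(0.0, 1.0)
    semi = np.asarray(params.semi_axes) * (1.0 + 0.05 * rng.uniform(-1, 1, size=3))
    mean_r = float(np.cbrt(np.prod(semi)))

    dirs = {}
    for name, d in _FEATURE_DIRS.items():
        d = np.asarray(d, dtype=np.float64)
        if name in PV_NAMES:
            d = d + rng.normal(scale=0.03, size=3)
        dirs[name] = _unit(d)

    # feasibility: openings must not overlap
    ann_theta = params.annulus_radius / mean_r
    pv_theta = 1.35 * params.pv_tube_radius / mean_r
    feats = list(PV_NAMES) + ["mitral_annulus"]
    radii = {n: (pv_theta if n in PV_NAMES else ann_theta) for n in feats}
    for a in range(len(feats)):
        for b in range(a + 1, len(feats)):
            gap = np.arccos(np.clip(dirs[feats[a]] @ dirs[feats[b]], -1, 1))
            if gap < radii[feats[a]] + radii[feats[b]]:
                raise ValueError(
                    f"infeasible geometry: openings {feats[a]} and {feats[b]} overlap"
                )

    pts = _fibonacci_sphere(params.target_node_count, offset)
    hull = ConvexHull(pts)
    tris = _orient_outward(pts, hull.simplices.astype(np.int64))

    # ellipsoid scaling then feature displacement along feature axes
    verts = pts * semi
    ang = {n: np.arccos(np.clip(pts @ dirs[n], -1.0, 1.0)) for n in dirs}
    for name in PV_NAMES:
        bump = _smooth_bump(ang[name] / pv_theta)
        verts += np.outer(bump * params.pv_tube_length, dirs[name])
    laa_theta = 2.1 * pv_theta
    verts += np.outer(
        _smooth_bump(ang["laa"] / laa_theta) * 0.9 * params.pv_tube_length, dirs["laa"]
    )

    # open holes: PV tube tips and the mitral annulus cap
    drop_vertex = np.zeros(len(verts), dtype=bool)
    tip_theta = 0.45 * pv_theta
    for name in PV_NAMES:
        drop_vertex |= ang[name] < tip_theta
    drop_vertex |= ang["mitral_annulus"] < ann_theta
    keep_face = ~drop_vertex[tris].any(axis=1)
    tris = tris[keep_face]

    used = np.unique(tris)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    verts_new = verts[used]
    tris_new = remap[tris]
    ang = {n: a[used] for n, a in ang.items()}

    mesh = SurfaceMesh(verts_new, tris_new, {})

    # landmarks
    boundary = np.unique(mesh.boundary_edges())
    lm: dict[str, np.ndarray] = {}
    for name in PV_NAMES:
        lm[name] = np.flatnonzero(ang[name] <= 1.02 * pv_theta)
    lm["mitral_annulus"] = np.intersect1d(
        boundary, np.flatnonzero(ang["mitral_annulus"] <= 1.6 * ann_theta)
    )
    lm["laa_ostium"] = np.flatnonzero(ang["laa"] <= 0.55 * laa_theta)
    graph = mesh.adjacency_graph()
    for name in ("bachmann_site", "roof_apex"):
        seed_vertex = int(np.argmin(ang[name]))
        lm[name] = _geodesic_disk(graph, seed_vertex, 2.0)
    for name, idx in lm.items():
        lm[name] = _largest_connected_subset(graph, idx)
    mesh.landmark_sets = {k: np.asarray(v, dtype=np.int64) for k, v in lm.items()}
    mesh.validate()
    return mesh


def _geodesic_disk(graph: sp.csr_matrix, seed: int, radius_mm: float) -> np.ndarray:
    d = dijkstra(graph, directed=False, indices=seed, limit=radius_mm * 1.001)
    return np.flatnonzero(np.isfinite(d))


def _largest_connected_subset(graph: sp.csr_matrix, idx: np.ndarray) -> np.ndarray:
    if len(idx) <= 1:
        return idx
    sub = graph[np.ix_(idx, idx)]
    ncomp, labels = connected_components(sub, directed=False)
    if ncomp == 1:
        return idx
    counts = np.bincount(labels)
    return idx[labels == np.argmax(counts)]


# ---------------------------------------------------------------------------
# Monolayer extrusion and diffusion-weight assembly
# ---------------------------------------------------------------------------

DEFAULT_THICKNESS_MM = 1.89


def cotangent_weights(mesh: SurfaceMesh, clamp: bool = True) -> sp.csr_matrix:
    """Symmetric cotangent edge-weight matrix of the surface.

    w_ij = (cot a + cot b)/2 over the one or two triangles sharing edge ij.
    Negative weights from obtuse triangles are clamped to zero so that the
    discrete diffusion operator stays monotone.
    """
    v = mesh.vertices
    t = mesh.triangles
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    for k in range(3):
        i = t[:, (k + 1) % 3]
        j = t[:, (k + 2) % 3]
        o = t[:, k]
        e1 = v[i] - v[o]
        e2 = v[j] - v[o]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-12)
        rows.append(i)
        cols.append(j)
        vals.append(0.5 * cot)
    w = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    w = w + w.T
    if clamp:
        w.data = np.maximum(w.data, 0.0)
    w.eliminate_zeros()
    return w


def extrude_monolayer(
    surface: SurfaceMesh,
    thickness: float = DEFAULT_THICKNESS_MM,
    validate: bool = True,
) -> MonolayerMesh:
    """Extrude the surface into a constant-thickness prism monolayer.

    One prism per triangle; node areas follow the barycentric one-third rule;
    the mitral annulus landmark set is flagged non-conductive.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if validate:
        surface.validate(require_landmarks=False)
    areas = surface.triangle_areas()
    degenerate = np.flatnonzero(areas < 1e-10)
    if len(degenerate):
        raise MeshValidationError(f"degenerate triangles at indices {degenerate.tolist()}")
    node_area = surface.vertex_areas()
    adjacency = cotangent_weights(surface)
    nonconductive = np.zeros(surface.n_vertices, dtype=bool)
    if "mitral_annulus" in surface.landmark_sets:
        nonconductive[surface.landmark_sets["mitral_annulus"]] = True
    return MonolayerMesh(
        surface=surface,
        thickness=float(thickness),
        node_area=node_area,
        adjacency=adjacency,
        nonconductive_mask=nonconductive,
    )


# ---------------------------------------------------------------------------
# Geodesics
# ---------------------------------------------------------------------------


class PathError(RuntimeError):
    """Raised when no conductive path exists between the requested nodes."""


def geodesic_path(
    mesh: MonolayerMesh | SurfaceMesh,
    src_node: int,
    dst_node: int,
    conductive_only: bool = True,
) -> list[int]:
    """Shortest edge-path between two nodes (graph geodesic, mm edge weights).

    On a :class:`MonolayerMesh` with ``conductive_only`` the path avoids
    non-conductive nodes.  Returns the ordered node list from src to dst.
    """
    if isinstance(mesh, MonolayerMesh):
        graph = mesh.surface.adjacency_graph()
        if conductive_only:
            blocked = np.flatnonzero(mesh.nonconductive_mask)
            if src_node in blocked or dst_node in blocked:
                raise PathError("endpoint lies on non-conductive tissue")
            mask = sp.lil_matrix(graph.shape)
            graph = graph.tolil()
            graph[blocked, :] = 0
            graph[:, blocked] = 0
            graph = graph.tocsr()
            del mask
    else:
        graph = mesh.adjacency_graph()
    if src_node == dst_node:
        return [int(src_node)]
    dist, pred = dijkstra(
        graph, directed=False, indices=src_node, return_predecessors=True
    )
    if not np.isfinite(dist[dst_node]):
        raise PathError(f"nodes {src_node} and {dst_node} are not connected")
    path = [int(dst_node)]
    while path[-1] != src_node:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def rectangular_strip(
    length_mm: float = 40.0,
    width_mm: float = 8.0,
    spacing_mm: float = 0.5,
    thickness: float = DEFAULT_THICKNESS_MM,
) -> MonolayerMesh:
    """Flat rectangular tissue strip used for conduction-velocity measurement.

    Structured triangulated grid in the z=0 plane, x in [0, length], y in
    [0, width], with alternating diagonals to avoid a preferred direction.
    """
    nx = int(round(length_mm / spacing_mm)) + 1
    ny = int(round(width_mm / spacing_mm)) + 1
    xs = np.linspace(0.0, length_mm, nx)
    ys = np.linspace(0.0, width_mm, ny)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(nx * ny)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            c = (i + 1) * ny + j + 1
            d = i * ny + j + 1
            if (i + j) % 2 == 0:
                tris.append((a, b, c))
                tris.append((a, c, d))
            else:
                tris.append((a, b, d))
                tris.append((b, c, d))
    surf = SurfaceMesh(verts, np.asarray(tris, dtype=np.int64), {})
    return extrude_monolayer(surf, thickness=thickness, validate=False)


def path_length(mesh: MonolayerMesh | SurfaceMesh, path: list[int]) -> float:
    surf = mesh.surface if isinstance(mesh, MonolayerMesh) else mesh
    v = surf.vertices
    if len(path) < 2:
        return 0.0
    p = np.asarray(path)
    return float(np.linalg.norm(v[p[1:]] - v[p[:-1]], axis=1).sum())
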