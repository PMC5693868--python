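"""Cross-section mesh of the early embryo.

The embryo is modelled as a circular epithelium of columnar cells sandwiched
between the rigid vitelline membrane (outer circle, radius ``R_v``) and the
yolk (the region enclosed by the basal cell surfaces).  Each cell is a
quadrilateral sector whose membrane is subdivided into ``lateral_sections``
segments along each apico-basal side and ``apical_sections`` /
``basal_sections`` segments along the apical and basal sides.  The membrane
subdivision induces a grid of ``lateral_sections x apical_sections``
quadrilateral sub-regions per cell (15 by default) that act as the viscous
finite elements of the cytoplasm.

Conventions
-----------
* The embryo centre is at the origin.  The dorso-ventral (DV) angle ``theta``
  is measured in degrees with the ventral midline at 0 deg and the dorsal
  midline at +-180 deg; ``theta`` increases counter-clockwise and the mesh is
  mirror symmetric about the DV axis (``theta -> -theta`` maps ``x -> -x``).
* Lateral membranes are shared between neighbouring cells (one node set);
  the interior subdivision nodes of apical and basal sides are private to
  each cell, so the ring is watertight by construction.
* Cell boundary loops are ordered counter-clockwise (positive shoelace area).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "GeometryConfig",
    "EmbryoMesh",
    "DomainLabels",
    "DOMAIN_NAMES",
    "build_embryo",
    "assign_domains",
    "cell_metrics",
    "polygon_area",
    "polyline_length",
    "polyline_midpoint",
]

DOMAIN_NAMES = ("central_mesoderm", "lateral_mesoderm", "mesectoderm", "ectoderm")


class GeometryError(ValueError):
    """Raised for inconsistent geometry configuration or degenerate meshes."""


class GeometryConfig(BaseModel):
    """Geometry block of the run configuration.

    ``inner_radius``/``vitelline_radius`` default to a columnar initial
    aspect (cell height : apical width of roughly 6:1, i.e. ~35 um tall,
    ~6 um wide cells for a ~100 um embryo radius, in arbitrary length units
    of ~5 um).  The apical surface starts in contact with the vitelline
    membrane (outer cell radius equals ``vitelline_radius``).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_cells: int = 84
    vitelline_radius: float = 20.0
    inner_radius: float = 13.0
    apical_sections: int = 3
    basal_sections: int = 3
    lateral_sections: int = 5

    @model_validator(mode="after")
    def _check(self) -> "GeometryConfig":
        if self.n_cells < 4:
            raise ValueError("n_cells must be >= 4")
        if self.inner_radius <= 0 or self.vitelline_radius <= 0:
            raise ValueError("radii must be positive")
        if not self.inner_radius < self.vitelline_radius:
            raise ValueError("inner_radius must be < vitelline_radius")
        if self.apical_sections != self.basal_sections:
            raise ValueError(
                "apical_sections and basal_sections must match (grid elements)"
            )
        if min(self.apical_sections, self.lateral_sections) < 1:
            raise ValueError("section counts must be >= 1")
        return self


def _unit(theta_deg: np.ndarray) -> np.ndarray:
    """Unit vector for DV angle: ventral (0 deg) points down, dorsal up."""
    t = np.deg2rad(np.asarray(theta_deg, dtype=float))
    return np.stack([np.sin(t), -np.cos(t)], axis=-1)


@dataclass(frozen=True)
class EmbryoMesh:
    """Watertight ring mesh of the embryo cross-section.

    Attributes
    ----------
    nodes : (N, 2) array of initial node positions.
    loops : (n_cells, P) int array; per-cell boundary node loop (CCW).
    elements : (n_cells, n_elements_per_cell, 4) int array of quadrilateral
        sub-regions, indexed into the *extended* point set (real nodes
        followed by per-cell interior Coons points).
    triangles : (T, 3) int array of constant-strain-rate triangles over the
        extended point set (a 4-fan around each element quad's centroid).
    extension : sparse (N_ext, N) operator mapping node positions to the
        extended point set (identity rows for real nodes, fixed Coons
        weights for interior grid points, corner averages for quad
        centroids).
    yolk_loop : ordered (CCW) node loop of the yolk boundary (union of the
        basal sides).
    """

    config: GeometryConfig
    nodes: np.ndarray
    ray_ids: np.ndarray        # (n_cells, L+1) shared lateral nodes, basal->apical
    apical_ids: np.ndarray     # (n_cells, A-1) private apical interior nodes
    basal_ids: np.ndarray      # (n_cells, A-1) private basal interior nodes
    loops: np.ndarray          # (n_cells, 2L + 2A) CCW cell boundary loops
    theta_cells: np.ndarray    # (n_cells,) cell-centre DV angle, degrees
    apical_edges: np.ndarray   # (n_cells * A, 2)
    apical_edge_cell: np.ndarray
    basal_edges: np.ndarray
    basal_edge_cell: np.ndarray
    lateral_edges: np.ndarray  # (n_cells * L, 2)
    lateral_edge_cells: np.ndarray  # (n_cells * L, 2) the two cells sharing the edge
    yolk_loop: np.ndarray
    elements: np.ndarray
    triangles: np.ndarray
    tri_cell: np.ndarray
    extension: sp.csr_matrix = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.config.n_cells

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def vitelline_radius(self) -> float:
        return self.config.vitelline_radius

    @property
    def n_elements_per_cell(self) -> int:
        return self.config.lateral_sections * self.config.apical_sections

    def extended_points(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Real nodes followed by Coons-interpolated interior grid points."""
        x = self.nodes if positions is None else positions
        return self.extension @ x

    def cell_polygons(self, positions: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if positions is None else positions
        return x[self.loops]

    def yolk_area(self, positions: np.ndarray | None = None) -> float:
        x = self.nodes if positions is None else positions
        return polygon_area(x[self.yolk_loop])

    def cell_areas(self, positions: np.ndarray | None = None) -> np.ndarray:
        return shoelace_batch(self.cell_polygons(positions))

    def to_json_dict(self, positions: np.ndarray | None = None) -> dict:
        """Documented JSON snapshot (node array, cell loops, angles)."""
        x = self.nodes if positions is None else positions
        return {
            "config": self.config.model_dump(),
            "nodes": np.asarray(x).tolist(),
            "cell_loops": self.loops.tolist(),
            "theta_deg": self.theta_cells.tolist(),
            "yolk_loop": self.yolk_loop.tolist(),
        }


def expected_node_count(config: GeometryConfig) -> int:
    """Closed-form node count of the subdivision scheme.

    Per cell: one shared lateral ray of ``L+1`` nodes plus ``A-1`` private
    apical and ``B-1`` private basal interior nodes.
    """
    n, L, A, B = (
        config.n_cells,
        config.lateral_sections,
        config.apical_sections,
        config.basal_sections,
    )
    return n * ((L + 1) + (A - 1) + (B - 1))


def build_embryo(config: GeometryConfig | None = None) -> EmbryoMesh:
    """Construct the circular epithelium mesh (84 cells by default).

    Deterministic for a given config; rebuilding yields bit-identical arrays.
    """
    config = config or GeometryConfig()
    n = config.n_cells
    L = config.lateral_sections
    A = config.apical_sections
    R_i = config.inner_radius
    R_o = config.vitelline_radius  # apical surface initially on the vitelline

    delta = 360.0 / n
    # Ray i sits at the boundary between cells i-1 and i; cell k is centred
    # at theta = k * delta (cell 0 on the ventral midline).
    ray_theta = (np.arange(n) - 0.5) * delta
    radii = R_i + (R_o - R_i) * np.arange(L + 1) / L

    nodes = []
    ray_ids = np.arange(n * (L + 1)).reshape(n, L + 1)
    for i in range(n):
        nodes.append(_unit(np.full(L + 1, ray_theta[i])) * radii[:, None])
    offset = n * (L + 1)
    apical_ids = offset + np.arange(n * (A - 1)).reshape(n, A - 1)
    offset += n * (A - 1)
    basal_ids = offset + np.arange(n * (A - 1)).reshape(n, A - 1)
    interior_theta = np.array([(c / A) * delta for c in range(1, A)])
    for k in range(n):
        nodes.append(_unit(ray_theta[k] + interior_theta) * R_o)
    for k in range(n):
        nodes.append(_unit(ray_theta[k] + interior_theta) * R_i)
    nodes = np.concatenate(nodes, axis=0)

    theta_cells = np.arange(n) * delta
    theta_cells = (theta_cells + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
    theta_cells[np.isclose(theta_cells, -180.0)] = 180.0

    right = np.roll(np.arange(n), -1)  # right ray of cell k is ray k+1
    # CCW loop: left lateral basal->apical, apical left->right (interior),
    # right lateral apical->basal, basal right->left (interior).
    loops = np.concatenate(
        [
            ray_ids,                      # left ray, basal -> apical
            apical_ids,                   # apical interior, left -> right
            ray_ids[right, ::-1],         # right ray, apical -> basal
            basal_ids[:, ::-1],           # basal interior, right -> left
        ],
        axis=1,
    )

    # Membrane edges.
    apical_chain = np.concatenate(
        [ray_ids[:, -1:], apical_ids, ray_ids[right, -1:]], axis=1
    )
    basal_chain = np.concatenate(
        [ray_ids[:, :1], basal_ids, ray_ids[right, :1]], axis=1
    )
    apical_edges = np.stack(
        [apical_chain[:, :-1].ravel(), apical_chain[:, 1:].ravel()], axis=1
    )
    basal_edges = np.stack(
        [basal_chain[:, :-1].ravel(), basal_chain[:, 1:].ravel()], axis=1
    )
    apical_edge_cell = np.repeat(np.arange(n), A)
    basal_edge_cell = np.repeat(np.arange(n), A)
    lateral_edges = np.stack(
        [ray_ids[:, :-1].ravel(), ray_ids[:, 1:].ravel()], axis=1
    )
    left_cell = np.repeat((np.arange(n) - 1) % n, L)
    lateral_edge_cells = np.stack([left_cell, np.repeat(np.arange(n), L)], axis=1)

    # Yolk boundary: basal corners and interior nodes ordered CCW (+theta).
    yolk_loop = np.concatenate([ray_ids[:, :1], basal_ids], axis=1).ravel()

    # Extended point set: real nodes + 8 interior Coons grid points per cell.
    # Grid G[j, c]: j = 0..L (basal->apical), c = 0..A (left->right ray).
    n_real = nodes.shape[0]
    grid = np.empty((n, L + 1, A + 1), dtype=int)
    grid[:, :, 0] = ray_ids
    grid[:, :, A] = ray_ids[right]
    grid[:, 0, 1:A] = basal_ids
    grid[:, L, 1:A] = apical_ids
    n_int = (L - 1) * (A - 1)
    for k in range(n):
        ids = n_real + k * n_int + np.arange(n_int).reshape(L - 1, A - 1)
        grid[k, 1:L, 1:A] = ids

    rows, cols, vals = [], [], []
    rows.extend(range(n_real))
    cols.extend(range(n_real))
    vals.extend([1.0] * n_real)
    for j in range(1, L):
        for c in range(1, A):
            s, t = j / L, c / A
            # Transfinite (Coons) blend of the four boundary chains.
            stencil = [
                (0, c, 1 - s), (L, c, s), (j, 0, 1 - t), (j, A, t),
                (0, 0, -(1 - s) * (1 - t)), (0, A, -(1 - s) * t),
                (L, 0, -s * (1 - t)), (L, A, -s * t),
            ]
            for k in range(n):
                r = grid[k, j, c]
                for (jj, cc, w) in stencil:
                    rows.append(r)
                    cols.append(grid[k, jj, cc])
                    vals.append(w)
    extension = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n_real + n * n_int, n_real)
    )

    # Element quads (j, c) -> corners CCW.  Each quad is triangulated by a
    # 4-fan around its centroid (a fixed affine blend of the corners); the
    # fan is invariant under reflection, so the viscous operator respects
    # the mesh's mirror symmetry, which a single-diagonal split would break.
    elements = np.empty((n, L * A, 4), dtype=int)
    for j in range(L):
        for c in range(A):
            e = j * A + c
            elements[:, e, 0] = grid[:, j, c]
            elements[:, e, 1] = grid[:, j + 1, c]
            elements[:, e, 2] = grid[:, j + 1, c + 1]
            elements[:, e, 3] = grid[:, j, c + 1]
    n_ext0 = extension.shape[0]
    n_quads = n * L * A
    flat_elems = elements.reshape(-1, 4)
    Q = sp.coo_matrix(
        (
            np.full(4 * n_quads, 0.25),
            (np.repeat(np.arange(n_quads), 4), flat_elems.ravel()),
        ),
        shape=(n_quads, n_ext0),
    )
    extension = sp.vstack([extension, Q @ extension]).tocsr()
    centroid_ids = n_ext0 + np.arange(n_quads)
    tris = []
    for a, b2 in ((0, 1), (1, 2), (2, 3), (3, 0)):
        tris.append(
            np.stack([flat_elems[:, a], flat_elems[:, b2], centroid_ids], axis=1)
        )
    triangles = np.concatenate(
        [t[:, None, :] for t in tris], axis=1
    ).reshape(-1, 3)
    tri_cell = np.repeat(np.arange(n), 4 * L * A)

    return EmbryoMesh(
        config=config,
        nodes=nodes,
        ray_ids=ray_ids,
        apical_ids=apical_ids,
        basal_ids=basal_ids,
        loops=loops,
        theta_cells=theta_cells,
        apical_edges=apical_edges,
        apical_edge_cell=apical_edge_cell,
        basal_edges=basal_edges,
        basal_edge_cell=basal_edge_cell,
        lateral_edges=lateral_edges,
        lateral_edge_cells=lateral_edge_cells,
        yolk_loop=yolk_loop,
        elements=elements,
        triangles=triangles,
        tri_cell=tri_cell,
        extension=extension,
    )


# ---------------------------------------------------------------------------
# Domain labels
# ---------------------------------------------------------------------------

class DomainBands(BaseModel):
    """Symmetric DV bands: cutoffs (degrees) of |theta| for the three inner
    domains; everything beyond ``mesectoderm`` is ectoderm.

    The published cross-section shows the domains only as colour bands, so
    the defaults are approximate: 12 central-mesoderm cells, 3 lateral
    mesoderm and 2 mesectoderm cells per side for the default 84-cell ring.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    central_mesoderm: float = 25.8
    lateral_mesoderm: float = 38.6
    mesectoderm: float = 47.2

    @model_validator(mode="after")
    def _check(self) -> "DomainBands":
        cuts = [self.central_mesoderm, self.lateral_mesoderm, self.mesectoderm]
        if any(c <= 0 for c in cuts) or any(c >= 180 for c in cuts):
            raise ValueError("band cutoffs must lie in (0, 180) degrees")
        if not (cuts[0] < cuts[1] < cuts[2]):
            raise ValueError(
                "band cutoffs must be strictly increasing "
                "(overlapping or non-covering bands)"
            )
        return self


@dataclass(frozen=True)
class DomainLabels:
    """Per-cell domain label and DV angle (ventral = 0 deg, dorsal = +-180)."""

    labels: np.ndarray      # (n_cells,) strings from DOMAIN_NAMES
    theta_deg: np.ndarray   # (n_cells,)
    bands: DomainBands

    def cells(self, domain: str) -> np.ndarray:
        if domain not in DOMAIN_NAMES:
            raise ValueError(f"unknown domain {domain!r}")
        return np.flatnonzero(self.labels == domain)


def assign_domains(
    mesh: EmbryoMesh, bands: DomainBands | None = None
) -> DomainLabels:
    """Label cells by DV angle into the four domains.

    Bands are symmetric about the ventral midline by construction; the cell
    nearest theta = 0 is central mesoderm and the cell nearest +-180 deg is
    ectoderm.
    """
    bands = bands or DomainBands()
    a = np.abs(mesh.theta_cells)
    labels = np.full(mesh.n_cells, "ectoderm", dtype=object)
    labels[a <= bands.mesectoderm] = "mesectoderm"
    labels[a <= bands.lateral_mesoderm] = "lateral_mesoderm"
    labels[a <= bands.central_mesoderm] = "central_mesoderm"
    return DomainLabels(labels=labels.astype(str), theta_deg=mesh.theta_cells.copy(),
                        bands=bands)


# ---------------------------------------------------------------------------
# Polygon / polyline primitives and per-cell metrics
# ---------------------------------------------------------------------------

def polygon_area(poly: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as (P, 2) vertices."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def shoelace_batch(polys: np.ndarray) -> np.ndarray:
    """Signed areas of a (n, P, 2) batch of polygons."""
    x, y = polys[..., 0], polys[..., 1]
    return 0.5 * np.sum(
        x * np.roll(y, -1, axis=-1) - np.roll(x, -1, axis=-1) * y, axis=-1
    )


def polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def polyline_midpoint(points: np.ndarray) -> np.ndarray:
    """Arc-length midpoint of an open polyline."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        return points[0].astype(float)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    half = total / 2.0
    i = int(np.searchsorted(s, half, side="right") - 1)
    i = min(i, len(seg) - 1)
    f = (half - s[i]) / seg[i] if seg[i] > 0 else 0.0
    return points[i] + f * (points[i + 1] - points[i])


def _apical_chain_points(mesh: EmbryoMesh, positions: np.ndarray) -> np.ndarray:
    right = np.roll(np.arange(mesh.n_cells), -1)
    ids = np.concatenate(
        [mesh.ray_ids[:, -1:], mesh.apical_ids, mesh.ray_ids[right, -1:]], axis=1
    )
    return positions[ids]


def _basal_chain_points(mesh: EmbryoMesh, positions: np.ndarray) -> np.ndarray:
    right = np.roll(np.arange(mesh.n_cells), -1)
    ids = np.concatenate(
        [mesh.ray_ids[:, :1], mesh.basal_ids, mesh.ray_ids[right, :1]], axis=1
    )
    return positions[ids]


def cell_metrics(
    mesh: EmbryoMesh, positions: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-cell area, apical width and height for one node configuration.

    area
        shoelace area of the boundary loop;
    apical_width
        length of the apical polyline;
    height
        distance between the arc-length midpoints of the apical and basal
        sides.
    """
    x = mesh.nodes if positions is None else np.asarray(positions, dtype=float)
    if x.shape != mesh.nodes.shape:
        raise GeometryError(
            f"positions shape {x.shape} incongruent with mesh ({mesh.nodes.shape})"
        )
    polys = mesh.cell_polygons(x)
    areas = shoelace_batch(polys)
    bad = np.flatnonzero(areas <= 0)
    if bad.size:
        raise GeometryError(f"degenerate (non-positive area) cell polygon: cell {bad[0]}")
    apical = _apical_chain_points(mesh, x)
    basal = _basal_chain_points(mesh, x)
    widths = np.sum(np.linalg.norm(np.diff(apical, axis=1), axis=2), axis=1)
    heights = np.linalg.norm(
        np.array([polyline_midpoint(a) for a in apical])
        - np.array([polyline_midpoint(b) for b in basal]),
        axis=1,
    )
    return pd.DataFrame(
        {
            "cell": np.arange(mesh.n_cells),
            "theta_deg": mesh.theta_cells,
            "area": areas,
            "apical_width": widths,
            "height": heights,
        }
    )


def polygon_aspect_ratio(poly: np.ndarray) -> float:
    """Major/minor axis ratio of the best-fit (second-moment) ellipse.

    Computed from the area moments of the polygon interior; for an a x b
    rectangle this returns a/b.
    """
    x, y = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    A = 0.5 * np.sum(cross)
    if A <= 0:
        raise GeometryError("aspect ratio undefined for degenerate polygon")
    cx = np.sum((x + x1) * cross) / (6 * A)
    cy = np.sum((y + y1) * cross) / (6 * A)
    xs, ys = x - cx, y - cy
    xs1, ys1 = np.roll(xs, -1), np.roll(ys, -1)
    c = xs * ys1 - xs1 * ys
    Ixx = np.sum(c * (ys * ys + ys * ys1 + ys1 * ys1)) / 12.0
    Iyy = np.sum(c * (xs * xs + xs * xs1 + xs1 * xs1)) / 12.0
    Ixy = np.sum(c * (xs * ys1 + 2 * xs * ys + 2 * xs1 * ys1 + xs1 * ys)) / 24.0
    cov = np.array([[Iyy, Ixy], [Ixy, Ixx]]) / A
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 1e-300, None)
    return float(np.sqrt(lam[1] / lam[0]))
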