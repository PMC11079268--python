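"""Computational geometry: pre-shrink, zero-stress opening map, layered meshing.

The imaged (in vivo) slice is pressurized and axially stretched, so model
construction walks backwards: contours are shrunk circumferentially and
axially to a candidate no-load state, then the closed no-load ring is cut
open into a stress-free sector.  The opening construction imposes the two
classical conservation assumptions exactly: (1) wall area (volume per unit
thickness) is conserved, and (2) the circumference of the middle line of the
wall is unchanged.  The opening angle OA follows Fung's tip-angle
convention, giving a sector central angle  Theta_s = 2*(pi - OA).

With r the closed-configuration radius about the lumen centroid and
r_m the mean midwall radius, the map is

    Theta = (Theta_s / 2*pi) * theta
    R_m   = (2*pi / Theta_s) * r_m            (midwall-length conservation)
    R(r)^2 = R_m^2 + (2*pi/Theta_s) * (r^2 - r_m^2)   (local area conservation)

which preserves area element-wise (R dR dTheta = r dr dtheta) for arbitrary
star-shaped contours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath

from .contours import Component, LayeredContourSet, INTERFACES, LAYERS


# --------------------------------------------------------------------------- shrink
def shrink_contours(contours: LayeredContourSet, s_circ: float,
                    s_axial: float = 0.05):
    """Pre-shrink the in vivo contours toward the no-load candidate state.

    Radial coordinates about the lumen centroid (and component polygons) are
    scaled by (1 - s_circ).  The axial shrink is not a geometric operation on
    the slice; it is returned as the target in vivo axial stretch
    lambda_z = 1/(1 - s_axial) to be applied by the mechanics stage.

    Returns (shrunk_contours, lambda_z).
    """
    if not (0.0 <= s_circ < 0.5):
        raise ValueError("s_circ must be in [0, 0.5)")
    if not (0.0 <= s_axial < 0.5):
        raise ValueError("s_axial must be in [0, 0.5)")
    lam_z = 1.0 / (1.0 - s_axial)
    return contours.scaled(1.0 - s_circ), lam_z


# --------------------------------------------------------------------------- opening
@dataclass
class OpenSectorGeometry:
    """The zero-stress opened configuration of one slice.

    The sector occupies Theta in [0, sector_angle] about the origin; the
    closed source contours are retained so meshes can carry exact
    closed-configuration preimages for the wrap (closure) step.
    """

    sector_angle: float  # Theta_s, rad
    opening_angle_deg: float
    angles: np.ndarray  # opened angular samples Theta (same count as closed)
    radii: dict  # interface name -> R(Theta)
    midwall_radius_opened: float  # R_m, mm
    midwall_radius_closed: float  # r_m, mm
    closed: LayeredContourSet = None
    components: list = field(default_factory=list)  # mapped polygons (mm)

    @property
    def k(self) -> float:
        """Area-map factor 2*pi / Theta_s."""
        return 2.0 * np.pi / self.sector_angle

    def map_radius(self, r):
        """Closed radius -> opened radius."""
        r = np.asarray(r, dtype=float)
        return np.sqrt(self.midwall_radius_opened**2
                       + self.k * (r**2 - self.midwall_radius_closed**2))

    def unmap_radius(self, R):
        """Opened radius -> closed radius (inverse map)."""
        R = np.asarray(R, dtype=float)
        return np.sqrt(self.midwall_radius_closed**2
                       + (R**2 - self.midwall_radius_opened**2) / self.k)

    def map_points(self, xy_closed: np.ndarray) -> np.ndarray:
        """Map Cartesian points of the closed slice into the opened sector."""
        rel = np.asarray(xy_closed, dtype=float) - self.closed.centroid
        r = np.hypot(rel[..., 0], rel[..., 1])
        th = np.mod(np.arctan2(rel[..., 1], rel[..., 0]), 2 * np.pi)
        R = self.map_radius(r)
        Th = th / self.k
        return np.stack([R * np.cos(Th), R * np.sin(Th)], axis=-1)

    def wall_area(self) -> float:
        """Sector wall area via the same angular quadrature as the closed set."""
        dTh = self.sector_angle / self.angles.size
        return float(0.5 * np.sum(self.radii["adv"] ** 2
                                  - self.radii["lumen"] ** 2) * dTh)

    def midwall_arc_length(self) -> float:
        """Arc length of the conserved middle line, Theta_s * R_m."""
        return float(self.sector_angle * self.midwall_radius_opened)


def sector_angle_from_opening(opening_angle_deg: float) -> float:
    """Fung tip-angle convention: Theta_s = 2*(pi - OA)."""
    if not (0.0 <= opening_angle_deg < 180.0):
        raise ValueError(
            f"opening angle {opening_angle_deg} deg unsupported: the sector "
            "central angle 2*(pi - OA) must be positive (OA < 180 deg)")
    return 2.0 * (np.pi - np.deg2rad(opening_angle_deg))


def open_to_zero_stress(contours: LayeredContourSet,
                        opening_angle_deg: float | None = 120.0,
                        sector_angle: float | None = None) -> OpenSectorGeometry:
    """Cut the closed no-load ring open into its stress-free sector.

    Either the opening angle (tip-angle convention, default 120 deg) or the
    sector central angle may be given.  OA = 0 (sector 2*pi) is the identity.
    """
    if sector_angle is None:
        sector_angle = sector_angle_from_opening(opening_angle_deg)
    else:
        opening_angle_deg = float(np.rad2deg(np.pi - sector_angle / 2.0))
    if not (0.0 < sector_angle <= 2.0 * np.pi):
        raise ValueError("sector angle must lie in (0, 2*pi]")
    r_m = contours.midwall_mean_radius()
    k = 2.0 * np.pi / sector_angle
    geo = OpenSectorGeometry(
        sector_angle=float(sector_angle),
        opening_angle_deg=float(opening_angle_deg),
        angles=contours.angles / k,
        radii={},
        midwall_radius_opened=k * r_m,
        midwall_radius_closed=r_m,
        closed=contours,
    )
    geo.radii = {name: geo.map_radius(contours.radii[name]) for name in INTERFACES}
    geo.components = [
        Component(c.kind, geo.map_points(c.polygon_xy_mm)) for c in contours.components
    ]
    return geo


# --------------------------------------------------------------------------- meshing
#: region label integers
REGION_NAMES = ("intima", "media", "adventitia", "lipid", "calcification", "wall")
REGION_ID = {name: i for i, name in enumerate(REGION_NAMES)}


@dataclass
class Mesh:
    """Structured quadrilateral mesh of one slice (closed ring or opened sector).

    ``nodes`` are mm coordinates in the mesh's own reference configuration;
    for sector meshes ``closed_nodes`` carries the exact closed-configuration
    preimage of every node (used as wrap targets by the closure step).
    Elements are counter-clockwise; ``region`` holds one label id per element.
    """

    nodes: np.ndarray  # (N, 2)
    elems: np.ndarray  # (E, 4) int
    region: np.ndarray  # (E,) int, see REGION_ID
    n_theta: int
    n_rows: int  # radial node rows
    periodic: bool  # True for closed rings
    lumen_edges: np.ndarray  # (n_theta, 2) node pairs, CCW around lumen
    outer_edges: np.ndarray  # (n_theta, 2)
    cut_face_a: np.ndarray | None = None  # node ids on the Theta=0 face
    cut_face_b: np.ndarray | None = None  # node ids on the Theta=Theta_s face
    closed_nodes: np.ndarray | None = None  # (N, 2) closed-config preimages
    sector_angle: float | None = None
    midwall_radius_closed: float | None = None  # r_m of the source ring, mm
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(2))
    thickness_mm: float = 0.5  # slice thickness carried as metadata
    layer_of_row: np.ndarray | None = None  # (n_rows-1,) layer index per element row

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def region_names(self) -> np.ndarray:
        return np.asarray(REGION_NAMES)[self.region]

    def element_centroids(self, coords: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if coords is None else coords
        return x[self.elems].mean(axis=1)

    def jacobians(self) -> np.ndarray:
        """Corner Jacobian determinants, (E, 4); all must be positive."""
        x = self.nodes[self.elems]  # (E,4,2)
        out = np.empty((self.n_elems, 4))
        for c in range(4):
            p, q, s = x[:, c], x[:, (c + 1) % 4], x[:, (c - 1) % 4]
            a, b = q - p, s - p
            out[:, c] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        return out


def build_layered_mesh(geometry, n_radial=(2, 2, 2), n_theta: int = 48,
                       single_layer: bool = False) -> Mesh:
    """Structured "volume-fitting" quadrilateral mesh of a slice.

    ``geometry`` is a closed :class:`LayeredContourSet` or an
    :class:`OpenSectorGeometry`.  Each layer band is subdivided into
    ``n_radial[layer]`` element rows at equal radial parameter steps, with
    ``n_theta`` columns.  Element labels are the layer of the element
    centroid, overridden to a component label when the centroid (evaluated in
    the closed configuration) lies inside a component polygon; in
    single-layer mode all wall elements are labelled "wall" (bound to intima
    parameters downstream).  Sector meshes are built by mapping a closed-ring
    mesh through the opening map so every node carries its closed preimage.
    """
    if len(n_radial) != 3 or any(n < 1 for n in n_radial):
        raise ValueError("n_radial must give >= 1 rows for each of 3 layers")
    if n_theta < 16:
        raise ValueError("n_theta must be >= 16")
    opened = isinstance(geometry, OpenSectorGeometry)
    closed = geometry.closed if opened else geometry

    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    if opened:
        theta_cols = np.concatenate([theta, [2 * np.pi]])  # duplicate seam column
    else:
        theta_cols = theta
    ncols = theta_cols.size

    # closed-configuration radial stations per column
    iface = {k: closed.radius(k, theta_cols) for k in INTERFACES}
    stations = [iface["lumen"]]
    band_pairs = (("lumen", "iem"), ("iem", "eem"), ("eem", "adv"))
    layer_of_row = []
    for li, ((a, b), n_r) in enumerate(zip(band_pairs, n_radial)):
        for j in range(1, n_r + 1):
            t = j / n_r
            stations.append((1 - t) * iface[a] + t * iface[b])
            layer_of_row.append(li)
    stations = np.asarray(stations)  # (n_rows, ncols)
    n_rows = stations.shape[0]

    cx, cy = closed.centroid
    closed_nodes = np.stack(
        [cx + stations * np.cos(theta_cols), cy + stations * np.sin(theta_cols)],
        axis=-1,
    ).reshape(-1, 2)  # row-major: node id = row * ncols + col

    def nid(row, col):
        return row * ncols + col

    elems = []
    for i in range(n_rows - 1):
        for j in range(n_theta):
            jp = (j + 1) % n_theta if not opened else j + 1
            # CCW: radially out along theta_j, then CCW to theta_{j+1}
            elems.append([nid(i, j), nid(i + 1, j), nid(i + 1, jp), nid(i, jp)])
    elems = np.asarray(elems, dtype=np.int64)

    if opened:
        nodes = geometry.map_points(closed_nodes)
    else:
        nodes = closed_nodes

    # region labels from closed-configuration element centroids
    ecent_closed = closed_nodes[elems].mean(axis=1)
    row_of_elem = np.repeat(np.arange(n_rows - 1), n_theta)
    layer_of_row = np.asarray(layer_of_row)
    if single_layer:
        region = np.full(elems.shape[0], REGION_ID["wall"], dtype=np.int64)
    else:
        region = layer_of_row[row_of_elem].copy()
    for comp in closed.components:
        path = MplPath(comp.polygon_xy_mm)
        inside = path.contains_points(ecent_closed)
        region[inside] = REGION_ID[comp.kind]

    lumen_edges = np.asarray(
        [[nid(0, j), nid(0, (j + 1) % n_theta if not opened else j + 1)]
         for j in range(n_theta)], dtype=np.int64)
    outer_edges = np.asarray(
        [[nid(n_rows - 1, j), nid(n_rows - 1, (j + 1) % n_theta if not opened else j + 1)]
         for j in range(n_theta)], dtype=np.int64)

    mesh = Mesh(
        nodes=nodes,
        elems=elems,
        region=region,
        n_theta=n_theta,
        n_rows=n_rows,
        periodic=not opened,
        lumen_edges=lumen_edges,
        outer_edges=outer_edges,
        cut_face_a=np.arange(n_rows) * ncols if opened else None,
        cut_face_b=np.arange(n_rows) * ncols + n_theta if opened else None,
        closed_nodes=closed_nodes if opened else None,
        sector_angle=geometry.sector_angle if opened else None,
        midwall_radius_closed=geometry.midwall_radius_closed if opened else None,
        centroid=np.asarray(closed.centroid, dtype=float),
        layer_of_row=layer_of_row,
    )
    jac = mesh.jacobians()
    if np.any(jac <= 0):
        bad = int(np.argwhere(np.any(jac <= 0, axis=1))[0, 0])
        raise ValueError(f"tangled mesh: non-positive Jacobian in element {bad}")
    return mesh


# --------------------------------------------------------------------- refinement
def refine_until_converged(geometry, solver, n_radial=(1, 1, 1), n_theta: int = 24,
                           tol: float = 0.02, shrink: float = 0.9,
                           max_levels: int = 8):
    """Refine the mesh by 10% element-size steps until the solution settles.

    ``solver(mesh)`` must return the monitored scalar (the inner-wall maximum
    principal stress summary).  Element size is reduced by ``1 - shrink`` per
    level in each dimension; iteration stops when the monitored quantity
    changes by less than ``tol`` (relative) between consecutive solved
    levels.  Because the element counts are integers, a 10% step does not
    always change the radial subdivision; levels whose radial discretization
    repeats the previously solved one are skipped (they add no resolution to
    the transmural profile the monitor tracks), so consecutive comparisons
    always see a genuinely finer wall.  Returns (mesh, history) with the
    finer mesh of the converged pair; history is a list of dicts per solved
    level.
    """
    history = []
    prev = None
    prev_rad = None
    for level in range(max_levels):
        scale = (1.0 / shrink) ** level
        nth = max(16, int(round(n_theta * scale)))
        nrad = tuple(max(1, int(round(n * scale))) for n in n_radial)
        if nrad == prev_rad:
            continue
        prev_rad = nrad
        mesh = build_layered_mesh(geometry, n_radial=nrad, n_theta=nth)
        value = float(solver(mesh))
        history.append({"level": level, "n_theta": nth, "n_radial": nrad,
                        "n_elems": mesh.n_elems, "value": value})
        if prev is not None:
            denom = max(abs(prev), 1e-300)
            if abs(value - prev) / denom < tol:
                return mesh, history
        prev = value
    raise RuntimeError(
        f"mesh refinement did not converge within {max_levels} levels; "
        f"history: {[(h['n_elems'], h['value']) for h in history]}")


# --------------------------------------------------------------------------- VTK
def write_vtk(path, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid (quad cells)."""
    n, e = mesh.n_nodes, mesh.n_elems
    lines = ["# vtk DataFile Version 3.0", "plaquemech slice mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {n} double"]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9g} {y:.9g} 0")
    lines.append(f"CELLS {e} {5 * e}")
    for quad in mesh.elems:
        lines.append("4 " + " ".join(str(i) for i in quad))
    lines.append(f"CELL_TYPES {e}")
    lines.extend(["9"] * e)

    cell_data = {"region": mesh.region, **(cell_data or {})}
    lines.append(f"CELL_DATA {e}")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if arr.ndim == 1:
            dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            lines.append(f"SCALARS {name} {dtype} 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" if dtype == "double" else str(int(v)) for v in arr)
        elif arr.ndim == 3 and arr.shape[1:] == (3, 3):
            lines.append(f"TENSORS {name} double")
            for t in arr:
                for row in t:
                    lines.append(" ".join(f"{v:.9g}" for v in row))
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] in (2, 3):
                lines.append(f"VECTORS {name} double")
                for v in arr:
                    z = v[2] if arr.shape[1] == 3 else 0.0
                    lines.append(f"{v[0]:.9g} {v[1]:.9g} {z:.9g}")
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
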