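"""Synthetic nested phantoms standing in for MRI-derived anatomy.

The study anatomy (maternal abdomen containing the uterus and spine) is
emulated by nested closed triangulated surfaces at anatomical scale.  The
canonical validation phantom is two concentric spheres — a 0.25 m "abdomen"
shell around a 0.15 m "uterus" core in an air exterior — for which an
analytical reference solution exists (:mod:`uteroacoustics.layered_sphere`).

Mesh density follows an elements-per-wavelength rule: each surface is
refined until its mean edge length is at most ``lambda_min / epw`` where
``lambda_min`` is the wavelength in the adjacent medium with the smaller
sound speed (air for the outer surface, interior tissue for inner ones).

Coordinates are metres in a right-handed Cartesian frame; incident plane
waves travel along +/- x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from uteroacoustics.media import Medium

__all__ = [
    "SurfaceMesh",
    "NestedTopology",
    "EvaluationGrid",
    "icosphere",
    "ellipsoid",
    "nested_sphere_phantom",
    "nested_three_region_phantom",
    "interior_grid",
    "volume_centroid",
    "signed_solid_angles",
    "winding_number",
    "subdivisions_for_edge",
    "read_mesh",
    "write_mesh",
]

# Edge length of an icosahedron inscribed in the unit sphere.
_ICOSA_EDGE = 4.0 / np.sqrt(10.0 + 2.0 * np.sqrt(5.0))


class MeshFormatError(ValueError):
    """Raised for unreadable or non-triangular mesh input."""


@dataclass
class SurfaceMesh:
    """Closed, consistently oriented triangulated surface.

    ``vertices`` is (n, 3) float in metres, ``triangles`` (m, 3) int with
    counter-clockwise winding seen from outside (outward normals).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    region_label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshFormatError("triangles must be (m, 3) vertex index triples")

    # -- derived quantities -------------------------------------------------

    @property
    def corners(self) -> np.ndarray:
        """(m, 3, 3) triangle corner coordinates."""
        return self.vertices[self.triangles]

    @property
    def cross(self) -> np.ndarray:
        """(m, 3) un-normalised normals ``(v1-v0) x (v2-v0)`` (2x area)."""
        c = self.corners
        return np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])

    @property
    def areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.cross, axis=1)

    @property
    def normals(self) -> np.ndarray:
        cr = self.cross
        return cr / np.linalg.norm(cr, axis=1, keepdims=True)

    @property
    def area(self) -> float:
        return float(self.areas.sum())

    @property
    def edges(self) -> np.ndarray:
        """(3m, 2) directed edges."""
        t = self.triangles
        return np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])

    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())

    def volume(self) -> float:
        """Enclosed volume via the divergence theorem (positive if outward)."""
        c = self.corners
        return float(np.einsum("ij,ij->i", c[:, 0], np.cross(c[:, 1], c[:, 2])).sum() / 6.0)

    # -- validity -----------------------------------------------------------

    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two triangles, with
        opposite directions (consistent orientation)."""
        e = self.edges
        directed = set(map(tuple, e))
        if len(directed) != len(e):
            return False  # repeated directed edge
        und = {}
        for a, b in e:
            key = (min(a, b), max(a, b))
            und[key] = und.get(key, 0) + 1
        if any(v != 2 for v in und.values()):
            return False
        # consistent orientation: each undirected edge seen once per direction
        return all((b, a) in directed for a, b in directed)

    def validate(self) -> None:
        if np.any(self.areas <= 0):
            raise MeshFormatError(f"{self.region_label or 'mesh'}: zero-area triangle")
        if not self.is_watertight():
            raise MeshFormatError(f"{self.region_label or 'mesh'}: not watertight")
        if self.volume() <= 0:
            raise MeshFormatError(
                f"{self.region_label or 'mesh'}: normals are not outward (volume <= 0)"
            )

    def translated(self, t) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices + np.asarray(t, float), self.triangles.copy(),
                           self.region_label)


@dataclass
class NestedTopology:
    """Nested acoustic regions bounded by closed surfaces.

    ``surfaces[i]`` separates its enclosed region (named by the surface's
    ``region_label``) from the parent region ``containment[i]`` (index of the
    enclosing surface, or -1 for the unbounded exterior).  ``region_media``
    maps region names — including ``"exterior"`` — to :class:`Medium`.
    """

    surfaces: list
    containment: list
    region_media: dict

    def __post_init__(self) -> None:
        if len(self.containment) != len(self.surfaces):
            raise ValueError("containment must give one parent index per surface")
        if "exterior" not in self.region_media:
            raise ValueError("region_media must name the 'exterior' medium")
        for s in self.surfaces:
            if s.region_label not in self.region_media:
                raise ValueError(f"no medium assigned to region {s.region_label!r}")

    def parent_region(self, i: int) -> str:
        """Region name on the outer side of surface ``i``."""
        p = self.containment[i]
        return "exterior" if p == -1 else self.surfaces[p].region_label

    def medium_outside(self, i: int) -> Medium:
        return self.region_media[self.parent_region(i)]

    def medium_inside(self, i: int) -> Medium:
        return self.region_media[self.surfaces[i].region_label]

    def surface_index(self, label: str) -> int:
        for i, s in enumerate(self.surfaces):
            if s.region_label == label:
                return i
        raise KeyError(label)

    def validate(self, check_containment: bool = True) -> None:
        for s in self.surfaces:
            s.validate()
        if not check_containment:
            return
        for i, p in enumerate(self.containment):
            if p == -1:
                continue
            parent = self.surfaces[p]
            w = winding_number(parent, self.surfaces[i].vertices)
            if not np.all(np.abs(w) > 0.5):
                raise ValueError(
                    f"surface {self.surfaces[i].region_label!r} is not strictly "
                    f"inside its parent {parent.region_label!r}"
                )
        # siblings must not intersect: cheap vertex-containment check
        for i, pi in enumerate(self.containment):
            for j, pj in enumerate(self.containment):
                if i >= j or pi != pj:
                    continue
                wi = winding_number(self.surfaces[i], self.surfaces[j].vertices)
                if np.any(np.abs(wi) > 0.5):
                    raise ValueError(
                        f"sibling surfaces {self.surfaces[i].region_label!r} and "
                        f"{self.surfaces[j].region_label!r} overlap"
                    )


@dataclass
class EvaluationGrid:
    """Cartesian sample points inside one region, after near-surface exclusion."""

    points: np.ndarray
    spacing: float
    excluded_count: int
    region_label: str = ""
    solid_angle_threshold: float = 0.5

    def __len__(self) -> int:
        return int(self.points.shape[0])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def icosphere(radius: float, subdivisions: int, center=(0.0, 0.0, 0.0),
              region_label: str = "") -> SurfaceMesh:
    """Geodesic sphere: subdivided icosahedron projected onto the sphere.

    Has ``20 * 4**subdivisions`` triangles with outward normals.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if subdivisions < 0:
        raise ValueError(f"subdivisions must be >= 0, got {subdivisions}")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        verts_list = list(verts)
        midpoint: dict = {}

        def mid(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in midpoint:
                m = verts_list[a] + verts_list[b]
                m = m / np.linalg.norm(m)
                midpoint[key] = len(verts_list)
                verts_list.append(m)
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=np.int64)
    mesh = SurfaceMesh(radius * verts + np.asarray(center, float), faces, region_label)
    if mesh.volume() < 0:  # defensive; base icosahedron above is outward
        mesh.triangles = mesh.triangles[:, [0, 2, 1]]
    return mesh


def ellipsoid(semi_axes, subdivisions: int, center=(0.0, 0.0, 0.0),
              region_label: str = "") -> SurfaceMesh:
    """Axis-aligned ellipsoid by anisotropic scaling of an icosphere."""
    a = np.asarray(semi_axes, dtype=float)
    if a.shape != (3,) or np.any(a <= 0):
        raise ValueError("semi_axes must be three positive numbers")
    s = icosphere(1.0, subdivisions, region_label=region_label)
    s.vertices = s.vertices * a + np.asarray(center, float)
    return s


def subdivisions_for_edge(radius: float, target_edge: float,
                          min_subdivisions: int = 2, max_subdivisions: int = 8) -> int:
    """Icosphere subdivision level whose mean edge length is <= target_edge.

    A floor of ``min_subdivisions`` preserves geometric fidelity of the
    sphere at low frequencies, where the wavelength rule alone would allow
    very coarse polyhedra.
    """
    if target_edge <= 0:
        raise ValueError("target edge length must be positive")
    edge0 = _ICOSA_EDGE * radius
    n = int(np.ceil(np.log2(edge0 / target_edge))) if target_edge < edge0 else 0
    n = max(n, min_subdivisions)
    if n > max_subdivisions:
        raise ValueError(
            f"mesh density rule requires subdivision level {n} "
            f"(> {max_subdivisions}): {20 * 4 ** n} triangles is beyond the "
            f"intended problem scale; raise target edge or lower the frequency"
        )
    return n


def nested_sphere_phantom(
    outer_radius: float,
    inner_radius: float,
    elements_per_wavelength: float,
    f: float,
    media: dict | None = None,
    min_subdivisions: int = 2,
) -> NestedTopology:
    """Two concentric spheres: abdomen shell around a uterus core, in air.

    ``media`` maps ``{"exterior", "abdomen", "uterus"}`` to
    :class:`Medium`; the default is air / abdominal tissue / amniotic fluid.
    Each surface is refined until its mean edge length is at most
    ``lambda_min / elements_per_wavelength`` at frequency ``f``, where
    ``lambda_min`` uses the slower-sounding adjacent medium.
    """
    from uteroacoustics.media import AIR, get_medium

    if not 0 < inner_radius < outer_radius:
        raise ValueError("require 0 < inner_radius < outer_radius")
    if elements_per_wavelength <= 0:
        raise ValueError("elements_per_wavelength must be positive")
    if f <= 0:
        raise ValueError("build frequency must be positive")
    if media is None:
        media = {
            "exterior": AIR,
            "abdomen": get_medium("Abdominal tissue"),
            "uterus": get_medium("Amniotic fluid"),
        }
    c_outer = min(media["exterior"].c0, media["abdomen"].c0)
    c_inner = min(media["abdomen"].c0, media["uterus"].c0)
    n_out = subdivisions_for_edge(
        outer_radius, (c_outer / f) / elements_per_wavelength, min_subdivisions
    )
    n_in = subdivisions_for_edge(
        inner_radius, (c_inner / f) / elements_per_wavelength, min_subdivisions
    )
    topo = NestedTopology(
        surfaces=[
            icosphere(outer_radius, n_out, region_label="abdomen"),
            icosphere(inner_radius, n_in, region_label="uterus"),
        ],
        containment=[-1, 0],
        region_media=media,
    )
    topo.validate(check_containment=False)  # spheres are concentric by construction
    return topo


def nested_three_region_phantom(
    outer_radius: float,
    inner_radius: float,
    spine_semi_axes,
    spine_center,
    elements_per_wavelength: float,
    f: float,
    media: dict | None = None,
    min_subdivisions: int = 2,
) -> NestedTopology:
    """Abdomen containing a uterus sphere and a sibling spine ellipsoid."""
    from uteroacoustics.media import AIR, get_medium

    if media is None:
        media = {
            "exterior": AIR,
            "abdomen": get_medium("Abdominal tissue"),
            "uterus": get_medium("Amniotic fluid"),
            "spine": get_medium("Spine bone"),
        }
    base = nested_sphere_phantom(
        outer_radius, inner_radius, elements_per_wavelength, f,
        media={k: media[k] for k in ("exterior", "abdomen", "uterus")},
        min_subdivisions=min_subdivisions,
    )
    c_sp = min(media["abdomen"].c0, media["spine"].c0)
    n_sp = subdivisions_for_edge(
        float(np.max(spine_semi_axes)),
        (c_sp / f) / elements_per_wavelength,
        min_subdivisions,
    )
    spine = ellipsoid(spine_semi_axes, n_sp, center=spine_center, region_label="spine")
    topo = NestedTopology(
        surfaces=base.surfaces + [spine],
        containment=[-1, 0, 0],
        region_media=media,
    )
    topo.validate()
    return topo


# ---------------------------------------------------------------------------
# interior tests and grids
# ---------------------------------------------------------------------------

def signed_solid_angles(mesh: SurfaceMesh, points: np.ndarray,
                        chunk: int = 2_000_000) -> np.ndarray:
    """Signed solid angle (sr) subtended by each triangle at each point.

    Van Oosterom-Strackee formula; positive when the triangle's outward
    normal faces away from the point.  Returns an (npoints, ntris) array.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    corners = mesh.corners
    npts, ntri = pts.shape[0], corners.shape[0]
    out = np.empty((npts, ntri))
    rows = max(1, chunk // max(ntri, 1))
    for s in range(0, npts, rows):
        p = pts[s:s + rows]
        a = corners[None, :, 0, :] - p[:, None, :]
        b = corners[None, :, 1, :] - p[:, None, :]
        c = corners[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        numer = np.einsum("pti,pti->pt", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("pti,pti->pt", a, b) * lc
            + np.einsum("pti,pti->pt", a, c) * lb
            + np.einsum("pti,pti->pt", b, c) * la
        )
        out[s:s + rows] = 2.0 * np.arctan2(numer, denom)
    return out


def winding_number(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Generalised winding number: ~1 inside a watertight outward mesh, ~0 outside."""
    return signed_solid_angles(mesh, points).sum(axis=1) / (4.0 * np.pi)


def interior_grid(
    mesh: SurfaceMesh,
    spacing: float | None = None,
    solid_angle_threshold: float = 0.5,
) -> EvaluationGrid:
    """Axis-aligned Cartesian grid of interior points, with near-surface exclusion.

    A candidate point is retained when (a) it is inside the surface by the
    winding-number test and (b) no single triangle subtends more than
    ``solid_angle_threshold`` steradians at it.  The per-triangle rule
    discards points so close to the surface that boundary-element potential
    evaluation would be inaccurate.  Default spacing is 1/20 of the largest
    bounding-box extent of the region.
    """
    if not mesh.is_watertight():
        raise MeshFormatError("interior_grid requires a watertight mesh")
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    if spacing is None:
        spacing = float(np.max(hi - lo)) / 20.0
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    axes = [np.arange(lo[d] + spacing / 2.0, hi[d], spacing) for d in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ValueError(f"spacing {spacing} too coarse for region bounding box")
    omega = signed_solid_angles(mesh, pts)
    inside = np.abs(omega.sum(axis=1)) / (4.0 * np.pi) > 0.5
    near = np.abs(omega).max(axis=1) > solid_angle_threshold
    keep = inside & ~near
    if not np.any(keep):
        raise ValueError(
            f"no interior points retained at spacing {spacing}; try a smaller spacing"
        )
    return EvaluationGrid(
        points=pts[keep],
        spacing=float(spacing),
        excluded_count=int(np.count_nonzero(inside & near)),
        region_label=mesh.region_label,
        solid_angle_threshold=solid_angle_threshold,
    )


def volume_centroid(mesh: SurfaceMesh) -> np.ndarray:
    """Centroid of the enclosed solid, via the divergence theorem.

    This is the "barycentre" used for point-pressure metrics: it depends on
    the enclosed volume, not on how the surface happens to be triangulated.
    """
    if not mesh.is_watertight():
        raise MeshFormatError("volume_centroid requires a watertight mesh")
    c = mesh.corners
    # divergence theorem with F = x^2/2 etc.: per-tet (origin, v0, v1, v2)
    vol6 = np.einsum("ij,ij->i", c[:, 0], np.cross(c[:, 1], c[:, 2]))
    centroid_tet = c.sum(axis=1) / 4.0
    v = vol6.sum()
    if v == 0:
        raise MeshFormatError("degenerate mesh: zero enclosed volume")
    return (vol6[:, None] * centroid_tet).sum(axis=0) / v


# ---------------------------------------------------------------------------
# mesh IO (STL through trimesh, Gmsh .msh natively)
# ---------------------------------------------------------------------------

def read_mesh(path, region_label: str | None = None,
              merge_tolerance: float = 1e-8) -> SurfaceMesh:
    """Read a triangulated surface from STL (binary/ASCII) or Gmsh .msh.

    STL files duplicate vertices per facet; they are merged back within
    ``merge_tolerance`` (relative to the bounding-box diagonal) to recover a
    watertight connectivity.  Non-triangular elements are rejected.
    """
    import pathlib

    path = pathlib.Path(path)
    suffix = path.suffix.lower()
    if suffix == ".msh":
        from uteroacoustics.gmshio import read_msh

        mesh = read_msh(path)
    elif suffix == ".stl":
        import trimesh

        tm = trimesh.load(str(path), file_type="stl", process=True,
                          merge_tex=True, merge_norm=True)
        if not isinstance(tm, trimesh.Trimesh):
            raise MeshFormatError(f"{path}: not a single triangulated surface")
        tol = merge_tolerance * float(np.linalg.norm(tm.bounds[1] - tm.bounds[0]))
        tm.merge_vertices(digits_vertex=max(1, int(-np.log10(max(tol, 1e-16)))))
        mesh = SurfaceMesh(np.asarray(tm.vertices, float),
                           np.asarray(tm.faces, np.int64))
    else:
        raise MeshFormatError(f"{path}: unsupported mesh format {suffix!r}")
    if region_label is not None:
        mesh.region_label = region_label
    return mesh


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write STL (binary) or Gmsh .msh v2.2 ASCII, by file extension."""
    import pathlib

    path = pathlib.Path(path)
    suffix = path.suffix.lower()
    if suffix == ".msh":
        from uteroacoustics.gmshio import write_msh

        write_msh(mesh, path)
    elif suffix == ".stl":
        import trimesh

        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                             process=False)
        tm.export(str(path))
    else:
        raise MeshFormatError(f"{path}: unsupported mesh format {suffix!r}")
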