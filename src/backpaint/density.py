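"""Density-map contouring and the hybrid wireframe-front / solid-back
mesh split.

A thick density slab drawn entirely as chickenwire is unreadable — it is
hard to see what is in front of what.  The hybrid style keeps the part of
the isosurface nearest the eye as wireframe and renders the rest solid,
so atoms "inside" the surface are apparent at a glance.  Here that is a
purely geometric classification of contour triangles against a split
plane parallel to the front clipping plane.

Maps are regular grids; CCP4/MRC files are read and written through
gemmi (mode 2, axis order normalized to X-fastest on read).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import gemmi
import numpy as np
from skimage import measure

from .model import BackboneChain
from .selection import ClipFrustum, frustum_contains

__all__ = [
    "DensityGrid",
    "ContourMesh",
    "synthetic_map",
    "contour",
    "split_front_back",
    "clip_mesh_to_frustum",
    "read_ccp4",
    "write_ccp4",
    "write_obj",
]

FRONT = "front"
BACK = "back"


@dataclass(frozen=True)
class DensityGrid:
    """A scalar field sampled on a regular orthogonal grid.

    ``values[i, j, k]`` sits at ``origin + (i, j, k) * spacing`` (world
    Angstrom); X is the fastest-varying stored axis.
    """

    origin: np.ndarray
    spacing: np.ndarray  # per-axis, Angstrom
    values: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        s = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(s > 0):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite map values")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "spacing", s)
        object.__setattr__(self, "values", v)

    def interpolate(self, points) -> np.ndarray:
        """Trilinear interpolation at world coordinates."""
        from scipy.interpolate import RegularGridInterpolator

        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.values.shape[d])
            for d in range(3)
        ]
        rgi = RegularGridInterpolator(axes, self.values, bounds_error=False, fill_value=0.0)
        return rgi(np.atleast_2d(points))


@dataclass(frozen=True)
class ContourMesh:
    """Triangle mesh in world coordinates; ``tri_class`` (once assigned)
    labels every triangle 'front' or 'back', exactly one of the two."""

    vertices: np.ndarray
    triangles: np.ndarray
    tri_class: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        t = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise ValueError("triangle indices out of range")
        if self.tri_class is not None:
            c = np.asarray(self.tri_class)
            if c.shape != (len(t),):
                raise ValueError("tri_class must label every triangle")
            if not np.all(np.isin(c, [FRONT, BACK])):
                raise ValueError("tri_class entries must be 'front' or 'back'")
            object.__setattr__(self, "tri_class", c)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def euler_characteristic(self) -> int:
        """V - E + F with undirected edge counting (2 for a sphere)."""
        edges = np.sort(
            self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        n_edges = len(np.unique(edges, axis=0))
        return len(self.vertices) - n_edges + len(self.triangles)


def synthetic_map(
    chains: list[BackboneChain] | BackboneChain,
    spacing: float = 0.5,
    sigma: float = 1.0,
    padding: float = 6.0,
) -> DensityGrid:
    """Gaussian-atom density: a unit-height isotropic Gaussian of width
    ``sigma`` at every atom, sampled on a grid covering the model plus
    ``padding`` on all sides.  A stand-in for an experimental map so the
    contouring pipeline needs no external data."""
    if isinstance(chains, BackboneChain):
        chains = [chains]
    centers = np.array(
        [p for ch in chains for res in ch for p in res.atoms.values()], dtype=float
    )
    if centers.size == 0:
        raise ValueError("no atoms: cannot build a map from an empty model")
    lo = centers.min(axis=0) - padding
    hi = centers.max(axis=0) + padding
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[d] + spacing * np.arange(shape[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    values = np.zeros(tuple(shape))
    inv = 1.0 / (2.0 * sigma * sigma)
    for c in centers:
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        values += np.exp(-r2 * inv)
    return DensityGrid(lo, spacing, values)


def contour(grid: DensityGrid, level: float) -> ContourMesh:
    """Marching-cubes isosurface at ``level``, vertices in world
    Angstrom.  The level must lie strictly inside the value range."""
    vmin, vmax = float(grid.values.min()), float(grid.values.max())
    if not vmin < level < vmax:
        raise ValueError(
            f"contour level {level} outside map value range ({vmin:.4g}, {vmax:.4g})"
        )
    verts, faces, _, _ = measure.marching_cubes(
        grid.values, level=level, spacing=tuple(grid.spacing)
    )
    return ContourMesh(verts + grid.origin, faces)


def split_front_back(
    mesh: ContourMesh, f: ClipFrustum, fraction: float = 0.5
) -> ContourMesh:
    """Classify triangles against the split plane parallel to the front
    clipping plane at depth near + fraction * (far - near): nearer
    centroids become 'front' (wireframe), the rest 'back' (solid)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    split_depth = f.near_depth + fraction * (f.far_depth - f.near_depth)
    depth = (mesh.centroids() - f.eye) @ f.forward
    cls = np.where(depth < split_depth, FRONT, BACK)
    return replace(mesh, tri_class=cls)


def clip_mesh_to_frustum(mesh: ContourMesh, f: ClipFrustum) -> ContourMesh:
    """Keep triangles whose centroid lies inside the frustum; vertices are
    compacted.  (Exact polygon clipping at the boundary is out of scope.)"""
    keep = frustum_contains(f, mesh.centroids())
    tris = mesh.triangles[keep]
    cls = mesh.tri_class[keep] if mesh.tri_class is not None else None
    used = np.unique(tris)
    remap = np.zeros(len(mesh.vertices), dtype=int)
    remap[used] = np.arange(len(used))
    return ContourMesh(mesh.vertices[used], remap[tris], cls)


def write_ccp4(grid: DensityGrid, path: str) -> None:
    """Write as a CCP4/MRC mode-2 map (orthogonal cell, P1); the world
    origin goes in the MRC ORIGIN header words."""
    m = gemmi.Ccp4Map()
    g = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    nx, ny, nz = grid.values.shape
    g.set_unit_cell(
        gemmi.UnitCell(
            grid.spacing[0] * nx, grid.spacing[1] * ny, grid.spacing[2] * nz,
            90.0, 90.0, 90.0,
        )
    )
    g.spacegroup = gemmi.SpaceGroup("P1")
    m.grid = g
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


def read_ccp4(path: str) -> DensityGrid:
    """Read a CCP4/MRC map; axis order is normalized so X varies fastest
    in memory, matching :class:`DensityGrid` conventions."""
    m = gemmi.read_ccp4_map(str(path), setup=True)
    g = m.grid
    values = np.array(g, copy=True)
    nx, ny, nz = values.shape
    spacing = np.array(
        [g.unit_cell.a / nx, g.unit_cell.b / ny, g.unit_cell.c / nz]
    )
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    return DensityGrid(origin, spacing, values)


def write_obj(mesh: ContourMesh, path: str) -> None:
    """Wavefront OBJ export; classified triangles go into groups named
    'wire' (front) and 'solid' (back), unclassified meshes into 'mesh'."""
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        if mesh.tri_class is None:
            groups = {"mesh": mesh.triangles}
        else:
            groups = {
                "wire": mesh.triangles[mesh.tri_class == FRONT],
                "solid": mesh.triangles[mesh.tri_class == BACK],
            }
        for name, tris in groups.items():
            fh.write(f"g {name}\n")
            for t in tris:
                fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
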