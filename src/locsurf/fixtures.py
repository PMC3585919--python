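"""Deterministic test-surface generators.

Two families:

* parametric meshes (sphere, plane, cylinder, saddle, pocket-in-plane) at a
  target sampling density, with analytic curvatures attached as reference
  metadata — closed-form oracles for the geometry stack;
* synthetic toy complexes: a pseudo-protein atom cloud with category tags,
  a surface mesh over it, a two-atom pseudo-ligand posed on the surface,
  and a planted feature-space "signature" near each ligand atom.  These
  embody the working assumptions of the predictor — each ligand atom has a
  distinct micro-environment that is consistent across binders — in a form
  where ground truth is known exactly.

Everything is a pure function of its seed and parameters.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import ConvexHull, Delaunay

from .chemistry import Atom, Structure
from .geometry import TriangleMesh, vertex_areas

DEFAULT_DENSITY = 3.0  # surface samples per Å²

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))


@dataclasses.dataclass
class ParametricShape:
    """Specification of an analytic surface fixture."""

    kind: str                      # sphere | plane | cylinder | saddle | pocket
    parameters: dict
    density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        for k, v in self.parameters.items():
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"parameter {k} must be positive")


def _hex_grid(extent: float, density: float) -> np.ndarray:
    """Hexagonal lattice covering [-extent/2, extent/2]² at a point density."""
    d = np.sqrt(2.0 / (np.sqrt(3.0) * density))
    nx = int(np.ceil(extent / d)) + 1
    ny = int(np.ceil(extent / (d * np.sqrt(3) / 2))) + 1
    pts = []
    for j in range(ny):
        y = j * d * np.sqrt(3) / 2
        off = 0.5 * d if j % 2 else 0.0
        for i in range(nx):
            pts.append((i * d + off, y))
    pts = np.asarray(pts)
    pts -= pts.mean(axis=0)
    half = extent / 2
    return pts[(np.abs(pts[:, 0]) <= half) & (np.abs(pts[:, 1]) <= half)]


def sphere_mesh(radius: float, density: float = DEFAULT_DENSITY) -> TriangleMesh:
    """Fibonacci-lattice sphere triangulated by its convex hull.

    The vertex count is ``round(density · 4πr²)`` so the realized sampling
    density matches the request exactly up to rounding.
    """
    n = int(round(density * 4 * np.pi * radius**2))
    if n < 12:
        raise ValueError("density too low: sphere mesh would degenerate")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    phi = i * _GOLDEN
    pts = radius * np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    hull = ConvexHull(pts)
    tris = hull.simplices.copy()
    # orient all triangles outward (hull simplices are arbitrarily wound)
    p0, p1, p2 = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    outward = np.einsum("ij,ij->i", np.cross(p1 - p0, p2 - p0), (p0 + p1 + p2) / 3)
    tris[outward < 0] = tris[outward < 0][:, ::-1]
    normals = pts / radius
    return TriangleMesh(
        vertices=pts,
        triangles=tris,
        normals=normals,
        vertex_areas=vertex_areas(pts, tris),
        reference={"kind": "sphere", "radius": radius,
                   "curvature": 1.0 / radius, "anisotropy": 0.0},
    )


def plane_mesh(extent: float = 12.0, density: float = DEFAULT_DENSITY) -> TriangleMesh:
    """Flat triangulated square in the z=0 plane, normal +z."""
    pts2 = _hex_grid(extent, density)
    if len(pts2) < 6:
        raise ValueError("density too low: plane mesh would degenerate")
    tris = Delaunay(pts2).simplices.astype(np.int64)
    pts = np.column_stack([pts2, np.zeros(len(pts2))])
    normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return TriangleMesh(
        vertices=pts, triangles=tris, normals=normals,
        vertex_areas=vertex_areas(pts, tris),
        reference={"kind": "plane", "curvature": 0.0, "anisotropy": 0.0},
    )


def cylinder_mesh(
    radius: float, height: float = 12.0, density: float = DEFAULT_DENSITY
) -> TriangleMesh:
    """Open lateral cylinder surface about the z axis, normals radial."""
    d = np.sqrt(2.0 / (np.sqrt(3.0) * density))
    n_around = max(8, int(round(2 * np.pi * radius / d)))
    dz = d * np.sqrt(3) / 2
    n_z = max(3, int(round(height / dz)) + 1)
    verts, tris = [], []
    for j in range(n_z):
        off = 0.5 * (2 * np.pi / n_around) if j % 2 else 0.0
        for i in range(n_around):
            th = i * 2 * np.pi / n_around + off
            verts.append((radius * np.cos(th), radius * np.sin(th),
                          j * height / (n_z - 1) - height / 2))
    for j in range(n_z - 1):
        for i in range(n_around):
            a = j * n_around + i
            b = j * n_around + (i + 1) % n_around
            c = (j + 1) * n_around + i
            e = (j + 1) * n_around + (i + 1) % n_around
            if j % 2 == 0:
                tris += [(a, b, c), (b, e, c)]
            else:
                tris += [(a, b, e), (a, e, c)]
    pts = np.asarray(verts)
    tris = np.asarray(tris, dtype=np.int64)
    normals = pts.copy()
    normals[:, 2] = 0.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return TriangleMesh(
        vertices=pts, triangles=tris, normals=normals,
        vertex_areas=vertex_areas(pts, tris),
        reference={"kind": "cylinder", "radius": radius,
                   "curvature": 0.5 / radius, "anisotropy": 1.0,
                   "k1": 1.0 / radius, "k2": 0.0},
    )


def saddle_mesh(
    bend_radius: float = 4.0, extent: float = 12.0, density: float = DEFAULT_DENSITY
) -> TriangleMesh:
    """Saddle height field z = (x² − y²) / (2·bend_radius)."""
    pts2 = _hex_grid(extent, density)
    tris = Delaunay(pts2).simplices.astype(np.int64)
    z = (pts2[:, 0] ** 2 - pts2[:, 1] ** 2) / (2 * bend_radius)
    pts = np.column_stack([pts2, z])
    gx, gy = pts2[:, 0] / bend_radius, -pts2[:, 1] / bend_radius
    normals = np.column_stack([-gx, -gy, np.ones(len(pts2))])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return TriangleMesh(
        vertices=pts, triangles=tris, normals=normals,
        vertex_areas=vertex_areas(pts, tris),
        reference={"kind": "saddle", "curvature_at_center": 0.0,
                   "anisotropy_at_center": 1.0},
    )


def pocket_mesh(
    pocket_radius: float = 4.0, extent: float = 16.0, density: float = DEFAULT_DENSITY
) -> TriangleMesh:
    """Plane with a hemispherical pocket of the given radius sunk into it.

    The pocket bottom has curvature −1/pocket_radius under the outward
    (out-of-material, +z at the bottom) normal convention.  Points are placed
    uniformly on the true surface and triangulated via an azimuthal
    arc-length parameterization, so the sampling density is uniform across
    both the plane and the bowl.
    """
    a = pocket_radius
    if extent <= 2 * a:
        raise ValueError("extent must exceed the pocket diameter")
    # hemisphere points (lower half of the sphere centered at origin, z ≤ 0)
    n_hemi = max(12, int(round(density * 2 * np.pi * a * a)))
    i = np.arange(n_hemi)
    z = -(2.0 * i + 1.0) / (2 * n_hemi)          # cosθ from −1 → 0
    zz = z * 2  # map to (−1, 0): uniform in z over the lower hemisphere
    rr = np.sqrt(np.maximum(1 - zz * zz, 0))
    phi = i * _GOLDEN
    hemi = a * np.column_stack([rr * np.cos(phi), rr * np.sin(phi), zz])
    hemi_n = -hemi / a                            # outward = into the bowl
    # param radius: arc length from the bottom pole
    theta = np.arccos(np.clip(-zz, -1, 1))        # 0 at bottom, π/2 at rim
    hemi_param_r = a * theta

    # plane points outside the pocket rim
    pts2 = _hex_grid(extent, density)
    keep = np.linalg.norm(pts2, axis=1) > a + 0.3 / np.sqrt(density)
    plane2 = pts2[keep]
    plane = np.column_stack([plane2, np.zeros(len(plane2))])
    plane_n = np.tile([0.0, 0.0, 1.0], (len(plane2), 1))
    rho = np.linalg.norm(plane2, axis=1)
    plane_param_r = a * np.pi / 2 + (rho - a)

    pts = np.vstack([hemi, plane])
    normals = np.vstack([hemi_n, plane_n])
    az = np.concatenate([np.arctan2(hemi[:, 1], hemi[:, 0]),
                         np.arctan2(plane2[:, 1], plane2[:, 0])])
    pr = np.concatenate([hemi_param_r, plane_param_r])
    param = np.column_stack([pr * np.cos(az), pr * np.sin(az)])
    tris = Delaunay(param).simplices.astype(np.int64)
    # drop slivers produced at the square outer boundary of the parameter domain
    p0, p1, p2 = (param[tris[:, k]] for k in range(3))
    area2 = np.abs((p1 - p0)[:, 0] * (p2 - p0)[:, 1] - (p1 - p0)[:, 1] * (p2 - p0)[:, 0])
    tris = tris[area2 > 1e-9]
    # drop vertices orphaned by the sliver filter and remap indices
    used = np.zeros(len(pts), dtype=bool)
    used[tris.ravel()] = True
    remap = np.cumsum(used) - 1
    pts, normals = pts[used], normals[used]
    tris = remap[tris]
    # wind triangles to agree with the analytic outward normals
    q0, q1, q2 = (pts[tris[:, k]] for k in range(3))
    fn = np.cross(q1 - q0, q2 - q0)
    flip = np.einsum("ij,ij->i", fn, (normals[tris[:, 0]] + normals[tris[:, 1]]
                                      + normals[tris[:, 2]])) < 0
    tris[flip] = tris[flip][:, ::-1]
    bottom = int(np.argmin(pts[:, 2]))
    return TriangleMesh(
        vertices=pts, triangles=tris, normals=normals,
        vertex_areas=vertex_areas(pts, tris),
        reference={"kind": "pocket", "pocket_radius": a,
                   "bottom_vertex": bottom,
                   "curvature_at_bottom": -1.0 / a},
    )


def make_parametric_mesh(shape: ParametricShape) -> TriangleMesh:
    """Dispatch a :class:`ParametricShape` to its generator."""
    p, d = shape.parameters, shape.density
    if shape.kind == "sphere":
        return sphere_mesh(p["radius"], d)
    if shape.kind == "plane":
        return plane_mesh(p.get("extent", 12.0), d)
    if shape.kind == "cylinder":
        return cylinder_mesh(p["radius"], p.get("height", 12.0), d)
    if shape.kind == "saddle":
        return saddle_mesh(p.get("bend_radius", 4.0), p.get("extent", 12.0), d)
    if shape.kind in {"pocket", "pocket-in-plane"}:
        return pocket_mesh(p.get("pocket_radius", 4.0), p.get("extent", 16.0), d)
    raise ValueError(f"unknown parametric shape kind {shape.kind!r}")


# ---------------------------------------------------------------------------
# synthetic complexes with planted micro-environments
# ---------------------------------------------------------------------------

# feature subsets (Table-order indices, 0-based) planted for the two
# pseudo-ligand atoms: disjoint, spanning chemistry and patch statistics
DEFAULT_SIGNATURE_A = (1, 13, 18, 28, 33)
DEFAULT_SIGNATURE_B = (3, 15, 20, 30, 35)
DEFAULT_SHIFT = 2.0          # planted effect, in per-feature sd units
LIGAND_VDW = 1.7             # Å, pseudo-ligand atom radius

# residue/atom templates covering all 14 chemical categories
_ATOM_TEMPLATES = [
    ("GLY", "CA", "C"), ("GLY", "C", "C"), ("GLY", "N", "N"), ("GLY", "O", "O"),
    ("PHE", "CZ", "C"), ("ALA", "CB", "C"), ("CYS", "SG", "S"),
    ("ASN", "ND2", "N"), ("ASN", "OD1", "O"), ("TRP", "CZ2", "C"),
    ("SER", "OG", "O"), ("ASP", "OD1", "O"), ("LYS", "NZ", "N"),
    ("ARG", "NH1", "N"), ("THR", "OG1", "O"), ("ILE", "CD1", "C"),
]


@dataclasses.dataclass
class SyntheticComplex:
    """A toy protein/ligand complex with known planted binding truth."""

    structure: Structure
    mesh: TriangleMesh
    ligand_pose: list          # the two pseudo-ligand Atom objects
    planted_vertices: np.ndarray
    planted_by_atom: dict      # atom name -> vertex id array
    signature: tuple           # ((features_A, shift), (features_B, shift))
    seed: int
    surface: "object"          # raw DescriptorSurface with planted shifts
    actual_spacing: float      # realized ligand inter-atom distance (Å)


def make_synthetic_complex(
    seed: int,
    n_protein_atoms: int = 60,
    signature: tuple | None = None,
    spacing: float = 4.0,
    shift: float = DEFAULT_SHIFT,
    mesh_radius: float = 4.0,
    density: float = DEFAULT_DENSITY,
    n_rays: int = 32,
) -> SyntheticComplex:
    """Generate one synthetic complex; pure function of seed + parameters.

    A pseudo-protein atom cloud with category-bearing residue/atom names is
    drawn inside a spherical surface mesh; a two-atom pseudo-ligand is posed
    just off the surface at the requested atom spacing; raw descriptors are
    assembled from the mesh and structure, then the designated feature subset
    of each ligand atom is shifted by ``shift`` per-feature standard
    deviations at the vertices within the interface cutoff of that atom.
    """
    from .descriptor import assemble_descriptors  # deferred: avoids import cycle
    from .training import surface_offsets

    if shift < 0:
        raise ValueError("shift must be ≥ 0")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if signature is None:
        signature = (
            (DEFAULT_SIGNATURE_A, shift),
            (DEFAULT_SIGNATURE_B, shift),
        )
    rng = np.random.default_rng(seed)
    mesh = sphere_mesh(mesh_radius, density)

    # pseudo-protein: atom cloud strictly inside the mesh
    rmax = mesh_radius - 1.2
    pos = rng.normal(size=(n_protein_atoms, 3))
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    pos *= rmax * rng.uniform(0.2, 1.0, size=(n_protein_atoms, 1)) ** (1 / 3)
    ti = rng.integers(0, len(_ATOM_TEMPLATES), size=n_protein_atoms)
    atoms = [
        Atom(
            serial=i + 1,
            name=_ATOM_TEMPLATES[t][1],
            element=_ATOM_TEMPLATES[t][2],
            residue_name=_ATOM_TEMPLATES[t][0],
            chain="A",
            residue_seq=i + 1,
            position=pos[i],
            is_hetero=False,
        )
        for i, t in enumerate(ti)
    ]

    # pose the two-atom pseudo-ligand on the surface; atom centers sit just
    # off the mesh, so spacing is matched between prospective centers
    centers = mesh.vertices + mesh.normals * (LIGAND_VDW + 0.5)
    v0 = int(rng.integers(0, mesh.n_vertices))
    dc = np.linalg.norm(centers - centers[v0], axis=1)
    dc[v0] = np.inf
    v1 = int(np.argmin(np.abs(dc - spacing)))
    lig = []
    for k, v in enumerate((v0, v1)):
        center = centers[v]
        lig.append(
            Atom(
                serial=9000 + k, name=f"L{k + 1}", element="C",
                residue_name="LIG", chain="L", residue_seq=900,
                position=center, vdw_radius=LIGAND_VDW, is_hetero=True,
            )
        )
    actual = float(np.linalg.norm(lig[0].position - lig[1].position))

    structure = Structure(atoms=atoms, ligand_instances=[("LIG", lig)])
    surface = assemble_descriptors(mesh, structure, grid=None, n_rays=n_rays)

    planted_by_atom = {}
    sd = surface.features.std(axis=0)
    sd = np.where(sd > 1e-6, sd, 1.0)
    for (features, s), atom in zip(signature, lig):
        near = np.flatnonzero(surface_offsets(mesh, atom) <= 1.6)
        planted_by_atom[atom.name] = near
        surface.features[np.ix_(near, np.asarray(features))] += s * sd[list(features)]
    planted = np.unique(np.concatenate(list(planted_by_atom.values())))

    return SyntheticComplex(
        structure=structure,
        mesh=mesh,
        ligand_pose=lig,
        planted_vertices=planted,
        planted_by_atom=planted_by_atom,
        signature=signature,
        seed=seed,
        surface=surface,
        actual_spacing=actual,
    )


def make_synthetic_corpus(
    n: int,
    seed: int,
    template: dict | None = None,
) -> list[SyntheticComplex]:
    """Generate ``n`` complexes with independent child seeds.

    ``template`` takes the keyword arguments of :func:`make_synthetic_complex`
    plus ``spacing_range=(lo, hi)``: when present, each complex draws its
    ligand spacing uniformly from that interval (so inter-atom distance-bound
    recovery is testable against a known generative window).
    """
    if n <= 0:
        raise ValueError("n must be ≥ 1")
    template = dict(template or {})
    spacing_range = template.pop("spacing_range", None)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for cs in child_seeds:
        kw = dict(template)
        if spacing_range is not None:
            kw["spacing"] = float(np.random.default_rng(int(cs)).uniform(*spacing_range))
        out.append(make_synthetic_complex(int(cs), **kw))
    return out
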