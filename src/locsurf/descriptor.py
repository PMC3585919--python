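"""Per-vertex 40-feature surface descriptors and corpus normalization.

Every surface sample (mesh vertex) carries a fixed-order 40-vector:

====  ==============================================================
 #    feature
====  ==============================================================
 1    visibility — fraction of the outside world visible from the point
 2–13 Euclidean distance to the nearest atom of 12 chemical categories
14–18 patch anisotropy at scales 1.6 / 3.2 / 4.8 / 6.4 / 8 Å
19–23 patch curvature at the 5 scales
24–28 patch curvature variance at the 5 scales
29–33 patch-averaged hydropathy at the 5 scales
34–38 patch-averaged electrostatic potential at the 5 scales
39–40 distance to nearest H-bond donor / acceptor
====  ==============================================================

Raw features mix units (Å, 1/Å, kT/e, ...), so before any comparison they
are z-scored against a reference corpus: per-feature mean and standard
deviation pooled over all vertices of a set of reference surfaces (the
original study used 100 random PDB proteins).  Stats are explicit, versioned
inputs — a surface records the id of the stats used to normalize it, so
results are reproducible and renormalizable.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np

from . import chemistry, geometry
from .chemistry import PotentialGrid, Structure
from .geometry import TriangleMesh

SCALES = (1.6, 3.2, 4.8, 6.4, 8.0)
N_FEATURES = 40

_CATEGORY_LABELS = (
    "dist_non_polar_backbone", "dist_aromatic_sidechain", "dist_aliphatic_sidechain",
    "dist_N_backbone", "dist_O_backbone", "dist_S_sidechain",
    "dist_amide_N_sidechain", "dist_amide_O_sidechain", "dist_trp_sidechain",
    "dist_hydroxyl_sidechain", "dist_charged_O_sidechain", "dist_charged_N_sidechain",
)

FEATURE_NAMES: tuple[str, ...] = (
    ("visibility",)
    + _CATEGORY_LABELS
    + tuple(f"anisotropy_{s:g}A" for s in SCALES)
    + tuple(f"curvature_{s:g}A" for s in SCALES)
    + tuple(f"curvature_var_{s:g}A" for s in SCALES)
    + tuple(f"hydropathy_{s:g}A" for s in SCALES)
    + tuple(f"charge_{s:g}A" for s in SCALES)
    + ("dist_hbond_donor", "dist_hbond_acceptor")
)
assert len(FEATURE_NAMES) == N_FEATURES

# index blocks into the 40-vector
IDX_VISIBILITY = 0
IDX_CATEGORY = tuple(range(1, 13))
IDX_ANISOTROPY = tuple(range(13, 18))
IDX_CURVATURE = tuple(range(18, 23))
IDX_CURV_VAR = tuple(range(23, 28))
IDX_HYDROPATHY = tuple(range(28, 33))
IDX_CHARGE = tuple(range(33, 38))
IDX_DONOR = 38
IDX_ACCEPTOR = 39


class NormalizationError(ValueError):
    """Normalization misuse (double-normalize, empty corpus, stats mismatch)."""


@dataclasses.dataclass
class NormalizationStats:
    """Per-feature corpus mean/sd (sd floored at 1e-6) with provenance ids."""

    mean: np.ndarray
    sd: np.ndarray
    corpus_ids: tuple = ()

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (N_FEATURES,) or self.sd.shape != (N_FEATURES,):
            raise NormalizationError("stats must have exactly 40 features")
        if (self.sd <= 0).any():
            raise NormalizationError("stats sd must be positive")

    @property
    def stats_id(self) -> str:
        h = hashlib.sha1()
        h.update(self.mean.tobytes())
        h.update(self.sd.tobytes())
        return h.hexdigest()[:12]


@dataclasses.dataclass
class DescriptorSurface:
    """A mesh plus one 40-feature descriptor per vertex."""

    mesh: TriangleMesh
    features: np.ndarray            # (n_vertices, 40)
    normalized: bool = False
    stats_id: str | None = None
    surface_id: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (self.mesh.n_vertices, N_FEATURES):
            raise ValueError(
                f"features must be ({self.mesh.n_vertices}, {N_FEATURES}), "
                f"got {self.features.shape}"
            )
        if not np.isfinite(self.features).all():
            raise ValueError("descriptor features must all be finite")


def assemble_descriptors(
    mesh: TriangleMesh,
    structure: Structure,
    grid: PotentialGrid | None = None,
    *,
    coulomb_fallback: bool = True,
    n_rays: int = 64,
    cap: float = chemistry.DISTANCE_CAP,
    method: str = "corner_cut",
    surface_id: str = "",
) -> DescriptorSurface:
    """Compute the raw 40-feature descriptor for every vertex of a surface.

    The mesh and structure must share a coordinate frame.  Electrostatics
    come from ``grid`` when given, else from the Coulomb fallback (or an
    error when ``coulomb_fallback=False``).
    """
    if structure is None or not structure.atoms:
        raise ValueError("a structure with at least one protein atom is required")
    if grid is None and not coulomb_fallback:
        raise ValueError("no potential grid supplied and the Coulomb fallback is disabled")

    n = mesh.n_vertices
    feats = np.empty((n, N_FEATURES))

    feats[:, IDX_VISIBILITY] = geometry.visibility_all(mesh, n_rays)

    assignment = chemistry.classify_atoms(structure)
    cat = chemistry.category_distance_field(mesh.vertices, structure, assignment, cap)
    feats[:, IDX_CATEGORY] = cat[:, :12]
    feats[:, IDX_DONOR] = cat[:, 12]
    feats[:, IDX_ACCEPTOR] = cat[:, 13]

    hyd = chemistry.hydropathy_field(mesh, structure)
    if grid is not None:
        charge = chemistry.sample_potential(grid, mesh.vertices)
    else:
        charge = chemistry.coulomb_potential(structure, mesh.vertices)

    # one Dijkstra pass at the largest scale; smaller scales filter it
    lists = geometry.geodesic_distance_lists(mesh, SCALES[-1], method)
    kk = geometry.point_curvatures(mesh, SCALES[0], method=method)
    kmean = 0.5 * (kk[:, 0] + kk[:, 1])
    aniso = geometry._anisotropy(kk[:, 0], kk[:, 1])
    areas = mesh.vertex_areas

    for v in range(n):
        members, dists = lists[v]
        for si, scale in enumerate(SCALES):
            sel = members[dists <= scale]
            if si == 0 and len(sel) < geometry.MIN_PATCH_MEMBERS:
                raise geometry.UnderConstrainedError(
                    f"vertex {v}: only {len(sel)} members within the smallest "
                    f"scale {scale} Å — mesh density too low"
                )
            w = areas[sel]
            w = w / w.sum()
            km = kmean[sel]
            mu = w @ km
            feats[v, IDX_ANISOTROPY[si]] = w @ aniso[sel]
            feats[v, IDX_CURVATURE[si]] = mu
            feats[v, IDX_CURV_VAR[si]] = w @ (km - mu) ** 2
            feats[v, IDX_HYDROPATHY[si]] = w @ hyd[sel]
            feats[v, IDX_CHARGE[si]] = w @ charge[sel]

    return DescriptorSurface(mesh=mesh, features=feats, normalized=False,
                             surface_id=surface_id)


def fit_normalization(surfaces: list[DescriptorSurface]) -> NormalizationStats:
    """Pool all vertices of a reference corpus and fit per-feature mean/sd."""
    if not surfaces:
        raise NormalizationError("empty normalization corpus")
    for s in surfaces:
        if s.normalized:
            raise NormalizationError("normalization corpus must be raw surfaces")
    pooled = np.vstack([s.features for s in surfaces])
    if len(pooled) < 2:
        raise NormalizationError("pooled corpus must contain at least 2 vertices")
    sd = pooled.std(axis=0)
    return NormalizationStats(
        mean=pooled.mean(axis=0),
        sd=np.maximum(sd, 1e-6),
        corpus_ids=tuple(s.surface_id for s in surfaces),
    )


def apply_normalization(
    surface: DescriptorSurface, stats: NormalizationStats
) -> DescriptorSurface:
    """Z-score a raw surface against corpus stats; records the stats id."""
    if surface.normalized:
        raise NormalizationError("surface is already normalized")
    return DescriptorSurface(
        mesh=surface.mesh,
        features=(surface.features - stats.mean) / stats.sd,
        normalized=True,
        stats_id=stats.stats_id,
        surface_id=surface.surface_id,
    )


def invert_normalization(
    surface: DescriptorSurface, stats: NormalizationStats
) -> DescriptorSurface:
    """Undo :func:`apply_normalization` (exact up to float rounding)."""
    if not surface.normalized:
        raise NormalizationError("surface is not normalized")
    if surface.stats_id != stats.stats_id:
        raise NormalizationError(
            f"surface was normalized with stats {surface.stats_id}, "
            f"not {stats.stats_id}"
        )
    return DescriptorSurface(
        mesh=surface.mesh,
        features=surface.features * stats.sd + stats.mean,
        normalized=False,
        stats_id=None,
        surface_id=surface.surface_id,
    )
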