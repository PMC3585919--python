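"""Greedy disc-based grouping of redundant surface samples.

A dense surface mesh over-samples slowly varying regions.  Before prediction,
samples that are both geodesically close and similar in the features that
matter for a given atom (its "important" features) are collapsed onto a
single representative.  The algorithm sweeps a decreasing schedule of disc
radii; at each radius it scores every candidate geodesic disc by the average
pairwise feature distance among its members, accepts discs in ascending score
order provided the average is below a threshold T and the disc shares no
sample with an already accepted disc, and replaces each accepted disc by its
center sample (retaining the disc radius, which later relaxes inter-atom
distance windows).  Leftover samples merge into an adjacent accepted disc
when within T of its center, else stand alone.  Because features are
corpus-normalized, T is in units of per-feature standard deviations.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy.spatial.distance import pdist

from .descriptor import DescriptorSurface, N_FEATURES
from .geometry import geodesic_distance_lists

DEFAULT_SCHEDULE = (4.0, 2.0, 1.0, 0.5)
MAX_EXACT_PAIRS = 200  # discs with more pairs use a seeded pair subsample


@dataclasses.dataclass
class GroupingParams:
    """Disc radii schedule and feature-distance threshold."""

    R_max: float = 4.0
    r_min: float = 0.5
    T: float = 0.5
    radius_schedule: tuple = None  # default: halving from R_max to r_min

    def __post_init__(self) -> None:
        if not (self.R_max >= self.r_min > 0):
            raise ValueError("need R_max ≥ r_min > 0")
        if self.T <= 0:
            raise ValueError("threshold T must be positive")
        if self.radius_schedule is None:
            sched = []
            r = self.R_max
            while r > self.r_min:
                sched.append(r)
                r /= 2.0
            sched.append(self.r_min)
            self.radius_schedule = tuple(sched)
        self.radius_schedule = tuple(float(r) for r in self.radius_schedule)
        diffs = np.diff(self.radius_schedule)
        if len(self.radius_schedule) == 0 or (diffs >= 0).any():
            raise ValueError("radius schedule must be strictly decreasing")


@dataclasses.dataclass
class SampleGroups:
    """Result of grouping: representatives and the vertex partition.

    ``member_of`` maps every vertex to its representative (representatives map
    to themselves); ``patch_radius`` holds the accepted disc radius per
    representative (0 for singletons); ``unassigned`` lists the singleton
    leftovers that joined no disc.
    """

    representatives: np.ndarray
    member_of: dict
    patch_radius: dict
    unassigned: np.ndarray

    @property
    def n_representatives(self) -> int:
        return len(self.representatives)

    def radii_array(self) -> np.ndarray:
        return np.array([self.patch_radius[int(r)] for r in self.representatives])


def feature_distance(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Root-mean-square difference over masked features (per-feature σ units)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("feature mask must select at least one feature")
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float))[mask]
    return float(np.sqrt(np.mean(d * d)))


def _avg_pairwise(F: np.ndarray, rng: np.random.Generator) -> float:
    """Mean pairwise RMS feature distance among rows of F."""
    m = len(F)
    if m < 2:
        return 0.0
    n_pairs = m * (m - 1) // 2
    k = F.shape[1]
    if n_pairs <= MAX_EXACT_PAIRS * 40:  # exact is cheap enough well past the guard
        return float(pdist(F).mean() / np.sqrt(k))
    ii = rng.integers(0, m, size=MAX_EXACT_PAIRS)
    jj = rng.integers(0, m - 1, size=MAX_EXACT_PAIRS)
    jj = np.where(jj >= ii, jj + 1, jj)
    d = F[ii] - F[jj]
    return float(np.sqrt((d * d).mean(axis=1)).mean())


def group_samples(
    surface: DescriptorSurface,
    mask: np.ndarray,
    params: GroupingParams | None = None,
    method: str = "corner_cut",
    seed: int = 0,
) -> SampleGroups:
    """Greedy disc grouping under the masked feature distance.

    Deterministic for a fixed surface and parameters: candidate ties break by
    (average distance, lowest center id), and the leftover merge scans vertex
    ids in ascending order.
    """
    if not surface.normalized:
        raise ValueError("grouping requires a normalized surface")
    params = params or GroupingParams()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (N_FEATURES,):
        raise ValueError(f"mask must have {N_FEATURES} entries")
    if not mask.any():
        raise ValueError("feature mask must select at least one feature")

    n = surface.mesh.n_vertices
    F = surface.features[:, mask]
    rng = np.random.default_rng(seed)
    assigned = np.full(n, -1, dtype=int)   # vertex -> representative (or -1)
    patch_radius: dict[int, float] = {}

    lists = geodesic_distance_lists(surface.mesh, params.radius_schedule[0], method)

    for R in params.radius_schedule:
        candidates = []
        for center in range(n):
            if assigned[center] >= 0:
                continue
            members, dists = lists[center]
            members = members[dists <= R]
            if len(members) < 2:
                continue
            if (assigned[members] >= 0).any():
                continue
            score = _avg_pairwise(F[members], rng)
            if score < params.T:
                candidates.append((score, center, members))
        candidates.sort(key=lambda t: (t[0], t[1]))
        for score, center, members in candidates:
            if (assigned[members] >= 0).any():
                continue
            assigned[members] = center
            patch_radius[center] = R

    # leftovers: join an edge-adjacent accepted disc when close to its center
    neighbors = _vertex_neighbors(surface.mesh)
    unassigned = []
    for v in range(n):
        if assigned[v] >= 0:
            continue
        reps = sorted({int(assigned[u]) for u in neighbors[v] if assigned[u] >= 0})
        best = None
        for r in reps:
            d = feature_distance(surface.features[v], surface.features[r], mask)
            if d < params.T and (best is None or d < best[0]):
                best = (d, r)
        if best is not None:
            assigned[v] = best[1]
        else:
            assigned[v] = v
            patch_radius[v] = 0.0
            unassigned.append(v)

    representatives = np.array(sorted(patch_radius), dtype=int)
    member_of = {v: int(assigned[v]) for v in range(n)}
    return SampleGroups(
        representatives=representatives,
        member_of=member_of,
        patch_radius=patch_radius,
        unassigned=np.array(unassigned, dtype=int),
    )


def _vertex_neighbors(mesh) -> list:
    nbr: list[set] = [set() for _ in range(mesh.n_vertices)]
    for t in mesh.triangles:
        for a, b in itertools.combinations(t, 2):
            nbr[a].add(int(b))
            nbr[b].add(int(a))
    return [sorted(s) for s in nbr]


def groups_to_json(groups: SampleGroups) -> dict:
    members: dict[int, list] = {int(r): [] for r in groups.representatives}
    for v, r in groups.member_of.items():
        if v != r:
            members[int(r)].append(int(v))
    return {
        "format": "locsurf-groups", "version": 1,
        "groups": [
            {"representative": int(r), "radius": float(groups.patch_radius[int(r)]),
             "members": sorted(members[int(r)])}
            for r in groups.representatives
        ],
        "unassigned": [int(v) for v in groups.unassigned],
    }
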