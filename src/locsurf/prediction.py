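"""Combining per-atom classifiers into a per-surface-point binding probability.

Prediction is fine-to-coarse.  Each atom classifier is run over its own
reduced sample set, giving a probability field P_A per atom.  Fields then
confirm each other through the learned inter-atom distance bounds: a high
P_A at a sample is only trustworthy if some plausible partner location for
every other atom B carries probability mass within the observed [min, max]
distance window of the (A, B) pair.  Concretely, for sample s of atom A and
partner atom B,

    conf_B(s) = mean of P_B over B-samples s' with ‖x_s − x_s'‖ in
                [min_AB − r(s'), max_AB + r(s')]

(the window is relaxed by the grouping patch radius r(s') of the partner
sample, which compensates for the positional coarsening introduced by
grouping; an empty window is disconfirming, conf_B = 0), and

    PC_A(s) = P_A(s) × mean over contributing B of conf_B(s).

Averaging inside the window (rather than taking the maximum) keeps spurious
isolated peaks from vouching for each other.  Atom pairs whose minimum
observed distance exceeds a cutoff (15 Å) are never combined.  Confirmed
fields expand back to the full vertex set and merge by pointwise maximum
into a moiety field P_M, and moiety fields merge by maximum into the final
ligand field P.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

from .descriptor import DescriptorSurface
from .grouping import GroupingParams, SampleGroups, group_samples
from .training import AtomClassifier, DistanceBounds, LigandModel

PAIR_CUTOFF = 15.0  # Å: atom pairs with larger minimum separation are not combined

ROLES = ("P_A", "PC_A", "P_M", "P")


class ProvenanceError(ValueError):
    """Surface/model normalization stats mismatch."""


@dataclasses.dataclass
class ProbabilityField:
    """Probabilities in [0, 1] per sample, at representative or vertex resolution."""

    surface_id: str
    values: np.ndarray
    role: str
    resolution: str = "vertices"        # "vertices" | "representatives"
    sample_ids: np.ndarray | None = None  # vertex ids when resolution=representatives

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"unknown field role {self.role!r}")
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)


def predict_atom_field(
    surface: DescriptorSurface,
    groups: SampleGroups,
    clf: AtomClassifier,
    expected_stats_id: str | None = None,
) -> ProbabilityField:
    """Run one atom classifier over the representative samples."""
    if not surface.normalized:
        raise ProvenanceError("surface must be normalized before prediction")
    if expected_stats_id is not None and surface.stats_id != expected_stats_id:
        raise ProvenanceError(
            f"surface normalized with stats {surface.stats_id}, "
            f"model expects {expected_stats_id}"
        )
    reps = groups.representatives
    if len(reps) == 0:
        raise ValueError("empty representative set")
    p = clf.predict_proba(surface.features[reps])
    return ProbabilityField(
        surface_id=surface.surface_id, values=p, role="P_A",
        resolution="representatives", sample_ids=reps,
    )


def expand_field(field: ProbabilityField, groups: SampleGroups) -> ProbabilityField:
    """Propagate representative values to every vertex of their group."""
    if field.resolution != "representatives":
        raise ValueError("field is already at vertex resolution")
    rep_value = dict(zip((int(r) for r in field.sample_ids), field.values))
    n = len(groups.member_of)
    out = np.empty(n)
    for v in range(n):
        r = groups.member_of[v]
        try:
            out[v] = rep_value[r]
        except KeyError:
            raise ValueError(f"vertex {v}: representative {r} has no value") from None
    return ProbabilityField(
        surface_id=field.surface_id, values=out, role=field.role,
        resolution="vertices",
    )


def confirm_fields(
    fields: dict,
    positions: np.ndarray,
    bounds: DistanceBounds,
    patch_radii: dict,
    pair_cutoff: float = PAIR_CUTOFF,
    combine: str = "arithmetic",
) -> dict:
    """Confirm each per-atom field against all partners (distance windows).

    ``fields`` maps atom name -> representative-resolution P_A field;
    ``positions`` are the vertex coordinates of the shared surface;
    ``patch_radii`` maps atom name -> per-representative disc radius array.
    Returns atom name -> PC_A field at the same resolution.  Exact range
    search (vectorized distance evaluation); no approximation.
    """
    if combine not in {"arithmetic", "geometric"}:
        raise ValueError(f"unknown combine mode {combine!r}")
    names = sorted(fields)
    sid = {fields[a].surface_id for a in names}
    if len(sid) > 1:
        raise ValueError("all fields must live on the same surface")
    out = {}
    for a in names:
        fa = fields[a]
        xa = positions[fa.sample_ids]
        confs = []
        for b in names:
            if b == a:
                continue
            if not bounds.has(a, b):
                raise KeyError(f"missing distance bounds for pair ({a}, {b})")
            lo, hi = bounds.get(a, b)
            if lo > pair_cutoff:
                continue
            fb = fields[b]
            xb = positions[fb.sample_ids]
            rb = np.asarray(patch_radii[b], dtype=float)
            D = cdist(xa, xb)
            inside = (D >= lo - rb[None, :]) & (D <= hi + rb[None, :])
            cnt = inside.sum(axis=1)
            s = inside @ fb.values
            with np.errstate(invalid="ignore"):
                conf = np.where(cnt > 0, s / np.maximum(cnt, 1), 0.0)
            confs.append(conf)
        if confs:
            C = np.stack(confs)
            agg = C.mean(axis=0) if combine == "arithmetic" else \
                np.exp(np.log(np.maximum(C, 1e-300)).mean(axis=0)) * (C > 0).all(axis=0)
            values = fa.values * agg
        else:
            values = fa.values.copy()
        out[a] = ProbabilityField(
            surface_id=fa.surface_id, values=values, role="PC_A",
            resolution=fa.resolution, sample_ids=fa.sample_ids,
        )
    return out


def _merge_max(fields: list, role: str) -> ProbabilityField:
    if not fields:
        raise ValueError("need at least one field to merge")
    sid = {f.surface_id for f in fields}
    if len(sid) > 1:
        raise ValueError(f"surface-id mismatch in merge: {sorted(sid)}")
    res = {f.resolution for f in fields}
    if len(res) > 1 or {len(f.values) for f in fields} != {len(fields[0].values)}:
        raise ValueError("fields must share resolution and length")
    return ProbabilityField(
        surface_id=fields[0].surface_id,
        values=np.max(np.stack([f.values for f in fields]), axis=0),
        role=role,
        resolution=fields[0].resolution,
    )


def merge_moiety(fields: list) -> ProbabilityField:
    """P_M = pointwise maximum of the confirmed per-atom fields."""
    return _merge_max(list(fields), "P_M")


def merge_ligand(fields: list) -> ProbabilityField:
    """P = pointwise maximum over the moiety fields."""
    return _merge_max(list(fields), "P")


@dataclasses.dataclass
class PredictConfig:
    grouping: GroupingParams = dataclasses.field(default_factory=GroupingParams)
    pair_cutoff: float = PAIR_CUTOFF
    combine: str = "arithmetic"
    keep_intermediates: bool = False
    seed: int = 0


@dataclasses.dataclass
class PredictionResult:
    field: ProbabilityField                  # final P over all vertices
    moiety_fields: dict                      # moiety name -> P_M
    intermediates: dict | None = None        # per moiety: groups, P_A, PC_A


def predict_ligand(
    surface: DescriptorSurface,
    model: LigandModel,
    config: PredictConfig | None = None,
) -> PredictionResult:
    """Full pipeline: group → P_A → confirm → expand → merge moiety/ligand."""
    config = config or PredictConfig()
    if not surface.normalized:
        raise ProvenanceError("surface must be normalized before prediction")
    if model.stats_id is not None and surface.stats_id != model.stats_id:
        raise ProvenanceError(
            f"surface normalized with stats {surface.stats_id}, "
            f"model expects {model.stats_id}"
        )
    moiety_fields = {}
    intermediates: dict = {}
    for mm in model.moieties:
        groups_by_atom, pa_by_atom, radii_by_atom = {}, {}, {}
        for atom_name in mm.spec.atom_names:
            clf = mm.classifiers[atom_name]
            mask = clf.important_mask
            if not mask.any():
                mask = np.ones_like(mask)
            groups = group_samples(surface, mask, config.grouping, seed=config.seed)
            groups_by_atom[atom_name] = groups
            pa_by_atom[atom_name] = predict_atom_field(surface, groups, clf, mm.stats_id)
            radii_by_atom[atom_name] = groups.radii_array()
        pc_by_atom = confirm_fields(
            pa_by_atom, surface.mesh.vertices, mm.bounds, radii_by_atom,
            pair_cutoff=config.pair_cutoff, combine=config.combine,
        )
        expanded = [
            expand_field(pc_by_atom[a], groups_by_atom[a]) for a in mm.spec.atom_names
        ]
        moiety_fields[mm.spec.name] = merge_moiety(expanded)
        if config.keep_intermediates:
            intermediates[mm.spec.name] = {
                "groups": groups_by_atom, "P_A": pa_by_atom, "PC_A": pc_by_atom,
            }
    final = merge_ligand(list(moiety_fields.values()))
    return PredictionResult(
        field=final,
        moiety_fields=moiety_fields,
        intermediates=intermediates if config.keep_intermediates else None,
    )
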