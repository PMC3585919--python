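"""Per-atom classifier training and moiety/ligand model construction.

A ligand model is built atom by atom.  For each atom of each moiety (a
chemist-defined rigid fragment such as the adenine of ATP), surface samples
within 1.6 Å of the bound atom's van der Waals surface across a corpus of
example complexes become positive examples; an equal number of negatives is
drawn uniformly from the rest of each surface, and a probability-calibrated
RBF-kernel support-vector classifier is trained on the normalized 40-feature
descriptors.  Alongside the classifiers, the observed minimum and maximum
Euclidean distance between every atom pair over the training conformers is
stored: these bounds capture ligand flexibility and later constrain how
per-atom predictions may confirm each other.

Training corpora are selected with at most one example per cluster of
homologous proteins (the cluster assignment — e.g. BLASTCLUST output — is a
precomputed input), which keeps redundant near-identical binding sites from
dominating the corpus.
"""

from __future__ import annotations

import base64
import dataclasses
import io as _io
import itertools
import logging
import pickle

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .chemistry import Atom
from .descriptor import N_FEATURES, DescriptorSurface, NormalizationStats
from .geometry import TriangleMesh

logger = logging.getLogger(__name__)

INTERFACE_RADIUS = 1.6  # Å from the vdW surface


@dataclasses.dataclass
class MoietySpec:
    """A named ligand fragment: its atom names and the ligand codes that carry it."""

    name: str
    atom_names: list
    matching_ligand_codes: list

    def __post_init__(self) -> None:
        if not self.atom_names:
            raise ValueError("moiety must have at least one atom name")
        self.matching_ligand_codes = [c.upper() for c in self.matching_ligand_codes]


@dataclasses.dataclass
class AtomClassifier:
    """Probability-calibrated RBF-SVM for one ligand atom's micro-environment."""

    atom_name: str
    model: CalibratedClassifierCV
    important_mask: np.ndarray
    n_pos: int
    n_neg: int
    train_seed: int
    shortfall: bool = False
    hyper: tuple = (1.0, None)   # (C, gamma) actually used

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """P(positive) per sample, guaranteed in [0, 1]."""
        features = np.asarray(features, dtype=float)
        if features.ndim == 1:
            features = features[None, :]
        pos_col = int(np.flatnonzero(self.model.classes_ == 1)[0])
        return np.clip(self.model.predict_proba(features)[:, pos_col], 0.0, 1.0)


class DistanceBounds:
    """Observed (min, max) Euclidean distance per unordered atom-name pair."""

    def __init__(self, bounds: dict | None = None, n_observations: dict | None = None):
        self._b: dict[frozenset, tuple[float, float]] = dict(bounds or {})
        self.n_observations: dict[frozenset, int] = dict(n_observations or {})
        for k, (lo, hi) in self._b.items():
            if not (0 < lo <= hi):
                raise ValueError(f"invalid bounds {lo, hi} for pair {sorted(k)}")

    def pairs(self):
        return list(self._b)

    def has(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._b

    def get(self, a: str, b: str) -> tuple[float, float]:
        try:
            return self._b[frozenset((a, b))]
        except KeyError:
            raise KeyError(f"no distance bounds observed for pair ({a}, {b})") from None

    def items(self):
        return self._b.items()


@dataclasses.dataclass
class MoietyModel:
    spec: MoietySpec
    classifiers: dict                  # atom name -> AtomClassifier
    bounds: DistanceBounds
    stats_id: str | None = None

    def __post_init__(self) -> None:
        missing = set(self.spec.atom_names) - set(self.classifiers)
        if missing:
            raise ValueError(f"moiety {self.spec.name}: no classifier for {sorted(missing)}")


@dataclasses.dataclass
class LigandModel:
    ligand_code: str
    moieties: list
    stats: NormalizationStats | None = None

    def __post_init__(self) -> None:
        if not self.moieties:
            raise ValueError("ligand model needs at least one moiety")

    @property
    def stats_id(self) -> str | None:
        return self.stats.stats_id if self.stats is not None else None


# ---------------------------------------------------------------------------
# corpus selection
# ---------------------------------------------------------------------------

def select_corpus(
    candidates: list,
    clusters: dict,
    spec: MoietySpec,
    max_size: int,
    seed: int,
) -> list:
    """Pick a training corpus: matching ligands, one id per homology cluster.

    ``candidates`` is a list of (protein id, iterable of ligand codes);
    ``clusters`` maps protein id -> cluster id.  Within each cluster one
    matching candidate is chosen uniformly at random (seeded); if more than
    ``max_size`` clusters match, a uniform subsample is taken.
    """
    wanted = set(spec.matching_ligand_codes)
    by_cluster: dict = {}
    for pid, codes in candidates:
        if pid not in clusters:
            raise KeyError(f"candidate {pid!r} has no cluster assignment")
        if wanted & {c.upper() for c in codes}:
            by_cluster.setdefault(clusters[pid], []).append(pid)
    if not by_cluster:
        raise ValueError(f"no candidates bind a ligand matching moiety {spec.name!r}")
    rng = np.random.default_rng(seed)
    picks = []
    for cid in sorted(by_cluster, key=str):
        members = sorted(by_cluster[cid])
        picks.append(members[rng.integers(0, len(members))])
    if len(picks) > max_size:
        idx = rng.choice(len(picks), size=max_size, replace=False)
        picks = [picks[i] for i in sorted(idx)]
    return picks


def remove_homologs(corpus: list, test_ids: list, clusters: dict) -> list:
    """Drop corpus ids sharing a homology cluster with any test id."""
    test_clusters = {clusters[t] for t in test_ids if t in clusters}
    return [p for p in corpus if clusters.get(p) not in test_clusters]


# ---------------------------------------------------------------------------
# positive / negative sample selection
# ---------------------------------------------------------------------------

def surface_offsets(mesh: TriangleMesh, atom: Atom) -> np.ndarray:
    """Signed distance from each vertex to the atom's vdW sphere surface."""
    return np.linalg.norm(mesh.vertices - atom.position, axis=1) - atom.vdw_radius


def label_positives(
    surface: DescriptorSurface,
    atom: Atom,
    radius: float = INTERFACE_RADIUS,
    mode: str = "surface",
) -> set:
    """Vertices within ``radius`` of the atom (boundary inclusive).

    ``mode="surface"`` (default) measures to the van der Waals sphere surface,
    matching the interface ground-truth definition; ``mode="center"`` measures
    to the atom center.
    """
    d = np.linalg.norm(surface.mesh.vertices - atom.position, axis=1)
    if mode == "surface":
        d = d - atom.vdw_radius
    elif mode != "center":
        raise ValueError(f"unknown mode {mode!r}")
    return set(np.flatnonzero(d <= radius + 1e-12).tolist())


@dataclasses.dataclass
class NegativeDraw:
    vertices: set
    shortfall: bool


def draw_negatives(surface: DescriptorSurface, positives: set, seed: int) -> NegativeDraw:
    """Uniform sample of non-positive vertices, same size as the positive set.

    When fewer non-positive vertices remain than requested, all are taken and
    the shortfall flag is set.
    """
    if not positives:
        raise ValueError("positive set is empty")
    pool = np.setdiff1d(np.arange(surface.mesh.n_vertices), np.fromiter(positives, dtype=int))
    want = len(positives)
    rng = np.random.default_rng(seed)
    if len(pool) <= want:
        return NegativeDraw(set(pool.tolist()), shortfall=len(pool) < want)
    pick = rng.choice(pool, size=want, replace=False)
    return NegativeDraw(set(pick.tolist()), shortfall=False)


# ---------------------------------------------------------------------------
# classifier training
# ---------------------------------------------------------------------------

def important_features(pos: np.ndarray) -> np.ndarray:
    """Mask of features whose variance over the positives is below background.

    Features are corpus-normalized, so the background variance is 1; a
    feature is "important" for an atom when its positive examples agree more
    than the background does (sample variance strictly < 1).
    """
    pos = np.asarray(pos, dtype=float)
    if pos.ndim != 2 or len(pos) < 2:
        raise ValueError("need at least 2 positive vectors")
    return pos.var(axis=0, ddof=1) < 1.0


def train_atom_classifier(
    pos: np.ndarray,
    neg: np.ndarray,
    hyper: tuple | None = None,
    seed: int = 0,
    atom_name: str = "",
    shortfall: bool = False,
) -> AtomClassifier:
    """Train a probability-calibrated RBF-SVM on normalized descriptors.

    Default hyperparameters: C = 1 and gamma = 1/(40 · pooled feature
    variance); Platt (sigmoid) scaling with internal 5-fold CV provides
    calibrated probabilities.  Both are recorded on the returned classifier.
    Each class needs at least 2 examples (the calibration folds must see
    both classes).
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both positive and negative sets must be nonempty")
    if min(len(pos), len(neg)) < 2:
        raise ValueError("probability calibration needs ≥ 2 examples per class")
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]).astype(int)
    if hyper is None:
        pooled_var = float(X.var())
        gamma = 1.0 / (N_FEATURES * pooled_var) if pooled_var > 0 else 1.0 / N_FEATURES
        hyper = (1.0, gamma)
    C, gamma = hyper
    model = CalibratedClassifierCV(
        SVC(C=C, kernel="rbf", gamma=gamma, random_state=seed),
        method="sigmoid",
        cv=min(5, len(pos), len(neg)),
        ensemble=False,
    )
    model.fit(X, y)
    return AtomClassifier(
        atom_name=atom_name,
        model=model,
        important_mask=important_features(pos) if len(pos) >= 2 else np.ones(N_FEATURES, bool),
        n_pos=len(pos),
        n_neg=len(neg),
        train_seed=seed,
        shortfall=shortfall,
        hyper=(float(C), float(gamma)),
    )


# ---------------------------------------------------------------------------
# inter-atom distance bounds
# ---------------------------------------------------------------------------

def measure_distance_bounds(instances: list, spec: MoietySpec) -> DistanceBounds:
    """Min/max Euclidean distance per atom pair over ligand conformers.

    ``instances`` is a list of ligand atom lists (one per training conformer);
    instances missing either atom of a pair are excluded from that pair's
    statistics, and pairs never co-observed are absent (with a warning).
    """
    names = list(spec.atom_names)
    bounds: dict[frozenset, tuple[float, float]] = {}
    counts: dict[frozenset, int] = {}
    for inst in instances:
        pos = {}
        for atom in inst:
            if atom.name in names:
                pos[atom.name] = atom.position
        for a, b in itertools.combinations(sorted(pos), 2):
            d = float(np.linalg.norm(pos[a] - pos[b]))
            key = frozenset((a, b))
            if key in bounds:
                lo, hi = bounds[key]
                bounds[key] = (min(lo, d), max(hi, d))
            else:
                bounds[key] = (d, d)
            counts[key] = counts.get(key, 0) + 1
    for a, b in itertools.combinations(sorted(names), 2):
        if frozenset((a, b)) not in bounds:
            logger.warning("no instance contains both %s and %s; pair absent", a, b)
    return DistanceBounds(bounds, counts)


# ---------------------------------------------------------------------------
# model construction and serialization
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainingExample:
    """One example complex: a raw descriptor surface plus its bound moiety atoms."""

    surface: DescriptorSurface
    ligand_atoms: list
    example_id: str = ""


def build_ligand_model(
    ligand_code: str,
    specs: list,
    corpora: dict,
    stats: NormalizationStats | None = None,
    seed: int = 0,
    hyper: tuple | None = None,
    radius: float = INTERFACE_RADIUS,
) -> LigandModel:
    """Orchestrate corpus normalization, per-atom training and bounds.

    ``corpora`` maps moiety name -> list of :class:`TrainingExample` with raw
    surfaces.  When ``stats`` is None, normalization stats are fitted on the
    pooled training surfaces themselves.
    """
    for spec in specs:
        if not corpora.get(spec.name):
            raise ValueError(f"empty training corpus for moiety {spec.name!r}")
    from .descriptor import apply_normalization, fit_normalization

    if stats is None:
        all_surfaces, seen = [], set()
        for spec in specs:
            for ex in corpora[spec.name]:
                if id(ex.surface) not in seen:
                    seen.add(id(ex.surface))
                    all_surfaces.append(ex.surface)
        stats = fit_normalization(all_surfaces)

    rng = np.random.default_rng(seed)
    moieties = []
    for spec in specs:
        examples = corpora[spec.name]
        normalized = [apply_normalization(ex.surface, stats) for ex in examples]
        classifiers = {}
        for atom_name in spec.atom_names:
            pos_vecs, neg_vecs, shortfall = [], [], False
            for ex, nsurf in zip(examples, normalized):
                atoms = [a for a in ex.ligand_atoms if a.name == atom_name]
                if not atoms:
                    continue
                positives: set = set()
                for atom in atoms:
                    positives |= label_positives(nsurf, atom, radius)
                if not positives:
                    continue
                draw = draw_negatives(nsurf, positives, int(rng.integers(2**31 - 1)))
                shortfall |= draw.shortfall
                pos_vecs.append(nsurf.features[sorted(positives)])
                neg_vecs.append(nsurf.features[sorted(draw.vertices)])
            if not pos_vecs:
                raise ValueError(
                    f"atom {atom_name!r} of moiety {spec.name!r} has zero "
                    "positive samples across the corpus"
                )
            classifiers[atom_name] = train_atom_classifier(
                np.vstack(pos_vecs), np.vstack(neg_vecs),
                hyper=hyper, seed=int(rng.integers(2**31 - 1)),
                atom_name=atom_name, shortfall=shortfall,
            )
        bounds = measure_distance_bounds([ex.ligand_atoms for ex in examples], spec)
        moieties.append(
            MoietyModel(spec=spec, classifiers=classifiers, bounds=bounds,
                        stats_id=stats.stats_id)
        )
    return LigandModel(ligand_code=ligand_code, moieties=moieties, stats=stats)


def model_to_json(model: LigandModel) -> dict:
    """Versioned JSON envelope with base64-pickled SVM payloads."""
    def clf_payload(c: AtomClassifier) -> dict:
        buf = _io.BytesIO()
        pickle.dump(c.model, buf)
        return {
            "atom_name": c.atom_name,
            "svm_pickle_b64": base64.b64encode(buf.getvalue()).decode(),
            "important_mask": c.important_mask.astype(int).tolist(),
            "n_pos": c.n_pos, "n_neg": c.n_neg,
            "train_seed": c.train_seed, "shortfall": c.shortfall,
            "hyper": list(c.hyper),
        }

    return {
        "format": "locsurf-model", "version": 1,
        "ligand_code": model.ligand_code,
        "stats": None if model.stats is None else {
            "mean": model.stats.mean.tolist(),
            "sd": model.stats.sd.tolist(),
            "corpus_ids": list(model.stats.corpus_ids),
        },
        "moieties": [
            {
                "spec": {
                    "name": m.spec.name,
                    "atom_names": list(m.spec.atom_names),
                    "matching_ligand_codes": list(m.spec.matching_ligand_codes),
                },
                "stats_id": m.stats_id,
                "classifiers": [clf_payload(c) for c in m.classifiers.values()],
                "bounds": [
                    {"pair": sorted(k), "min": lo, "max": hi,
                     "n": m.bounds.n_observations.get(k, 0)}
                    for k, (lo, hi) in m.bounds.items()
                ],
            }
            for m in model.moieties
        ],
    }


def model_from_json(doc: dict) -> LigandModel:
    if doc.get("format") != "locsurf-model":
        raise ValueError("not a locsurf model file")
    stats = None
    if doc.get("stats") is not None:
        stats = NormalizationStats(
            mean=np.asarray(doc["stats"]["mean"]),
            sd=np.asarray(doc["stats"]["sd"]),
            corpus_ids=tuple(doc["stats"]["corpus_ids"]),
        )
    moieties = []
    for md in doc["moieties"]:
        spec = MoietySpec(**md["spec"])
        classifiers = {}
        for cd in md["classifiers"]:
            svm = pickle.loads(base64.b64decode(cd["svm_pickle_b64"]))
            classifiers[cd["atom_name"]] = AtomClassifier(
                atom_name=cd["atom_name"], model=svm,
                important_mask=np.asarray(cd["important_mask"], dtype=bool),
                n_pos=cd["n_pos"], n_neg=cd["n_neg"],
                train_seed=cd["train_seed"], shortfall=cd["shortfall"],
                hyper=tuple(cd["hyper"]),
            )
        bounds = DistanceBounds(
            {frozenset(b["pair"]): (b["min"], b["max"]) for b in md["bounds"]},
            {frozenset(b["pair"]): b["n"] for b in md["bounds"]},
        )
        moieties.append(MoietyModel(spec=spec, classifiers=classifiers,
                                    bounds=bounds, stats_id=md["stats_id"]))
    return LigandModel(ligand_code=doc["ligand_code"], moieties=moieties, stats=stats)
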