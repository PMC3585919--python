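"""Structures, atom typing, and per-vertex chemical/physical fields.

Atoms are typed into 14 chemical categories (backbone carbons, aromatic and
aliphatic sidechain atoms, backbone N/O, sidechain S, amide N/O, tryptophan
sidechain, hydroxyls, charged O/N, hydrogen-bond donors and acceptors); the
descriptor uses the Euclidean distance from each surface point to the nearest
atom of each category.  Hydropathy is the Kyte–Doolittle index of the residue
owning the nearest heavy atom.  Electrostatic potential is sampled from an
APBS-style OpenDX grid by trilinear interpolation, or — as a flagged fallback
when no grid is supplied — from a Coulomb sum with a distance-dependent
dielectric ε(r) = 4r.

Hydrogens are usually absent from PDB files, so donor capability is inferred
from heavy-atom identity (e.g. a serine OG can donate) rather than from
explicit protons.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .geometry import GeodesicPatch, TriangleMesh

logger = logging.getLogger(__name__)


class PDBParseError(ValueError):
    """Unreadable PDB record (message names the line number)."""


def _load_vdw():
    with resources.files("locsurf.data").joinpath("vdw_radii.json").open() as fh:
        d = json.load(fh)
    return {k.upper(): float(v) for k, v in d["radii"].items()}, float(d["default"])

VDW_RADII, VDW_DEFAULT = _load_vdw()


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper().strip(), VDW_DEFAULT)


# Kyte & Doolittle hydropathy index per residue
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

DISTANCE_CAP = 20.0  # Å sentinel when a category is absent from the structure


@dataclasses.dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_seq: int
    position: np.ndarray
    vdw_radius: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.isfinite(self.position).all():
            raise ValueError(f"atom {self.serial}: non-finite position")
        if self.vdw_radius <= 0:
            self.vdw_radius = vdw_radius(self.element)


@dataclasses.dataclass
class Structure:
    """Protein atoms plus HETATM ligand instances grouped by residue."""

    atoms: list
    ligand_instances: list = dataclasses.field(default_factory=list)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms]).reshape(-1, 3)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_WATER = {"HOH", "WAT", "DOD"}

_AROMATIC_RING = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def _infer_element(name: str, residue: str) -> str:
    """Element from a PDB atom name when the element column is blank."""
    s = name.strip()
    if not s:
        return ""
    if s[:2].upper() in VDW_RADII and not s[0].isdigit() and len(s) >= 2 \
            and s[:2].upper() in {"FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "SE", "NI", "CO"}:
        return s[:2].upper()
    for ch in s:
        if ch.isalpha():
            return ch.upper()
    return s[0].upper()


def read_structure(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    ATOM records become protein atoms; HETATM records (waters excluded) are
    grouped into ligand instances by residue.  Elements are inferred from
    atom names when the element column is blank.
    """
    path = Path(path)
    atoms: list[Atom] = []
    het: dict[tuple, list[Atom]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21:22].strip() or " "
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"{path.name} line {ln}: unreadable record ({exc})") from exc
            element = line[76:78].strip().upper() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(name, resname)
            atom = Atom(
                serial=serial, name=name, element=element, residue_name=resname,
                chain=chain, residue_seq=resseq, position=np.array([x, y, z]),
                is_hetero=(rec == "HETATM"),
            )
            if rec == "HETATM" and resname not in _WATER:
                het.setdefault((chain, resseq, resname), []).append(atom)
            elif rec == "ATOM  ":
                atoms.append(atom)
    ligands = [(key[2], group) for key, group in het.items()]
    return Structure(atoms=atoms, ligand_instances=ligands)


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write a minimal PDB file (fixture/round-trip support)."""
    path = Path(path)
    with open(path, "w") as fh:
        for a in structure.atoms:
            fh.write(_pdb_line("ATOM", a))
        for _, group in structure.ligand_instances:
            for a in group:
                fh.write(_pdb_line("HETATM", a))
        fh.write("END\n")
    return path


def _pdb_line(rec: str, a: Atom) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name}"
    return (
        f"{rec:<6}{a.serial:>5} {name:<4} {a.residue_name:<3} {a.chain:1}"
        f"{a.residue_seq:>4}    {a.position[0]:8.3f}{a.position[1]:8.3f}"
        f"{a.position[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2}\n"
    )


# ---------------------------------------------------------------------------
# atom categories (Table-order vocabulary)
# ---------------------------------------------------------------------------

CATEGORIES = (
    "non_polar_backbone",
    "aromatic_sidechain",
    "aliphatic_sidechain",
    "N_backbone",
    "O_backbone",
    "S_sidechain",
    "amide_N_sidechain",
    "amide_O_sidechain",
    "trp_sidechain",
    "hydroxyl_sidechain",
    "charged_O_sidechain",
    "charged_N_sidechain",
    "hbond_donor",
    "hbond_acceptor",
)

_ALIPHATIC_RES = {"ALA", "VAL", "LEU", "ILE", "MET", "PRO"}
_HYDROXYL = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}
_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CHARGED_N = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
              ("HIS", "ND1"), ("HIS", "NE2")}
_AMIDE_N = {("ASN", "ND2"), ("GLN", "NE2")}
_AMIDE_O = {("ASN", "OD1"), ("GLN", "OE1")}
_S_SIDE = {("CYS", "SG"), ("MET", "SD")}
_SIDE_DONOR = (
    _HYDROXYL | _AMIDE_N | _CHARGED_N | {("TRP", "NE1")}
)
_SIDE_ACCEPTOR = (
    _HYDROXYL | _AMIDE_O | _CHARGED_O
    | {("HIS", "ND1"), ("HIS", "NE2")}
)

_KNOWN_RESIDUES = set(KYTE_DOOLITTLE)


@dataclasses.dataclass
class CategoryAssignment:
    """Per-atom category sets over the 14-member vocabulary."""

    per_atom: list  # list of frozenset[str], parallel to structure.atoms

    def mask(self, category: str) -> np.ndarray:
        if category not in CATEGORIES:
            raise KeyError(f"unknown category {category!r}")
        return np.array([category in s for s in self.per_atom], dtype=bool)


def _atom_categories(residue: str, name: str) -> frozenset:
    res, nm = residue.upper(), name.upper()
    key = (res, nm)
    cats = set()
    if nm in {"C", "CA"}:
        cats.add("non_polar_backbone")
    if nm == "N":
        cats.add("N_backbone")
        if res != "PRO":                    # proline nitrogen has no amide H
            cats.add("hbond_donor")
    if nm in {"O", "OXT"}:
        cats.add("O_backbone")
        cats.add("hbond_acceptor")
    is_backbone = nm in _BACKBONE
    if not is_backbone:
        if res in _AROMATIC_RING and nm in _AROMATIC_RING[res]:
            cats.add("aromatic_sidechain")
        if res in _ALIPHATIC_RES and nm.startswith("C"):
            cats.add("aliphatic_sidechain")
        if res == "TRP":
            cats.add("trp_sidechain")
        if key in _HYDROXYL:
            cats.add("hydroxyl_sidechain")
        if key in _CHARGED_O:
            cats.add("charged_O_sidechain")
        if key in _CHARGED_N:
            cats.add("charged_N_sidechain")
        if key in _AMIDE_N:
            cats.add("amide_N_sidechain")
        if key in _AMIDE_O:
            cats.add("amide_O_sidechain")
        if key in _S_SIDE:
            cats.add("S_sidechain")
        if key in _SIDE_DONOR:
            cats.add("hbond_donor")
        if key in _SIDE_ACCEPTOR:
            cats.add("hbond_acceptor")
    return frozenset(cats)


def classify_atoms(structure: Structure) -> CategoryAssignment:
    """Assign every protein atom its matching categories (possibly several)."""
    per_atom = []
    for a in structure.atoms:
        if a.residue_name.upper() not in _KNOWN_RESIDUES:
            logger.warning(
                "atom %s: unknown residue %r left uncategorized", a.serial, a.residue_name
            )
            per_atom.append(frozenset())
            continue
        per_atom.append(_atom_categories(a.residue_name, a.name))
    return CategoryAssignment(per_atom=per_atom)


def category_distances(
    point: np.ndarray,
    structure: Structure,
    assignment: CategoryAssignment,
    cap: float = DISTANCE_CAP,
) -> np.ndarray:
    """Distance from one point to the nearest atom of each of the 14 categories."""
    return category_distance_field(
        np.asarray(point, dtype=float).reshape(1, 3), structure, assignment, cap
    )[0]


def category_distance_field(
    points: np.ndarray,
    structure: Structure,
    assignment: CategoryAssignment,
    cap: float = DISTANCE_CAP,
) -> np.ndarray:
    """(n_points, 14) nearest-category distances, capped at the sentinel."""
    if not structure.atoms:
        raise ValueError("empty structure")
    points = np.asarray(points, dtype=float)
    pos = structure.positions
    out = np.full((len(points), len(CATEGORIES)), cap)
    for j, cat in enumerate(CATEGORIES):
        m = assignment.mask(cat)
        if m.any():
            d, _ = cKDTree(pos[m]).query(points)
            out[:, j] = np.minimum(d, cap)
    return out


def hydropathy_field(mesh: TriangleMesh, structure: Structure) -> np.ndarray:
    """Kyte–Doolittle index of the residue owning each vertex's nearest heavy atom.

    Equidistant ties break deterministically toward the lower atom serial.
    """
    heavy = [a for a in structure.atoms if a.element.upper() != "H"]
    if not heavy:
        raise ValueError("structure has no protein heavy atoms")
    heavy.sort(key=lambda a: a.serial)
    pos = np.array([a.position for a in heavy])
    values = np.array([KYTE_DOOLITTLE.get(a.residue_name.upper(), 0.0) for a in heavy])
    k = min(4, len(heavy))
    d, idx = cKDTree(pos).query(mesh.vertices, k=k)
    if k == 1:
        d, idx = d[:, None], idx[:, None]
    # among near-ties, take the lowest-serial atom (list already serial-sorted)
    tie = d <= d[:, [0]] + 1e-9
    choice = np.where(tie, idx, np.iinfo(np.int64).max).min(axis=1)
    return values[choice]


# ---------------------------------------------------------------------------
# electrostatics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PotentialGrid:
    """Scalar potential on a regular lattice (APBS OpenDX convention, kT/e)."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if (self.spacing <= 0).any():
            raise ValueError("grid spacing must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("degenerate grid: need ≥ 2 lattice points per axis")

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.values.shape) - 1)


def read_dx(path: str | Path) -> PotentialGrid:
    """Read an OpenDX scalar grid (as written by APBS) via gridData."""
    from gridData import Grid

    g = Grid(str(path))
    delta = np.asarray(g.delta)
    if delta.ndim == 2:
        delta = np.diag(delta)
    return PotentialGrid(origin=np.asarray(g.origin), spacing=delta, values=np.asarray(g.grid))


def write_dx(grid: PotentialGrid, path: str | Path) -> Path:
    from gridData import Grid

    g = Grid(grid.values, origin=grid.origin, delta=grid.spacing)
    g.export(str(path), file_format="dx")
    return Path(path)


def sample_potential(grid: PotentialGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the lattice at each point.

    Points outside the grid bounds are clamped to the nearest border value
    (with a warning), matching the usual treatment of surface points that
    poke out of a tight APBS box.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    axes = [
        grid.origin[k] + grid.spacing[k] * np.arange(grid.values.shape[k])
        for k in range(3)
    ]
    lo, hi = grid.origin, grid.upper
    outside = (points < lo - 1e-9).any(axis=1) | (points > hi + 1e-9).any(axis=1)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} point(s) outside the potential grid; "
            "using nearest-border values",
            stacklevel=2,
        )
    clipped = np.clip(points, lo, hi)
    interp = RegularGridInterpolator(axes, grid.values, method="linear")
    return interp(clipped)


# crude per-atom partial charges for the Coulomb fallback (e units)
_PARTIAL_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
    ("HIS", "ND1"): 0.1, ("HIS", "NE2"): 0.1,
}
_BACKBONE_CHARGES = {"O": -0.4, "N": 0.4}


def coulomb_potential(structure: Structure, points: np.ndarray) -> np.ndarray:
    """Screened Coulomb potential with distance-dependent dielectric ε(r)=4r.

    φ(p) = Σᵢ qᵢ / (ε(rᵢ)·rᵢ) = Σᵢ qᵢ / (4·rᵢ²), with crude formal-charge-like
    partial charges on titratable sidechain atoms and backbone N/O.  A rough
    stand-in for a Poisson–Boltzmann map, logged as such when used.
    """
    logger.info("no potential grid supplied: using Coulomb ε(r)=4r fallback")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    charges, pos = [], []
    for a in structure.atoms:
        q = _PARTIAL_CHARGES.get((a.residue_name.upper(), a.name.upper()))
        if q is None:
            q = _BACKBONE_CHARGES.get(a.name.upper(), 0.0)
        if q:
            charges.append(q)
            pos.append(a.position)
    if not charges:
        return np.zeros(len(points))
    pos = np.asarray(pos)
    charges = np.asarray(charges)
    d2 = ((points[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    d2 = np.maximum(d2, 1.0)  # avoid singularities at atom centers
    return (charges[None, :] / (4.0 * d2)).sum(axis=1)


def patch_average(field: np.ndarray, patch: GeodesicPatch) -> float:
    """Vertex-area weighted average of a per-vertex field over a patch."""
    w = np.asarray(patch.weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("patch has all-zero weights")
    f = np.asarray(field, dtype=float)[patch.members]
    return float((w * f).sum() / w.sum())
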