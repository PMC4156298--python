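"""Typed structure I/O for receptors (PDB) and docked ligand poses (PDBQT).

Readers populate lightweight dataclasses carrying exactly the chemistry the
fingerprint engine needs: per-atom hydrogen-bond donor/acceptor roles, formal
charge centres, aromatic-ring membership with ring centroids and normals, and
a backbone/sidechain partition. The PDB path is parsed with :mod:`gemmi`; the
PDBQT dialect (AutoDock's PDB extension with a trailing atom-type column and
multi-``MODEL`` pose blocks) is handled by a dedicated reader/writer.

Coordinates are Å in the frame of the input file; no symmetry expansion is
performed, so oligomeric binding sites spanning protomer interfaces must be
provided pre-expanded (one chain per protomer).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Ring",
    "TypedStructure",
    "LigandPose",
    "PoseEnsemble",
    "ParseError",
    "read_pdb",
    "write_pdb",
    "read_pdbqt_poses",
    "write_pdbqt_poses",
    "classify_residue",
    "assign_atom_roles",
    "assign_ligand_roles",
    "perceive_ligand_rings",
]


class ParseError(ValueError):
    """Raised for malformed structure files; carries the offending line number."""


# --------------------------------------------------------------------------
# chemistry tables
# --------------------------------------------------------------------------

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

# Residue-level chemistry classes. A residue may belong to several classes;
# the fingerprint bits themselves are evaluated per atom pair, so these
# classes are descriptive rather than load-bearing for bit detection.
_POLAR = {"SER", "THR", "ASN", "GLN", "TYR", "CYS", "HIS", "LYS", "ARG",
          "ASP", "GLU"}
_HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY"}
_AROMATIC = {"PHE", "TYR", "TRP", "HIS"}
_CHARGED = {"ASP", "GLU", "LYS", "ARG", "HIS"}

# Aromatic ring atom names per residue; TRP carries two fused rings.
AROMATIC_RING_ATOMS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TYR": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "HIS": [["CG", "ND1", "CE1", "NE2", "CD2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
}

# Sidechain hydrogen-bond roles; backbone roles are assigned generically.
_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"}, "HIS": {"ND1", "NE2"},
}
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
_SIDECHAIN_CATIONS: dict[str, set[str]] = {
    "LYS": {"NZ"}, "ARG": {"CZ", "NE", "NH1", "NH2"},
}
_SIDECHAIN_ANIONS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}

# AutoDock4 atom-type -> element (PDBQT trailing column).
AD4_TYPE_TO_ELEMENT = {
    "H": "H", "HD": "H", "HS": "H",
    "C": "C", "A": "C",
    "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O",
    "S": "S", "SA": "S",
    "P": "P", "F": "F", "CL": "CL", "BR": "BR", "I": "I",
    "MG": "MG", "MN": "MN", "ZN": "ZN", "CA": "CA", "FE": "FE",
}

COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
}
_BOND_TOLERANCE = 0.45  # Å added to the covalent-radius sum

RING_PLANARITY_TOL = 0.15  # Å max out-of-plane deviation for aromatic rings


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

ResidueKey = tuple  # (chain id, residue number, residue name)


@dataclass(eq=False)
class Atom:
    """One atom with the annotations the fingerprint engine consumes.

    ``roles`` is a subset of ``{"donor", "acceptor", "cation", "anion",
    "aromatic"}`` (the last marks aromatic-ring membership).
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_key: ResidueKey
    is_backbone: bool = False
    roles: set[str] = field(default_factory=set)
    is_hydrogen: bool = False
    is_water: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom serial {self.serial}")


@dataclass(eq=False)
class Ring:
    """An aromatic ring: ordered member atoms plus centroid and unit normal."""

    atoms: list[Atom]
    centroid: np.ndarray
    normal: np.ndarray
    residue_key: ResidueKey | None = None


@dataclass(eq=False)
class Residue:
    key: ResidueKey
    name: str
    atoms: list[Atom]
    classes: set[str] = field(default_factory=set)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in residue {self.key}")


@dataclass(eq=False)
class TypedStructure:
    """A receptor: ordered residues plus perceived aromatic rings."""

    residues: list[Residue]
    rings: list[Ring] = field(default_factory=list)
    typed: bool = False  # set by assign_atom_roles

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue keys in structure")

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def heavy_atoms(self, include_water: bool = False) -> list[Atom]:
        return [
            a
            for r in self.residues
            for a in r.atoms
            if not a.is_hydrogen and (include_water or not a.is_water)
        ]


@dataclass(eq=False)
class LigandPose:
    """One docked conformation. Atom order must match across poses of a ligand."""

    ligand_id: str
    pose_index: int
    atoms: list[Atom]
    rings: list[Ring] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pose_index < 0:
            raise ValueError("pose_index must be >= 0")

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms if heavy_only else self.atoms
        return np.array([a.coords for a in atoms], dtype=float)


@dataclass(eq=False)
class PoseEnsemble:
    receptor: TypedStructure
    poses: list[LigandPose]

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("PoseEnsemble requires at least one pose")


# --------------------------------------------------------------------------
# residue classification and role assignment
# --------------------------------------------------------------------------

def classify_residue(name: str) -> set[str]:
    """Chemistry classes of a standard residue.

    Returns a subset of ``{"polar", "hydrophobic", "aromatic", "charged"}``;
    multiple membership is allowed (His is polar, aromatic and charged).
    Unknown codes yield an empty set with a warning.
    """
    code = name.strip().upper()
    if code not in STANDARD_RESIDUES:
        warnings.warn(f"unknown residue code {name!r}; no classes assigned",
                      stacklevel=2)
        return set()
    classes: set[str] = set()
    if code in _POLAR:
        classes.add("polar")
    if code in _HYDROPHOBIC:
        classes.add("hydrophobic")
    if code in _AROMATIC:
        classes.add("aromatic")
    if code in _CHARGED:
        classes.add("charged")
    return classes


def _fit_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-fit plane through points: (centroid, unit normal, max deviation)."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    deviation = float(np.max(np.abs(centered @ normal))) if len(coords) else 0.0
    return centroid, normal, deviation


def assign_atom_roles(structure: TypedStructure) -> TypedStructure:
    """Annotate donor/acceptor/cation/anion/aromatic roles in place.

    Backbone N atoms are donors and backbone O (and OXT) acceptors for every
    residue; sidechain roles follow the standard tables above. The first
    residue of each chain gets an N-terminal cation on N; OXT marks a
    C-terminal anion. Aromatic rings of Phe/Tyr/Trp/His are perceived with
    centroid and best-fit-plane normal (Trp contributes two rings).
    """
    structure.rings = []
    seen_chains: set[str] = set()
    for residue in structure.residues:
        code = residue.name.upper()
        if code in WATER_NAMES:
            continue
        residue.classes = classify_residue(code) if code in STANDARD_RESIDUES else set()
        chain = residue.key[0]
        is_chain_start = chain not in seen_chains
        seen_chains.add(chain)
        for atom in residue.atoms:
            if atom.is_hydrogen:
                continue
            if atom.name == "N":
                atom.roles.add("donor")
                if is_chain_start:
                    atom.roles.add("cation")
            elif atom.name in ("O", "OXT"):
                atom.roles.add("acceptor")
                if atom.name == "OXT":
                    atom.roles.add("anion")
            if atom.name in _SIDECHAIN_DONORS.get(code, ()):
                atom.roles.add("donor")
            if atom.name in _SIDECHAIN_ACCEPTORS.get(code, ()):
                atom.roles.add("acceptor")
            if atom.name in _SIDECHAIN_CATIONS.get(code, ()):
                atom.roles.add("cation")
            if atom.name in _SIDECHAIN_ANIONS.get(code, ()):
                atom.roles.add("anion")
        for ring_names in AROMATIC_RING_ATOMS.get(code, ()):
            members = []
            for name in ring_names:
                try:
                    members.append(residue.atom(name))
                except KeyError:
                    members = []
                    break
            if not members:
                continue  # incomplete sidechain; skip the ring
            coords = np.array([a.coords for a in members])
            centroid, normal, deviation = _fit_plane(coords)
            if deviation > RING_PLANARITY_TOL:
                warnings.warn(
                    f"ring in residue {residue.key} deviates {deviation:.2f} Å "
                    "from planarity; skipped", stacklevel=2)
                continue
            for a in members:
                a.roles.add("aromatic")
            structure.rings.append(
                Ring(members, centroid, normal, residue_key=residue.key))
    structure.typed = True
    return structure


# --------------------------------------------------------------------------
# ligand perception
# --------------------------------------------------------------------------

def _bond_graph(atoms: Sequence[Atom]) -> nx.Graph:
    """Covalent bonds by the covalent-radius distance rule."""
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    coords = np.array([a.coords for a in atoms])
    for i in range(len(atoms)):
        ri = COVALENT_RADII.get(atoms[i].element.upper(), 0.77)
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        for off, dist in enumerate(d):
            j = i + 1 + off
            rj = COVALENT_RADII.get(atoms[j].element.upper(), 0.77)
            if 0.4 < dist <= ri + rj + _BOND_TOLERANCE:
                g.add_edge(i, j)
    return g


def _order_cycle(graph: nx.Graph, nodes: set[int]) -> list[int] | None:
    """Order a cycle's node set by walking edges within the induced subgraph."""
    sub = graph.subgraph(nodes)
    if any(d != 2 for _, d in sub.degree):
        return None
    start = next(iter(nodes))
    order = [start]
    prev = None
    while len(order) < len(nodes):
        nbrs = [n for n in sub.neighbors(order[-1]) if n != prev]
        if not nbrs:
            return None
        prev = order[-1]
        order.append(nbrs[0])
    return order


def perceive_ligand_rings(pose: LigandPose) -> list[Ring]:
    """Detect aromatic 5/6-membered rings in a ligand pose.

    The bond graph is built from covalent radii; cycles of size 5–6 whose
    members are all C/N/O/S and coplanar within ``RING_PLANARITY_TOL`` are
    flagged aromatic. Acyclic ligands yield an empty list. Saturated rings
    (e.g. cyclohexane chairs) fail the planarity filter.
    """
    atoms = pose.heavy_atoms
    if len(atoms) < 5:
        return []
    graph = _bond_graph(atoms)
    rings: list[Ring] = []
    for cycle in nx.minimum_cycle_basis(graph):
        if not 5 <= len(cycle) <= 6:
            continue
        ordered = _order_cycle(graph, set(cycle))
        if ordered is None:
            continue
        members = [atoms[i] for i in ordered]
        if any(a.element.upper() not in ("C", "N", "O", "S") for a in members):
            continue
        coords = np.array([a.coords for a in members])
        centroid, normal, deviation = _fit_plane(coords)
        if deviation > RING_PLANARITY_TOL:
            continue
        for a in members:
            a.roles.add("aromatic")
        rings.append(Ring(members, centroid, normal))
    return rings


def assign_ligand_roles(pose: LigandPose) -> LigandPose:
    """Heuristic donor/acceptor/charge typing for ligand atoms.

    Uses the covalent bond graph. Oxygens are acceptors, donors when they
    bear a hydrogen, and anions when part of a carboxylate (two terminal
    oxygens on one carbon). Nitrogens are donors when protonated, acceptors
    when bare with ≤2 heavy neighbours, cations when carrying ≥2 hydrogens
    or four heavy neighbours. If the pose carries no hydrogens at all
    (nonpolar-H-stripped files), every N/O falls back to donor+acceptor.
    Aromatic rings are perceived as a side effect.
    """
    atoms = pose.atoms
    graph = _bond_graph(atoms)
    has_hydrogens = any(a.is_hydrogen for a in atoms)
    elements = [a.element.upper() for a in atoms]

    def h_count(i: int) -> int:
        return sum(1 for j in graph.neighbors(i) if atoms[j].is_hydrogen)

    def heavy_neighbors(i: int) -> list[int]:
        return [j for j in graph.neighbors(i) if not atoms[j].is_hydrogen]

    # carboxylate carbons: C bonded to exactly two terminal O
    carboxylate_oxygens: set[int] = set()
    for i, el in enumerate(elements):
        if el != "C":
            continue
        terminal_o = [
            j for j in heavy_neighbors(i)
            if elements[j] == "O" and len(heavy_neighbors(j)) == 1
        ]
        if len(terminal_o) == 2:
            carboxylate_oxygens.update(terminal_o)

    for i, atom in enumerate(atoms):
        el = elements[i]
        if atom.is_hydrogen:
            continue
        if el == "O":
            atom.roles.add("acceptor")
            if h_count(i) > 0 or not has_hydrogens:
                atom.roles.add("donor")
            if i in carboxylate_oxygens:
                atom.roles.add("anion")
        elif el == "N":
            nh = h_count(i)
            heavies = heavy_neighbors(i)
            if nh > 0 or not has_hydrogens:
                atom.roles.add("donor")
            if nh == 0 and len(heavies) <= 2:
                atom.roles.add("acceptor")
            if nh >= 2 or len(heavies) == 4:
                atom.roles.add("cation")
        elif el == "S" and h_count(i) > 0:
            atom.roles.add("donor")
    pose.rings = perceive_ligand_rings(pose)
    return pose


# --------------------------------------------------------------------------
# PDB reading/writing (via gemmi)
# --------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in ("CL", "BR", "FE", "ZN", "MG", "MN") and len(stripped) >= 2:
        return two
    return stripped[0].upper()


def read_pdb(path: str | Path) -> TypedStructure:
    """Read a PDB file into a typed structure with atom roles assigned.

    Residues appear in file order; waters and hydrogens are retained but
    flagged so downstream fingerprinting can exclude them. Raises
    :class:`ParseError` for empty or malformed files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0 or sum(ch.count_atom_sites() for ch in st[0]) == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            resname = res.name.strip().upper()
            is_water = resname in WATER_NAMES
            key: ResidueKey = (chain.name, res.seqid.num, resname)
            atoms = []
            for at in res:
                element = at.element.name.upper() if at.element else ""
                if not element or element == "X":
                    element = _element_from_name(at.name)
                atom = Atom(
                    serial=at.serial,
                    name=at.name,
                    element=element,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_key=key,
                    is_backbone=(
                        resname in STANDARD_RESIDUES
                        and at.name in BACKBONE_NAMES
                    ),
                    is_hydrogen=element == "H",
                    is_water=is_water,
                )
                atoms.append(atom)
            residues.append(Residue(key=key, name=resname, atoms=atoms))
    structure = TypedStructure(residues=residues)
    return assign_atom_roles(structure)


def write_pdb(structure: TypedStructure, path: str | Path) -> None:
    """Write a typed structure back to PDB (coordinates at 3 decimals)."""
    st = gemmi.Structure()
    st.name = "siftkin"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for residue in structure.residues:
        chain_id = str(residue.key[0]) or "A"
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
        res = gemmi.Residue()
        res.name = residue.name
        res.seqid = gemmi.SeqId(int(residue.key[1]), " ")
        res.het_flag = "A" if residue.name in STANDARD_RESIDUES else "H"
        for atom in residue.atoms:
            at = gemmi.Atom()
            at.name = atom.name
            at.element = gemmi.Element(atom.element.capitalize())
            at.pos = gemmi.Position(*map(float, atom.coords))
            at.serial = atom.serial
            res.add_atom(at)
        chains[chain_id].add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# --------------------------------------------------------------------------
# PDBQT pose reading/writing
# --------------------------------------------------------------------------

def _parse_pdbqt_atom(line: str, lineno: int) -> tuple[Atom | None, str]:
    name = line[12:16].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(
            f"line {lineno}: malformed coordinate field: {line.rstrip()!r}"
        ) from exc
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    ad_type = line[77:79].strip().upper() if len(line) > 77 else ""
    if not ad_type:
        ad_type = _element_from_name(name)
    element = AD4_TYPE_TO_ELEMENT.get(ad_type, _element_from_name(name))
    resname = line[17:20].strip() or "LIG"
    chain = line[21:22].strip()
    try:
        resnum = int(line[22:26])
    except ValueError:
        resnum = 1
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        coords=np.array([x, y, z]),
        residue_key=(chain, resnum, resname),
        is_hydrogen=element == "H",
    )
    return atom, ad_type


def read_pdbqt_poses(path: str | Path, ligand_id: str | None = None,
                     type_atoms: bool = True) -> list[LigandPose]:
    """Read a multi-model PDBQT file into one pose per ``MODEL`` block.

    A file without ``MODEL`` records yields a single pose. The AutoDock
    atom-type column is mapped to elements (A→C, OA→O, NA→N, SA→S, HD→H, …);
    non-ATOM bookkeeping lines (ROOT/BRANCH/TORSDOF/REMARK…) are skipped.
    Raises :class:`ParseError` if pose atom counts differ, which would break
    the fixed-order RMSD contract.
    """
    path = Path(path)
    if ligand_id is None:
        ligand_id = path.stem
    poses: list[LigandPose] = []
    current: list[Atom] | None = None
    seen_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip().upper()
            if rec == "MODEL":
                seen_model = True
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    poses.append(LigandPose(ligand_id, len(poses), current))
                    current = None
            elif rec in ("ATOM", "HETATM"):
                atom, _ = _parse_pdbqt_atom(line, lineno)
                if current is None:
                    if seen_model:
                        continue  # stray atoms between models
                    current = []
                    seen_model = False
                current.append(atom)
    if current and not seen_model:
        poses.append(LigandPose(ligand_id, 0, current))
    if not poses:
        raise ParseError(f"{path}: no poses found")
    counts = {len(p.atoms) for p in poses}
    if len(counts) != 1:
        raise ParseError(
            f"{path}: differing atom counts across MODELs {sorted(counts)}; "
            "poses of one ligand must share atom order")
    if type_atoms:
        for pose in poses:
            assign_ligand_roles(pose)
    return poses


def _ad4_type_for(atom: Atom) -> str:
    el = atom.element.upper()
    if el == "C":
        return "A " if "aromatic" in atom.roles else "C "
    if el == "O":
        return "OA"
    if el == "N":
        return "NA" if "acceptor" in atom.roles and "donor" not in atom.roles else "N "
    if el == "S":
        return "SA"
    if el == "H":
        return "HD"
    return (el + " ")[:2]


def write_pdbqt_poses(poses: Iterable[LigandPose], path: str | Path) -> None:
    """Write poses as a multi-MODEL PDBQT file (AutoDock atom-type column)."""
    with open(path, "w") as fh:
        for i, pose in enumerate(poses, start=1):
            fh.write(f"MODEL {i:8d}\n")
            fh.write(f"REMARK  ligand {pose.ligand_id} pose {pose.pose_index}\n")
            fh.write("ROOT\n")
            for j, atom in enumerate(pose.atoms, start=1):
                key = atom.residue_key
                fh.write(
                    "ATOM  {serial:5d} {name:<4s} {res:<3s} {chain:1s}{num:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}    "
                    "{q:+6.3f} {typ:<2s}\n".format(
                        serial=j,
                        name=atom.name[:4],
                        res=str(key[2])[:3],
                        chain=(str(key[0]) or "A")[:1],
                        num=int(key[1]),
                        x=atom.coords[0], y=atom.coords[1], z=atom.coords[2],
                        occ=1.0, b=0.0, q=0.0,
                        typ=_ad4_type_for(atom).strip(),
                    ))
            fh.write("ENDROOT\nTORSDOF 0\nENDMDL\n")
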