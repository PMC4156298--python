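"""Synthetic fixtures: planted-interaction complexes, ensembles, kinetics.

Three generators make every pipeline stage testable without external
downloads:

* :func:`make_complex` — a toy receptor whose residues sit on a sparse grid
  (≥15 Å apart, so nothing but the planted contacts registers) with one
  ligand pose realizing each requested interaction at an exact geometry
  (e.g. a hydrogen bond at a stated donor–acceptor distance, on the 2–3 Å
  scale of real protease H-bonds).
* :func:`sample_ensemble` — a multi-pose ensemble in which each planted
  interaction is switched on with a prescribed per-pose probability, by
  toggling the interacting fragment between its exact geometry and a
  displaced, non-contacting position. This emulates the population of
  successfully docked poses over which fingerprints are averaged.
* :func:`simulate_kinetics` — noisy saturation datasets from stated Hill
  parameters with multiplicative Gaussian noise, over the 0.5–400 µM
  concentration range used in fluorogenic protease assays.

Each amino acid is represented by one pseudo-residue template carrying the
minimal atoms its roles need (e.g. Tyr = backbone + ring + OH), not a
rotamer library. All randomness flows through a single seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from siftkin.kinetics import AssayPoint, HillParams, hill_velocity
from siftkin.sift import BIT_NAMES
from siftkin.structure_io import (
    Atom,
    LigandPose,
    PoseEnsemble,
    Residue,
    Ring,
    TypedStructure,
    assign_atom_roles,
    assign_ligand_roles,
)

__all__ = [
    "PlantedInteraction",
    "ComplexSpec",
    "EnsembleSpec",
    "KineticsSpec",
    "make_complex",
    "sample_ensemble",
    "simulate_kinetics",
    "fused_bicyclic_coords",
    "benzene_coords",
]

DISPLACEMENT = 40.0  # Å shift that switches a planted fragment "off"


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def benzene_coords(side: float = 1.39) -> np.ndarray:
    """Vertices of a regular planar hexagon (z=0), e.g. ideal benzene."""
    r = side
    return np.array([
        [r * math.cos(math.radians(60 * k)), r * math.sin(math.radians(60 * k)), 0.0]
        for k in range(6)
    ])


def fused_bicyclic_coords(
    n_second: int = 5, side: float = 1.39
) -> tuple[np.ndarray, np.ndarray]:
    """A planar fused bicyclic: a hexagon sharing an edge with a second ring.

    Returns ``(hexagon_vertices, second_ring_vertices)``; the second ring's
    first two vertices coincide with the hexagon's first two (the shared
    edge). ``n_second=5`` gives an indole-like 6-5 system, ``6`` a
    naphthalene/coumarin-like 6-6 system.
    """
    hexagon = benzene_coords(side)
    h0, h1 = hexagon[0], hexagon[1]
    mid = (h0 + h1) / 2.0
    outward = mid / np.linalg.norm(mid)
    r2 = side / (2 * math.sin(math.pi / n_second))
    apothem2 = r2 * math.cos(math.pi / n_second)
    center2 = mid + apothem2 * outward

    def angle_of(p):
        v = p - center2
        return math.atan2(v[1], v[0])

    a0, a1 = angle_of(h0), angle_of(h1)
    step = a1 - a0
    step -= 2 * math.pi * round(step / (2 * math.pi))
    second = [h0, h1]
    for k in range(1, n_second - 1):
        ang = a1 + k * step
        second.append(center2 + r2 * np.array(
            [math.cos(ang), math.sin(ang), 0.0]))
    return hexagon, np.array(second)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, trial)
    return v / np.linalg.norm(v)


# --------------------------------------------------------------------------
# residue templates
# --------------------------------------------------------------------------

_BACKBONE = [
    ("N", "N", (0.000, 0.000, 0.000)),
    ("CA", "C", (1.458, 0.000, 0.000)),
    ("C", "C", (2.000, 1.360, 0.000)),
    ("O", "O", (1.430, 2.430, 0.000)),
]
_CB = ("CB", "C", (1.958, -1.000, 1.000))


def _ring_coords(names, elements, radius, center, plane="xz"):
    n = len(names)
    out = []
    for k in range(n):
        ang = 2 * math.pi * k / n
        if plane == "xz":
            offset = np.array([radius * math.cos(ang), 0.0,
                               radius * math.sin(ang)])
        else:
            offset = np.array([radius * math.cos(ang),
                               radius * math.sin(ang), 0.0])
        out.append((names[k], elements[k], tuple(np.asarray(center) + offset)))
    return out


def _residue_template(resname: str) -> list[tuple]:
    """Minimal (name, element, coords) atom list for one residue."""
    atoms = list(_BACKBONE)
    code = resname.upper()
    cb = np.array(_CB[2])
    if code != "GLY":
        atoms.append(_CB)
    if code == "SER":
        atoms.append(("OG", "O", tuple(cb + (0.0, -0.700, 1.200))))
    elif code == "THR":
        atoms.append(("OG1", "O", tuple(cb + (0.0, -0.700, 1.200))))
    elif code == "CYS":
        atoms.append(("SG", "S", tuple(cb + (0.0, -0.900, 1.500))))
    elif code == "LYS":
        atoms.append(("NZ", "N", tuple(cb + (0.0, -1.000, 3.000))))
    elif code in ("ASP", "ASN"):
        cg = cb + (0.0, -0.770, 1.200)
        o1, n2 = ("OD1", "OD2") if code == "ASP" else ("OD1", "ND2")
        e2 = "O" if code == "ASP" else "N"
        atoms.append(("CG", "C", tuple(cg)))
        atoms.append((o1, "O", tuple(cg + (1.050, -0.650, 0.0))))
        atoms.append((n2, e2, tuple(cg + (-1.050, -0.650, 0.0))))
    elif code in ("GLU", "GLN"):
        cg = cb + (0.0, -0.770, 1.200)
        cd = cg + (0.0, -0.770, 1.200)
        o1, x2 = ("OE1", "OE2") if code == "GLU" else ("OE1", "NE2")
        e2 = "O" if code == "GLU" else "N"
        atoms.append(("CG", "C", tuple(cg)))
        atoms.append(("CD", "C", tuple(cd)))
        atoms.append((o1, "O", tuple(cd + (1.050, -0.650, 0.0))))
        atoms.append((x2, e2, tuple(cd + (-1.050, -0.650, 0.0))))
    elif code == "ARG":
        ne = cb + (0.0, -0.770, 1.200)
        cz = ne + (0.0, -0.650, 1.150)
        atoms.append(("NE", "N", tuple(ne)))
        atoms.append(("CZ", "C", tuple(cz)))
        atoms.append(("NH1", "N", tuple(cz + (1.150, -0.650, 0.0))))
        atoms.append(("NH2", "N", tuple(cz + (-1.150, -0.650, 0.0))))
    elif code == "HIS":
        center = cb + (0.0, -1.200, 1.800)
        atoms += _ring_coords(
            ["CG", "ND1", "CE1", "NE2", "CD2"],
            ["C", "N", "C", "N", "C"], 1.170, center)
    elif code in ("PHE", "TYR"):
        center = cb + (0.0, -1.400, 2.000)
        ring = _ring_coords(
            ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"],
            ["C"] * 6, 1.390, center)
        atoms += ring
        if code == "TYR":
            cz = np.array(ring[3][2])
            direction = (cz - center) / np.linalg.norm(cz - center)
            atoms.append(("OH", "O", tuple(cz + 1.360 * direction)))
    elif code == "TRP":
        hexagon, pentagon = fused_bicyclic_coords(5)
        # map: pentagon = CD2 CE2 NE1 CD1 CG ; hexagon = CD2 CE2 CZ2 CH2 CZ3 CE3
        center = cb + np.array([0.0, -1.400, 2.200])
        rot = np.array([[1.0, 0.0, 0.0],
                        [0.0, 0.0, -1.0],
                        [0.0, 1.0, 0.0]])  # xy-plane -> xz-plane
        hex_names = ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]
        pent_names = ["CD2", "CE2", "NE1", "CD1", "CG"]
        pent_elems = ["C", "C", "N", "C", "C"]
        placed: dict[str, np.ndarray] = {}
        for name, xy in zip(hex_names, hexagon):
            placed[name] = center + rot @ xy
        for name, xy in zip(pent_names, pentagon):
            placed.setdefault(name, center + rot @ xy)
        for name, el in zip(hex_names, ["C"] * 6):
            atoms.append((name, el, tuple(placed[name])))
        for name, el in zip(pent_names, pent_elems):
            if name not in hex_names:
                atoms.append((name, el, tuple(placed[name])))
    return atoms


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInteraction:
    """One interaction to realize between a receptor residue and the ligand.

    ``bit`` names the fingerprint bit to plant; the residue, anchor atom,
    ligand fragment and geometry default to a recipe appropriate for the
    bit but can be overridden (e.g. plant an H-bond on the backbone O of an
    Arg numbered 71). ``satisfied=False`` plants the deliberately violating
    geometry (``distance`` then defaults to just beyond the bit's cutoff).
    ``frequency`` is used by :func:`sample_ensemble` only.
    """

    bit: str
    residue_name: str | None = None
    residue_number: int | None = None
    chain: str = "A"
    anchor_atom: str | None = None
    distance: float | None = None
    satisfied: bool = True
    frequency: float = 1.0

    def __post_init__(self) -> None:
        if self.bit not in BIT_NAMES:
            raise ValueError(f"unknown bit {self.bit!r}; one of {BIT_NAMES}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must lie in [0, 1]")


@dataclass(frozen=True)
class ComplexSpec:
    planted: tuple
    spacing: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(self.planted))
        if self.spacing < 15.0:
            raise ValueError("spacing must be >= 15 Å to isolate interactions")


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble with per-interaction target bit frequencies.

    ``exact=True`` realizes each interaction in exactly round(f·n) poses
    (chosen by a seeded shuffle); otherwise each pose draws an independent
    Bernoulli(f) per interaction.
    """

    planted: tuple
    n_poses: int
    seed: int = 0
    spacing: float = 20.0
    exact: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(self.planted))
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")


@dataclass(frozen=True)
class KineticsSpec:
    """Noisy saturation dataset from stated Hill parameters.

    Default concentration grid: 10 points log-spaced over 0.5–400 µM, three
    replicates, 3% multiplicative Gaussian noise.
    """

    params: HillParams
    concentrations: tuple = ()
    replicates: int = 3
    noise_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        conc = tuple(self.concentrations) or tuple(
            np.geomspace(0.5, 400.0, 10))
        if any(c < 0 for c in conc):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "concentrations", conc)


# --------------------------------------------------------------------------
# planting recipes
# --------------------------------------------------------------------------

# bit -> (default residue, anchor selector, fragment, satisfying Å, violating Å)
_RECIPES = {
    "any":            ("VAL", "sidechain_c", "C",    3.5, 8.0),
    "backbone":       ("GLY", "backbone_n",  "C",    4.0, 8.0),
    "sidechain":      ("VAL", "sidechain_c", "C",    3.5, 8.0),
    "polar":          ("SER", "polar",       "C=O",  3.7, 4.0),
    "hydrophobic":    ("VAL", "sidechain_c", "C",    3.5, 4.8),
    "hbond_acceptor": ("ASP", "acceptor",    "OH",   2.9, 3.9),
    "hbond_donor":    ("LYS", "donor",       "C=O",  2.9, 3.9),
    "aromatic":       ("TYR", "ring",        "ring", 4.0, 6.0),
    "charged":        ("ARG", "ion",         "ion",  3.7, 4.2),
}


def _select_anchor(residue: Residue, selector: str,
                   override: str | None) -> Atom:
    if override is not None:
        return residue.atom(override)
    heavy = residue.heavy_atoms
    if selector == "backbone_n":
        return residue.atom("N")
    if selector == "sidechain_c":
        for a in heavy:
            if not a.is_backbone and a.element == "C":
                return a
        return residue.atom("CA")
    if selector == "polar":
        for a in heavy:
            if not a.is_backbone and a.element in ("N", "O"):
                return a
        return residue.atom("O")
    if selector == "acceptor":
        for a in heavy:
            if "acceptor" in a.roles and not a.is_backbone:
                return a
        return residue.atom("O")
    if selector == "donor":
        for a in heavy:
            if "donor" in a.roles and not a.is_backbone:
                return a
        return residue.atom("N")
    if selector == "ion":
        charged = [a for a in heavy if a.roles & {"cation", "anion"}]
        if not charged:
            raise ValueError(f"residue {residue.name} has no charged atom")
        centroid = np.mean([a.coords for a in heavy], axis=0)
        # prefer the terminal charge centre so the fragment clears the rest
        # of the sidechain (e.g. Arg NH1 over NE)
        return max(charged, key=lambda a: np.linalg.norm(a.coords - centroid))
    raise ValueError(f"unknown anchor selector {selector!r}")


def _fragment_atoms(kind: str, anchor: np.ndarray, u: np.ndarray,
                    distance: float, tag: int,
                    receptor_ring: Ring | None = None,
                    receptor_anchor: Atom | None = None) -> list[Atom]:
    """Build the ligand fragment whose interacting atom sits at the exact
    planted distance from the receptor anchor along direction ``u``."""
    perp = _perpendicular(u)
    key = ("L", tag + 1, "LIG")

    def atom(name, element, coords):
        return Atom(serial=0, name=f"{name}", element=element,
                    coords=np.asarray(coords, dtype=float), residue_key=key,
                    is_hydrogen=element == "H")

    p = anchor + distance * u
    if kind == "C":
        return [atom("C1", "C", p)]
    if kind == "OH":
        # hydroxyl donating toward the receptor anchor: H on the D–A axis
        return [atom("O1", "O", p), atom("H1", "H", p - 0.96 * u)]
    if kind == "C=O":
        return [atom("O1", "O", p), atom("C1", "C", p + 1.22 * u)]
    if kind == "ion":
        if receptor_anchor is not None and "anion" in receptor_anchor.roles:
            # receptor anion -> plant an ammonium cation
            h1 = p + 1.0 * (0.5 * u + 0.866 * perp)
            h2 = p + 1.0 * (0.5 * u - 0.866 * perp)
            return [atom("N1", "N", p), atom("H1", "H", h1),
                    atom("H2", "H", h2)]
        # receptor cation -> plant a carboxylate
        c = p + 1.25 * u
        o2 = c + 1.25 * (0.5 * u + 0.866 * perp)
        return [atom("O1", "O", p), atom("C1", "C", c), atom("O2", "O", o2)]
    if kind == "ring":
        if receptor_ring is None:
            raise ValueError("aromatic planting requires a receptor ring")
        centroid = receptor_ring.centroid + distance * u
        v1 = _perpendicular(u)
        v2 = np.cross(u, v1)
        out = []
        for k in range(6):
            ang = 2 * math.pi * k / 6
            pos = centroid + 1.39 * (math.cos(ang) * v1 + math.sin(ang) * v2)
            out.append(atom(f"C{k + 1}", "C", pos))
        return out
    raise ValueError(f"unknown fragment kind {kind!r}")


def _build_complex(
    planted: Sequence[PlantedInteraction],
    spacing: float,
) -> tuple[TypedStructure, LigandPose, list[slice]]:
    """Receptor + single pose + per-interaction ligand atom ranges."""
    if not planted:
        raise ValueError("at least one planted interaction is required")
    residues: list[Residue] = []
    used_numbers: set[int] = set()
    resolved: list[tuple[PlantedInteraction, Residue, np.ndarray]] = []
    for i, pi in enumerate(planted):
        recipe = _RECIPES[pi.bit]
        resname = (pi.residue_name or recipe[0]).upper()
        number = pi.residue_number if pi.residue_number is not None else (i + 1) * 10
        if (pi.chain, number) in {(r.key[0], r.key[1]) for r in residues}:
            raise ValueError(
                f"two planted interactions map to residue {pi.chain}{number}")
        offset = np.array([i * spacing, 0.0, 0.0])
        key = (pi.chain, number, resname)
        atoms = [
            Atom(serial=0, name=name, element=el,
                 coords=np.asarray(xyz) + offset, residue_key=key,
                 is_backbone=name in ("N", "CA", "C", "O", "OXT"),
                 is_hydrogen=el == "H")
            for name, el, xyz in _residue_template(resname)
        ]
        residue = Residue(key=key, name=resname, atoms=atoms)
        residues.append(residue)
        used_numbers.add(number)
        resolved.append((pi, residue, offset))

    receptor = assign_atom_roles(TypedStructure(residues=residues))

    lig_atoms: list[Atom] = []
    ranges: list[slice] = []
    for i, (pi, residue, offset) in enumerate(resolved):
        recipe = _RECIPES[pi.bit]
        _, selector, fragment, d_ok, d_bad = recipe
        distance = pi.distance if pi.distance is not None else (
            d_ok if pi.satisfied else d_bad)
        ring = None
        if fragment == "ring":
            rings = [r for r in receptor.rings if r.residue_key == residue.key]
            if not rings:
                raise ValueError(
                    f"residue {residue.name} has no aromatic ring to stack on")
            ring = rings[0]
            u = ring.normal.copy()
            # orient away from the backbone so the stacked ligand ring does
            # not graze backbone atoms
            ca = residue.atom("CA").coords
            if np.dot(u, ring.centroid - ca) < 0:
                u = -u
            anchor_pos = ring.centroid
            anchor = None
        else:
            anchor = _select_anchor(residue, selector, pi.anchor_atom)
            anchor_pos = anchor.coords
            others = [a.coords for a in residue.heavy_atoms
                      if a.name != anchor.name]
            away = anchor_pos - np.mean(others, axis=0)
            norm = np.linalg.norm(away)
            u = away / norm if norm > 1e-6 else np.array([0.0, 0.0, 1.0])
        frag = _fragment_atoms(fragment, anchor_pos, u, distance, tag=i,
                               receptor_ring=ring, receptor_anchor=anchor)
        start = len(lig_atoms)
        lig_atoms.extend(frag)
        ranges.append(slice(start, len(lig_atoms)))

    for serial, a in enumerate(lig_atoms, start=1):
        a.serial = serial
    pose = LigandPose(ligand_id="synthetic", pose_index=0, atoms=lig_atoms)
    assign_ligand_roles(pose)
    return receptor, pose, ranges


def make_complex(spec: ComplexSpec) -> PoseEnsemble:
    """One receptor + one pose realizing every planted interaction exactly."""
    receptor, pose, _ = _build_complex(spec.planted, spec.spacing)
    return PoseEnsemble(receptor=receptor, poses=[pose])


def _copy_pose(pose: LigandPose, index: int) -> LigandPose:
    atoms = [
        Atom(serial=a.serial, name=a.name, element=a.element,
             coords=a.coords.copy(), residue_key=a.residue_key,
             is_backbone=a.is_backbone, roles=set(a.roles),
             is_hydrogen=a.is_hydrogen, is_water=a.is_water)
        for a in pose.atoms
    ]
    return LigandPose(ligand_id=pose.ligand_id, pose_index=index, atoms=atoms)


def sample_ensemble(spec: EnsembleSpec) -> PoseEnsemble:
    """Multi-pose ensemble realizing each planted bit at its target frequency.

    A pose that does not realize an interaction has that fragment displaced
    by ``DISPLACEMENT`` Å, far outside every cutoff, so the corresponding
    residue shows no interaction at all in that pose. Deterministic for a
    fixed seed.
    """
    receptor, base, ranges = _build_complex(spec.planted, spec.spacing)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_poses
    if spec.exact:
        on_masks = []
        for pi in spec.planted:
            k = int(round(pi.frequency * n))
            mask = np.zeros(n, dtype=bool)
            mask[rng.permutation(n)[:k]] = True
            on_masks.append(mask)
    else:
        on_masks = [rng.random(n) < pi.frequency for pi in spec.planted]

    shift = np.array([0.0, 0.0, DISPLACEMENT])
    poses = []
    for p in range(n):
        pose = _copy_pose(base, p)
        for j, rng_slice in enumerate(ranges):
            if not on_masks[j][p]:
                for a in pose.atoms[rng_slice]:
                    a.coords = a.coords + shift
        pose.rings = []
        assign_ligand_roles(pose)
        poses.append(pose)
    return PoseEnsemble(receptor=receptor, poses=poses)


def simulate_kinetics(spec: KineticsSpec) -> list[AssayPoint]:
    """Noisy Hill-equation velocities: v = v(S)·(1 + ε), ε ~ N(0, CV²).

    Noise is truncated below at −0.99 so velocities stay positive.
    Deterministic for a fixed seed; CV = 0 returns exact Hill values.
    """
    rng = np.random.default_rng(spec.seed)
    points = []
    for rep in range(spec.replicates):
        for S in spec.concentrations:
            v = hill_velocity(spec.params, float(S))
            eps = max(float(rng.normal(0.0, spec.noise_cv)), -0.99) \
                if spec.noise_cv > 0 else 0.0
            points.append(AssayPoint(float(S), v * (1.0 + eps), rep))
    return points
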