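"""The 9-bit per-residue structural interaction fingerprint (SIFt) engine.

For every docked pose, each receptor residue in contact with the ligand gets
a 9-bit fingerprint::

    (any, backbone, sidechain, polar, hydrophobic,
     H-bond acceptor, H-bond donor, aromatic, charged)

* ``any`` — at least one heavy-atom pair within ``contact_cutoff``;
* ``backbone`` / ``sidechain`` — the contact partitioned by whether the
  receptor atom is a backbone atom (N/CA/C/O/OXT);
* ``polar`` — an N/O–N/O pair within ``polar_max``;
* ``hydrophobic`` — a C/S–C/S pair within ``contact_cutoff``;
* ``hbond_acceptor`` — a receptor acceptor atom receives a hydrogen bond
  from a ligand donor (geometric criterion, see :func:`detect_hbond`);
* ``hbond_donor`` — a receptor donor atom donates to a ligand acceptor;
* ``aromatic`` — a receptor ring and a ligand ring with centroids within
  ``aromatic_centroid_max`` (distance-only π contact);
* ``charged`` — a salt bridge: receptor cation against ligand anion or
  vice versa within ``charged_max``.

Averaging fingerprints over a pose ensemble gives per-residue bit
frequencies in [0, 1] — the population view of the binding mode. Helper
operations compare fingerprints (Tanimoto), cluster poses by RMSD with the
greedy leader algorithm at a 1.0 Å cutoff (the AutoDock convention), and
extract binding-site residues above a contact-frequency threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from siftkin.structure_io import (
    Atom,
    LigandPose,
    Ring,
    TypedStructure,
)

__all__ = [
    "BIT_NAMES",
    "InteractionParams",
    "ClusterParams",
    "ResidueFingerprint",
    "SIFt",
    "AveragedSIFt",
    "PoseCluster",
    "residue_contacts",
    "detect_hbond",
    "detect_aromatic_contact",
    "compute_sift",
    "average_sift",
    "tanimoto",
    "pose_rmsd",
    "cluster_poses",
    "binding_site_residues",
]

BIT_NAMES = (
    "any",
    "backbone",
    "sidechain",
    "polar",
    "hydrophobic",
    "hbond_acceptor",
    "hbond_donor",
    "aromatic",
    "charged",
)

_POLAR_ELEMENTS = frozenset({"N", "O"})
_HYDROPHOBIC_ELEMENTS = frozenset({"C", "S"})


@dataclass(frozen=True)
class InteractionParams:
    """Geometric cutoffs for interaction detection (all Å, angle in degrees).

    The defaults are conventional interaction-geometry ranges: 4.5 Å
    heavy-atom contact, 3.5 Å donor–acceptor distance with a 120° minimum
    angle at the hydrogen when hydrogens are present, 5.0 Å ring-centroid
    distance for π contacts, 4.0 Å for salt bridges and 3.8 Å for generic
    polar contacts.
    """

    contact_cutoff: float = 4.5
    hbond_da_max: float = 3.5
    hbond_angle_min: float = 120.0
    aromatic_centroid_max: float = 5.0
    charged_max: float = 4.0
    polar_max: float = 3.8

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "hbond_da_max", "hbond_angle_min",
                     "aromatic_centroid_max", "charged_max", "polar_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hbond_da_max > self.contact_cutoff:
            raise ValueError("hbond_da_max must not exceed contact_cutoff")
        if self.contact_cutoff > self.aromatic_centroid_max + 1:
            raise ValueError(
                "contact_cutoff must not exceed aromatic_centroid_max + 1")


@dataclass(frozen=True)
class ClusterParams:
    rmsd_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be positive")


@dataclass(frozen=True)
class ResidueFingerprint:
    """The 9 interaction bits of one residue against one pose."""

    residue_key: tuple
    bits: tuple

    def __post_init__(self) -> None:
        if len(self.bits) != len(BIT_NAMES):
            raise ValueError(f"expected {len(BIT_NAMES)} bits")
        bits = tuple(bool(b) for b in self.bits)
        object.__setattr__(self, "bits", bits)
        if any(bits[1:]) and not bits[0]:
            raise ValueError("bit hierarchy violated: sub-bit set without 'any'")

    def __getitem__(self, bit: str) -> bool:
        return self.bits[BIT_NAMES.index(bit)]

    @property
    def as_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=float)


@dataclass
class SIFt:
    """Per-pose fingerprint: residue_key → ResidueFingerprint.

    Only residues with at least one set bit are stored; absence means an
    all-zero fingerprint.
    """

    ligand_id: str
    pose_index: int
    fingerprints: dict = field(default_factory=dict)
    residue_order: tuple = ()

    def __post_init__(self) -> None:
        for key, fp in self.fingerprints.items():
            if not any(fp.bits):
                raise ValueError(f"all-zero fingerprint stored for {key}")

    def bitstring(self) -> str:
        """Compact concatenated bitstring in residue order."""
        parts = []
        for key in self.residue_order:
            fp = self.fingerprints.get(key)
            parts.append("".join("1" if b else "0" for b in fp.bits)
                         if fp else "0" * len(BIT_NAMES))
        return "".join(parts)

    def set_bits(self) -> set:
        return {
            (key, bit)
            for key, fp in self.fingerprints.items()
            for bit, on in zip(BIT_NAMES, fp.bits)
            if on
        }


@dataclass
class AveragedSIFt:
    """Per-residue bit frequencies over an ensemble of fingerprints."""

    frequencies: dict  # residue_key -> np.ndarray of 9 floats
    n_fingerprints: int

    def __post_init__(self) -> None:
        for key, freq in self.frequencies.items():
            freq = np.asarray(freq, dtype=float)
            self.frequencies[key] = freq
            if np.any(freq < 0) or np.any(freq > 1):
                raise ValueError(f"frequencies out of [0,1] for {key}")

    def frequency(self, residue_key: tuple, bit: str) -> float:
        freq = self.frequencies.get(residue_key)
        return 0.0 if freq is None else float(freq[BIT_NAMES.index(bit)])

    def to_frame(self) -> pd.DataFrame:
        """Table-style view: one row per residue, one column per bit."""
        rows = {}
        for key, freq in self.frequencies.items():
            label = f"{key[2]}{key[1]}" if len(key) >= 3 else str(key)
            rows[label] = freq
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(BIT_NAMES))
        df.index.name = "amino_acid"
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().round(2).to_csv(path, sep="\t", float_format="%.2f")


@dataclass
class PoseCluster:
    representative: LigandPose
    members: list


# --------------------------------------------------------------------------
# geometric predicates
# --------------------------------------------------------------------------

def residue_contacts(
    receptor: TypedStructure,
    pose: LigandPose,
    params: InteractionParams = InteractionParams(),
) -> list[tuple]:
    """All heavy-atom receptor–ligand pairs within the contact cutoff.

    Returns ``(residue_key, receptor_atom, ligand_atom, distance)`` tuples,
    sorted by residue (file order) then distance. Uses a k-d tree neighbor
    search over receptor heavy atoms; waters are excluded.
    """
    rec_atoms = receptor.heavy_atoms(include_water=False)
    lig_atoms = pose.heavy_atoms
    if not rec_atoms or not lig_atoms:
        return []
    rec_coords = np.array([a.coords for a in rec_atoms])
    lig_coords = np.array([a.coords for a in lig_atoms])
    tree = cKDTree(rec_coords)
    pairs = tree.query_ball_point(lig_coords, r=params.contact_cutoff)
    residue_rank = {res.key: i for i, res in enumerate(receptor.residues)}
    contacts = []
    for li, rec_indices in enumerate(pairs):
        for ri in rec_indices:
            ratom = rec_atoms[ri]
            latom = lig_atoms[li]
            dist = float(np.linalg.norm(ratom.coords - latom.coords))
            contacts.append((ratom.residue_key, ratom, latom, dist))
    contacts.sort(key=lambda c: (residue_rank.get(c[0], len(residue_rank)), c[3]))
    return contacts


def detect_hbond(
    donor: Atom,
    acceptor: Atom,
    params: InteractionParams = InteractionParams(),
    hydrogen: Atom | None = None,
) -> bool:
    """Geometric hydrogen-bond test between a donor and an acceptor atom.

    True iff the donor–acceptor distance is within ``hbond_da_max`` and,
    when the donor's hydrogen is supplied, the donor–H–acceptor angle is at
    least ``hbond_angle_min``. Without an explicit hydrogen (the common case
    for crystallographic receptors) the criterion is distance-only.
    """
    if "donor" not in donor.roles:
        raise ValueError(f"atom {donor.name} lacks the donor role")
    if "acceptor" not in acceptor.roles:
        raise ValueError(f"atom {acceptor.name} lacks the acceptor role")
    d = float(np.linalg.norm(donor.coords - acceptor.coords))
    if d > params.hbond_da_max:
        return False
    if hydrogen is None:
        return True
    v1 = donor.coords - hydrogen.coords
    v2 = acceptor.coords - hydrogen.coords
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return True
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return angle >= params.hbond_angle_min


def detect_aromatic_contact(
    ring_a: Ring,
    ring_b: Ring,
    params: InteractionParams = InteractionParams(),
) -> bool:
    """π contact: ring centroids within ``aromatic_centroid_max``.

    Distance-only — both stacked and T-shaped geometries qualify; no
    interplanar-angle filter is applied.
    """
    d = float(np.linalg.norm(ring_a.centroid - ring_b.centroid))
    return d <= params.aromatic_centroid_max


# --------------------------------------------------------------------------
# fingerprint computation
# --------------------------------------------------------------------------

def _ligand_hydrogens_by_donor(pose: LigandPose) -> dict:
    """Map donor-atom id -> attached hydrogen atoms (for angle criteria)."""
    hydrogens = [a for a in pose.atoms if a.is_hydrogen]
    if not hydrogens:
        return {}
    out: dict[int, list[Atom]] = {}
    for donor in pose.atoms:
        if donor.is_hydrogen or "donor" not in donor.roles:
            continue
        attached = [
            h for h in hydrogens
            if np.linalg.norm(h.coords - donor.coords) < 1.3
        ]
        if attached:
            out[id(donor)] = attached
    return out


def compute_sift(
    receptor: TypedStructure,
    pose: LigandPose,
    params: InteractionParams = InteractionParams(),
) -> SIFt:
    """Compute the per-residue 9-bit fingerprint of one pose.

    Residues without any set bit are omitted from the result. Requires a
    receptor that has been through role assignment.
    """
    if not receptor.typed:
        raise ValueError(
            "receptor atoms are untyped; run assign_atom_roles first")
    contacts = residue_contacts(receptor, pose, params)
    lig_h = _ligand_hydrogens_by_donor(pose)
    bits_by_residue: dict[tuple, np.ndarray] = {}

    def bits_for(key: tuple) -> np.ndarray:
        return bits_by_residue.setdefault(
            key, np.zeros(len(BIT_NAMES), dtype=bool))

    for key, ratom, latom, dist in contacts:
        bits = bits_for(key)
        bits[0] = True  # any
        if ratom.is_backbone:
            bits[1] = True
        else:
            bits[2] = True
        rel, lel = ratom.element.upper(), latom.element.upper()
        if (rel in _POLAR_ELEMENTS and lel in _POLAR_ELEMENTS
                and dist <= params.polar_max):
            bits[3] = True
        if rel in _HYDROPHOBIC_ELEMENTS and lel in _HYDROPHOBIC_ELEMENTS:
            bits[4] = True
        if ("acceptor" in ratom.roles and "donor" in latom.roles
                and dist <= params.hbond_da_max):
            hs = lig_h.get(id(latom), [None])
            if any(detect_hbond(latom, ratom, params, hydrogen=h) for h in hs):
                bits[5] = True
        if ("donor" in ratom.roles and "acceptor" in latom.roles
                and dist <= params.hbond_da_max):
            # receptor hydrogens are typically absent: distance-only
            if detect_hbond(ratom, latom, params):
                bits[6] = True
        if dist <= params.charged_max and (
            ("cation" in ratom.roles and "anion" in latom.roles)
            or ("anion" in ratom.roles and "cation" in latom.roles)
        ):
            bits[8] = True

    # aromatic bit: ring-centroid criterion per residue ring vs ligand ring
    for rec_ring in receptor.rings:
        for lig_ring in pose.rings:
            if detect_aromatic_contact(rec_ring, lig_ring, params):
                bits = bits_for(rec_ring.residue_key)
                bits[7] = True
                bits[0] = True
                bits[2] = True  # sidechain rings only

    residue_rank = {res.key: i for i, res in enumerate(receptor.residues)}
    fingerprints = {
        key: ResidueFingerprint(key, tuple(bits))
        for key, bits in sorted(
            bits_by_residue.items(),
            key=lambda kv: residue_rank.get(kv[0], len(residue_rank)))
        if bits.any()
    }
    return SIFt(
        ligand_id=pose.ligand_id,
        pose_index=pose.pose_index,
        fingerprints=fingerprints,
        residue_order=tuple(res.key for res in receptor.residues),
    )


def average_sift(sifts: Sequence[SIFt]) -> AveragedSIFt:
    """Per-residue, per-bit frequency over an ensemble of fingerprints.

    frequency = (# fingerprints with the bit set) / n. Residues never
    contacted are omitted; output follows receptor residue order.
    """
    if not sifts:
        raise ValueError("cannot average an empty list of fingerprints")
    n = len(sifts)
    order = sifts[0].residue_order
    sums: dict[tuple, np.ndarray] = {}
    for s in sifts:
        for key, fp in s.fingerprints.items():
            sums.setdefault(key, np.zeros(len(BIT_NAMES)))
            sums[key] += fp.as_array
    rank = {key: i for i, key in enumerate(order)}
    frequencies = {
        key: sums[key] / n
        for key in sorted(sums, key=lambda k: rank.get(k, len(rank)))
    }
    return AveragedSIFt(frequencies=frequencies, n_fingerprints=n)


def tanimoto(a: SIFt, b: SIFt) -> float:
    """Tanimoto similarity of two fingerprints: |A∩B| / |A∪B| over set bits.

    Defined as 1.0 when both fingerprints are empty. Requires the same
    receptor residue ordering.
    """
    if a.residue_order != b.residue_order:
        raise ValueError("fingerprints computed against different receptors")
    sa, sb = a.set_bits(), b.set_bits()
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


# --------------------------------------------------------------------------
# pose geometry
# --------------------------------------------------------------------------

def pose_rmsd(a: LigandPose, b: LigandPose) -> float:
    """Heavy-atom RMSD between two poses of the same ligand, no superposition.

    Docking leaves all poses in the receptor frame, so the deviation is
    computed in place (the docking-frame convention).
    """
    ca, cb = a.coords(), b.coords()
    if ca.shape != cb.shape:
        raise ValueError(
            f"atom count mismatch: {ca.shape[0]} vs {cb.shape[0]}")
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def cluster_poses(
    poses: Sequence[LigandPose],
    params: ClusterParams = ClusterParams(),
) -> list[PoseCluster]:
    """Greedy leader clustering of poses at the RMSD cutoff.

    Poses are scanned in order; each joins the first existing cluster whose
    representative (the earliest member) lies within ``rmsd_cutoff``,
    otherwise it founds a new cluster. Deterministic for a fixed input
    order.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    clusters: list[PoseCluster] = []
    for pose in poses:
        for cluster in clusters:
            if pose_rmsd(cluster.representative, pose) <= params.rmsd_cutoff:
                cluster.members.append(pose)
                break
        else:
            clusters.append(PoseCluster(representative=pose, members=[pose]))
    return clusters


def binding_site_residues(
    avg: AveragedSIFt,
    threshold: float = 0.3,
) -> list[tuple]:
    """Residues whose contact ('any'-bit) frequency reaches the threshold.

    Returned in the averaged table's residue order (receptor sequence
    order). ``threshold=0`` returns every contacted residue.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return [
        key for key, freq in avg.frequencies.items()
        if freq[0] >= threshold
    ]


def sift_long_table(sifts: Iterable[SIFt]) -> pd.DataFrame:
    """Long-format per-pose fingerprint table (one row per residue per pose)."""
    rows = []
    for s in sifts:
        for key, fp in s.fingerprints.items():
            row = {
                "ligand_id": s.ligand_id,
                "pose_index": s.pose_index,
                "chain": key[0],
                "residue_number": key[1],
                "residue_name": key[2] if len(key) > 2 else "",
            }
            row.update({bit: int(v) for bit, v in zip(BIT_NAMES, fp.bits)})
            rows.append(row)
    return pd.DataFrame(rows)
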