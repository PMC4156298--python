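"""SIFt engine: contacts, geometric predicates, fingerprints, averaging,
similarity, RMSD clustering and binding-site extraction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import siftkin as sk
from siftkin.sift import BIT_NAMES, InteractionParams, ResidueFingerprint, SIFt
from siftkin.structure_io import Atom, LigandPose, Residue, Ring, TypedStructure


def _atom(coords, element="C", name=None, key=("A", 1, "VAL"),
          backbone=False, roles=()):
    return Atom(serial=0, name=name or element, element=element,
                coords=np.asarray(coords, float), residue_key=key,
                is_backbone=backbone, roles=set(roles))


def _one_residue_structure(atoms, key=("A", 1, "VAL"), name="VAL"):
    st_ = TypedStructure(residues=[Residue(key=key, name=name, atoms=atoms)])
    st_.typed = True
    return st_


def _pose(atoms, index=0):
    return LigandPose("lig", index, list(atoms))


# ------------------------------------------------------------------------
# residue_contacts
# ------------------------------------------------------------------------

def test_single_contact_reported_with_distance():
    rec = _one_residue_structure([_atom((0, 0, 0), name="CB")])
    pose = _pose([_atom((3, 0, 0), key=("L", 1, "LIG"))])
    contacts = sk.residue_contacts(rec, pose)
    assert len(contacts) == 1
    key, ratom, latom, dist = contacts[0]
    assert key == ("A", 1, "VAL") and dist == pytest.approx(3.0)


def test_far_ligand_gives_no_contacts():
    rec = _one_residue_structure([_atom((0, 0, 0))])
    pose = _pose([_atom((10, 0, 0), key=("L", 1, "LIG"))])
    assert sk.residue_contacts(rec, pose) == []


def test_neighbor_search_matches_all_pairs_brute_force(rng):
    """k-d-tree contact search equals the O(N·M) all-pairs oracle."""
    rec_atoms, residues = [], []
    for i in range(5):
        key = ("A", i + 1, "GLY")
        atoms = [
            _atom(rng.uniform(0, 12, 3), key=key, name=f"C{j}")
            for j in range(10)
        ]
        residues.append(Residue(key=key, name="GLY", atoms=atoms))
        rec_atoms.extend(atoms)
    rec = TypedStructure(residues=residues)
    rec.typed = True
    lig = [_atom(rng.uniform(0, 12, 3), key=("L", 1, "LIG"), name=f"C{j}")
           for j in range(20)]
    pose = _pose(lig)
    params = InteractionParams()
    got = {(id(c[1]), id(c[2])) for c in sk.residue_contacts(rec, pose, params)}
    expected = {
        (id(ra), id(la))
        for ra in rec_atoms for la in lig
        if np.linalg.norm(ra.coords - la.coords) <= params.contact_cutoff
    }
    assert got == expected


def test_contacts_sorted_by_residue_then_distance(rng):
    residues = []
    for i in range(3):
        key = ("A", i + 1, "GLY")
        atoms = [_atom(rng.uniform(0, 8, 3), key=key, name=f"C{j}")
                 for j in range(5)]
        residues.append(Residue(key=key, name="GLY", atoms=atoms))
    rec = TypedStructure(residues=residues)
    rec.typed = True
    pose = _pose([_atom(rng.uniform(0, 8, 3), key=("L", 1, "LIG"))
                  for _ in range(5)])
    contacts = sk.residue_contacts(rec, pose)
    order = [(c[0][1], c[3]) for c in contacts]
    assert order == sorted(order)


# ------------------------------------------------------------------------
# detect_hbond / detect_aromatic_contact
# ------------------------------------------------------------------------

def test_hbond_collinear_within_range_is_true():
    d = _atom((0, 0, 0), "N", roles={"donor"})
    a = _atom((2.9, 0, 0), "O", roles={"acceptor"})
    h = _atom((1.0, 0, 0), "H")
    assert sk.detect_hbond(d, a, hydrogen=h)


def test_hbond_beyond_distance_cutoff_is_false():
    d = _atom((0, 0, 0), "N", roles={"donor"})
    a = _atom((4.0, 0, 0), "O", roles={"acceptor"})
    assert not sk.detect_hbond(d, a)


def test_hbond_right_angle_at_hydrogen_is_false():
    """D at origin, H at (1,0,0), A at (1,2.8,0): D–A ≈ 2.97 Å but the
    D–H–A angle is 90°, below the 120° minimum (dot-product oracle)."""
    d = _atom((0, 0, 0), "N", roles={"donor"})
    h = _atom((1, 0, 0), "H")
    a = _atom((1, 2.8, 0), "O", roles={"acceptor"})
    v1, v2 = d.coords - h.coords, a.coords - h.coords
    angle = np.degrees(np.arccos(
        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
    assert angle == pytest.approx(90.0)
    assert np.linalg.norm(d.coords - a.coords) < 3.5
    assert not sk.detect_hbond(d, a, hydrogen=h)


def _ring_at(centroid, normal=(0, 0, 1)):
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    return Ring(atoms=[], centroid=np.asarray(centroid, float), normal=normal)


@pytest.mark.parametrize("centroid_b,normal_b,expected", [
    ((0, 0, 4.0), (0, 0, 1), True),     # parallel stack at 4 Å
    ((0, 0, 8.0), (0, 0, 1), False),    # far apart
    ((0, 4.8, 0), (0, 1, 0), True),     # T-shaped at 4.8 Å (distance-only)
])
def test_aromatic_contact_distance_criterion(centroid_b, normal_b, expected):
    a = _ring_at((0, 0, 0))
    b = _ring_at(centroid_b, normal_b)
    assert sk.detect_aromatic_contact(a, b) is expected


# ------------------------------------------------------------------------
# compute_sift
# ------------------------------------------------------------------------

def test_sift_requires_typed_receptor():
    rec = _one_residue_structure([_atom((0, 0, 0))])
    rec.typed = False
    with pytest.raises(ValueError, match="assign_atom_roles"):
        sk.compute_sift(rec, _pose([_atom((3, 0, 0), key=("L", 1, "LIG"))]))


def test_ligand_beyond_cutoff_gives_empty_sift(single_val_complex):
    rec = single_val_complex.receptor
    pose = _pose([_atom((500, 500, 500), key=("L", 1, "LIG"))])
    assert sk.compute_sift(rec, pose).fingerprints == {}


def test_tyr_stacked_benzene_sets_aromatic_bit():
    """A ligand benzene ring 4 Å from a Tyr ring registers the aromatic bit
    together with the sidechain hydrophobic contact — the Tyr interaction
    signature (any, sidechain, hydrophobic, aromatic)."""
    ens = sk.make_complex(
        sk.ComplexSpec(planted=(sk.PlantedInteraction("aromatic"),)))
    s = sk.compute_sift(ens.receptor, ens.poses[0])
    (key, fp), = s.fingerprints.items()
    assert key[2] == "TYR"
    expected = {"any", "sidechain", "hydrophobic", "aromatic"}
    assert {b for b, v in zip(BIT_NAMES, fp.bits) if v} == expected


def _brute_force_sift(receptor, pose, params=InteractionParams()):
    """Independent all-pairs re-derivation of every bit (no neighbor search,
    no shared code path beyond the atom containers)."""
    bits = {}

    def get(key):
        return bits.setdefault(key, dict.fromkeys(BIT_NAMES, False))

    lig_heavy = [a for a in pose.atoms if not a.is_hydrogen]
    hydrogens = [a for a in pose.atoms if a.is_hydrogen]
    for res in receptor.residues:
        for ra in res.atoms:
            if ra.is_hydrogen or ra.is_water:
                continue
            for la in lig_heavy:
                d = float(np.linalg.norm(ra.coords - la.coords))
                if d > params.contact_cutoff:
                    continue
                row = get(res.key)
                row["any"] = True
                row["backbone" if ra.is_backbone else "sidechain"] = True
                if (ra.element in ("N", "O") and la.element in ("N", "O")
                        and d <= params.polar_max):
                    row["polar"] = True
                if ra.element in ("C", "S") and la.element in ("C", "S"):
                    row["hydrophobic"] = True
                if ("acceptor" in ra.roles and "donor" in la.roles
                        and d <= params.hbond_da_max):
                    hs = [h for h in hydrogens
                          if np.linalg.norm(h.coords - la.coords) < 1.3]
                    if not hs:
                        row["hbond_acceptor"] = True
                    else:
                        for h in hs:
                            v1 = la.coords - h.coords
                            v2 = ra.coords - h.coords
                            ang = np.degrees(np.arccos(np.clip(
                                np.dot(v1, v2)
                                / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                                -1, 1)))
                            if ang >= params.hbond_angle_min:
                                row["hbond_acceptor"] = True
                if ("donor" in ra.roles and "acceptor" in la.roles
                        and d <= params.hbond_da_max):
                    row["hbond_donor"] = True
                if d <= params.charged_max and (
                        ("cation" in ra.roles and "anion" in la.roles)
                        or ("anion" in ra.roles and "cation" in la.roles)):
                    row["charged"] = True
    for rring in receptor.rings:
        for lring in pose.rings:
            if (np.linalg.norm(rring.centroid - lring.centroid)
                    <= params.aromatic_centroid_max):
                row = get(rring.residue_key)
                row["aromatic"] = row["any"] = row["sidechain"] = True
    return {
        key: tuple(row[b] for b in BIT_NAMES)
        for key, row in bits.items() if any(row.values())
    }


@pytest.mark.parametrize("bits", [
    ("hydrophobic",),
    ("hbond_acceptor", "charged"),
    ("aromatic", "polar", "backbone"),
    tuple(BIT_NAMES),
])
def test_compute_sift_equals_brute_force_on_planted_complexes(bits):
    ens = sk.make_complex(
        sk.ComplexSpec(planted=tuple(sk.PlantedInteraction(b) for b in bits)))
    assert len(ens.receptor.heavy_atoms()) + len(ens.poses[0].atoms) <= 150
    s = sk.compute_sift(ens.receptor, ens.poses[0])
    got = {k: fp.bits for k, fp in s.fingerprints.items()}
    assert got == _brute_force_sift(ens.receptor, ens.poses[0])


def test_compute_sift_equals_brute_force_on_random_clouds(rng):
    """Randomly scattered receptor/ligand atoms (≤100 total) with random
    roles: engine output equals the brute-force oracle."""
    for _ in range(5):
        residues = []
        for i in range(4):
            key = ("A", i + 1, "GLY")
            atoms = []
            for j in range(10):
                roles = set(rng.choice(
                    ["donor", "acceptor", "cation", "anion"],
                    size=rng.integers(0, 3), replace=False))
                atoms.append(Atom(
                    serial=0, name=f"X{j}",
                    element=str(rng.choice(["C", "N", "O", "S"])),
                    coords=rng.uniform(0, 10, 3), residue_key=key,
                    is_backbone=bool(rng.random() < 0.3), roles=roles))
            residues.append(Residue(key=key, name="GLY", atoms=atoms))
        rec = TypedStructure(residues=residues)
        rec.typed = True
        lig_atoms = []
        for j in range(15):
            roles = set(rng.choice(
                ["donor", "acceptor", "cation", "anion"],
                size=rng.integers(0, 3), replace=False))
            lig_atoms.append(Atom(
                serial=0, name=f"L{j}",
                element=str(rng.choice(["C", "N", "O"])),
                coords=rng.uniform(0, 10, 3), residue_key=("L", 1, "LIG"),
                roles=roles))
        pose = _pose(lig_atoms)
        s = sk.compute_sift(rec, pose)
        got = {k: fp.bits for k, fp in s.fingerprints.items()}
        assert got == _brute_force_sift(rec, pose)


def test_bit_hierarchy_enforced_on_computed_fingerprints(rng):
    """'any' dominates every sub-bit in every computed fingerprint."""
    bits_all = tuple(sk.PlantedInteraction(b) for b in BIT_NAMES)
    ens = sk.make_complex(sk.ComplexSpec(planted=bits_all))
    s = sk.compute_sift(ens.receptor, ens.poses[0])
    for fp in s.fingerprints.values():
        assert fp.bits[0] >= max(fp.bits[1:])


def test_residue_fingerprint_rejects_hierarchy_violation():
    with pytest.raises(ValueError, match="hierarchy"):
        ResidueFingerprint(("A", 1, "VAL"),
                           (False, True) + (False,) * 7)


# ------------------------------------------------------------------------
# average_sift
# ------------------------------------------------------------------------

def test_average_of_single_sift_equals_its_bits(single_val_complex):
    rec, pose = single_val_complex.receptor, single_val_complex.poses[0]
    s = sk.compute_sift(rec, pose)
    avg = sk.average_sift([s])
    for key, fp in s.fingerprints.items():
        np.testing.assert_array_equal(avg.frequencies[key], fp.as_array)


def test_twelve_of_29_hbond_poses_average_to_0_41():
    """12 of 29 poses hydrogen-bonding to an Arg residue average to
    12/29 ≈ 0.41 on the H-bond-acceptor bit."""
    spec = sk.EnsembleSpec(
        planted=(sk.PlantedInteraction(
            "hbond_acceptor", residue_name="ARG", residue_number=71,
            anchor_atom="O", frequency=12 / 29),),
        n_poses=29, seed=3, exact=True)
    ens = sk.sample_ensemble(spec)
    avg = sk.average_sift(
        [sk.compute_sift(ens.receptor, p) for p in ens.poses])
    freq = avg.frequency(("A", 71, "ARG"), "hbond_acceptor")
    assert freq == pytest.approx(12 / 29)
    assert round(freq, 2) == 0.41


def test_average_equals_arithmetic_mean_oracle(rng):
    spec = sk.EnsembleSpec(
        planted=(sk.PlantedInteraction("hydrophobic", frequency=0.6),
                 sk.PlantedInteraction("polar", frequency=0.3)),
        n_poses=40, seed=11)
    ens = sk.sample_ensemble(spec)
    sifts = [sk.compute_sift(ens.receptor, p) for p in ens.poses]
    avg = sk.average_sift(sifts)
    for key, freq in avg.frequencies.items():
        vectors = [
            s.fingerprints[key].as_array if key in s.fingerprints
            else np.zeros(len(BIT_NAMES))
            for s in sifts
        ]
        np.testing.assert_allclose(freq, np.mean(vectors, axis=0), atol=1e-12)
        # counts are integers
        np.testing.assert_allclose(
            freq * avg.n_fingerprints,
            np.round(freq * avg.n_fingerprints), atol=1e-9)


def test_average_empty_list_raises():
    with pytest.raises(ValueError):
        sk.average_sift([])


# ------------------------------------------------------------------------
# tanimoto
# ------------------------------------------------------------------------

def _sift_with(bits_by_key, order):
    return SIFt("lig", 0, {
        k: ResidueFingerprint(k, b) for k, b in bits_by_key.items()
    }, residue_order=order)


_K1, _K2 = ("A", 1, "VAL"), ("A", 2, "SER")
_ORDER = (_K1, _K2)


def _bits(*names):
    return tuple(b in names for b in BIT_NAMES)


def test_tanimoto_identical_nonempty_is_one():
    a = _sift_with({_K1: _bits("any", "sidechain")}, _ORDER)
    assert sk.tanimoto(a, a) == 1.0


def test_tanimoto_disjoint_is_zero():
    a = _sift_with({_K1: _bits("any", "sidechain")}, _ORDER)
    b = _sift_with({_K2: _bits("any", "backbone")}, _ORDER)
    assert sk.tanimoto(a, b) == 0.0


def test_tanimoto_partial_overlap_counts():
    # a: 3 set bits; b shares 2 plus 1 more -> 2/4
    a = _sift_with({_K1: _bits("any", "sidechain", "hydrophobic")}, _ORDER)
    b = _sift_with({_K1: _bits("any", "sidechain", "polar")}, _ORDER)
    assert sk.tanimoto(a, b) == pytest.approx(0.5)


def test_tanimoto_empty_pair_is_one_and_symmetric():
    a = _sift_with({}, _ORDER)
    b = _sift_with({_K1: _bits("any")}, _ORDER)
    assert sk.tanimoto(a, a) == 1.0
    assert sk.tanimoto(a, b) == sk.tanimoto(b, a)


def test_tanimoto_different_receptors_raise():
    a = _sift_with({}, _ORDER)
    b = _sift_with({}, (_K1,))
    with pytest.raises(ValueError):
        sk.tanimoto(a, b)


# ------------------------------------------------------------------------
# pose RMSD and clustering
# ------------------------------------------------------------------------

def _pose_at(offsets, index=0):
    return _pose(
        [_atom(o, key=("L", 1, "LIG"), name=f"C{i}")
         for i, o in enumerate(offsets)], index)


def test_rmsd_identity_and_uniform_translation():
    p0 = _pose_at([(0, 0, 0), (1, 1, 1), (2, 0, 1)])
    assert sk.pose_rmsd(p0, p0) == 0.0
    p1 = _pose_at([(1, 0, 0), (2, 1, 1), (3, 0, 1)], 1)
    assert sk.pose_rmsd(p0, p1) == pytest.approx(1.0)


def test_rmsd_matches_direct_formula(rng):
    a = rng.normal(size=(7, 3))
    b = rng.normal(size=(7, 3))
    pa, pb = _pose_at(a), _pose_at(b, 1)
    expected = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    assert sk.pose_rmsd(pa, pb) == pytest.approx(expected)


def test_rmsd_atom_count_mismatch_raises():
    with pytest.raises(ValueError):
        sk.pose_rmsd(_pose_at([(0, 0, 0)]), _pose_at([(0, 0, 0), (1, 0, 0)]))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_rmsd_is_a_metric_on_random_triples(seed):
    r = np.random.default_rng(seed)
    a, b, c = (r.normal(size=(5, 3)) for _ in range(3))
    pa, pb, pc = _pose_at(a), _pose_at(b, 1), _pose_at(c, 2)
    dab, dba = sk.pose_rmsd(pa, pb), sk.pose_rmsd(pb, pa)
    assert dab == pytest.approx(dba)
    assert sk.pose_rmsd(pa, pa) == 0.0
    assert sk.pose_rmsd(pa, pc) <= dab + sk.pose_rmsd(pb, pc) + 1e-12


def test_identical_poses_form_one_cluster():
    poses = [_pose_at([(0, 0, 0), (1, 0, 0)], i) for i in range(5)]
    clusters = sk.cluster_poses(poses)
    assert len(clusters) == 1
    assert clusters[0].representative.pose_index == 0


def test_two_separated_groups_form_two_clusters():
    group_a = [_pose_at([(0, 0, 0.05 * i)], i) for i in range(3)]
    group_b = [_pose_at([(5, 0, 0.05 * i)], 3 + i) for i in range(3)]
    clusters = sk.cluster_poses(group_a + group_b,
                                sk.ClusterParams(rmsd_cutoff=1.0))
    assert len(clusters) == 2
    assert [c.representative.pose_index for c in clusters] == [0, 3]


def test_clustering_is_deterministic(rng):
    poses = [_pose_at(rng.normal(scale=2.0, size=(4, 3)), i)
             for i in range(20)]
    first = sk.cluster_poses(poses)
    second = sk.cluster_poses(poses)
    assert [[m.pose_index for m in c.members] for c in first] == \
        [[m.pose_index for m in c.members] for c in second]


# ------------------------------------------------------------------------
# binding-site extraction
# ------------------------------------------------------------------------

def test_binding_site_threshold_selects_frequent_residues():
    """An ensemble engineered so exactly 12 residues exceed the threshold
    (mirroring a 12-residue protease binding site) returns those 12."""
    high = [sk.PlantedInteraction("hydrophobic", residue_number=n,
                                  frequency=0.9)
            for n in range(10, 130, 10)]          # 12 residues, f=0.9
    low = [sk.PlantedInteraction("hydrophobic", residue_number=n,
                                 frequency=0.1)
           for n in range(200, 230, 10)]          # 3 residues, f=0.1
    spec = sk.EnsembleSpec(planted=tuple(high + low), n_poses=30, seed=5,
                           exact=True)
    ens = sk.sample_ensemble(spec)
    avg = sk.average_sift(
        [sk.compute_sift(ens.receptor, p) for p in ens.poses])
    site = sk.binding_site_residues(avg, threshold=0.3)
    assert len(site) == 12
    assert [k[1] for k in site] == list(range(10, 130, 10))
    # threshold 0 returns every contacted residue
    assert len(sk.binding_site_residues(avg, threshold=0.0)) == 15


def test_binding_site_of_empty_average_is_empty():
    avg = sk.AveragedSIFt(frequencies={}, n_fingerprints=1)
    assert sk.binding_site_residues(avg, 0.5) == []
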