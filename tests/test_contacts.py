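"""Contact detection, SIFt classification, grouping and surface exposure."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from conftest import build_assembly, random_rotation, transform_assembly
from structprof import fixtures as fx
from structprof.chemtypes import LigandEntity
from structprof.config import default_config
from structprof.contacts import (DISTANCE_FLAGS, FEATURE_FLAGS, FLAG_ORDER,
                                 contacts_tsv, entity_label,
                                 group_interactions, neighbor_pairs,
                                 profile_contacts, surface_exposed)
from structprof.model import parse_structure


def _cloud_assembly(n, rng, span=30.0):
    coords = rng.uniform(0, span, size=(n, 3))
    spec = [("ATM", i + 1, [("C1", "C", c)]) for i, c in enumerate(coords)]
    return build_assembly(spec), coords


def test_sift_has_five_distance_and_eight_feature_flags():
    assert len(DISTANCE_FLAGS) == 5
    assert len(FEATURE_FLAGS) == 8
    assert len(FLAG_ORDER) == 13


def test_two_atoms_within_cutoff_are_one_pair():
    spec = [("ATM", 1, [("C1", "C", (0, 0, 0))]),
            ("ATM", 2, [("C1", "C", (3, 0, 0))])]
    asm = build_assembly(spec)
    assert len(neighbor_pairs(asm, 4.0)) == 1
    assert neighbor_pairs(asm, 2.9) == []


def test_neighbor_pairs_equal_brute_force_scan():
    rng = np.random.default_rng(5)
    asm, coords = _cloud_assembly(200, rng)
    atoms = list(asm.iter_atoms())
    got = {frozenset((id(a), id(b))) for a, b, _ in neighbor_pairs(asm, 5.0)}
    want = set()
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if np.linalg.norm(coords[i] - coords[j]) <= 5.0:
                want.add(frozenset((id(atoms[i]), id(atoms[j]))))
    assert got == want


def test_invalid_cutoff_rejected(toy):
    asm, _ = toy
    with pytest.raises(ValueError):
        neighbor_pairs(asm, -1.0)


# ---------------------------------------------------------------------------
# classification closed loop against generator declarations
# ---------------------------------------------------------------------------

CASES = [
    ("donor", "acceptor", 2.9, 150.0),
    ("donor", "acceptor", 2.9, 60.0),      # donor angle fails
    ("halogen", "acceptor", 3.2, 165.0),
    ("halogen", "acceptor", 3.2, 100.0),   # sigma-hole angle fails
    ("carbon", "acceptor", 3.3, 120.0),
    ("carbonyl", "acceptor", 3.0, 120.0),
    ("cation", "acceptor", 3.4, 120.0),
    ("apolar", "apolar", 4.0, 120.0),
    ("apolar", "apolar", 7.0, 120.0),      # beyond proximal: not stored
]


def _probe_contact(result, gt):
    keys = {tuple(gt["probe_a"]), tuple(gt["probe_b"])}
    for c in result.contacts:
        ka = (c.atom_a.parent.chain.id, c.atom_a.parent.number,
              c.atom_a.name)
        kb = (c.atom_b.parent.chain.id, c.atom_b.parent.number,
              c.atom_b.name)
        if {ka, kb} == keys:
            return c
    return None


@pytest.mark.parametrize("type_a,type_b,distance,angle", CASES)
def test_probe_pair_flags_match_generator_declaration(
        store, type_a, type_b, distance, angle):
    text, gt = fx.make_contact_pair(type_a, type_b, distance, angle)
    asm = parse_structure(text, "pdb")
    result = profile_contacts(asm, store)
    contact = _probe_contact(result, gt)
    if not gt["stored"]:
        assert contact is None
        return
    assert contact is not None
    assert sorted(contact.flags.set_features()) == gt["expected_flags"]
    # every stored contact carries exactly one distance bin
    assert sum(getattr(contact.flags, f) for f in DISTANCE_FLAGS) == 1


def test_feature_flags_never_exceed_their_distance_cutoffs(toy_profile):
    result, _ = toy_profile
    cfg = default_config()
    limits = {"hbond": cfg.features.hbond,
              "weak_hbond": cfg.features.weak_hbond,
              "ionic": cfg.features.ionic,
              "metal_complex": cfg.features.metal,
              "hydrophobic": cfg.features.hydrophobic,
              "carbonyl": cfg.features.carbonyl}
    for c in result.contacts:
        for flag, cutoff in limits.items():
            if getattr(c.flags, flag):
                assert c.distance <= cutoff


def test_shrinking_cutoffs_never_adds_flags(store):
    text, _ = fx.make_toy_complex(7)
    asm1 = parse_structure(text, "pdb")
    asm2 = parse_structure(text, "pdb")
    tight = default_config()
    tight.features = replace(tight.features, hbond=3.0, weak_hbond=3.0,
                             hydrophobic=4.0, carbonyl=3.0, ionic=3.5,
                             aromatic_centroid=4.0)
    loose = profile_contacts(asm1, store)
    strict = profile_contacts(asm2, store, tight)

    def keyed(result):
        return {(result.assembly.atom_path(c.atom_a).components,
                 result.assembly.atom_path(c.atom_b).components):
                c.flags.set_features() & set(FEATURE_FLAGS)
                for c in result.contacts}

    kl, ks = keyed(loose), keyed(strict)
    for key, strict_flags in ks.items():
        assert strict_flags <= kl[key]


def test_flags_and_classes_survive_rigid_body_motion(store):
    text, _ = fx.make_toy_complex(7)
    asm1 = parse_structure(text, "pdb")
    asm2 = parse_structure(text, "pdb")
    rng = np.random.default_rng(3)
    transform_assembly(asm2, random_rotation(rng), np.array([-7.0, 2.0, 5.0]))
    r1 = profile_contacts(asm1, store)
    r2 = profile_contacts(asm2, store)

    def digest(result):
        return sorted(
            (str(result.assembly.atom_path(c.atom_a)),
             str(result.assembly.atom_path(c.atom_b)),
             c.pair_class, tuple(sorted(c.flags.set_features())))
            for c in result.contacts)

    assert digest(r1) == digest(r2)


def test_same_residue_and_bonded_pairs_excluded(toy_profile):
    result, _ = toy_profile
    for c in result.contacts:
        assert c.atom_a.parent is not c.atom_b.parent
        assert not result.context.bond_graph.bonded_or_13(c.atom_a, c.atom_b)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def test_toy_entity_pair_census_matches_ground_truth(toy_profile):
    result, gt = toy_profile
    groups = group_interactions(result)
    asm = result.assembly

    def label(entity):
        s = entity_label(asm, entity)
        parts = s.split("/")
        if len(parts) == 3:
            return parts[2]                    # chain
        return f"{parts[2]}/{parts[3].split('`')[0]}"   # ligand

    got = sorted(sorted([label(g.entity_a), label(g.entity_b)])
                 + [g.pair_class] for g in groups)
    assert got == gt["entity_pairs"]


def test_cofactor_census_two_binding_sites_one_ligand_ligand(store):
    text, gt = fx.make_cofactor_complex()
    asm = parse_structure(text, "pdb")
    groups = group_interactions(profile_contacts(asm, store))
    assert Counter(g.pair_class for g in groups) == gt["census"]


def test_grouping_conserves_inter_entity_contacts(toy_profile):
    result, _ = toy_profile
    groups = group_interactions(result)
    n_inter = sum(1 for c in result.contacts if not c.is_intramolecular)
    assert sum(g.contact_count for g in groups) == n_inter


def test_interface_reports_residue_counts_per_side(toy_profile):
    result, _ = toy_profile
    groups = group_interactions(result)
    iface = next(g for g in groups if g.pair_class == "interface")
    assert len(iface.residues_a) >= 10 and len(iface.residues_b) >= 10


def test_planted_contacts_detected_with_expected_flags(toy_profile):
    result, gt = toy_profile
    index = {}
    for c in result.contacts:
        ka = (c.atom_a.parent.chain.id, c.atom_a.parent.number,
              c.atom_a.name)
        kb = (c.atom_b.parent.chain.id, c.atom_b.parent.number,
              c.atom_b.name)
        index[frozenset((ka, kb))] = c
    for planted in gt["planted_contacts"]:
        key = frozenset((tuple(planted["a"]), tuple(planted["b"])))
        assert key in index
        assert set(planted["flags"]) <= index[key].flags.set_features()


def test_waters_excluded_from_census_by_default(toy_profile):
    result, _ = toy_profile
    for c in result.contacts:
        assert not c.atom_a.parent.is_water
        assert not c.atom_b.parent.is_water


def test_contact_table_rows_have_13_flag_columns(toy_profile):
    result, _ = toy_profile
    lines = contacts_tsv(result).strip().splitlines()
    header = lines[0].split("\t")
    assert header[3:] == list(FLAG_ORDER)
    for line in lines[1:]:
        cells = line.split("\t")
        assert len(cells) == 16
        assert set(cells[3:]) <= {"0", "1"}


# ---------------------------------------------------------------------------
# surface exposure
# ---------------------------------------------------------------------------

def test_free_small_molecule_fully_exposed(toy_profile):
    result, _ = toy_profile
    benzene = next(l for l in result.ligands if "BNZ" in str(l.path_id))
    exposure = surface_exposed(benzene)
    assert all(exposure.atom_exposed.values())


def test_core_of_compact_globule_is_buried():
    pts = [(x, y, z) for x in range(5) for y in range(5) for z in range(5)]
    spec = [("GLB", 1, [(f"C{i}", "C", (2.0 * x, 2.0 * y, 2.0 * z))
                        for i, (x, y, z) in enumerate(pts, 1)])]
    asm = build_assembly(spec)
    res = asm.chains[0].residues[0]
    entity = LigandEntity([res], asm.residue_path(res))
    exposure = surface_exposed(entity)
    center = res.get_atom("C63")   # lattice midpoint (2,2,2)
    corner = res.get_atom("C1")
    assert np.allclose(center.coords, [4.0, 4.0, 4.0])
    assert not exposure.is_exposed(center)
    assert exposure.is_exposed(corner)
    # fine-resolution oracle agrees on the buried atom
    cfg = default_config()
    cfg.exposure.n_points = 1000
    fine = surface_exposed(entity, cfg)
    assert not fine.is_exposed(center)


def test_exposure_is_per_entity_not_per_assembly(toy_profile):
    # a ligand buried in a pocket is still exposed as an isolated entity
    result, _ = toy_profile
    lg1 = next(l for l in result.ligands if "LG1" in str(l.path_id))
    exposure = surface_exposed(lg1)
    assert all(exposure.atom_exposed.values())
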