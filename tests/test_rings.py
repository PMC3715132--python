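"""Ring-ring geometry, nine-class assignment, atom-ring interactions."""

import math

import numpy as np
import pytest

from conftest import random_rotation, transform_assembly
from structprof import fixtures as fx
from structprof.chemtypes import assign_atom_types, perceive_aromatic_rings
from structprof.config import default_config
from structprof.model import parse_structure
from structprof.rings import (RingGeometryError, classify_ring_ring,
                              detect_atom_ring, detect_ring_ring,
                              ring_ring_geometry)


def _rings_of(text, store):
    asm = parse_structure(text, "pdb")
    assign_atom_types(asm, store)
    return asm, perceive_aromatic_rings(asm, store)


def test_parallel_stack_has_zero_angles(store):
    text, _ = fx.make_ring_pair(3.5, 0.0, 0.0)
    _, rings = _rings_of(text, store)
    d, dihedral, theta_a, theta_b = ring_ring_geometry(rings[0], rings[1])
    assert d == pytest.approx(3.5, abs=0.01)
    assert dihedral == pytest.approx(0.0, abs=0.1)
    assert theta_a == pytest.approx(0.0, abs=0.1)
    assert theta_b == pytest.approx(0.0, abs=0.1)


def test_perpendicular_t_shape_geometry(store):
    text, _ = fx.make_ring_pair(5.0, 90.0, 0.0)
    _, rings = _rings_of(text, store)
    d, dihedral, theta_a, theta_b = ring_ring_geometry(rings[0], rings[1])
    assert dihedral == pytest.approx(90.0, abs=0.1)
    assert theta_a == pytest.approx(0.0, abs=0.1)
    assert theta_b == pytest.approx(90.0, abs=0.1)


def test_geometry_matches_independent_vector_algebra(store):
    rng = np.random.default_rng(9)
    for _ in range(5):
        d = rng.uniform(3.5, 5.8)
        dih = rng.uniform(0, 90)
        th = rng.uniform(0, 90)
        text, _ = fx.make_ring_pair(float(d), float(dih), float(th))
        _, rings = _rings_of(text, store)
        got = ring_ring_geometry(rings[0], rings[1])
        # oracle: plane normals from cross products of ring-atom vectors
        def oracle_normal(ring):
            c = np.mean([a.coords for a in ring.atoms], axis=0)
            v1 = ring.atoms[0].coords - c
            v2 = ring.atoms[2].coords - c
            n = np.cross(v1, v2)
            return n / np.linalg.norm(n)

        ca = np.mean([a.coords for a in rings[0].atoms], axis=0)
        cb = np.mean([a.coords for a in rings[1].atoms], axis=0)
        na, nb = oracle_normal(rings[0]), oracle_normal(rings[1])
        u = (cb - ca) / np.linalg.norm(cb - ca)

        def fold(x):
            return math.degrees(math.acos(min(1.0, abs(x))))

        assert got[0] == pytest.approx(np.linalg.norm(cb - ca), abs=1e-6)
        assert got[1] == pytest.approx(fold(np.dot(na, nb)), abs=0.05)
        assert got[2] == pytest.approx(fold(np.dot(na, u)), abs=0.05)
        assert got[3] == pytest.approx(fold(np.dot(nb, u)), abs=0.05)


def test_coincident_centroids_rejected(store):
    text, _ = fx.make_ring_pair(3.5, 0.0, 0.0)
    _, rings = _rings_of(text, store)
    with pytest.raises(RingGeometryError):
        ring_ring_geometry(rings[0], rings[0])


def test_classifier_image_has_exactly_nine_labels():
    labels = {classify_ring_ring(d, t)
              for d in range(0, 91, 5) for t in range(0, 91, 5)}
    assert len(labels) == 9
    assert labels == {"FF", "OF", "EE", "FT", "OT", "ET", "FE", "OE", "EF"}


@pytest.mark.parametrize("dihedral,theta,label", [
    (5, 5, "FF"), (89, 89, "EF"), (15, 45, "OF"), (45, 15, "FT"),
    (30, 0, "FT"), (0, 30, "OF"), (60, 30, "OE"), (90, 90, "EF"),
])
def test_boundary_and_interior_bins(dihedral, theta, label):
    assert classify_ring_ring(dihedral, theta) == label


def test_out_of_range_angles_rejected():
    with pytest.raises(RingGeometryError):
        classify_ring_ring(95.0, 10.0)


@pytest.mark.parametrize("dihedral,theta", [
    (15, 15), (15, 45), (15, 75), (45, 15), (45, 45), (45, 75),
    (75, 15), (75, 45), (75, 75),
])
def test_nine_canonical_fixture_poses_reproduce_intended_class(
        store, dihedral, theta):
    text, gt = fx.make_ring_pair(5.0, dihedral, theta)
    _, rings = _rings_of(text, store)
    (interaction,) = detect_ring_ring(rings)
    assert interaction.class_label == gt["class_label"]


def test_classification_invariant_under_rigid_motion_and_normal_flip(store):
    text, _ = fx.make_ring_pair(4.2, 40.0, 20.0)
    asm, rings = _rings_of(text, store)
    (before,) = detect_ring_ring(rings)
    rng = np.random.default_rng(4)
    transform_assembly(asm, random_rotation(rng), np.array([10.0, -2.0, 1.0]))
    rings2 = perceive_aromatic_rings(asm, store)
    rings2[0].normal = -rings2[0].normal
    (after,) = detect_ring_ring(rings2)
    assert after.class_label == before.class_label
    assert after.dihedral == pytest.approx(before.dihedral, abs=1e-6)
    assert after.theta_a == pytest.approx(before.theta_a, abs=1e-6)


def test_fused_rings_of_one_system_are_not_an_interaction(store):
    # TRP-style fused pair shares atoms -> no ring-ring record
    from conftest import build_assembly, hexagon, ring_extension

    hexa = hexagon()
    six = ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]
    ext = ring_extension(hexa[1], hexa[0], 5)
    atoms = [(n, "C", xyz) for n, xyz in zip(six, hexa)]
    atoms += [("NE1", "N", ext[0]), ("CD1", "C", ext[1]),
              ("CG", "C", ext[2])]
    asm = build_assembly([("TRP", 1, atoms)], polymer=True)
    from structprof.templates import default_store

    assign_atom_types(asm, default_store())
    rings = perceive_aromatic_rings(asm, default_store())
    assert len(rings) == 2
    assert detect_ring_ring(rings) == []


# ---------------------------------------------------------------------------
# atom-ring interactions
# ---------------------------------------------------------------------------

def test_cation_on_ring_axis_is_cation_pi(store):
    # ammonium N directly over a benzene ring
    ring_text, _ = fx.make_ring_pair(3.5, 0.0, 0.0)
    asm = parse_structure(ring_text, "pdb")
    # replace second ring by a single ammonium N on the first ring's axis
    asm.chains[0].residues = asm.chains[0].residues[:1]
    from structprof.model import Atom, Residue

    amm = Residue(name="AMM", number=9, chain=asm.chains[0])
    amm.atoms = [Atom(serial=99, name="N1", element="N",
                      coords=np.array([0.0, 0.0, 3.4]), parent=amm)]
    asm.chains[0].residues.append(amm)
    assign_atom_types(asm, store)
    rings = perceive_aromatic_rings(asm, store)
    records = detect_atom_ring(amm.atoms, rings)
    assert len(records) == 1
    assert records[0].label == "cation_pi"
    assert records[0].theta == pytest.approx(0.0, abs=1e-6)


def test_theta_beyond_thirty_degrees_never_recorded(store):
    text, _ = fx.make_halogen_probe(4.0, 45.0)
    asm = parse_structure(text, "pdb")
    assign_atom_types(asm, store)
    rings = perceive_aromatic_rings(asm, store)
    assert detect_atom_ring(list(asm.iter_atoms()), rings) == []


def test_halogen_probe_labelled_halogen_pi(store):
    text, gt = fx.make_halogen_probe(3.4, 25.0)
    asm = parse_structure(text, "pdb")
    assign_atom_types(asm, store)
    rings = perceive_aromatic_rings(asm, store)
    records = detect_atom_ring(list(asm.iter_atoms()), rings)
    labels = {r.label for r in records}
    assert gt["label"] in labels
    assert all(r.theta <= 30.0 for r in records)


def test_weak_donor_carbon_is_carbon_pi(store):
    # methane carbon 3.6 Å over the ring at theta 10°
    ring_text, _ = fx.make_ring_pair(3.5, 0.0, 0.0)
    asm = parse_structure(ring_text, "pdb")
    asm.chains[0].residues = asm.chains[0].residues[:1]
    from structprof.model import Atom, Residue

    t = math.radians(10.0)
    mth = Residue(name="MTH", number=9, chain=asm.chains[0])
    mth.atoms = [Atom(serial=99, name="C1", element="C",
                      coords=3.6 * np.array([math.sin(t), 0, math.cos(t)]),
                      parent=mth)]
    asm.chains[0].residues.append(mth)
    assign_atom_types(asm, store)
    rings = perceive_aromatic_rings(asm, store)
    (rec,) = detect_atom_ring(mth.atoms, rings)
    assert rec.label == "carbon_pi"
    assert rec.theta == pytest.approx(10.0, abs=0.01)


def test_label_priority_cation_over_donor(store):
    # ammonium is both donor and positively ionisable: cation_pi wins
    from structprof.chemtypes import AtomTypeFlags
    from structprof.rings import label_atom_ring
    from structprof.model import Atom

    a = Atom(serial=1, name="N1", element="N", coords=np.zeros(3))
    a.flags = AtomTypeFlags(hbond_donor=True, pos_ionisable=True)
    assert label_atom_ring(a) == "cation_pi"
    a.flags = AtomTypeFlags(hbond_donor=True, halogen_donor=True)
    assert label_atom_ring(a) == "halogen_pi"


def test_ring_cutoff_limits_recording(store):
    text, _ = fx.make_ring_pair(5.5, 0.0, 0.0)
    _, rings = _rings_of(text, store)
    cfg = default_config()
    cfg.rings.ring_ring_cutoff = 5.0
    assert detect_ring_ring(rings, cfg) == []
    cfg.rings.ring_ring_cutoff = 6.0
    assert len(detect_ring_ring(rings, cfg)) == 1
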