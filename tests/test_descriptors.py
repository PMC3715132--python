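"""Cavity fingerprints, shape moments and SIFt-matrix clustering."""

import math
from itertools import combinations, combinations_with_replacement

import numpy as np
import pytest

from conftest import build_assembly, random_rotation
from structprof.config import default_config
from structprof.chemtypes import LigandEntity
from structprof.descriptors import (FUZCAV_FEATURES, MappingError,
                                    build_sift_matrix, cluster_sifts,
                                    fuzcav_fingerprint, fuzcav_similarity,
                                    residue_features, site_anchors,
                                    site_eligible, usrcat_ensemble,
                                    usrcat_moments, usrcat_similarity)
from structprof.model import Atom, Residue


def _site(specs, polymer=True):
    """specs: [(resname, resnum, CA xyz)] -> residue list with CA anchors."""
    residues = []
    asm = build_assembly(
        [(name, num, [("CA", "C", xyz)]) for name, num, xyz in specs],
        polymer=polymer)
    return asm.chains[0].residues


FOUR_RES = [("LYS", 1, (0.0, 0.0, 0.0)), ("ASP", 2, (5.0, 0.0, 0.0)),
            ("PHE", 3, (0.0, 7.0, 0.0)), ("SER", 4, (3.0, 3.0, 10.0))]


def _brute_force_counts(residues, edges):
    """Independent triple loop over anchors with its own binning code."""
    feats = residue_features()
    anchors = [(r.get_atom("CA").coords,
                tuple(sorted(FUZCAV_FEATURES.index(f)
                             for f in feats[r.name])))
               for r in residues]
    n_bins = len(edges) + 1
    fc = list(combinations_with_replacement(range(6), 3))
    bc = list(combinations_with_replacement(range(n_bins), 3))
    counts = np.zeros(len(fc) * len(bc), dtype=int)

    def bin_of(d):
        for i, e in enumerate(edges):
            if d < e:
                return i
        return len(edges)

    for (ca, fa), (cb, fb), (cc, fcts) in combinations(anchors, 3):
        dists = sorted(bin_of(float(np.linalg.norm(x - y)))
                       for x, y in ((ca, cb), (ca, cc), (cb, cc)))
        b = bc.index(tuple(dists))
        for x in fa:
            for y in fb:
                for z in fcts:
                    f = fc.index(tuple(sorted((x, y, z))))
                    counts[f * len(bc) + b] += 1
    return counts


def test_four_residue_site_equals_brute_force_enumeration():
    residues = _site(FOUR_RES)
    fp = fuzcav_fingerprint(residues)
    edges = default_config().descriptors.fuzcav_bin_edges
    assert np.array_equal(fp.counts, _brute_force_counts(residues, edges))
    # conservation: total counts = sum over triples of feature multiplicity
    feats = residue_features()
    mult = {r.name: len(feats[r.name]) for r in residues}
    expected_total = sum(
        mult[a.name] * mult[b.name] * mult[c.name]
        for a, b, c in combinations(residues, 3))
    assert fp.counts.sum() == expected_total


def test_fingerprint_invariant_under_rigid_motion_and_order():
    residues = _site(FOUR_RES)
    fp1 = fuzcav_fingerprint(residues)
    rng = np.random.default_rng(2)
    rot, shift = random_rotation(rng), np.array([4.0, -1.0, 8.0])
    moved = _site([(n, i, tuple(rot @ np.array(x) + shift))
                   for n, i, x in FOUR_RES[::-1]])
    fp2 = fuzcav_fingerprint(moved)
    assert np.array_equal(fp1.counts, fp2.counts)


def test_small_sites_give_zero_vector_with_warning():
    with pytest.warns(UserWarning):
        fp = fuzcav_fingerprint(_site(FOUR_RES[:2]))
    assert not fp.counts.any()


def test_sidechain_representative_mode_uses_designated_atoms():
    residues = _site(FOUR_RES)
    anchors = site_anchors(residues, "side_chain_rep")
    # CA fallback when the representative atom is absent
    assert len(anchors) == 4
    with pytest.raises(ValueError):
        site_anchors(residues, "nope")


def test_similarity_metrics_bounds_and_identities():
    residues = _site(FOUR_RES)
    fp = fuzcav_fingerprint(residues)
    other = fuzcav_fingerprint(_site(
        [("GLY", 1, (0, 0, 0)), ("GLY", 2, (4, 0, 0)),
         ("GLY", 3, (0, 4, 0)), ("ALA", 4, (9, 9, 9))]))
    for metric in ("tanimoto", "normalized_shared", "local"):
        assert fuzcav_similarity(fp, fp, metric) == 1.0
        s = fuzcav_similarity(fp, other, metric)
        assert 0.0 <= s <= 1.0
        assert s == fuzcav_similarity(other, fp, metric)
    # tanimoto equals the hand-computed formula
    want = np.minimum(fp.counts, other.counts).sum() \
        / np.maximum(fp.counts, other.counts).sum()
    assert fuzcav_similarity(fp, other, "tanimoto") \
        == pytest.approx(float(want))
    with pytest.warns(UserWarning):
        from structprof.descriptors import FuzCavFingerprint

        z = FuzCavFingerprint(np.zeros_like(fp.counts), fp.mode)
        assert fuzcav_similarity(z, z) == 0.0


def test_disjoint_support_fingerprints_score_zero():
    from structprof.descriptors import FuzCavFingerprint

    a = FuzCavFingerprint(np.array([1, 0, 2, 0]), "calpha")
    b = FuzCavFingerprint(np.array([0, 3, 0, 1]), "calpha")
    for metric in ("tanimoto", "normalized_shared", "local"):
        assert fuzcav_similarity(a, b, metric) == 0.0


# ---------------------------------------------------------------------------
# eligibility filter
# ---------------------------------------------------------------------------

def _ligand_with_atoms(n):
    res = Residue(name="LIG", number=1)
    res.atoms = [Atom(serial=i, name=f"C{i}", element="C",
                      coords=np.array([float(i), 0.0, 0.0]), parent=res)
                 for i in range(1, n + 1)]
    from structprof.pathid import PathID

    return LigandEntity([res], PathID("XXXX", "0", "L", f"LIG`1"))


def test_heavy_atom_boundary_is_seven():
    assert not site_eligible(_ligand_with_atoms(6), [])
    assert site_eligible(_ligand_with_atoms(7), [])


def test_clashing_ligand_is_excluded():
    from structprof.contacts import Contact, ContactFlags

    lig = _ligand_with_atoms(12)
    other = _ligand_with_atoms(1)
    clash = Contact(lig.atoms()[0], other.atoms()[0], 0.8,
                    ContactFlags(clash=True))
    assert not site_eligible(lig, [clash])
    benign = Contact(lig.atoms()[0], other.atoms()[0], 3.5,
                     ContactFlags(vdw=True))
    assert site_eligible(lig, [benign])


# ---------------------------------------------------------------------------
# USRCAT
# ---------------------------------------------------------------------------

def test_moments_have_sixty_components_and_zero_blocks():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(15, 3)) * 4
    d = usrcat_moments(coords, {"donor": np.array([0, 1, 2])})
    assert d.moments.shape == (60,)
    assert d.moments[:12].any()            # all-atom block
    # subsets not provided are zero blocks
    block = dict(zip(("all", "hydrophobic", "aromatic", "donor",
                      "acceptor"), range(5)))
    aromatic = d.moments[block["aromatic"] * 12:(block["aromatic"] + 1) * 12]
    assert not aromatic.any()
    donor = d.moments[block["donor"] * 12:(block["donor"] + 1) * 12]
    assert donor.any()


def test_moments_match_brute_force_distance_statistics():
    rng = np.random.default_rng(7)
    coords = rng.normal(size=(10, 3)) * 5
    d = usrcat_moments(coords)
    ctd = coords.mean(axis=0)
    dist = np.linalg.norm(coords - ctd, axis=1)
    mean = dist.mean()
    sigma = math.sqrt(np.mean((dist - mean) ** 2))
    mu3 = np.mean((dist - mean) ** 3)
    assert d.moments[0] == pytest.approx(mean, rel=1e-12)
    assert d.moments[1] == pytest.approx(sigma, rel=1e-12)
    assert d.moments[2] == pytest.approx(np.cbrt(mu3), rel=1e-12)


def test_moments_invariant_under_rigid_motion():
    rng = np.random.default_rng(1)
    coords = rng.normal(size=(20, 3)) * 3
    subsets = {"hydrophobic": np.arange(5), "acceptor": np.arange(5, 9)}
    d1 = usrcat_moments(coords, subsets)
    rot = random_rotation(rng)
    d2 = usrcat_moments(coords @ rot.T + np.array([9.0, -2.0, 4.0]), subsets)
    assert np.max(np.abs(d1.moments - d2.moments)) < 1e-9


def test_centrosymmetric_set_has_zero_skewness():
    pts = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 2.0, 0], [0, -2.0, 0],
                    [0, 0, 3.0], [0, 0, -3.0]])
    d = usrcat_moments(pts)
    assert d.moments[2] == pytest.approx(0.0, abs=1e-12)   # ctd skew term


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        usrcat_moments(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    with pytest.raises(ValueError):
        usrcat_moments(np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))


def test_similarity_identity_symmetry_and_monotonicity():
    rng = np.random.default_rng(3)
    a = usrcat_moments(rng.normal(size=(12, 3)) * 4)
    b = usrcat_moments(rng.normal(size=(12, 3)) * 4)
    assert usrcat_similarity(a, a) == 1.0
    s = usrcat_similarity(a, b)
    assert 0.0 < s <= 1.0
    assert s == usrcat_similarity(b, a)
    # widening any coordinate gap strictly decreases the score
    from structprof.descriptors import USRCATDescriptor

    worse = USRCATDescriptor(b.moments.copy())
    worse.moments[5] += 1.0
    assert usrcat_similarity(a, worse) < s


def test_conformer_cap_limits_ensemble_to_25():
    rng = np.random.default_rng(4)
    conformers = [rng.normal(size=(8, 3)) * 3 for _ in range(40)]
    descriptors = usrcat_ensemble(conformers)
    assert len(descriptors) == default_config().descriptors.max_conformers


# ---------------------------------------------------------------------------
# SIFt matrices and clustering
# ---------------------------------------------------------------------------

MAPPING = {("A", i): 100 + i for i in range(1, 60)}


def test_single_ligand_two_hbond_residues_gives_two_ones():
    m = build_sift_matrix(
        {"lig1": {("A", 1): {"hbond"}, ("A", 2): {"hbond"}}}, MAPPING)
    row = m.row("lig1")
    assert row.sum() == 2
    assert m.data.loc["lig1", (101, "hbond")]
    assert m.data.loc["lig1", (102, "hbond")]


def test_alignment_makes_rows_numbering_independent():
    flags = {"hbond", "vdw"}
    m = build_sift_matrix(
        {"a": {("A", 10): flags}, "b": {("A", 25): flags}},
        {("A", 10): 500, ("A", 25): 500})
    assert np.array_equal(m.row("a"), m.row("b"))


def test_planted_shared_column_is_all_ones():
    rng = np.random.default_rng(0)
    lf = {}
    for k in range(6):
        picks = rng.choice(np.arange(2, 30), size=4, replace=False)
        flags = {("A", int(p)): {"hydrophobic"} for p in picks}
        flags[("A", 1)] = {"hbond"}           # the plant
        lf[f"lig{k}"] = flags
    m = build_sift_matrix(lf, MAPPING)
    assert m.data[(101, "hbond")].all()


def test_unmapped_residues_dropped_with_warning():
    with pytest.warns(UserWarning, match="no reference mapping"):
        m = build_sift_matrix({"a": {("A", 1): {"hbond"},
                                     ("Z", 99): {"ionic"}}}, MAPPING)
    assert m.row("a").sum() == 1


def test_conflicting_mapping_raises():
    with pytest.raises(MappingError):
        build_sift_matrix(
            {"a": {("A", 1): {"hbond"}, ("A", 2): {"hbond"}}},
            {("A", 1): 7, ("A", 2): 7})


def test_unknown_flag_name_rejected():
    with pytest.raises(ValueError):
        build_sift_matrix({"a": {("A", 1): {"zap"}}}, MAPPING)


def _planted_two_blocks(seed, n_per_block=10):
    rng = np.random.default_rng(seed)
    lf = {}
    for k in range(n_per_block):
        picks = rng.choice(np.arange(1, 16), size=5, replace=False)
        lf[f"g1_{k}"] = {("A", int(p)): {"hbond"} for p in picks}
        lf[f"g1_{k}"][("A", 1)] = {"hbond"}
    for k in range(n_per_block):
        picks = rng.choice(np.arange(30, 45), size=5, replace=False)
        lf[f"g2_{k}"] = {("A", int(p)): {"hydrophobic"} for p in picks}
        lf[f"g2_{k}"][("A", 30)] = {"hydrophobic"}
    return build_sift_matrix(lf, {("A", i): i for i in range(1, 60)})


def test_top_split_recovers_planted_blocks():
    tree = cluster_sifts(_planted_two_blocks(11))
    g1, g2 = tree.top_split()
    prefixes = ({l.split("_")[0] for l in g1},
                {l.split("_")[0] for l in g2})
    assert set(map(frozenset, prefixes)) \
        == {frozenset({"g1"}), frozenset({"g2"})}


def test_identical_rows_merge_at_height_zero_and_twin_neighbour():
    lf = {"a": {("A", 1): {"hbond"}}, "b": {("A", 1): {"hbond"}},
          "c": {("A", 9): {"ionic"}}}
    tree = cluster_sifts(build_sift_matrix(lf, MAPPING))
    assert tree.linkage[0, 2] == 0.0
    assert tree.neighbour("a") == "b"
    assert tree.neighbour("b") == "a"


def test_merge_heights_are_monotone_nondecreasing():
    tree = cluster_sifts(_planted_two_blocks(5))
    heights = tree.heights()
    assert np.all(np.diff(heights) >= -1e-12)


def test_newick_export_contains_all_leaves():
    tree = cluster_sifts(_planted_two_blocks(2, n_per_block=3))
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for leaf in tree.leaf_ids:
        assert leaf in nwk


def test_single_row_cannot_be_clustered():
    m = build_sift_matrix({"a": {("A", 1): {"hbond"}}}, MAPPING)
    with pytest.raises(ValueError):
        cluster_sifts(m)
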