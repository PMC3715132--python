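"""Deterministic synthetic-structure generator with known ground truth.

Every generator emits legal single-model PDB text plus a machine-readable
:class:`GroundTruth` describing what was planted (ring geometry class,
expected contact flags, entity-pair census, missing regions, ...).  The
ground truth is declared from the generator's own constants — it is never
computed by running the profiling pipeline, so closed-loop tests compare
two independent routes.  Same parameters + seed give byte-identical
output.  Geometry is idealized, not physically relaxed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .templates import Bond, ComponentTemplate, TemplateStore

# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    kind: str
    data: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, **self.data}, indent=2,
                          sort_keys=True)

    def __getitem__(self, key):
        return self.data[key]


# ---------------------------------------------------------------------------
# probe-molecule templates (heavy atoms in coordinates, H only in templates)
# ---------------------------------------------------------------------------

def _benzene_template(het: str, prefix: str = "C") -> ComponentTemplate:
    atoms = {}
    bonds = []
    for i in range(1, 7):
        atoms[f"{prefix}{i}"] = "C"
        atoms[f"H{i}"] = "H"
        bonds.append(Bond(f"{prefix}{i}", f"H{i}"))
    for i in range(1, 7):
        j = i % 6 + 1
        bonds.append(Bond(f"{prefix}{i}", f"{prefix}{j}",
                          order=2 if i % 2 else 1, aromatic=True))
    return ComponentTemplate(het, atoms, bonds)


def fixture_templates() -> TemplateStore:
    """Template store seeded with the probe components used by fixtures."""
    store = TemplateStore(use_ccd=True)
    store.register(_benzene_template("BNZ"))
    # methylamine: N1 is a hydrogen-bond donor, aliphatic amine
    store.register(ComponentTemplate(
        "DNR",
        {"C1": "C", "N1": "N", "H1": "H", "H2": "H",
         "H11": "H", "H12": "H", "H13": "H"},
        [Bond("C1", "N1"), Bond("N1", "H1"), Bond("N1", "H2"),
         Bond("C1", "H11"), Bond("C1", "H12"), Bond("C1", "H13")]))
    # acetone: O1 acceptor + carbonyl group
    store.register(ComponentTemplate(
        "ACP",
        {"C1": "C", "O1": "O", "C2": "C", "C3": "C",
         "H21": "H", "H31": "H"},
        [Bond("C1", "O1", order=2), Bond("C1", "C2"), Bond("C1", "C3"),
         Bond("C2", "H21"), Bond("C3", "H31")]))
    # chlorobenzene: CL1 is a halogen-bond donor
    clb = _benzene_template("CLB")
    clb.atoms.pop("H1")
    clb.bonds = [b for b in clb.bonds if "H1" not in (b.a, b.b)]
    clb.atoms["CL1"] = "CL"
    clb.bonds.append(Bond("C1", "CL1"))
    store.register(ComponentTemplate("CLB", clb.atoms, clb.bonds))
    # chloromethane: minimal C-Cl probe
    store.register(ComponentTemplate(
        "CLM", {"C1": "C", "CL1": "CL", "H1": "H"},
        [Bond("C1", "CL1"), Bond("C1", "H1")]))
    # methane: weak (carbon) donor, hydrophobe
    store.register(ComponentTemplate(
        "MTH", {"C1": "C", "H1": "H", "H2": "H", "H3": "H", "H4": "H"},
        [Bond("C1", "H1"), Bond("C1", "H2"), Bond("C1", "H3"),
         Bond("C1", "H4")]))
    # ammonium cation
    store.register(ComponentTemplate(
        "AMM", {"N1": "N", "H1": "H", "H2": "H", "H3": "H", "H4": "H"},
        [Bond("N1", "H1"), Bond("N1", "H2"), Bond("N1", "H3"),
         Bond("N1", "H4")], charges={"N1": 1}))
    # benzamide-like ligand: aromatic ring + amide
    lg1 = _benzene_template("LG1")
    lg1.atoms.pop("H1")
    lg1.bonds = [b for b in lg1.bonds if "H1" not in (b.a, b.b)]
    lg1.atoms.update({"C7": "C", "O1": "O", "N1": "N",
                      "HN1": "H", "HN2": "H"})
    lg1.bonds += [Bond("C1", "C7"), Bond("C7", "O1", order=2),
                  Bond("C7", "N1"), Bond("N1", "HN1"), Bond("N1", "HN2")]
    store.register(ComponentTemplate("LG1", lg1.atoms, lg1.bonds))
    return store


# ---------------------------------------------------------------------------
# PDB text assembly
# ---------------------------------------------------------------------------

def _pdb_line(record: str, serial: int, name: str, resname: str,
              chain: str, resnum: int, xyz, occ: float = 1.0,
              b: float = 0.0, element: str | None = None) -> str:
    el = (element or name[0]).upper()
    if len(el) == 1 and len(name) < 4:
        field_name = f" {name:<3}"
    else:
        field_name = f"{name:<4}"
    x, y, z = xyz
    return (f"{record:<6}{serial:>5} {field_name} {resname:>3} {chain:1}"
            f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {el:>2}")


class _PDBBuilder:
    def __init__(self, pdb_id: str = "9FIX") -> None:
        self.lines = [f"HEADER    {'SYNTHETIC FIXTURE':<40}"
                      f"{'01-JAN-00':<9}   {pdb_id:>4}"]
        self.serial = 0

    def remark(self, text: str) -> None:
        self.lines.append(f"REMARK 999 {text}")

    def seqres(self, chain: str, resnames: list[str]) -> None:
        for i in range(0, len(resnames), 13):
            chunk = resnames[i:i + 13]
            self.lines.append(
                f"SEQRES {i // 13 + 1:>3} {chain:1} {len(resnames):>4}  "
                + " ".join(f"{r:>3}" for r in chunk))

    def atom(self, record: str, name: str, resname: str, chain: str,
             resnum: int, xyz, element: str | None = None,
             b: float = 0.0) -> None:
        self.serial += 1
        self.lines.append(_pdb_line(record, self.serial, name, resname,
                                    chain, resnum, xyz, b=b,
                                    element=element))

    def ter(self) -> None:
        self.lines.append("TER")

    def text(self) -> str:
        return "\n".join(self.lines + ["END"]) + "\n"


def _hexagon(center: np.ndarray, normal: np.ndarray, radius: float = 1.39,
             phase: float = 0.0) -> np.ndarray:
    """Six ring vertices around ``center`` in the plane normal to ``normal``."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    angles = phase + np.arange(6) * (math.pi / 3)
    return np.array([center + radius * (math.cos(a) * u + math.sin(a) * v)
                     for a in angles])


# fixture-local constants for declaring expected contact flags; these
# duplicate the documented defaults on purpose so that the declaration is
# independent of the contact engine
_FIX_VDW = {"C": 1.70, "N": 1.50, "O": 1.40, "CL": 1.75}
_FIX_COV = {"C": 0.73, "N": 0.71, "O": 0.63, "CL": 0.99}

_RING_TABLE = (("FF", "OF", "EE"), ("FT", "OT", "ET"), ("FE", "OE", "EF"))


def _declared_distance_flag(el_a: str, el_b: str, d: float) -> str | None:
    rcov = _FIX_COV[el_a] + _FIX_COV[el_b]
    rvdw = _FIX_VDW[el_a] + _FIX_VDW[el_b]
    if d < rcov - 0.4:
        return "clash"
    if d < rcov + 0.1:
        return "covalent"
    if d < rvdw - 0.1:
        return "vdw_clash"
    if d <= rvdw + 0.1:
        return "vdw"
    if d <= 6.0:
        return "proximal"
    return None


# ---------------------------------------------------------------------------
# ring pair
# ---------------------------------------------------------------------------

def make_ring_pair(distance: float = 3.5, dihedral: float = 0.0,
                   theta: float = 0.0,
                   seed: int = 0) -> tuple[str, GroundTruth]:
    """Two benzene rings posed at the requested centroid distance,
    inter-plane dihedral and theta (first ring's normal vs the centroid-
    centroid vector), all in degrees/Å.
    """
    if distance <= 0.5:
        raise ValueError("unrealizable ring separation")
    if not (0 <= dihedral <= 90 and 0 <= theta <= 90):
        raise ValueError("angles must lie in [0, 90]")
    t, dih = math.radians(theta), math.radians(dihedral)
    center_a = np.zeros(3)
    normal_a = np.array([0.0, 0.0, 1.0])
    center_b = center_a + distance * np.array(
        [math.sin(t), 0.0, math.cos(t)])
    normal_b = np.array([math.sin(dih), 0.0, math.cos(dih)])

    b = _PDBBuilder()
    b.remark(f"ring pair d={distance:.2f} dihedral={dihedral:.1f} "
             f"theta={theta:.1f} seed={seed}")
    for k, (c, n) in enumerate(((center_a, normal_a),
                                (center_b, normal_b)), start=1):
        for i, xyz in enumerate(_hexagon(c, n), start=1):
            b.atom("HETATM", f"C{i}", "BNZ", "X", k, xyz, element="C")
    label = _RING_TABLE[min(int(dihedral // 30), 2)][min(int(theta // 30), 2)]
    gt = GroundTruth("ring_pair", {
        "distance": distance, "dihedral": dihedral, "theta": theta,
        "class_label": label,
        "recorded": distance <= 6.0,
    })
    return b.text(), gt


def make_halogen_probe(distance: float = 3.5, theta: float = 0.0,
                       seed: int = 0) -> tuple[str, GroundTruth]:
    """Chloromethane Cl posed over a benzene ring at (distance, theta)."""
    t = math.radians(theta)
    b = _PDBBuilder()
    b.remark(f"halogen probe d={distance:.2f} theta={theta:.1f} seed={seed}")
    for i, xyz in enumerate(_hexagon(np.zeros(3), [0, 0, 1]), start=1):
        b.atom("HETATM", f"C{i}", "BNZ", "X", 1, xyz, element="C")
    direction = np.array([math.sin(t), 0.0, math.cos(t)])
    cl = distance * direction
    c = cl + 1.78 * direction   # C further out along the same axis
    b.atom("HETATM", "C1", "CLM", "X", 2, c, element="C")
    b.atom("HETATM", "CL1", "CLM", "X", 2, cl, element="CL")
    gt = GroundTruth("halogen_probe", {
        "distance": distance, "theta": theta,
        "recorded": distance <= 4.5 and theta <= 30.0,
        "label": "halogen_pi",
    })
    return b.text(), gt


# ---------------------------------------------------------------------------
# contact pair
# ---------------------------------------------------------------------------

_PROBES = {
    # type -> (het id, probe atom, neighbour atom or None, bond length)
    "donor": ("DNR", "N1", "C1", 1.47),
    "acceptor": ("ACP", "O1", "C1", 1.23),
    "halogen": ("CLB", "CL1", "C1", 1.74),
    "carbon": ("MTH", "C1", None, 0.0),
    "cation": ("AMM", "N1", None, 0.0),
    "apolar": ("MTH", "C1", None, 0.0),
    "carbonyl": ("ACP", "C1", "O1", 1.23),
}

_PROBE_ELEMENT = {"N1": "N", "O1": "O", "CL1": "CL", "C1": "C"}


def _declared_feature_flags(type_a: str, type_b: str, d: float,
                            angle: float) -> set[str]:
    pair = {type_a, type_b}
    flags: set[str] = set()
    if pair == {"donor", "acceptor"} and d <= 3.5 and angle >= 90:
        flags.add("hbond")
    if pair == {"halogen", "acceptor"}:
        if d <= _FIX_VDW["CL"] + _FIX_VDW["O"] + 0.1 and angle >= 120:
            flags.add("halogen_bond")
    if pair == {"carbon", "acceptor"} and d <= 3.6:
        flags.add("weak_hbond")
    if pair == {"carbonyl", "acceptor"} and d <= 3.6:
        flags.add("carbonyl")   # probe C of one C=O vs carbonyl O of another
    if pair == {"cation", "acceptor"} and d <= 3.5:
        flags.add("hbond")   # ammonium N-H donates
    if pair <= {"carbon", "apolar", "halogen"} and d <= 4.5:
        flags.add("hydrophobic")
    return flags


def make_contact_pair(type_a: str = "donor", type_b: str = "acceptor",
                      distance: float = 2.9, angle: float = 150.0,
                      seed: int = 0) -> tuple[str, GroundTruth]:
    """Two probe molecules with their probe atoms at the requested
    separation; ``angle`` is the neighbour-probe-partner angle at probe A
    (degrees).  Ground truth declares the expected flag set for the probe
    atom pair under default cutoffs.
    """
    for t in (type_a, type_b):
        if t not in _PROBES:
            raise ValueError(f"unknown probe type: {t}")
    het_a, pa, na, bond_a = _PROBES[type_a]
    het_b, pb, nb, bond_b = _PROBES[type_b]
    pos_a = np.zeros(3)
    pos_b = np.array([distance, 0.0, 0.0])

    b = _PDBBuilder()
    b.remark(f"contact pair {type_a}/{type_b} d={distance:.2f} "
             f"angle={angle:.1f} seed={seed}")

    def place(het, probe_name, nbr_name, bond_len, origin, towards,
              resnum, theta_deg):
        coords = {probe_name: origin}
        if nbr_name:
            th = math.radians(theta_deg)
            u = np.array([math.cos(th), math.sin(th), 0.0])
            if towards[0] < origin[0]:
                u = np.array([-math.cos(th), math.sin(th), 0.0])
            coords[nbr_name] = origin + bond_len * u
        if het == "CLB":   # complete the ring behind the C-Cl axis
            axis = (coords["C1"] - origin)
            axis /= np.linalg.norm(axis)
            center = coords["C1"] + 1.39 * axis
            ring = _hexagon(center, np.array([0.0, 0.0, 1.0]),
                            phase=math.atan2(-axis[1], -axis[0]))
            for i, xyz in enumerate(ring, start=1):
                coords[f"C{i}"] = xyz
            coords["C1"] = coords["C1"]  # keep exact attachment point
        # ACP methyls stay unplaced on purpose: typing is template-based
        # and extra atoms could stray into the probe axis
        for name, xyz in coords.items():
            b.atom("HETATM", name, het, "L", resnum, xyz,
                   element="CL" if name.startswith("CL") else name[0])

    place(het_a, pa, na, bond_a, pos_a, pos_b, 1, angle)
    place(het_b, pb, nb, bond_b, pos_b, pos_a, 2, 180.0)

    expected = set()
    dist_flag = _declared_distance_flag(_PROBE_ELEMENT[pa],
                                        _PROBE_ELEMENT[pb], distance)
    stored = dist_flag is not None
    if stored:
        expected.add(dist_flag)
        expected |= _declared_feature_flags(type_a, type_b, distance, angle)
    gt = GroundTruth("contact_pair", {
        "probe_a": ["L", 1, pa], "probe_b": ["L", 2, pb],
        "distance": distance, "angle": angle,
        "stored": stored, "expected_flags": sorted(expected),
    })
    return b.text(), gt


# ---------------------------------------------------------------------------
# polypeptide helpers
# ---------------------------------------------------------------------------

def _ala_residue(base: np.ndarray, flip: bool = False) -> dict[str, np.ndarray]:
    s = -1.0 if flip else 1.0
    return {
        "N": base + np.array([-1.2, s * 0.5, 0.0]),
        "CA": base.copy(),
        "C": base + np.array([1.2, s * 0.4, 0.0]),
        "O": base + np.array([1.4, s * 1.6, 0.0]),
        "CB": base + np.array([0.0, -s * 1.5, 0.0]),
    }


def _write_ala_chain(b: _PDBBuilder, chain: str, n_res: int,
                     origin: np.ndarray, flip: bool = False,
                     start_num: int = 1, skip: set[int] = frozenset(),
                     truncate: set[int] = frozenset()) -> None:
    for i in range(n_res):
        num = start_num + i
        if num in skip:
            continue
        res = _ala_residue(origin + np.array([3.8 * i, 0.0, 0.0]), flip)
        for name in ("N", "CA", "C", "O", "CB"):
            if name == "CB" and num in truncate:
                continue
            res_name = "ALA"
            b.atom("ATOM", name, res_name, chain, num, res[name],
                   element=name[0])
    b.ter()


# ---------------------------------------------------------------------------
# toy complex
# ---------------------------------------------------------------------------

def make_toy_complex(seed: int = 7) -> tuple[str, GroundTruth]:
    """Two-chain poly-ALA protein + benzamide ligand + stacked benzene.

    Planted interactions: an N-H...O=C hydrogen bond between the
    benzamide amide nitrogen and a chain-A backbone carbonyl; a
    face-to-face aromatic stack between the two ligand rings
    (ligand-ligand); CB...CB hydrophobic contacts across the A/B
    interface.  Chains are 12 residues long so they stay polymers, the
    two ligands touch each other but chain B touches neither ligand.
    """
    rng = np.random.default_rng(seed)
    b = _PDBBuilder()
    b.remark(f"toy complex seed={seed}")
    n_res = 12
    b.seqres("A", ["ALA"] * n_res)
    b.seqres("B", ["ALA"] * n_res)
    _write_ala_chain(b, "A", n_res, np.zeros(3))
    _write_ala_chain(b, "B", n_res, np.array([0.0, -7.0, 0.0]), flip=True)
    n_protein_atoms = 2 * n_res * 5

    # benzamide LG1 in a plane above chain A, amide N over residue 4's O
    o4 = np.array([3.8 * 3 + 1.4, 1.6, 0.0])      # chain A res 4 backbone O
    n1 = o4 + np.array([0.0, 1.45, 2.512])         # |.| = 2.9 -> hbond
    c7 = n1 + np.array([0.0, 1.35, 0.0])
    o1 = c7 + np.array([-1.065, 0.615, 0.0])
    c1 = c7 + np.array([0.74, 1.281, 0.0])
    ring_dir = np.array([0.5, 0.866, 0.0])
    ring_center = c1 + 1.39 * ring_dir
    ring = _hexagon(ring_center, np.array([0.0, 0.0, 1.0]),
                    phase=math.atan2(-ring_dir[1], -ring_dir[0]))
    lg1 = {"C7": c7, "O1": o1, "N1": n1}
    for i, xyz in enumerate(ring, start=1):
        lg1[f"C{i}"] = xyz
    lg1["C1"] = c1
    for name in ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "O1", "N1"):
        b.atom("HETATM", name, "LG1", "C", 201, lg1[name],
               element=name[0] if not name.startswith("O") else "O")
    b.ter()

    # benzene LG2 stacked face-to-face on the LG1 ring
    lg2_center = ring_center + np.array([0.0, 0.0, 3.6])
    for i, xyz in enumerate(_hexagon(lg2_center, [0, 0, 1],
                                     phase=math.pi / 6), start=1):
        b.atom("HETATM", f"C{i}", "BNZ", "D", 301, xyz, element="C")
    b.ter()

    # two waters, far from everything interesting
    for k in range(2):
        w = np.array([-8.0 - 4.0 * k, 8.0, 4.0]) + rng.normal(0, 0.2, 3)
        b.atom("HETATM", "O", "HOH", "W", 401 + k, w, element="O")
    b.ter()

    gt = GroundTruth("toy_complex", {
        "seed": seed,
        "n_atoms": n_protein_atoms + 9 + 6 + 2,
        "n_chains": 5,
        "n_ligands": 2,
        "ligand_het_ids": ["BNZ", "LG1"],
        "entity_pairs": sorted([
            ["A", "C/LG1", "binding_site"],
            ["A", "B", "interface"],
            ["C/LG1", "D/BNZ", "ligand_ligand"],
        ]),
        "planted_contacts": [
            {"a": ["A", 4, "O"], "b": ["C", 201, "N1"],
             "flags": ["hbond"]},
            {"a": ["C", 201, "C3"], "b": ["D", 301, "C1"],
             "flags": ["aromatic"]},
            {"a": ["A", 1, "CB"], "b": ["B", 1, "CB"],
             "flags": ["hydrophobic"]},
        ],
        "lg1_recap_leaves": 2,
        "ring_stack_class": "FF",
    })
    return b.text(), gt


def make_cofactor_complex(seed: int = 0) -> tuple[str, GroundTruth]:
    """Protein + cofactor ring + drug ring, the drug touching both.

    Emulates inhibition through ligand-ligand interactions (a drug
    stacking on an enzyme cofactor): expected census is two binding
    sites and one ligand-ligand interaction.
    """
    b = _PDBBuilder()
    b.remark(f"cofactor complex seed={seed}")
    n_res = 12
    b.seqres("A", ["ALA"] * n_res)
    _write_ala_chain(b, "A", n_res, np.zeros(3))
    cof_center = np.array([13.0, 1.0, 2.8])
    for i, xyz in enumerate(_hexagon(cof_center, [0, 0, 1]), start=1):
        b.atom("HETATM", f"C{i}", "BNZ", "C", 201, xyz, element="C")
    b.ter()
    # offset stack: close enough for an aromatic ring-ring contact with
    # the cofactor while still reaching the protein surface
    drug_center = cof_center + np.array([2.2, 0.0, 3.1])
    for i, xyz in enumerate(_hexagon(drug_center, [0, 0, 1],
                                     phase=math.pi / 6), start=1):
        b.atom("HETATM", f"C{i}", "BNZ", "D", 301, xyz, element="C")
    b.ter()
    gt = GroundTruth("cofactor_complex", {
        "census": {"binding_site": 2, "ligand_ligand": 1},
    })
    return b.text(), gt


# ---------------------------------------------------------------------------
# gapped chain
# ---------------------------------------------------------------------------

def make_gapped_chain(first: int = 1, last: int = 20,
                      gaps: tuple[tuple[int, int], ...] = ((11, 14),),
                      seqres_length: int = 20,
                      seed: int = 0) -> tuple[str, GroundTruth]:
    """Poly-ALA chain with planted numbering gaps and a SEQRES reference."""
    skip = {n for lo, hi in gaps for n in range(lo, hi + 1)}
    b = _PDBBuilder()
    b.remark(f"gapped chain {first}-{last} gaps={gaps} seed={seed}")
    b.seqres("A", ["ALA"] * seqres_length)
    _write_ala_chain(b, "A", last - first + 1, np.zeros(3),
                     start_num=first, skip=skip)
    observed = [n for n in range(first, last + 1) if n not in skip]
    regions = []
    if first > 1:
        regions.append({"start": 1, "end": first - 1, "terminal": True,
                        "flanking": [None, first]})
    for lo, hi in gaps:
        regions.append({"start": lo, "end": hi, "terminal": False,
                        "flanking": [lo - 1, hi + 1]})
    if last < seqres_length:
        regions.append({"start": last + 1, "end": seqres_length,
                        "terminal": True, "flanking": [last, None]})
    gt = GroundTruth("gapped_chain", {
        "observed": observed, "regions": regions,
        "seqres_length": seqres_length,
    })
    return b.text(), gt


# ---------------------------------------------------------------------------
# structure-factor metadata
# ---------------------------------------------------------------------------

def make_sf_meta(seed: int = 0) -> tuple[str, GroundTruth]:
    """Plausible refinement statistics as a sidecar TSV."""
    rng = np.random.default_rng(seed)
    d_min = round(float(rng.uniform(1.4, 2.8)), 2)
    r_factor = round(float(rng.uniform(0.16, 0.23)), 3)
    r_free = round(r_factor + float(rng.uniform(0.02, 0.05)), 3)
    completeness = round(float(rng.uniform(0.90, 0.999)), 3)
    n_atoms = int(rng.integers(1500, 6000))
    # about one heavy atom per 20 Å³ with a full sphere to d_min
    n_reflections = int(n_atoms * 20.0 / d_min ** 3 * completeness)
    fields = {
        "r_factor": r_factor, "r_free": r_free, "d_min": d_min,
        "completeness": completeness, "n_atoms": n_atoms,
        "n_reflections": n_reflections,
    }
    tsv = "\n".join(f"{k}\t{v}" for k, v in fields.items()) + "\n"
    return tsv, GroundTruth("sf_meta", dict(fields))


GENERATORS = {
    "ring_pair": make_ring_pair,
    "halogen_probe": make_halogen_probe,
    "contact_pair": make_contact_pair,
    "toy_complex": make_toy_complex,
    "cofactor_complex": make_cofactor_complex,
    "gapped_chain": make_gapped_chain,
    "sf_meta": make_sf_meta,
}
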