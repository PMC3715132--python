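"""Pairwise atomic contact detection and SIFt classification.

Every stored heavy-atom pair within the proximal cutoff (6.0 Å default)
is encoded as a 13-flag structural interaction fingerprint: five mutually
exclusive distance bins (clash, covalent, vdw_clash, vdw, proximal — the
first satisfied bin wins) and eight feature flags (hbond, weak_hbond,
halogen_bond, ionic, metal_complex, aromatic, hydrophobic, carbonyl) with
atom-type, distance and angle constraints.  Same-residue pairs and 1-2 /
1-3 bonded pairs are excluded everywhere.  Contacts are grouped into typed
entity-pair interactions: binding sites (polypeptide-ligand), interfaces
(polypeptide-polypeptide), grooves (polypeptide-oligonucleotide),
ligand-ligand and ligand-nucleic interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemtypes import (AromaticRing, AtomTypeFlags, LigandEntity,
                        assign_atom_types, perceive_aromatic_rings,
                        perceive_ligands)
from .config import (ProfilerConfig, covalent_radius, default_config,
                     vdw_radius)
from .model import Assembly, Atom, Chain, Residue
from .templates import TemplateStore

DISTANCE_FLAGS = ("clash", "covalent", "vdw_clash", "vdw", "proximal")
FEATURE_FLAGS = ("hbond", "weak_hbond", "halogen_bond", "ionic",
                 "metal_complex", "aromatic", "hydrophobic", "carbonyl")
FLAG_ORDER = DISTANCE_FLAGS + FEATURE_FLAGS


@dataclass
class ContactFlags:
    clash: bool = False
    covalent: bool = False
    vdw_clash: bool = False
    vdw: bool = False
    proximal: bool = False
    hbond: bool = False
    weak_hbond: bool = False
    halogen_bond: bool = False
    ionic: bool = False
    metal_complex: bool = False
    aromatic: bool = False
    hydrophobic: bool = False
    carbonyl: bool = False

    def bits(self) -> tuple[int, ...]:
        return tuple(int(getattr(self, f)) for f in FLAG_ORDER)

    def any_feature(self) -> bool:
        return any(getattr(self, f) for f in FEATURE_FLAGS)

    def set_features(self) -> set[str]:
        return {f for f in FLAG_ORDER if getattr(self, f)}


@dataclass(eq=False)
class Contact:
    atom_a: Atom
    atom_b: Atom
    distance: float
    flags: ContactFlags
    is_intramolecular: bool = False
    pair_class: str = "other"


PAIR_CLASS_MATRIX = {
    frozenset(["polypeptide", "ligand"]): "binding_site",
    frozenset(["polypeptide"]): "interface",
    frozenset(["polypeptide", "oligonucleotide"]): "groove",
    frozenset(["ligand"]): "ligand_ligand",
    frozenset(["ligand", "oligonucleotide"]): "ligand_nucleic",
}


# ---------------------------------------------------------------------------
# bond graph (1-2/1-3 exclusions, donor-angle neighbours)
# ---------------------------------------------------------------------------

class BondGraph:
    """Heavy-atom covalent adjacency from templates + inter-residue links."""

    def __init__(self) -> None:
        self._nbrs: dict[int, set[int]] = {}
        self._atoms: dict[int, Atom] = {}

    def add_bond(self, a: Atom, b: Atom) -> None:
        self._atoms[id(a)] = a
        self._atoms[id(b)] = b
        self._nbrs.setdefault(id(a), set()).add(id(b))
        self._nbrs.setdefault(id(b), set()).add(id(a))

    def neighbors(self, a: Atom) -> list[Atom]:
        return [self._atoms[i] for i in self._nbrs.get(id(a), ())]

    def bonded_or_13(self, a: Atom, b: Atom) -> bool:
        na = self._nbrs.get(id(a), set())
        if id(b) in na:
            return True
        nb = self._nbrs.get(id(b), set())
        return bool(na & nb)


def build_bond_graph(assembly: Assembly, store: TemplateStore,
                     config: ProfilerConfig | None = None) -> BondGraph:
    cfg = config or default_config()
    g = BondGraph()
    residues = list(assembly.iter_residues())
    for res in residues:
        tmpl = store.get_or_none(res.name)
        atoms = {a.name: a for a in res.atoms}
        if tmpl is not None:
            for b in tmpl.bonds:
                if b.a in atoms and b.b in atoms:
                    g.add_bond(atoms[b.a], atoms[b.b])
    # inter-residue covalent inference (peptide/glycosidic/covalent ligands)
    all_atoms = [a for r in residues for a in r.atoms]
    if len(all_atoms) >= 2:
        from scipy.spatial import cKDTree

        coords = np.array([a.coords for a in all_atoms])
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(cfg.ligands.bond_cutoff_sp):
            a, b = all_atoms[i], all_atoms[j]
            if a.parent is b.parent:
                continue
            cut = cfg.ligands.bond_cutoff
            if a.element in ("S", "P") or b.element in ("S", "P"):
                cut = cfg.ligands.bond_cutoff_sp
            if np.linalg.norm(a.coords - b.coords) < cut:
                g.add_bond(a, b)
    return g


# ---------------------------------------------------------------------------
# neighbour search
# ---------------------------------------------------------------------------

def neighbor_pairs(assembly: Assembly, cutoff: float,
                   ) -> list[tuple[Atom, Atom, float]]:
    """All unordered heavy-atom pairs with distance <= cutoff, once each."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    from scipy.spatial import cKDTree

    atoms = list(assembly.iter_atoms())
    if len(atoms) < 2:
        return []
    coords = np.array([a.coords for a in atoms])
    tree = cKDTree(coords)
    out = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        out.append((atoms[i], atoms[j], d))
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ContactContext:
    """Geometry context needed beyond the two endpoints."""

    bond_graph: BondGraph
    rings_by_atom: dict[int, list[AromaticRing]] = field(default_factory=dict)

    @classmethod
    def build(cls, assembly: Assembly, store: TemplateStore,
              rings: list[AromaticRing] | None = None,
              config: ProfilerConfig | None = None) -> "ContactContext":
        rings = rings if rings is not None else perceive_aromatic_rings(
            assembly, store, config)
        by_atom: dict[int, list[AromaticRing]] = {}
        for ring in rings:
            for a in ring.atoms:
                by_atom.setdefault(id(a), []).append(ring)
        return cls(build_bond_graph(assembly, store, config), by_atom)


def _angle(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    v1 = p1 - vertex
    v2 = p2 - vertex
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _donor_angle_ok(donor: Atom, acceptor: Atom, ctx: ContactContext,
                    min_angle: float) -> bool:
    nbrs = [n for n in ctx.bond_graph.neighbors(donor) if n is not acceptor]
    if not nbrs:
        return True   # isolated donor (e.g. ammonium, water oxygen)
    return all(_angle(n.coords, donor.coords, acceptor.coords) >= min_angle
               for n in nbrs)


def classify_contact(a: Atom, b: Atom, distance: float,
                     ctx: ContactContext,
                     config: ProfilerConfig | None = None) -> ContactFlags:
    """13-flag SIFt for one atom pair (both atoms must carry type flags)."""
    cfg = config or default_config()
    fa: AtomTypeFlags | None = getattr(a, "flags", None)
    fb: AtomTypeFlags | None = getattr(b, "flags", None)
    if fa is None or fb is None:
        raise ValueError("atoms must be typed before contact classification")
    flags = ContactFlags()
    dist = cfg.distance
    rcov = covalent_radius(a.element) + covalent_radius(b.element)
    rvdw = vdw_radius(a.element) + vdw_radius(b.element)

    # mutually exclusive distance bins, most specific first
    if distance < rcov + dist.clash_offset:
        flags.clash = True
    elif distance < rcov + dist.covalent_offset:
        flags.covalent = True
    elif distance < rvdw + dist.vdw_clash_offset:
        flags.vdw_clash = True
    elif distance <= rvdw + dist.vdw_offset:
        flags.vdw = True
    elif distance <= dist.proximal:
        flags.proximal = True

    feat = cfg.features
    # hydrogen bond (either direction), donor angle over bonded neighbours
    if distance <= feat.hbond:
        for d_atom, d_fl, a_fl in ((a, fa, fb), (b, fb, fa)):
            other = b if d_atom is a else a
            if (d_fl.hbond_donor and a_fl.hbond_acceptor
                    and _donor_angle_ok(d_atom, other, ctx,
                                        feat.hbond_min_donor_angle)):
                flags.hbond = True
    # weak (carbon-donor) hydrogen bond
    if distance <= feat.weak_hbond and not flags.hbond:
        for d_fl, a_fl in ((fa, fb), (fb, fa)):
            if d_fl.weak_donor and a_fl.hbond_acceptor:
                flags.weak_hbond = True
    # halogen bond: C-X...A sigma-hole geometry
    if distance <= rvdw + feat.halogen_tolerance:
        for x_atom, x_fl, a_fl in ((a, fa, fb), (b, fb, fa)):
            other = b if x_atom is a else a
            if not (x_fl.halogen_donor and a_fl.hbond_acceptor):
                continue
            carbons = [n for n in ctx.bond_graph.neighbors(x_atom)
                       if n.element == "C"]
            if not carbons or any(
                    _angle(c.coords, x_atom.coords, other.coords)
                    >= feat.halogen_min_angle for c in carbons):
                flags.halogen_bond = True
    if distance <= feat.ionic and (
            (fa.pos_ionisable and fb.neg_ionisable)
            or (fa.neg_ionisable and fb.pos_ionisable)):
        flags.ionic = True
    if distance <= feat.metal and (
            (fa.metal and b.element in ("N", "O", "S"))
            or (fb.metal and a.element in ("N", "O", "S"))):
        flags.metal_complex = True
    # aromatic: both atoms belong to rings whose centroids are close
    if fa.aromatic and fb.aromatic:
        for ra in ctx.rings_by_atom.get(id(a), ()):
            for rb in ctx.rings_by_atom.get(id(b), ()):
                if ra is rb:
                    continue
                if (np.linalg.norm(ra.centroid - rb.centroid)
                        <= feat.aromatic_centroid):
                    flags.aromatic = True
    if (distance <= feat.hydrophobic and fa.hydrophobe and fb.hydrophobe):
        flags.hydrophobic = True
    if distance <= feat.carbonyl and (
            (fa.carbonyl_carbon and fb.carbonyl_oxygen)
            or (fa.carbonyl_oxygen and fb.carbonyl_carbon)):
        flags.carbonyl = True
    return flags


# ---------------------------------------------------------------------------
# entity map and the full pipeline
# ---------------------------------------------------------------------------

def _canonical_key(atom: Atom) -> tuple:
    res = atom.parent
    return (res.chain.id if res.chain else "", res.number,
            res.insertion_code, atom.serial)


class EntityMap:
    """residue -> entity (Chain for long polymers, LigandEntity, 'water')."""

    def __init__(self, assembly: Assembly, ligands: list[LigandEntity]):
        self._map: dict[int, object] = {}
        for lig in ligands:
            for res in lig.residues:
                self._map[id(res)] = lig
        for chain in assembly.chains:
            for res in chain.residues:
                if id(res) in self._map:
                    continue
                self._map[id(res)] = "water" if res.is_water else chain

    def entity_of(self, atom: Atom) -> object:
        return self._map[id(atom.parent)]

    @staticmethod
    def entity_kind(entity: object) -> str:
        if isinstance(entity, LigandEntity):
            return "ligand"
        if isinstance(entity, Chain):
            return entity.entity_type
        return "water"


@dataclass
class ProfileResult:
    assembly: Assembly
    contacts: list[Contact]
    ligands: list[LigandEntity]
    rings: list[AromaticRing]
    entity_map: EntityMap
    context: ContactContext


def profile_contacts(assembly: Assembly, store: TemplateStore,
                     config: ProfilerConfig | None = None,
                     include_intra: bool = True,
                     include_waters: bool = False) -> ProfileResult:
    """Full pipeline: typing, perception, neighbour search, classification.

    Intramolecular contacts are stored (flagged) but never grouped into
    entity-pair interactions; waters are excluded from the census unless
    requested.
    """
    cfg = config or default_config()
    assign_atom_types(assembly, store)
    ligands = perceive_ligands(assembly, store, cfg)
    rings = perceive_aromatic_rings(assembly, store, cfg)
    ctx = ContactContext.build(assembly, store, rings, cfg)
    emap = EntityMap(assembly, ligands)

    contacts: list[Contact] = []
    for a, b, d in neighbor_pairs(assembly, cfg.distance.proximal):
        if a.parent is b.parent:
            continue
        if not include_waters and (a.parent.is_water or b.parent.is_water):
            continue
        if ctx.bond_graph.bonded_or_13(a, b):
            continue
        ea, eb = emap.entity_of(a), emap.entity_of(b)
        intra = ea is eb
        if intra and not include_intra:
            continue
        flags = classify_contact(a, b, d, ctx, cfg)
        if _canonical_key(b) < _canonical_key(a):
            a, b = b, a
        kinds = frozenset((EntityMap.entity_kind(ea),
                           EntityMap.entity_kind(eb)))
        contacts.append(Contact(
            a, b, d, flags, is_intramolecular=intra,
            pair_class="other" if intra
            else PAIR_CLASS_MATRIX.get(kinds, "other")))
    return ProfileResult(assembly, contacts, ligands, rings, emap, ctx)


# ---------------------------------------------------------------------------
# entity-pair grouping
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class InteractionGroup:
    entity_a: object
    entity_b: object
    pair_class: str
    contacts: list[Contact]
    residues_a: set[Residue] = field(default_factory=set)
    residues_b: set[Residue] = field(default_factory=set)

    @property
    def contact_count(self) -> int:
        return len(self.contacts)

    @property
    def has_missing_atoms(self) -> bool:
        return any(r.missing_atoms is True
                   for r in self.residues_a | self.residues_b)


def group_interactions(result: ProfileResult) -> list[InteractionGroup]:
    """Bucket inter-entity contacts by unordered entity pair."""
    emap = result.entity_map
    buckets: dict[tuple[int, int], InteractionGroup] = {}
    order: dict[int, object] = {}
    for c in result.contacts:
        if c.is_intramolecular:
            continue
        ea, eb = emap.entity_of(c.atom_a), emap.entity_of(c.atom_b)
        if "water" in (EntityMap.entity_kind(ea), EntityMap.entity_kind(eb)):
            continue
        key = tuple(sorted((id(ea), id(eb))))
        order[id(ea)] = ea
        order[id(eb)] = eb
        if key not in buckets:
            first, second = (ea, eb) if key[0] == id(ea) else (eb, ea)
            buckets[key] = InteractionGroup(first, second, c.pair_class, [])
        buckets[key].contacts.append(c)
    groups = list(buckets.values())
    for g in groups:
        g.residues_a = {
            (c.atom_a if emap.entity_of(c.atom_a) is g.entity_a
             else c.atom_b).parent
            for c in g.contacts}
        g.residues_b = {
            (c.atom_a if emap.entity_of(c.atom_a) is g.entity_b
             else c.atom_b).parent
            for c in g.contacts}
    return groups


def entity_label(assembly: Assembly, entity: object) -> str:
    if isinstance(entity, LigandEntity):
        return str(entity.path_id)
    if isinstance(entity, Chain):
        return f"{assembly.pdb_id}/{assembly.serial}/{entity.id}"
    return "water"


# ---------------------------------------------------------------------------
# surface exposure
# ---------------------------------------------------------------------------

@dataclass
class SurfaceExposure:
    atom_exposed: dict[int, bool]
    residue_exposed: dict[int, bool]

    def is_exposed(self, atom: Atom) -> bool:
        return self.atom_exposed[id(atom)]

    def residue_is_exposed(self, residue: Residue) -> bool:
        return self.residue_exposed[id(residue)]


def surface_exposed(entity: Chain | LigandEntity,
                    config: ProfilerConfig | None = None) -> SurfaceExposure:
    """Per-atom exposure of the *isolated* entity.

    Exposure is computed per entity, never for the whole assembly: a
    ligand buried in a pocket is still exposed as an isolated molecule.
    An atom is exposed iff its solvent-accessible surface area (probe
    1.4 Å) is at least the configured minimum (0.1 Å² default).
    """
    import biotite.structure as struc

    cfg = config or default_config()
    atoms = (entity.atoms() if isinstance(entity, LigandEntity)
             else [a for r in entity.residues for a in r.atoms])
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a.coords for a in atoms])
    arr.element = np.array([a.element for a in atoms])
    arr.atom_name = np.array([a.name for a in atoms])
    arr.res_name = np.array([a.parent.name for a in atoms])
    arr.res_id = np.array([a.parent.number for a in atoms])
    arr.chain_id = np.array([
        a.parent.chain.id if a.parent.chain else "X" for a in atoms])
    sasa = struc.sasa(arr, probe_radius=cfg.exposure.probe_radius,
                      point_number=cfg.exposure.n_points,
                      vdw_radii="Single")
    sasa = np.nan_to_num(sasa, nan=0.0)
    atom_exposed = {id(a): bool(s >= cfg.exposure.min_sasa)
                    for a, s in zip(atoms, sasa)}
    residue_exposed: dict[int, bool] = {}
    for a in atoms:
        rid = id(a.parent)
        residue_exposed[rid] = residue_exposed.get(rid, False) \
            or atom_exposed[id(a)]
    return SurfaceExposure(atom_exposed, residue_exposed)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def contacts_tsv(result: ProfileResult) -> str:
    asm = result.assembly
    header = ["atom_a", "atom_b", "distance"] + list(FLAG_ORDER)
    lines = ["\t".join(header)]
    for c in result.contacts:
        row = [str(asm.atom_path(c.atom_a)), str(asm.atom_path(c.atom_b)),
               f"{c.distance:.3f}"]
        row += [str(b) for b in c.flags.bits()]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def contacts_json(result: ProfileResult) -> list[dict]:
    asm = result.assembly
    return [
        {
            "atom_a": str(asm.atom_path(c.atom_a)),
            "atom_b": str(asm.atom_path(c.atom_b)),
            "distance": round(c.distance, 3),
            "intramolecular": c.is_intramolecular,
            "pair_class": c.pair_class,
            "flags": {f: bool(getattr(c.flags, f)) for f in FLAG_ORDER},
        }
        for c in result.contacts
    ]


def interactions_tsv(result: ProfileResult,
                     groups: list[InteractionGroup]) -> str:
    asm = result.assembly
    lines = ["entity_a\tentity_b\tclass\tcontacts\tresidues_a\tresidues_b"
             "\tmissing_atoms"]
    for g in groups:
        lines.append("\t".join([
            entity_label(asm, g.entity_a), entity_label(asm, g.entity_b),
            g.pair_class, str(g.contact_count),
            str(len(g.residues_a)), str(len(g.residues_b)),
            str(int(g.has_missing_atoms)),
        ]))
    return "\n".join(lines) + "\n"
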