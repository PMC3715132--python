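"""Per-atom chemical feature flags, ligand and aromatic-ring perception.

Typing works on heavy atoms only — hydrogens are never required from the
coordinates (crystal structures usually lack them).  Donor/acceptor
capacity is inferred from the component template: explicit template
hydrogens when the dictionary provides them, valence heuristics otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from .config import HALOGENS, METALS, ProfilerConfig, default_config
from .model import Assembly, Atom, Residue
from .pathid import PathID
from .templates import ComponentTemplate, TemplateStore


class UntypedComponentError(ValueError):
    """A residue has no template and cannot be atom-typed."""


@dataclass
class AtomTypeFlags:
    hbond_donor: bool = False
    hbond_acceptor: bool = False
    weak_donor: bool = False
    pos_ionisable: bool = False
    neg_ionisable: bool = False
    aromatic: bool = False
    halogen_donor: bool = False
    hydrophobe: bool = False
    metal: bool = False
    carbonyl_oxygen: bool = False
    carbonyl_carbon: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _type_atom(atom: Atom, tmpl: ComponentTemplate) -> AtomTypeFlags:
    el = atom.element.upper()
    name = atom.name
    flags = AtomTypeFlags()
    if name not in tmpl.atoms:
        # atom absent from dictionary (e.g. terminal OXT variants): type by
        # element only
        flags.hbond_acceptor = el == "O"
        flags.metal = el in METALS
        flags.pos_ionisable = el in METALS
        return flags

    heavy_nbrs = tmpl.heavy_neighbors(name)
    heavy_deg = len(heavy_nbrs)
    template_has_h = any(e == "H" for e in tmpl.atoms.values())
    n_h = tmpl.h_count(name)
    charge = tmpl.charges.get(name, 0)
    aromatic_atoms = tmpl.aromatic_atoms()
    is_aromatic = name in aromatic_atoms

    def has_h() -> bool:
        if template_has_h:
            return n_h > 0
        # heavy-only template: infer free valence
        free = {"N": 3, "O": 2, "S": 2, "C": 4}.get(el, 0) - heavy_deg
        return free + max(charge, 0) > 0

    double_bonded = {
        b.b if b.a == name else b.a
        for b in tmpl.bonds
        if name in (b.a, b.b) and b.order == 2 and not b.aromatic
    }

    if el == "N":
        flags.hbond_donor = has_h()
        flags.hbond_acceptor = not has_h() and heavy_deg <= 2
    elif el == "O":
        flags.hbond_acceptor = True
        flags.hbond_donor = has_h()
    elif el == "S":
        flags.hbond_donor = has_h()
        flags.hbond_acceptor = heavy_deg <= 2 and not has_h()
    elif el == "C":
        flags.weak_donor = has_h()

    flags.aromatic = is_aromatic
    flags.metal = el in METALS
    flags.halogen_donor = el in HALOGENS and any(
        tmpl.atoms[n] == "C" for n in heavy_nbrs)

    # positive ionisable: metals, charged template atoms, guanidinium/
    # amidine nitrogens, aliphatic amines (anilines and amides excluded)
    if el in METALS:
        flags.pos_ionisable = True
    elif el == "N":
        if charge > 0:
            flags.pos_ionisable = True
        else:
            for nb in heavy_nbrs:
                if tmpl.atoms[nb] != "C" or nb in aromatic_atoms:
                    continue
                c_nbrs = tmpl.heavy_neighbors(nb)
                n_n = sum(1 for x in c_nbrs if tmpl.atoms[x] == "N")
                n_o = sum(1 for x in c_nbrs if tmpl.atoms[x] == "O")
                if n_n >= 2 and n_o == 0:   # guanidinium / amidine
                    flags.pos_ionisable = True
            if (not is_aromatic and not double_bonded
                    and not any(n in aromatic_atoms for n in heavy_nbrs)
                    and not _amide_nitrogen(name, tmpl)
                    and has_h()):
                flags.pos_ionisable = True

    # negative ionisable: carboxylate / phosphate / sulfate oxygens
    if charge < 0:
        flags.neg_ionisable = True
    if el == "O" and heavy_deg == 1:
        center = next(iter(heavy_nbrs))
        if tmpl.atoms[center] in ("C", "P", "S"):
            terminal_o = sum(
                1 for x in tmpl.heavy_neighbors(center)
                if tmpl.atoms[x] == "O" and len(tmpl.heavy_neighbors(x)) == 1)
            if terminal_o >= 2:
                flags.neg_ionisable = True

    # hydrophobe: apolar carbon, halogen on carbon, all-carbon sulfur
    if el == "C":
        flags.hydrophobe = not any(
            tmpl.atoms[n] in ("N", "O", "P") for n in heavy_nbrs)
    elif el in HALOGENS:
        flags.hydrophobe = True
    elif el == "S":
        flags.hydrophobe = bool(heavy_nbrs) and all(
            tmpl.atoms[n] == "C" for n in heavy_nbrs)

    # carbonyl group membership (C=O double bond)
    if el == "C" and any(tmpl.atoms[n] == "O" for n in double_bonded):
        flags.carbonyl_carbon = True
    if el == "O" and any(tmpl.atoms[n] == "C" for n in double_bonded):
        flags.carbonyl_oxygen = True
    return flags


def _amide_nitrogen(name: str, tmpl: ComponentTemplate) -> bool:
    for nb in tmpl.heavy_neighbors(name):
        if tmpl.atoms[nb] not in ("C", "S"):
            continue
        for b in tmpl.bonds:
            if nb in (b.a, b.b) and b.order == 2:
                other = b.b if b.a == nb else b.a
                if tmpl.atoms[other] in ("O", "S"):
                    return True
    return False


def assign_atom_types(assembly: Assembly, store: TemplateStore) -> int:
    """Attach an :class:`AtomTypeFlags` to every atom (``atom.flags``).

    Raises :class:`UntypedComponentError` listing every component for
    which no template could be found.  Returns the number of typed atoms.
    """
    from .model import _is_amino

    missing: set[str] = set()
    n = 0
    for res in assembly.iter_residues():
        tmpl = store.get_or_none(res.name)
        if tmpl is None:
            missing.add(res.name)
            continue
        amino = _is_amino(res.name)
        for atom in res.atoms:
            atom.flags = _type_atom(atom, tmpl)
            # the backbone nitrogen is an amide in the chain context even
            # though the residue template cannot show the peptide bond
            if amino and res.is_polymer and atom.name == "N":
                atom.flags.pos_ionisable = False
            n += 1
    if missing:
        raise UntypedComponentError(
            "no template for component(s): " + ", ".join(sorted(missing)))
    return n


# ---------------------------------------------------------------------------
# ligand perception
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class LigandEntity:
    residues: list[Residue]
    path_id: PathID
    is_unknown: bool = False
    is_drug_like: bool | None = None

    @property
    def het_ids(self) -> list[str]:
        return [r.name for r in self.residues]

    @property
    def heavy_atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]


def _residues_bonded(a: Residue, b: Residue, cfg: ProfilerConfig) -> bool:
    ca = np.array([at.coords for at in a.atoms])
    cb = np.array([at.coords for at in b.atoms])
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    ii, jj = np.nonzero(d < cfg.ligands.bond_cutoff_sp)
    for i, j in zip(ii, jj):
        cut = cfg.ligands.bond_cutoff
        if (a.atoms[i].element in ("S", "P")
                or b.atoms[j].element in ("S", "P")):
            cut = cfg.ligands.bond_cutoff_sp
        if d[i, j] < cut:
            return True
    return False


def perceive_ligands(assembly: Assembly, store: TemplateStore,
                     config: ProfilerConfig | None = None,
                     ) -> list[LigandEntity]:
    """Connected components of non-water hetero residues.

    Short polypeptide chains (length <= configured maximum, default 10)
    are included as heteropeptide ligands.  Every non-water hetero
    residue belongs to exactly one ligand; isolated unknown components
    become single-residue ligands flagged unknown.
    """
    import networkx as nx

    cfg = config or default_config()
    candidates: list[Residue] = []
    for chain in assembly.chains:
        poly = chain.polymer_residues()
        short_peptide = (chain.entity_type == "polypeptide"
                         and 0 < len(poly) <= cfg.ligands.max_peptide_length)
        for res in chain.residues:
            if res.is_water:
                continue
            if res.is_polymer and not short_peptide:
                continue
            candidates.append(res)

    g = nx.Graph()
    g.add_nodes_from(range(len(candidates)))
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            # cheap bounding check before the pairwise distance scan
            ci = candidates[i].atoms[0].coords
            cj = candidates[j].atoms[0].coords
            if np.linalg.norm(ci - cj) > 25.0:
                continue
            if _residues_bonded(candidates[i], candidates[j], cfg):
                g.add_edge(i, j)

    ligands: list[LigandEntity] = []
    for comp in nx.connected_components(g):
        residues = sorted((candidates[i] for i in comp),
                          key=lambda r: (r.chain.id, r.sort_key))
        first = residues[0]
        lig = LigandEntity(
            residues=residues,
            path_id=assembly.residue_path(first),
            is_unknown=any(store.get_or_none(r.name) is None
                           for r in residues),
        )
        ligands.append(lig)
    ligands.sort(key=lambda l: str(l.path_id))
    return ligands


# ---------------------------------------------------------------------------
# aromatic ring perception
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class AromaticRing:
    owner: Residue
    atoms: list[Atom]
    centroid: np.ndarray
    normal: np.ndarray

    @property
    def size(self) -> int:
        return len(self.atoms)


def fit_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane: returns (centroid, unit normal, rms deviation)."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return centroid, normal, rms


def perceive_aromatic_rings(assembly: Assembly, store: TemplateStore,
                            config: ProfilerConfig | None = None,
                            ) -> list[AromaticRing]:
    """One record per smallest aromatic cycle, per residue.

    Fused systems yield one ring per constituent cycle (TRP -> 2 rings).
    Rings whose least-squares plane fit exceeds the planarity tolerance
    are rejected with a warning, as are aromatic systems that would span
    two polymer residues (not representable in this model).
    """
    import networkx as nx

    cfg = config or default_config()
    rings: list[AromaticRing] = []
    for res in assembly.iter_residues():
        tmpl = store.get_or_none(res.name)
        if tmpl is None:
            continue
        observed = {a.name: a for a in res.atoms}
        g = nx.Graph()
        for b in tmpl.bonds:
            if b.aromatic and b.a in observed and b.b in observed:
                g.add_edge(b.a, b.b)
        if not g.number_of_edges():
            continue
        for cycle in nx.minimum_cycle_basis(g):
            if len(cycle) < 5:
                continue
            members = _order_cycle(g, cycle)
            atoms = [observed[n] for n in members]
            coords = np.array([a.coords for a in atoms])
            centroid, normal, rms = fit_plane(coords)
            if rms > cfg.rings.planarity_rms_tol:
                warnings.warn(
                    f"ring in {res.token} rejected: out-of-plane rms "
                    f"{rms:.3f} Å exceeds {cfg.rings.planarity_rms_tol} Å")
                continue
            rings.append(AromaticRing(res, atoms, centroid, normal))
    _warn_split_rings(assembly, rings)
    return rings


def _order_cycle(g, cycle: list[str]) -> list[str]:
    # minimum_cycle_basis returns an unordered node set; walk the cycle
    sub = g.subgraph(cycle)
    start = sorted(cycle)[0]
    order = [start]
    prev = None
    while len(order) < len(cycle):
        nxt = [n for n in sub.neighbors(order[-1]) if n != prev]
        prev = order[-1]
        order.append(sorted(nxt)[0])
    return order


def _warn_split_rings(assembly: Assembly, rings: list[AromaticRing]) -> None:
    aromatic_atoms = [a for ring in rings for a in ring.atoms]
    for i in range(len(aromatic_atoms)):
        for j in range(i + 1, len(aromatic_atoms)):
            a, b = aromatic_atoms[i], aromatic_atoms[j]
            if a.parent is b.parent or not (a.parent.is_polymer
                                            and b.parent.is_polymer):
                continue
            if np.linalg.norm(a.coords - b.coords) < 1.8:
                warnings.warn(
                    f"aromatic system spans residues {a.parent.token} and "
                    f"{b.parent.token}; such rings are not representable "
                    f"and are reported per residue only")
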