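"""Retrosynthetic (RECAP-style) fragmentation and fragment contact density.

Ligand chemistry is cleaved recursively at rule-defined acyclic bonds
(amide, ester, amine, urea, ether, olefin, quaternary N, aromatic-N to
aliphatic-C, lactam, biaryl, sulfonamide, plus a phosphate-ester
extension for phosphate-containing natural products) until no rule
applies.  Leaves are the smallest fragments; dummy-atom caps mark the cut
positions and are excluded from all atom counts.

The fragment contact density (FCD) measures whether a fragment makes
proportionally more contacts than its parent ligand:

    FCD = (C_f / A_f) / (C_l / A_l)

with C_f/C_l the number of contact endpoints on fragment/ligand atoms and
A_f/A_l the heavy-atom counts.  FCD = 1 for the whole ligand, and the
leaf set satisfies sum_f (A_f/A_l) * FCD_f = 1 exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .chemtypes import LigandEntity
from .contacts import Contact
from .model import Atom
from .templates import ComponentTemplate


@dataclass(frozen=True)
class RecapRule:
    rule_id: str
    smarts: str
    bond: tuple[int, int]


def load_rules() -> list[RecapRule]:
    text = (resources.files("structprof") / "data" / "recap_rules.json"
            ).read_text()
    data = json.loads(text)
    return [RecapRule(r["id"], r["smarts"], tuple(r["bond"]))
            for r in data["rules"]]


# ---------------------------------------------------------------------------
# molecule construction
# ---------------------------------------------------------------------------

def mol_from_template(tmpl: ComponentTemplate):
    """RDKit molecule from a component template (heavy atoms only).

    Atom names are preserved as the ``name`` property so fragments can be
    mapped back onto structure atoms.
    """
    from rdkit import Chem

    mol = Chem.RWMol()
    index: dict[str, int] = {}
    for name, element in tmpl.atoms.items():
        if element == "H":
            continue
        atom = Chem.Atom(element.capitalize())
        atom.SetFormalCharge(tmpl.charges.get(name, 0))
        atom.SetProp("name", name)
        index[name] = mol.AddAtom(atom)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE}
    for b in tmpl.bonds:
        if b.a in index and b.b in index:
            mol.AddBond(index[b.a], index[b.b],
                        order_map.get(b.order, Chem.BondType.SINGLE))
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def mol_from_smiles(smiles: str):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES: {smiles}")
    return mol


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Fragment:
    mol: object                      # RDKit Mol, caps included
    atom_map: frozenset[int]         # parent heavy-atom indices, caps excluded
    smiles: str
    is_smallest: bool = False
    children: list["Fragment"] = field(default_factory=list)

    @property
    def heavy_atom_count(self) -> int:
        return len(self.atom_map)

    def leaves(self) -> list["Fragment"]:
        if not self.children:
            return [self]
        out: list[Fragment] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _cleavable_bonds(mol, rules: list[RecapRule]) -> list[int]:
    from rdkit import Chem

    bonds: set[int] = set()
    for rule in rules:
        patt = Chem.MolFromSmarts(rule.smarts)
        for match in mol.GetSubstructMatches(patt):
            i, j = match[rule.bond[0]], match[rule.bond[1]]
            bond = mol.GetBondBetweenAtoms(i, j)
            if bond is None or bond.IsInRing():
                continue
            bonds.add(bond.GetIdx())
    return sorted(bonds)


def _tag_atoms(mol) -> None:
    for i, atom in enumerate(mol.GetAtoms()):
        if not atom.HasProp("origIdx"):
            atom.SetIntProp("origIdx", i)


def _atom_map(mol) -> frozenset[int]:
    return frozenset(a.GetIntProp("origIdx") for a in mol.GetAtoms()
                     if a.GetAtomicNum() != 0)


def _smiles(mol) -> str:
    from rdkit import Chem

    # normalise cap labels so the canonical text is independent of the
    # parent's atom order (FragmentOnBonds numbers dummies by bond index)
    clean = Chem.Mol(mol)
    for atom in clean.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
    try:
        return Chem.MolToSmiles(clean)
    except Exception:   # pragma: no cover - unsanitizable corner case
        return Chem.MolToSmiles(clean, canonical=False)


def recap_fragment(mol_or_smiles, rules: list[RecapRule] | None = None,
                   ) -> Fragment:
    """Recursive cleavage; returns the fragment tree root.

    A molecule with no cleavable bond yields a single leaf (itself).
    Deterministic: at each level the lowest-index cleavable bond is cut.
    """
    from rdkit import Chem

    if isinstance(mol_or_smiles, str):
        mol = mol_from_smiles(mol_or_smiles)
    else:
        mol = Chem.Mol(mol_or_smiles)
    rules = rules if rules is not None else load_rules()
    _tag_atoms(mol)
    return _recurse(mol, rules)


def _recurse(mol, rules: list[RecapRule]) -> Fragment:
    from rdkit import Chem

    bonds = _cleavable_bonds(mol, rules)
    node = Fragment(mol, _atom_map(mol), _smiles(mol))
    if not bonds:
        node.is_smallest = True
        return node
    pieces = Chem.FragmentOnBonds(mol, [bonds[0]], addDummies=True)
    frags = Chem.GetMolFrags(pieces, asMols=True, sanitizeFrags=False)
    for f in frags:
        try:
            Chem.SanitizeMol(f)
        except Exception:
            Chem.SanitizeMol(
                f, Chem.SanitizeFlags.SANITIZE_ALL
                ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
        node.children.append(_recurse(f, rules))
    node.children.sort(key=lambda fr: min(fr.atom_map) if fr.atom_map else -1)
    return node


# ---------------------------------------------------------------------------
# mapping fragments back onto structure atoms
# ---------------------------------------------------------------------------

class AtomMappingError(ValueError):
    pass


def map_fragment_atoms(fragment: Fragment, parent_mol,
                       ligand: LigandEntity) -> list[Atom]:
    """Injective map from fragment heavy atoms to structure atoms.

    Uses the atom names preserved on the parent molecule; caps are
    excluded.  Raises when a fragment atom has no counterpart in the
    observed ligand.
    """
    lig_atoms = {a.name: a for a in ligand.atoms()}
    out: list[Atom] = []
    parent_atoms = list(parent_mol.GetAtoms())
    for idx in sorted(fragment.atom_map):
        patom = parent_atoms[idx]
        if not patom.HasProp("name"):
            raise AtomMappingError(
                f"parent atom {idx} carries no name; build the molecule "
                f"with mol_from_template")
        name = patom.GetProp("name")
        if name not in lig_atoms:
            raise AtomMappingError(
                f"fragment atom {name} not observed in ligand "
                f"{ligand.path_id}")
        out.append(lig_atoms[name])
    if len({id(a) for a in out}) != len(out):
        raise AtomMappingError("fragment-to-ligand map is not injective")
    return out


# ---------------------------------------------------------------------------
# fragment contact density
# ---------------------------------------------------------------------------

@dataclass
class FCDResult:
    C_f: int
    A_f: int
    C_l: int
    A_l: int
    fcd: float | None
    defined: bool = True


def count_contact_endpoints(atoms: list[Atom],
                            contacts: list[Contact]) -> int:
    """Endpoint count: an atom participating in k contacts contributes k."""
    ids = {id(a) for a in atoms}
    n = 0
    for c in contacts:
        if id(c.atom_a) in ids:
            n += 1
        if id(c.atom_b) in ids:
            n += 1
    return n


def ligand_feature_contacts(contacts: list[Contact], ligand: LigandEntity,
                            feature_only: bool = True) -> list[Contact]:
    """The ligand's inter-entity contact list used for FCD.

    By default only contacts with at least one feature flag count; with
    ``feature_only=False`` every stored contact counts.
    """
    lig_ids = {id(a) for a in ligand.atoms()}
    out = []
    for c in contacts:
        if c.is_intramolecular:
            continue
        in_a, in_b = id(c.atom_a) in lig_ids, id(c.atom_b) in lig_ids
        if in_a == in_b:   # none or both endpoints in the ligand
            continue
        if feature_only and not c.flags.any_feature():
            continue
        out.append(c)
    return out


def fragment_contact_density(fragment_atoms: list[Atom],
                             ligand: LigandEntity,
                             contacts: list[Contact]) -> FCDResult:
    """FCD = (C_f/A_f) / (C_l/A_l); undefined (not zero) when C_l = 0."""
    A_f = len(fragment_atoms)
    A_l = ligand.heavy_atom_count
    if A_f == 0 or A_l == 0:
        raise ValueError("fragment and ligand must have heavy atoms")
    C_l = count_contact_endpoints(ligand.atoms(), contacts)
    C_f = count_contact_endpoints(fragment_atoms, contacts)
    if C_l == 0:
        return FCDResult(C_f, A_f, C_l, A_l, None, defined=False)
    return FCDResult(C_f, A_f, C_l, A_l,
                     (C_f / A_f) / (C_l / A_l), defined=True)


def fcd_from_counts(C_f: int, A_f: int, C_l: int, A_l: int) -> FCDResult:
    """FCD directly from the four counts (same arithmetic, no structure)."""
    if A_f <= 0 or A_l <= 0:
        raise ValueError("atom counts must be positive")
    if C_l == 0:
        return FCDResult(C_f, A_f, C_l, A_l, None, defined=False)
    return FCDResult(C_f, A_f, C_l, A_l, (C_f / A_f) / (C_l / A_l))
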