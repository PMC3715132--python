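"""Chemical component templates: atom/bond connectivity per HET-ID.

Templates drive atom typing, ligand connectivity, aromatic-ring perception
and missing-atom detection.  Known components (standard residues and PDB
HET ids) are resolved from the chemical component dictionary bundled with
biotite; additional components can be supplied as a CCD-style mmCIF subset
(``_chem_comp_atom`` / ``_chem_comp_bond``) or registered programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class UnknownComponentError(KeyError):
    """No template available for a component id."""


@dataclass
class Bond:
    a: str
    b: str
    order: int = 1
    aromatic: bool = False


@dataclass
class ComponentTemplate:
    het_id: str
    # atom name -> element symbol (upper case), hydrogens included if known
    atoms: dict[str, str]
    bonds: list[Bond]
    charges: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for b in self.bonds:
            if b.a not in self.atoms or b.b not in self.atoms:
                raise ValueError(
                    f"{self.het_id}: bond {b.a}-{b.b} references unknown atom")
        self._nbrs: dict[str, set[str]] = {n: set() for n in self.atoms}
        for b in self.bonds:
            self._nbrs[b.a].add(b.b)
            self._nbrs[b.b].add(b.a)

    # -- connectivity helpers -------------------------------------------
    def neighbors(self, name: str) -> set[str]:
        return self._nbrs[name]

    def heavy_neighbors(self, name: str) -> set[str]:
        return {n for n in self._nbrs[name] if self.atoms[n] != "H"}

    def h_count(self, name: str) -> int:
        return sum(1 for n in self._nbrs[name] if self.atoms[n] == "H")

    def bond_between(self, a: str, b: str) -> Bond | None:
        for bd in self.bonds:
            if {bd.a, bd.b} == {a, b}:
                return bd
        return None

    @property
    def expected_heavy_atoms(self) -> set[str]:
        """Heavy atoms expected in an observed residue (terminal OXT excluded)."""
        return {n for n, el in self.atoms.items()
                if el != "H" and n != "OXT"}

    def aromatic_atoms(self) -> set[str]:
        out: set[str] = set()
        for b in self.bonds:
            if b.aromatic:
                out.add(b.a)
                out.add(b.b)
        return out


def template_from_ccd(het_id: str) -> ComponentTemplate:
    """Build a template from the bundled chemical component dictionary."""
    import biotite.structure.info as info

    try:
        arr = info.residue(het_id.upper())
    except Exception as exc:
        raise UnknownComponentError(het_id) from exc
    if arr is None:
        raise UnknownComponentError(het_id)
    names = [str(n) for n in arr.atom_name]
    elements = [str(e).upper() for e in arr.element]
    atoms = dict(zip(names, elements))
    charges = {}
    if "charge" in arr.get_annotation_categories():
        for n, c in zip(names, arr.charge):
            if int(c) != 0:
                charges[n] = int(c)
    bonds = []
    for i, j, t in arr.bonds.as_array():
        aromatic = int(t) in (5, 6, 7, 9)  # biotite AROMATIC_* codes
        order = {1: 1, 2: 2, 3: 3, 5: 1, 6: 2, 7: 3}.get(int(t), 1)
        bonds.append(Bond(names[i], names[j], order, aromatic))
    return ComponentTemplate(het_id.upper(), atoms, bonds, charges)


def templates_from_cif(text: str) -> list[ComponentTemplate]:
    """Read templates from a chemical-component-dictionary mmCIF subset."""
    import gemmi.cif

    doc = gemmi.cif.read_string(text)
    out = []
    for block in doc:
        atom_names = list(block.find_loop("_chem_comp_atom.atom_id"))
        if not atom_names:
            continue
        comp_ids = list(block.find_loop("_chem_comp_atom.comp_id"))
        elements = list(block.find_loop("_chem_comp_atom.type_symbol"))
        het_id = comp_ids[0] if comp_ids else block.name
        atoms = {n.strip('"'): e.upper()
                 for n, e in zip(atom_names, elements)}
        bonds = []
        b1 = list(block.find_loop("_chem_comp_bond.atom_id_1"))
        b2 = list(block.find_loop("_chem_comp_bond.atom_id_2"))
        orders = list(block.find_loop("_chem_comp_bond.value_order"))
        arom = list(block.find_loop("_chem_comp_bond.pdbx_aromatic_flag"))
        for k in range(len(b1)):
            order = {"SING": 1, "DOUB": 2, "TRIP": 3}.get(
                orders[k].upper() if k < len(orders) else "SING", 1)
            aromatic = (arom[k].upper() == "Y") if k < len(arom) else False
            bonds.append(Bond(b1[k].strip('"'), b2[k].strip('"'),
                              order, aromatic))
        out.append(ComponentTemplate(het_id.upper(), atoms, bonds))
    return out


class TemplateStore:
    """Component-id -> template lookup with CCD fallback."""

    def __init__(self, use_ccd: bool = True):
        self._local: dict[str, ComponentTemplate] = {}
        self._use_ccd = use_ccd

    def register(self, template: ComponentTemplate) -> None:
        self._local[template.het_id.upper()] = template

    def load_cif(self, text: str) -> None:
        for t in templates_from_cif(text):
            self.register(t)

    def get(self, het_id: str) -> ComponentTemplate:
        key = het_id.upper()
        if key in self._local:
            return self._local[key]
        if self._use_ccd:
            t = template_from_ccd(key)
            self._local[key] = t
            return t
        raise UnknownComponentError(het_id)

    def get_or_none(self, het_id: str) -> ComponentTemplate | None:
        try:
            return self.get(het_id)
        except UnknownComponentError:
            return None

    def __contains__(self, het_id: str) -> bool:
        return self.get_or_none(het_id) is not None


def default_store() -> TemplateStore:
    return TemplateStore(use_ccd=True)
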