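"""Structure model: parsing, entity hierarchy, missing regions, SS fragments.

Structures (PDB or mmCIF, asymmetric unit or a pre-generated biological
assembly file) are parsed with gemmi into a light hierarchy
Assembly -> Chain -> Residue -> Atom.  Only the first model is used and
hydrogens are dropped; alternate locations are resolved to the location
set with the highest summed occupancy (ties broken alphabetically).
Entries encoding two distinct orientations as alternate location groups
with different residue identifiers are rejected with a structured error
rather than guessed at.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pathid import PathID, residue_token
from .templates import ComponentTemplate


class ParseError(ValueError):
    """Malformed structure input."""


class UnsupportedRepresentationError(ParseError):
    """Syntactically valid but semantically ambiguous representation."""


WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# 8-state DSSP -> 3-state collapse (H/G/I helix, E/B strand, rest coil)
SS_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


@dataclass(eq=False)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    parent: "Residue | None" = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Atom {self.name} #{self.serial}>"


@dataclass(eq=False)
class Residue:
    name: str
    number: int
    insertion_code: str = ""
    one_letter: str = "X"
    ss_code: str | None = None
    atoms: list[Atom] = field(default_factory=list)
    missing_atoms: bool | None = None   # None = unknown component
    is_polymer: bool = False
    is_water: bool = False
    chain: "Chain | None" = None

    @property
    def sort_key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    @property
    def token(self) -> str:
        return residue_token(self.name, self.number, self.insertion_code)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Residue {self.token}>"


ENTITY_TYPES = ("polypeptide", "oligonucleotide", "polysaccharide",
                "nonpolymer", "water")


@dataclass(eq=False)
class Chain:
    id: str
    entity_type: str = "nonpolymer"
    residues: list[Residue] = field(default_factory=list)
    full_sequence: str = ""   # SEQRES-equivalent one-letter reference

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def observed_sequence(self) -> str:
        return "".join(r.one_letter for r in self.polymer_residues())


@dataclass(eq=False)
class Assembly:
    pdb_id: str
    serial: int = 0
    chains: list[Chain] = field(default_factory=list)

    def get_chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    def iter_residues(self):
        for c in self.chains:
            yield from c.residues

    def iter_atoms(self):
        for r in self.iter_residues():
            yield from r.atoms

    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    # ---- path identifiers --------------------------------------------
    def residue_path(self, residue: Residue) -> PathID:
        return PathID(self.pdb_id, str(self.serial),
                      residue.chain.id, residue.token)

    def atom_path(self, atom: Atom) -> PathID:
        res = atom.parent
        return PathID(self.pdb_id, str(self.serial),
                      res.chain.id, res.token, atom.name)


@dataclass
class MissingRegion:
    chain_id: str
    start: int
    end: int
    flanking: tuple[int | None, int | None]
    terminal: bool

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("missing region start > end")


@dataclass
class SSFragment:
    chain_id: str
    index: int | None
    ss_code: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def start(self) -> int:
        return self.residues[0].number

    @property
    def end(self) -> int:
        return self.residues[-1].number


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _one_letter(name: str) -> str:
    import gemmi

    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"
    return "X"


def _is_amino(name: str) -> bool:
    import gemmi

    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def _is_nucleic(name: str) -> bool:
    import gemmi

    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_nucleic_acid()


def _altloc_of(atom) -> str:
    # gemmi encodes "no altloc" as NUL
    return atom.altloc if atom.altloc not in ("", "\x00") else ""


def _resolve_alt_locs(res) -> list:
    """Keep the alt-loc group with highest summed occupancy (ties: a-z)."""
    occ: dict[str, float] = {}
    for atom in res:
        al = _altloc_of(atom)
        if al:
            occ[al] = occ.get(al, 0.0) + atom.occ
    if not occ:
        return list(res)
    best = sorted(occ.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
    return [a for a in res if _altloc_of(a) in ("", best)]


def parse_structure(text: str, format: str = "pdb",
                    assembly_serial: int = 0,
                    pdb_id: str | None = None) -> Assembly:
    """Parse PDB/mmCIF text into an :class:`Assembly` (first model only).

    ``assembly_serial`` = 0 denotes the asymmetric unit; >= 1 marks the
    input as a pre-generated biological-assembly coordinate file.
    """
    import gemmi

    if format not in ("pdb", "mmcif"):
        raise ParseError(f"unknown format: {format}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {format} input: {exc}") from exc
    if len(st) == 0:
        raise ParseError("structure contains no model")
    st.setup_entities()
    model = st[0]

    entry_id = dict(st.info).get("_entry.id", "")
    if entry_id.lower() == "xxxx":
        entry_id = ""
    name = (pdb_id or entry_id
            or (st.name if st.name != "string" else "") or "XXXX").upper()
    if len(name) > 4:
        name = name[:4]
    asm = Assembly(pdb_id=name or "XXXX", serial=assembly_serial)

    seen_chain_ids: set[str] = set()
    for gchain in model:
        if gchain.name in seen_chain_ids:
            raise UnsupportedRepresentationError(
                f"duplicate chain id {gchain.name!r}; assembly files must "
                f"use unique chain identifiers")
        seen_chain_ids.add(gchain.name)
        chain = Chain(id=gchain.name)
        seen_positions: dict[tuple[int, str], str] = {}
        for gres in gchain:
            key = (gres.seqid.num, gres.seqid.icode.strip())
            prev = seen_positions.get(key)
            if prev is not None and prev != gres.name:
                raise UnsupportedRepresentationError(
                    f"chain {gchain.name} position {key}: alternate "
                    f"location groups with different residue identifiers "
                    f"({prev} vs {gres.name}); entry not representable")
            seen_positions[key] = gres.name
            residue = Residue(
                name=gres.name,
                number=gres.seqid.num,
                insertion_code=gres.seqid.icode.strip(),
                one_letter=_one_letter(gres.name),
                is_water=gres.name in WATER_NAMES
                or gres.is_water(),
                # PDB het flag wins when present; entity deduction only
                # decides for mmCIF records without a group_PDB tag
                is_polymer=(gres.het_flag == "A"
                            or (gres.het_flag not in ("A", "H")
                                and gres.entity_type
                                == gemmi.EntityType.Polymer))
                and gres.name not in WATER_NAMES,
                chain=chain,
            )
            for gatom in _resolve_alt_locs(gres):
                el = gatom.element.name.upper()
                if el == "H" or el == "D":
                    continue
                occ = min(max(float(gatom.occ), 0.0), 1.0)
                residue.atoms.append(Atom(
                    serial=gatom.serial,
                    name=gatom.name,
                    element=el,
                    coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    alt_loc=_altloc_of(gatom),
                    occupancy=occ,
                    b_factor=float(gatom.b_iso),
                    parent=residue,
                ))
            if residue.atoms:
                chain.residues.append(residue)
        if not chain.residues:
            continue
        chain.residues.sort(key=lambda r: r.sort_key)
        chain.entity_type = _chain_entity_type(chain)
        asm.chains.append(chain)

    _attach_full_sequences(st, model, asm)
    return asm


def _chain_entity_type(chain: Chain) -> str:
    res = chain.residues
    if all(r.is_water for r in res):
        return "water"
    poly = [r for r in res if r.is_polymer]
    if not poly:
        # chains made purely of standard amino acids are peptides even if
        # deposited as HETATM
        if all(_is_amino(r.name) for r in res if not r.is_water):
            for r in res:
                if not r.is_water:
                    r.is_polymer = True
            poly = [r for r in res if r.is_polymer]
        else:
            return "nonpolymer"
    n_amino = sum(1 for r in poly if _is_amino(r.name))
    n_nuc = sum(1 for r in poly if _is_nucleic(r.name))
    if n_nuc > n_amino:
        return "oligonucleotide"
    if n_amino:
        return "polypeptide"
    return "polysaccharide"


def _attach_full_sequences(st, model, asm: Assembly) -> None:
    import gemmi

    for gchain in model:
        chain = asm.get_chain(gchain.name)
        if chain is None:
            continue
        sub_ids = {r.subchain for r in gchain}
        for ent in st.entities:
            if ent.entity_type != gemmi.EntityType.Polymer:
                continue
            if not (set(ent.subchains) & sub_ids):
                continue
            if ent.full_sequence:
                chain.full_sequence = "".join(
                    _one_letter(gemmi.Entity.first_mon(m))
                    for m in ent.full_sequence)
            break


# ---------------------------------------------------------------------------
# missing regions
# ---------------------------------------------------------------------------

def find_missing_regions(chain: Chain) -> list[MissingRegion]:
    """Maximal gaps between observed polymer residues, plus terminal gaps.

    Terminal regions are reported only when a reference (SEQRES) sequence
    fixes the chain length; author numbering is assumed to start at 1 and
    align with that sequence.
    """
    if chain.entity_type not in ("polypeptide", "oligonucleotide",
                                 "polysaccharide"):
        return []
    numbers = sorted({r.number for r in chain.polymer_residues()})
    if not numbers:
        return []
    regions: list[MissingRegion] = []
    n_ref = len(chain.full_sequence)
    if n_ref and numbers[0] > 1:
        regions.append(MissingRegion(chain.id, 1, numbers[0] - 1,
                                     (None, numbers[0]), terminal=True))
    for prev, nxt in zip(numbers, numbers[1:]):
        if nxt > prev + 1:
            regions.append(MissingRegion(chain.id, prev + 1, nxt - 1,
                                         (prev, nxt), terminal=False))
    if n_ref and numbers[-1] < n_ref:
        regions.append(MissingRegion(chain.id, numbers[-1] + 1, n_ref,
                                     (numbers[-1], None), terminal=True))
    return regions


# ---------------------------------------------------------------------------
# secondary-structure fragments
# ---------------------------------------------------------------------------

class SSCodeError(ValueError):
    pass


def collapse_ss(code: str) -> str:
    return SS_COLLAPSE.get(code.upper(), "C")


def split_ss_fragments(chain: Chain, collapse: bool = True,
                       count_coil: bool = True) -> list[SSFragment]:
    """Split a polypeptide chain into maximal runs of equal SS code.

    A numbering gap (missing region) terminates a run.  Fragments are
    ordinal-numbered 1..n in chain order; with ``count_coil=False`` only
    helix/strand fragments receive ordinals (coil fragments get None).
    """
    residues = chain.polymer_residues()
    fragments: list[SSFragment] = []
    run: list[Residue] = []
    run_code: str | None = None

    def flush():
        nonlocal run, run_code
        if run:
            fragments.append(SSFragment(chain.id, None, run_code, run))
        run, run_code = [], None

    prev: Residue | None = None
    for r in residues:
        if r.ss_code is None:
            raise SSCodeError(f"residue {r.token} in chain {chain.id} "
                              f"has no secondary-structure code")
        code = collapse_ss(r.ss_code) if collapse else r.ss_code.upper()
        gap = prev is not None and r.number > prev.number + 1
        if code != run_code or gap:
            flush()
            run_code = code
        run.append(r)
        prev = r
    flush()

    counter = 0
    for frag in fragments:
        if count_coil or frag.ss_code in ("H", "E"):
            counter += 1
            frag.index = counter
    return fragments


def load_ss_codes(assembly: Assembly, tsv_text: str) -> int:
    """Assign per-residue SS codes from a TSV (chain, number[, icode], code).

    Returns the number of residues annotated.
    """
    n = 0
    for lineno, line in enumerate(tsv_text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 3:
            cid, num, code = parts
            icode = ""
        elif len(parts) == 4:
            cid, num, icode, code = parts
        else:
            raise ParseError(f"ss-code TSV line {lineno}: expected 3 or 4 "
                             f"columns, got {len(parts)}")
        chain = assembly.get_chain(cid)
        if chain is None:
            continue
        for r in chain.residues:
            if r.number == int(num) and r.insertion_code == icode.strip():
                r.ss_code = code.strip()
                n += 1
    return n


# ---------------------------------------------------------------------------
# missing atoms
# ---------------------------------------------------------------------------

def flag_missing_atoms(residue: Residue,
                       template: ComponentTemplate | None) -> bool | None:
    """True iff an expected heavy (non-OXT) atom is absent.

    Unknown components (no template) return None — flagged "unknown",
    never silently complete.  The result is also stored on the residue.
    """
    if template is None:
        residue.missing_atoms = None
        return None
    expected = template.expected_heavy_atoms
    observed = {a.name for a in residue.atoms}
    residue.missing_atoms = bool(expected - observed)
    return residue.missing_atoms


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def structure_summary(assembly: Assembly) -> dict:
    return {
        "pdb_id": assembly.pdb_id,
        "assembly": assembly.serial,
        "n_chains": len(assembly.chains),
        "n_atoms": assembly.n_atoms(),
        "chains": [
            {
                "id": c.id,
                "entity_type": c.entity_type,
                "n_residues": len(c.residues),
                "observed_sequence": c.observed_sequence(),
                "full_sequence": c.full_sequence,
            }
            for c in assembly.chains
        ],
    }


def missing_regions_tsv(regions: list[MissingRegion]) -> str:
    lines = ["chain\tstart\tend\tflank_start\tflank_end\tterminal"]
    for r in regions:
        lines.append(f"{r.chain_id}\t{r.start}\t{r.end}\t"
                     f"{r.flanking[0] if r.flanking[0] is not None else '.'}\t"
                     f"{r.flanking[1] if r.flanking[1] is not None else '.'}\t"
                     f"{int(r.terminal)}")
    return "\n".join(lines) + "\n"


def ss_fragments_tsv(fragments: list[SSFragment]) -> str:
    lines = ["chain\tindex\tcode\tstart\tend\tsequence"]
    for f in fragments:
        idx = f.index if f.index is not None else "."
        lines.append(f"{f.chain_id}\t{idx}\t{f.ss_code}\t{f.start}\t"
                     f"{f.end}\t{f.sequence}")
    return "\n".join(lines) + "\n"
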