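import math

import numpy as np
import pytest

from structprof import fixtures as fx
from structprof.contacts import profile_contacts
from structprof.model import Assembly, Atom, Chain, Residue, parse_structure


@pytest.fixture(scope="session")
def store():
    return fx.fixture_templates()


@pytest.fixture(scope="session")
def toy():
    text, gt = fx.make_toy_complex(7)
    return parse_structure(text, "pdb"), gt


@pytest.fixture(scope="session")
def toy_profile(toy, store):
    asm, gt = toy
    return profile_contacts(asm, store), gt


def build_assembly(residue_specs, pdb_id="TEST", chain_id="A",
                   polymer=False):
    """Assemble model objects directly: [(resname, resnum, [(atom, el,
    xyz), ...]), ...] -> Assembly."""
    chain = Chain(id=chain_id, entity_type="polypeptide" if polymer
                  else "nonpolymer")
    serial = 0
    for resname, resnum, atoms in residue_specs:
        res = Residue(name=resname, number=resnum, is_polymer=polymer,
                      chain=chain)
        for name, el, xyz in atoms:
            serial += 1
            res.atoms.append(Atom(serial=serial, name=name, element=el,
                                  coords=np.asarray(xyz, dtype=float),
                                  parent=res))
        chain.residues.append(res)
    return Assembly(pdb_id=pdb_id, serial=0, chains=[chain])


def hexagon(center=(0.0, 0.0, 0.0), radius=1.39, z=0.0):
    c = np.asarray(center, dtype=float)
    return [c + np.array([radius * math.cos(k * math.pi / 3),
                          radius * math.sin(k * math.pi / 3), z])
            for k in range(6)]


def ring_extension(start, end, n):
    """Remaining n-2 vertices of a regular planar n-gon traversed
    start -> end -> ... -> start, extended away from the origin."""
    start, end = np.asarray(start, float), np.asarray(end, float)
    side = end - start
    best = None
    for sign in (1.0, -1.0):
        ext = math.radians(sign * 360.0 / n)
        rot = np.array([[math.cos(ext), -math.sin(ext), 0],
                        [math.sin(ext), math.cos(ext), 0],
                        [0, 0, 1.0]])
        pts, d, p = [], side.copy(), end.copy()
        for _ in range(n - 2):
            d = rot @ d
            p = p + d
            pts.append(p.copy())
        centroid = np.mean([start, end] + pts, axis=0)
        if best is None or np.linalg.norm(centroid) > best[0]:
            best = (np.linalg.norm(centroid), pts)
    return best[1]


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def transform_assembly(asm, rot, shift):
    for atom in asm.iter_atoms():
        atom.coords = rot @ atom.coords + shift
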