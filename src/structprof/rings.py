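"""Aromatic ring-ring and atom-ring interaction geometry.

Ring pairs are classified into nine geometry groups by cross-binning the
inter-plane dihedral and the angle theta between the first ring's normal
and the centroid-centroid vector, three half-open 30-degree bins each:

              theta [0,30)   [30,60)   [60,90]
 dihedral
 [0,30)          FF            OF         EE      (parallel: face/offset/edge)
 [30,60)         FT            OT         ET      (tilted)
 [60,90]         FE            OE         EF      (perpendicular / T-shaped)

All angles are sign-insensitive and folded into [0, 90].  Atom-ring
interactions keep only approaches with theta <= 30.0 degrees (measured
between the ring normal and the centroid->atom vector) and are labelled by
the approaching atom's chemistry with priority
cation-pi > halogen-pi > donor-pi > carbon-pi > undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemtypes import AromaticRing
from .config import ProfilerConfig, default_config
from .model import Atom

# row-major: dihedral bin x theta bin
RING_CLASS_TABLE: tuple[tuple[str, str, str], ...] = (
    ("FF", "OF", "EE"),
    ("FT", "OT", "ET"),
    ("FE", "OE", "EF"),
)

ATOM_RING_LABELS = ("cation_pi", "halogen_pi", "donor_pi", "carbon_pi",
                    "undefined")


class RingGeometryError(ValueError):
    pass


@dataclass
class RingRingInteraction:
    ring_a: AromaticRing
    ring_b: AromaticRing
    centroid_distance: float
    dihedral: float
    theta_a: float
    theta_b: float
    class_label: str


@dataclass
class AtomRingInteraction:
    atom: Atom
    ring: AromaticRing
    centroid_distance: float
    theta: float
    label: str


def _fold_angle(cos_value: float) -> float:
    """Angle in degrees folded into [0, 90] (sign-insensitive)."""
    c = min(1.0, abs(float(cos_value)))
    return float(np.degrees(np.arccos(c)))


def ring_ring_geometry(a: AromaticRing, b: AromaticRing,
                       ) -> tuple[float, float, float, float]:
    """(centroid_distance, dihedral, theta_a, theta_b), angles in [0,90]."""
    v = b.centroid - a.centroid
    d = float(np.linalg.norm(v))
    if d < 1e-6:
        raise RingGeometryError("coincident ring centroids")
    u = v / d
    dihedral = _fold_angle(np.dot(a.normal, b.normal))
    theta_a = _fold_angle(np.dot(a.normal, u))
    theta_b = _fold_angle(np.dot(b.normal, u))
    return d, dihedral, theta_a, theta_b


def _bin30(angle: float) -> int:
    """Half-open 30-degree bins over [0,90]; 90 falls in the last bin."""
    if not 0.0 <= angle <= 90.0:
        raise RingGeometryError(f"angle out of [0,90]: {angle}")
    return min(int(angle // 30.0), 2)


def classify_ring_ring(dihedral: float, theta: float,
                       table=RING_CLASS_TABLE) -> str:
    """Nine-group geometry class from (dihedral, theta) bins."""
    return table[_bin30(dihedral)][_bin30(theta)]


def detect_ring_ring(rings: list[AromaticRing],
                     config: ProfilerConfig | None = None,
                     ) -> list[RingRingInteraction]:
    """All ring pairs with centroid distance within the recording cutoff.

    By convention theta for the pair classification is theta_a, with
    ring_a the canonically first ring (chain id, residue number, first
    atom serial).
    """
    cfg = config or default_config()
    cutoff = cfg.rings.ring_ring_cutoff

    def key(r: AromaticRing):
        return (r.owner.chain.id if r.owner.chain else "",
                r.owner.sort_key, r.atoms[0].serial)

    ordered = sorted(rings, key=key)
    out: list[RingRingInteraction] = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            if a.owner is b.owner and set(a.atoms) & set(b.atoms):
                continue  # fused rings of one system are not an interaction
            d, dihedral, theta_a, theta_b = ring_ring_geometry(a, b)
            if d > cutoff:
                continue
            out.append(RingRingInteraction(
                a, b, d, dihedral, theta_a, theta_b,
                classify_ring_ring(dihedral, theta_a)))
    return out


def atom_ring_theta(atom_coords: np.ndarray, ring: AromaticRing,
                    ) -> tuple[float, float]:
    """(centroid distance, theta) for an atom over a ring."""
    v = atom_coords - ring.centroid
    d = float(np.linalg.norm(v))
    if d < 1e-6:
        raise RingGeometryError("atom coincides with ring centroid")
    return d, _fold_angle(np.dot(ring.normal, v / d))


def label_atom_ring(atom: Atom) -> str:
    f = getattr(atom, "flags", None)
    if f is None:
        return "undefined"
    if f.pos_ionisable:
        return "cation_pi"
    if f.halogen_donor:
        return "halogen_pi"
    if f.hbond_donor:
        return "donor_pi"
    if atom.element == "C" and f.weak_donor:
        return "carbon_pi"
    return "undefined"


def detect_atom_ring(atoms: list[Atom], rings: list[AromaticRing],
                     dist_cutoff: float | None = None,
                     config: ProfilerConfig | None = None,
                     ) -> list[AtomRingInteraction]:
    """Typed atom-over-ring approaches.

    A record is kept iff the atom is not part of the ring's own residue
    (which covers members and bonded substituents), its centroid distance
    is within the cutoff and theta is within the false-positive filter
    (default 30.0 degrees).
    """
    cfg = config or default_config()
    cutoff = dist_cutoff if dist_cutoff is not None else cfg.rings.atom_ring_cutoff
    max_theta = cfg.rings.atom_ring_max_theta
    out: list[AtomRingInteraction] = []
    for ring in rings:
        for atom in atoms:
            if atom.parent is ring.owner:
                continue
            d, theta = atom_ring_theta(atom.coords, ring)
            if d > cutoff or theta > max_theta:
                continue
            out.append(AtomRingInteraction(atom, ring, d, theta,
                                           label_atom_ring(atom)))
    return out


def ring_pairs_tsv(assembly, interactions: list[RingRingInteraction]) -> str:
    lines = ["ring_a\tring_b\tdistance\tdihedral\ttheta_a\ttheta_b\tclass"]
    for ix in interactions:
        pa = assembly.residue_path(ix.ring_a.owner)
        pb = assembly.residue_path(ix.ring_b.owner)
        lines.append(f"{pa}\t{pb}\t{ix.centroid_distance:.3f}\t"
                     f"{ix.dihedral:.1f}\t{ix.theta_a:.1f}\t"
                     f"{ix.theta_b:.1f}\t{ix.class_label}")
    return "\n".join(lines) + "\n"


def atom_rings_tsv(assembly, interactions: list[AtomRingInteraction]) -> str:
    lines = ["atom\tring_owner\tdistance\ttheta\tlabel"]
    for ix in interactions:
        pa = assembly.atom_path(ix.atom)
        pr = assembly.residue_path(ix.ring.owner)
        lines.append(f"{pa}\t{pr}\t{ix.centroid_distance:.3f}\t"
                     f"{ix.theta:.1f}\t{ix.label}")
    return "\n".join(lines) + "\n"
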