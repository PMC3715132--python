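"""Central configuration: every numeric default used by the profiler.

All cutoffs live in one dataclass so that a single TOML file can override
any of them (``profiler --config cutoffs.toml``).  The values below are the
package defaults and the single source of truth referenced by the docs.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field


# Van der Waals radii (Å) used for the distance-bin arithmetic.  This is a
# Pauling-style table (O 1.40, N 1.50) rather than Bondi; elements missing
# here fall back to gemmi's tabulated radii.
VDW_RADII: dict[str, float] = {
    "H": 1.09, "C": 1.70, "N": 1.50, "O": 1.40, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90, "B": 1.92,
}

# Elements treated as metals for metal-complex typing.
METALS = {
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "CO",
    "NI", "CU", "ZN", "CD", "HG", "AL", "GA", "V", "CR", "MO", "W", "PT",
    "PD", "AU", "AG",
}

HALOGENS = {"CL", "BR", "I"}


@dataclass
class DistanceBins:
    """Offsets defining the five mutually exclusive distance bins.

    A contact falls into the first bin whose inequality it satisfies, in
    the order clash < covalent < vdw_clash < vdw < proximal.
    """

    clash_offset: float = -0.4        # d < r_cov(a)+r_cov(b) + clash_offset
    covalent_offset: float = 0.1      # d < r_cov sum + covalent_offset
    vdw_clash_offset: float = -0.1    # d < r_vdw sum + vdw_clash_offset
    vdw_offset: float = 0.1           # d <= r_vdw sum + vdw_offset
    proximal: float = 6.0             # d <= proximal  (global storage cutoff)


@dataclass
class FeatureCutoffs:
    """Per-feature distance (Å) and angle (deg) constraints."""

    hbond: float = 3.5
    hbond_min_donor_angle: float = 90.0
    weak_hbond: float = 3.6
    halogen_tolerance: float = 0.1    # d <= r_vdw sum + tolerance
    halogen_min_angle: float = 120.0  # C-X...A
    ionic: float = 4.0
    metal: float = 2.8
    aromatic_centroid: float = 4.5    # ring-ring centroid, projected to atoms
    hydrophobic: float = 4.5
    carbonyl: float = 3.6


@dataclass
class RingConfig:
    ring_ring_cutoff: float = 6.0         # recording cutoff, centroid-centroid
    ring_ring_display_cutoff: float = 4.0  # export default for visualisation
    atom_ring_cutoff: float = 4.5          # recording cutoff, centroid-atom
    atom_ring_max_theta: float = 30.0      # deg; beyond this nothing is stored
    planarity_rms_tol: float = 0.1         # Å, ring plane fit


@dataclass
class ExposureConfig:
    probe_radius: float = 1.4   # Å
    min_sasa: float = 0.1       # Å²; atom exposed iff SASA >= this
    n_points: int = 300         # Shrake-Rupley sphere points


@dataclass
class LigandConfig:
    max_peptide_length: int = 10       # chains up to this length are ligands
    bond_cutoff: float = 1.9           # Å, inter-residue covalent inference
    bond_cutoff_sp: float = 2.2        # Å, when S or P is involved


@dataclass
class QualityConfig:
    min_interface_residues: int = 10   # per side, for the interface flag


@dataclass
class DescriptorConfig:
    min_site_heavy_atoms: int = 7      # FuzCav/USRCAT ligand eligibility
    max_conformers: int = 25
    fuzcav_bin_edges: tuple[float, ...] = (4.0, 6.0, 9.0, 13.0, 18.0)
    sift_linkage: str = "average"
    sift_metric: str = "jaccard"


@dataclass
class StructureConfig:
    ss_collapse: bool = True          # 8-state DSSP -> {H, E, C}
    ss_count_coil: bool = True        # coil runs get fragment ordinals too


@dataclass
class ProfilerConfig:
    """Bundle of every tunable threshold, with documented defaults."""

    distance: DistanceBins = field(default_factory=DistanceBins)
    features: FeatureCutoffs = field(default_factory=FeatureCutoffs)
    rings: RingConfig = field(default_factory=RingConfig)
    exposure: ExposureConfig = field(default_factory=ExposureConfig)
    ligands: LigandConfig = field(default_factory=LigandConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProfilerConfig":
        cfg = cls()
        for section, values in d.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section: {section}")
            sub = getattr(cfg, section)
            for key, val in values.items():
                if not hasattr(sub, key):
                    raise KeyError(f"unknown config key: {section}.{key}")
                if isinstance(getattr(sub, key), tuple):
                    val = tuple(val)
                setattr(sub, key, val)
        return cfg

    @classmethod
    def from_toml(cls, path: str) -> "ProfilerConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def default_config() -> ProfilerConfig:
    return ProfilerConfig()


def vdw_radius(element: str) -> float:
    """vdW radius in Å; package table first, gemmi as fallback."""
    el = element.upper()
    if el in VDW_RADII:
        return VDW_RADII[el]
    import gemmi

    r = gemmi.Element(element.capitalize()).vdw_r
    return float(r) if r > 0 else 1.7


def covalent_radius(element: str) -> float:
    import gemmi

    r = gemmi.Element(element.capitalize()).covalent_r
    return float(r) if r > 0 else 0.77
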