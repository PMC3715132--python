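"""Structure-precision metrics and per-entity quality flags.

The diffraction-component precision index (DPI) is a global estimate of
atomic coordinate uncertainty from refinement statistics.  We use the
distance (radial) form: Cruickshank's per-axis DPI scaled by sqrt(3) for
an isotropic radial error,

    DPI = sqrt(3) * sqrt(N_atoms / N_reflections) * C^(-1/3) * d_min * R

with R the free R-factor when available (flagged otherwise), C the data
completeness and d_min the nominal resolution.  The theoretically
smallest imprecision achievable at a given resolution evaluates the same
expression under ideal data: a full sphere of reflections to d_min
(about 20 Å³ of crystal volume per heavy atom, i.e. N_atoms/N_refl =
d_min³/20), completeness 1, and an empirical best-case free R that grows
linearly with resolution, R_best(d) = 0.03 + 0.05 d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import ProfilerConfig, default_config

# best-case free R-factor as a linear function of nominal resolution (Å)
R_BEST_INTERCEPT = 0.03
R_BEST_SLOPE = 0.05
# crystal volume per heavy atom (Å³) for the full-sphere reflection count
VOLUME_PER_ATOM = 20.0


class NotComputableError(ValueError):
    """Required structure-factor metadata is missing."""


@dataclass
class StructureFactors:
    r_factor: float
    d_min: float
    completeness: float
    n_atoms: int
    n_reflections: int
    r_free: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.r_factor < 1:
            raise ValueError("r_factor must be in (0,1)")
        if self.r_free is not None and not 0 < self.r_free < 1:
            raise ValueError("r_free must be in (0,1)")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if not 0 < self.completeness <= 1:
            raise ValueError("completeness must be in (0,1]")
        if self.n_reflections <= 0 or self.n_atoms <= 0:
            raise ValueError("atom/reflection counts must be positive")


@dataclass
class QualityReport:
    dpi: float | None
    min_dpi: float | None
    dpi_used_r_free: bool
    has_missing_binding_site_atoms: bool = False
    has_missing_interface_atoms: bool = False


def compute_dpi(sf: StructureFactors) -> float:
    """Radial-coordinate DPI in Å; prefers r_free, falls back to r_factor."""
    r = sf.r_free if sf.r_free is not None else sf.r_factor
    return (math.sqrt(3.0)
            * math.sqrt(sf.n_atoms / sf.n_reflections)
            * sf.completeness ** (-1.0 / 3.0)
            * sf.d_min * r)


def r_best(d_min: float) -> float:
    """Empirical best-case free R-factor at a nominal resolution."""
    return R_BEST_INTERCEPT + R_BEST_SLOPE * d_min


def compute_min_dpi(sf: StructureFactors) -> float:
    """Smallest radial DPI theoretically achievable at sf.d_min.

    Same expression as :func:`compute_dpi` with completeness 1, a full
    sphere of unique reflections to d_min and the best-case free R.
    Monotonically increasing in d_min.
    """
    d = sf.d_min
    na_over_no = d ** 3 / VOLUME_PER_ATOM
    return math.sqrt(3.0) * math.sqrt(na_over_no) * d * r_best(d)


def structure_factors_from_tsv(text: str) -> StructureFactors:
    """Read a key<TAB>value sidecar (r_factor, r_free, d_min, ...)."""
    fields: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        fields[key.strip()] = value.strip()
    required = ("r_factor", "d_min", "completeness", "n_atoms",
                "n_reflections")
    missing = [k for k in required if k not in fields]
    if missing:
        raise NotComputableError(
            "structure-factor metadata missing: " + ", ".join(missing))
    return StructureFactors(
        r_factor=float(fields["r_factor"]),
        d_min=float(fields["d_min"]),
        completeness=float(fields["completeness"]),
        n_atoms=int(fields["n_atoms"]),
        n_reflections=int(fields["n_reflections"]),
        r_free=float(fields["r_free"]) if "r_free" in fields else None,
    )


def structure_factors_from_mmcif(text: str) -> StructureFactors:
    """Extract refine/reflns metadata from an mmCIF header."""
    import gemmi.cif

    block = gemmi.cif.read_string(text).sole_block()

    def grab(tag: str) -> str | None:
        v = block.find_value(tag)
        return None if v in (None, ".", "?") else v

    r_factor = grab("_refine.ls_R_factor_R_work") or grab(
        "_refine.ls_R_factor_obs")
    r_free = grab("_refine.ls_R_factor_R_free")
    d_min = grab("_refine.ls_d_res_high") or grab(
        "_reflns.d_resolution_high")
    completeness = grab("_refine.ls_percent_reflns_obs")
    n_refl = grab("_refine.ls_number_reflns_obs") or grab(
        "_reflns.number_obs")
    n_atoms = grab("_refine_hist.number_atoms_total")
    missing = [name for name, v in (
        ("R factor", r_factor), ("resolution", d_min),
        ("completeness", completeness), ("reflection count", n_refl),
        ("atom count", n_atoms)) if v is None]
    if missing:
        raise NotComputableError(
            "mmCIF lacks " + ", ".join(missing))
    comp = float(completeness)
    if comp > 1.0:   # percent-valued category
        comp /= 100.0
    return StructureFactors(
        r_factor=float(r_factor), d_min=float(d_min), completeness=comp,
        n_atoms=int(float(n_atoms)), n_reflections=int(float(n_refl)),
        r_free=float(r_free) if r_free is not None else None)


def quality_flags(groups, sf: StructureFactors | None = None,
                  config: ProfilerConfig | None = None) -> QualityReport:
    """Per-assembly quality report from grouped interactions.

    The binding-site flag is raised iff any residue lining a binding site
    has missing atoms; the interface flag considers only interfaces with
    at least the configured number of interacting residues per side
    (default 10).
    """
    cfg = config or default_config()
    bs_flag = False
    if_flag = False
    for g in groups:
        if g.pair_class == "binding_site" and g.has_missing_atoms:
            bs_flag = True
        if (g.pair_class == "interface"
                and len(g.residues_a) >= cfg.quality.min_interface_residues
                and len(g.residues_b) >= cfg.quality.min_interface_residues
                and g.has_missing_atoms):
            if_flag = True
    dpi = min_dpi = None
    used_free = False
    if sf is not None:
        dpi = compute_dpi(sf)
        min_dpi = compute_min_dpi(sf)
        used_free = sf.r_free is not None
    return QualityReport(dpi, min_dpi, used_free, bs_flag, if_flag)
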