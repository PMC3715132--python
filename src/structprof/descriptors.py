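"""Binding-site, shape and interaction-matrix descriptors.

Three descriptor families live here:

* FuzCav-style cavity fingerprints — counts of pharmacophoric feature
  triplets over binding-site anchor atoms (Cα, or one representative
  side-chain atom per residue type) with binned triangle edge lengths.
  Alignment-free, permutation- and rigid-motion-invariant.
* USRCAT shape moments — the first three moments (mean, σ, cbrt of the
  third central moment) of the distance distributions from four reference
  points (centroid; closest / farthest atom to it; farthest from the
  farthest) over the all-atom set and four pharmacophoric subsets:
  5 subsets × 4 points × 3 moments = 60 numbers, rotation/translation
  invariant.
* UniProt-aligned SIFt matrices — one row per ligand, a 13-flag block per
  aligned reference-sequence position — with agglomerative clustering
  (Jaccard distance, average linkage by default) and neighbour queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations, combinations_with_replacement

import numpy as np

from .config import ProfilerConfig, default_config
from .contacts import FLAG_ORDER, Contact
from .chemtypes import LigandEntity
from .model import Residue

FUZCAV_FEATURES = ("donor", "acceptor", "positive", "negative",
                   "aromatic", "aliphatic")
USRCAT_SUBSETS = ("all", "hydrophobic", "aromatic", "donor", "acceptor")


def _load_table(filename: str) -> dict[str, tuple[str, ...]]:
    text = (resources.files("structprof") / "data" / filename).read_text()
    out: dict[str, tuple[str, ...]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        out[key] = tuple(value.split(","))
    return out


def residue_features() -> dict[str, tuple[str, ...]]:
    return _load_table("fuzcav_residue_features.tsv")


def sidechain_representatives() -> dict[str, str]:
    return {k: v[0] for k, v in
            _load_table("sidechain_representatives.tsv").items()}


# ---------------------------------------------------------------------------
# FuzCav-style cavity fingerprint
# ---------------------------------------------------------------------------

_FEATURE_COMBOS = list(combinations_with_replacement(range(6), 3))
_FEATURE_INDEX = {c: i for i, c in enumerate(_FEATURE_COMBOS)}


@dataclass
class FuzCavFingerprint:
    counts: np.ndarray
    mode: str   # "calpha" | "side_chain_rep"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def length(self) -> int:
        return len(self.counts)

    def nonzero_positions(self) -> np.ndarray:
        return np.nonzero(self.counts)[0]


def fingerprint_length(n_bins: int) -> int:
    n_bin_combos = len(list(combinations_with_replacement(range(n_bins), 3)))
    return len(_FEATURE_COMBOS) * n_bin_combos


def _bin_distance(d: float, edges: tuple[float, ...]) -> int:
    for i, e in enumerate(edges):
        if d < e:
            return i
    return len(edges)


def site_anchors(residues: list[Residue], mode: str = "calpha",
                 ) -> list[tuple[np.ndarray, tuple[int, ...]]]:
    """(anchor coordinates, feature index tuple) per eligible residue."""
    feats = residue_features()
    reps = sidechain_representatives()
    anchors = []
    for res in residues:
        if res.name not in feats:
            continue
        if mode == "calpha":
            anchor = res.get_atom("CA")
        elif mode == "side_chain_rep":
            anchor = res.get_atom(reps.get(res.name, "CA")) \
                or res.get_atom("CA")
        else:
            raise ValueError(f"unknown anchor mode: {mode}")
        if anchor is None:
            continue
        fidx = tuple(sorted(FUZCAV_FEATURES.index(f)
                            for f in feats[res.name]))
        anchors.append((anchor.coords, fidx))
    return anchors


def fuzcav_fingerprint(residues: list[Residue], mode: str = "calpha",
                       config: ProfilerConfig | None = None,
                       ) -> FuzCavFingerprint:
    """Triplet-count fingerprint over all anchor triples.

    Each triangle contributes one count per combination of one feature
    from each vertex, keyed by the (sorted) feature multiset and the
    (sorted) multiset of binned edge lengths.  Fewer than three anchors
    yield the zero vector with a warning.
    """
    cfg = config or default_config()
    edges = cfg.descriptors.fuzcav_bin_edges
    n_bins = len(edges) + 1
    bin_combos = list(combinations_with_replacement(range(n_bins), 3))
    bin_index = {c: i for i, c in enumerate(bin_combos)}
    counts = np.zeros(len(_FEATURE_COMBOS) * len(bin_combos), dtype=np.int64)
    anchors = site_anchors(residues, mode)
    if len(anchors) < 3:
        warnings.warn(f"only {len(anchors)} anchor atoms; returning the "
                      f"zero fingerprint")
        return FuzCavFingerprint(counts, mode)
    for (ca, fa), (cb, fb), (cc, fc) in combinations(anchors, 3):
        bins = tuple(sorted((
            _bin_distance(float(np.linalg.norm(ca - cb)), edges),
            _bin_distance(float(np.linalg.norm(ca - cc)), edges),
            _bin_distance(float(np.linalg.norm(cb - cc)), edges))))
        b_idx = bin_index[bins]
        for x in fa:
            for y in fb:
                for z in fc:
                    f_idx = _FEATURE_INDEX[tuple(sorted((x, y, z)))]
                    counts[f_idx * len(bin_combos) + b_idx] += 1
    return FuzCavFingerprint(counts, mode)


def fuzcav_similarity(a: FuzCavFingerprint, b: FuzCavFingerprint,
                      metric: str = "tanimoto") -> float:
    """Similarity in [0,1]; symmetric; 1 for identical nonzero prints.

    ``tanimoto``          Σ min / Σ max over counts (global profile).
    ``normalized_shared`` shared nonzero positions / union of nonzero.
    ``local``             shared nonzero positions / smaller support —
                          rewards a site contained within a larger one.
    """
    if a.mode != b.mode or a.length != b.length:
        raise ValueError("fingerprints of different mode/length")
    x, y = a.counts, b.counts
    if not x.any() and not y.any():
        warnings.warn("similarity of two empty fingerprints defined as 0")
        return 0.0
    nx, ny = x > 0, y > 0
    shared = int(np.sum(nx & ny))
    if metric == "tanimoto":
        return float(np.minimum(x, y).sum() / np.maximum(x, y).sum())
    if metric == "normalized_shared":
        union = int(np.sum(nx | ny))
        return shared / union if union else 0.0
    if metric == "local":
        smaller = min(int(nx.sum()), int(ny.sum()))
        return shared / smaller if smaller else 0.0
    raise ValueError(f"unknown metric: {metric}")


def site_eligible(ligand: LigandEntity, contacts: list[Contact],
                  config: ProfilerConfig | None = None) -> bool:
    """Sites are fingerprinted only for ligands with at least seven heavy
    atoms whose contacts never carry the clash flag."""
    cfg = config or default_config()
    if ligand.heavy_atom_count < cfg.descriptors.min_site_heavy_atoms:
        return False
    lig_ids = {id(a) for a in ligand.atoms()}
    for c in contacts:
        if (id(c.atom_a) in lig_ids or id(c.atom_b) in lig_ids) \
                and c.flags.clash:
            return False
    return True


# ---------------------------------------------------------------------------
# USRCAT shape moments
# ---------------------------------------------------------------------------

@dataclass
class USRCATDescriptor:
    moments: np.ndarray   # 60 = 5 subsets x 4 reference points x 3 moments

    def __post_init__(self) -> None:
        self.moments = np.asarray(self.moments, dtype=float)
        if self.moments.shape != (60,):
            raise ValueError("USRCAT descriptor must have 60 components")


def _three_moments(d: np.ndarray) -> tuple[float, float, float]:
    mean = float(d.mean())
    sigma = float(d.std())
    third = float(np.mean((d - mean) ** 3))
    return mean, sigma, float(np.cbrt(third))


def usrcat_moments(coords: np.ndarray,
                   subsets: dict[str, np.ndarray] | None = None,
                   ) -> USRCATDescriptor:
    """Shape moments of one conformer.

    ``coords``: (n, 3) heavy-atom coordinates, n >= 3 and non-collinear.
    ``subsets``: index arrays into ``coords`` for the pharmacophoric
    subsets (hydrophobic, aromatic, donor, acceptor); missing or empty
    subsets produce zero blocks.  Reference points are always computed
    from the full atom set.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 3:
        raise ValueError("need at least 3 atoms with 3D coordinates")
    if np.linalg.matrix_rank(coords - coords.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    subsets = subsets or {}

    ctd = coords.mean(axis=0)
    d_ctd = np.linalg.norm(coords - ctd, axis=1)
    cst = coords[int(np.argmin(d_ctd))]
    fct = coords[int(np.argmax(d_ctd))]
    ftf = coords[int(np.argmax(np.linalg.norm(coords - fct, axis=1)))]
    refs = (ctd, cst, fct, ftf)

    out: list[float] = []
    for name in USRCAT_SUBSETS:
        if name == "all":
            sel = coords
        else:
            idx = np.asarray(subsets.get(name, []), dtype=int)
            sel = coords[idx] if idx.size else None
        for ref in refs:
            if sel is None or len(sel) == 0:
                out.extend((0.0, 0.0, 0.0))
            else:
                out.extend(_three_moments(
                    np.linalg.norm(sel - ref, axis=1)))
    return USRCATDescriptor(np.array(out))


def usrcat_similarity(a: USRCATDescriptor, b: USRCATDescriptor,
                      weights: np.ndarray | None = None) -> float:
    """Inverse scaled Manhattan deviation, in (0, 1]; 1 iff identical.

    S = 1 / (1 + (1/12) Σ_s w_s Σ_i |a_si - b_si|), unit weights default.
    """
    w = np.ones(5) if weights is None else np.asarray(weights, dtype=float)
    diff = np.abs(a.moments - b.moments).reshape(5, 12).sum(axis=1)
    return float(1.0 / (1.0 + (w * diff).sum() / 12.0))


def usrcat_ensemble(conformers: list[np.ndarray],
                    subsets: dict[str, np.ndarray] | None = None,
                    config: ProfilerConfig | None = None,
                    ) -> list[USRCATDescriptor]:
    """Moments for up to the configured maximum number of conformers (25)."""
    cfg = config or default_config()
    used = conformers[: cfg.descriptors.max_conformers]
    return [usrcat_moments(c, subsets) for c in used]


def ligand_usrcat_subsets(ligand: LigandEntity) -> dict[str, np.ndarray]:
    """Pharmacophoric subset indices from per-atom type flags."""
    atoms = ligand.atoms()
    idx = {name: [] for name in USRCAT_SUBSETS if name != "all"}
    for i, a in enumerate(atoms):
        f = getattr(a, "flags", None)
        if f is None:
            continue
        if f.hydrophobe:
            idx["hydrophobic"].append(i)
        if f.aromatic:
            idx["aromatic"].append(i)
        if f.hbond_donor:
            idx["donor"].append(i)
        if f.hbond_acceptor:
            idx["acceptor"].append(i)
    return {k: np.array(v, dtype=int) for k, v in idx.items()}


# ---------------------------------------------------------------------------
# UniProt-aligned SIFt matrices and clustering
# ---------------------------------------------------------------------------

class MappingError(ValueError):
    pass


@dataclass
class SIFtMatrix:
    data: "object"              # pandas DataFrame, bool
    positions: tuple[int, ...]  # aligned reference positions (column blocks)

    @property
    def ligand_ids(self) -> list[str]:
        return list(self.data.index)

    def row(self, ligand_id: str) -> np.ndarray:
        return self.data.loc[ligand_id].to_numpy()


def read_residue_mapping(tsv_text: str) -> dict[tuple[str, int], int]:
    """chain<TAB>residue_number<TAB>reference_position."""
    out: dict[tuple[str, int], int] = {}
    for line in tsv_text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chain, num, pos = line.split("\t")
        out[(chain, int(num))] = int(pos)
    return out


def build_sift_matrix(
        ligand_flags: dict[str, dict[tuple[str, int], set[str]]],
        mapping: dict[tuple[str, int], int]) -> SIFtMatrix:
    """Stack per-ligand residue interaction flags into an aligned matrix.

    ``ligand_flags``: ligand id -> {(chain, residue number) -> set of
    flag names} — the union of SIFt flags over all contacts between that
    ligand and that residue.  Residues without a mapping are dropped with
    a warning; two residues of one ligand's structure mapping to the same
    reference position raise :class:`MappingError`.
    """
    import pandas as pd

    rows: dict[str, dict[tuple[int, str], bool]] = {}
    used_positions: set[int] = set()
    for lig, res_flags in ligand_flags.items():
        seen: dict[int, tuple[str, int]] = {}
        row: dict[tuple[int, str], bool] = {}
        for res_key, flags in res_flags.items():
            if res_key not in mapping:
                warnings.warn(f"residue {res_key} has no reference mapping; "
                              f"dropped from the matrix")
                continue
            pos = mapping[res_key]
            if pos in seen and seen[pos] != res_key:
                raise MappingError(
                    f"residues {seen[pos]} and {res_key} both map to "
                    f"reference position {pos}")
            seen[pos] = res_key
            used_positions.add(pos)
            for f in flags:
                if f not in FLAG_ORDER:
                    raise ValueError(f"unknown SIFt flag: {f}")
                row[(pos, f)] = True
        rows[lig] = row

    positions = tuple(sorted(used_positions))
    columns = pd.MultiIndex.from_tuples(
        [(p, f) for p in positions for f in FLAG_ORDER],
        names=["position", "flag"])
    df = pd.DataFrame(False, index=list(ligand_flags), columns=columns,
                      dtype=bool)
    for lig, row in rows.items():
        for key, val in row.items():
            df.loc[lig, key] = val
    return SIFtMatrix(df, positions)


@dataclass
class ClusterTree:
    linkage: np.ndarray          # scipy linkage matrix
    leaf_ids: list[str]
    distances: np.ndarray        # condensed pairwise distance vector

    def top_split(self) -> tuple[set[str], set[str]]:
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.linkage, t=2, criterion="maxclust")
        g1 = {l for l, lab in zip(self.leaf_ids, labels) if lab == 1}
        g2 = {l for l, lab in zip(self.leaf_ids, labels) if lab == 2}
        return g1, g2

    def neighbour(self, ligand_id: str) -> str:
        """Most similar interaction row to the given ligand (self excluded)."""
        from scipy.spatial.distance import squareform

        i = self.leaf_ids.index(ligand_id)
        dm = squareform(self.distances)
        dm[i, i] = np.inf
        return self.leaf_ids[int(np.argmin(dm[i]))]

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        from scipy.cluster.hierarchy import to_tree

        root = to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.leaf_ids[node.id]
            length_l = node.dist - node.left.dist
            length_r = node.dist - node.right.dist
            return (f"({rec(node.left)}:{length_l:.6g},"
                    f"{rec(node.right)}:{length_r:.6g})")

        return rec(root) + ";"


def cluster_sifts(matrix: SIFtMatrix, linkage: str | None = None,
                  metric: str | None = None,
                  config: ProfilerConfig | None = None) -> ClusterTree:
    """Agglomerative clustering of SIFt rows (Jaccard + average default)."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    cfg = config or default_config()
    linkage = linkage or cfg.descriptors.sift_linkage
    metric = metric or cfg.descriptors.sift_metric
    arr = matrix.data.to_numpy(dtype=bool)
    if arr.shape[0] < 2:
        raise ValueError("need at least two ligand rows to cluster")
    dist = pdist(arr, metric=metric)
    dist = np.nan_to_num(dist, nan=0.0)   # jaccard of two empty rows
    z = hierarchy.linkage(dist, method=linkage)
    return ClusterTree(z, matrix.ligand_ids, dist)


def sift_rows_from_contacts(result, ligands=None
                            ) -> dict[str, dict[tuple[str, int], set[str]]]:
    """Per-ligand residue->flag-set map from a contact profile."""
    from .contacts import EntityMap

    emap = result.entity_map
    ligands = ligands if ligands is not None else result.ligands
    wanted = {id(l): l for l in ligands}
    out: dict[str, dict[tuple[str, int], set[str]]] = {
        str(l.path_id): {} for l in ligands}
    for c in result.contacts:
        if c.is_intramolecular:
            continue
        ea, eb = emap.entity_of(c.atom_a), emap.entity_of(c.atom_b)
        for lig_ent, other_atom in ((ea, c.atom_b), (eb, c.atom_a)):
            if id(lig_ent) not in wanted:
                continue
            other_ent = eb if lig_ent is ea else ea
            if EntityMap.entity_kind(other_ent) != "polypeptide":
                continue
            res = other_atom.parent
            key = (res.chain.id, res.number)
            out[str(wanted[id(lig_ent)].path_id)].setdefault(
                key, set()).update(c.flags.set_features())
    return out
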