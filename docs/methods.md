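# Methods

`structprof` annotates macromolecular structures with typed pairwise
atomic interactions and a set of derived descriptors.  This note records
the models and procedures implemented, the numerical choices behind them,
and what the synthetic test structures do and do not demonstrate.

## Structure model and stable identifiers

Structures (PDB or mmCIF) are parsed with gemmi into a four-level
hierarchy — assembly / chain / residue / atom — using the first model
only and heavy atoms only.  Assembly serial 0 denotes the asymmetric
unit; serial ≥ 1 marks a pre-generated biological-assembly coordinate
file supplied by the user (symmetry expansion is out of scope, and chain
identifiers must be unique within an input file).

Alternate locations are resolved deterministically: the alt-loc group
with the highest summed occupancy is kept, ties broken alphabetically.
Files that encode two distinct orientations as alternate location groups
with *different residue identifiers* at one position are rejected with a
structured `UnsupportedRepresentationError` — such files are ambiguous
and guessing would silently corrupt the contact census.

Every entity carries a path-tree stable identifier of the form
`PDB/assembly/chain/NAME`NUM[/atom]`, e.g. ``2P33/0/A/J07`507``.  Two
query operations are provided with PostgreSQL-ltree-like semantics: a
*descendant* test (prefix containment) and a wildcard *match* where a
bare `*` level spans zero or more levels and a `*` embedded in a token
matches within one level (so `*/STI*` finds every entity whose last
level starts with `STI` at any depth).

Missing regions are maximal gaps in author numbering of polymer chains;
terminal gaps are reported only when a SEQRES-equivalent reference
sequence fixes the chain length, under the assumption that author
numbering starts at 1 and aligns with that sequence.  Secondary-structure
fragments are maximal runs of residues sharing one SS code; a numbering
gap terminates a run.  Eight-state DSSP codes are collapsed to
{H, E, C} (H/G/I → H, E/B → E, rest → C) before splitting by default;
fragment ordinals count every run including coil (a `count_coil=False`
switch numbers only helix/strand runs, since the original ordinal
convention is not documented).  SS codes are inputs (per-residue TSV or
any pluggable assigner); no external assigner binary is required.

## Atom typing and perception

Typing is template-driven: connectivity, bond orders, aromatic flags and
formal charges come from chemical-component templates (the component
dictionary bundled with biotite, a CCD-style mmCIF reader for custom
components, or programmatic registration).  Hydrogens are never required
in coordinates; donor capacity is read from template hydrogens, or from
free valence when a template is heavy-atom-only.  Eleven boolean flags
are assigned per atom: donor, acceptor, weak (carbon) donor,
positive/negative ionisable, aromatic, halogen donor (C-bound Cl/Br/I),
hydrophobe, metal, carbonyl carbon/oxygen.  Ionisation uses
physiological-pH heuristics (amines/amidines/guanidinium positive unless
amide- or aryl-bound; carboxylate/phosphate/sulfate oxygens negative).
The backbone nitrogen of polymer amino acids is forced non-ionisable —
the residue-local template cannot see the peptide bond.

Ligands are the connected components of non-water hetero residues, with
inter-residue covalent links inferred at < 1.9 Å (< 2.2 Å with S or P).
Polypeptide chains up to 10 residues count as heteropeptide ligands.
Aromatic rings are the smallest cycles of template-aromatic bonds
(fused systems give one ring per constituent cycle); each ring stores
the exact centroid and a least-squares (SVD) unit normal, and is
rejected with a warning if the out-of-plane RMS exceeds 0.1 Å.
Aromaticity is dictionary-faithful, never recomputed electronically.

## Contacts and the 13-flag interaction fingerprint

All heavy-atom pairs within 6.0 Å are enumerated with a k-d tree
(validated against an all-pairs scan).  Same-residue pairs and 1-2/1-3
bonded pairs are excluded everywhere.  Each stored contact carries five
mutually exclusive distance bins — the first satisfied inequality wins —

| bin | condition |
|---|---|
| clash | d < Σr_cov − 0.4 |
| covalent | d < Σr_cov + 0.1 |
| vdw_clash | d < Σr_vdw − 0.1 |
| vdw | d ≤ Σr_vdw + 0.1 |
| proximal | d ≤ 6.0 |

and eight feature flags with type + distance + geometry constraints:
hydrogen bond (≤ 3.5 Å, every donor-neighbour angle ≥ 90°), weak
hydrogen bond (carbon donor, ≤ 3.6 Å), halogen bond (≤ Σr_vdw + 0.1 Å,
C–X···A ≥ 120°), ionic (≤ 4.0 Å, opposite ionisable flags), metal
complex (≤ 2.8 Å), aromatic (both atoms in rings whose centroids are
≤ 4.5 Å apart), hydrophobic (≤ 4.5 Å between hydrophobes), carbonyl
(≤ 3.6 Å between the carbon of one C=O and the oxygen of another).  The
van der Waals radii table (C 1.70, N 1.50, O 1.40, S/P 1.80, Cl 1.75 …)
ships in `config.py`; every cutoff is a documented config value and a
single TOML file overrides any of them.

Inter-entity contacts are grouped by unordered entity pair and typed by
the entity-kind matrix: polypeptide×ligand → *binding site*,
polypeptide×polypeptide → *interface*, polypeptide×oligonucleotide →
*groove*, ligand×ligand and ligand×oligonucleotide for the less familiar
interaction classes.  Intramolecular contacts are stored but never
grouped; waters are excluded from the census by default.

Surface exposure is computed per entity, never for the whole assembly
(a pocket-buried ligand is still exposed as an isolated molecule), with
Shrake–Rupley solvent-accessible surface area at probe 1.4 Å; an atom is
exposed iff its SASA ≥ 0.1 Å².

## Ring interaction geometry

For a ring pair, the inter-plane dihedral and the angle θ between the
first ring's normal and the centroid–centroid vector are folded into
[0°, 90°] (all quantities are sign-insensitive; the normal is a
pseudo-vector and downstream angles never depend on its sign).  Pairs
within 6.0 Å are classified by cross-binning dihedral × θ into three
half-open 30° bins each, giving the nine geometry groups
FF/OF/EE/FT/OT/ET/FE/OE/EF (face-to-face through edge-tilted classes);
the table is data and can be swapped.  θ of the pair is θ of the
canonically first ring (chain, residue number, first atom serial); bins
are half-open so boundary values classify deterministically.  Atom–ring
records keep approaches within 4.5 Å of the centroid with θ ≤ 30.0° (the
false-positive filter) and are labelled by atom chemistry with priority
cation-π > halogen-π > donor-π > carbon-π > undefined (the priority
order is a package decision; the underlying labels have no documented
precedence).

## Coordinate precision (DPI)

The diffraction-component precision index implemented here is the radial
(distance) form of Cruickshank's per-axis DPI:

    DPI = √3 · √(N_atoms / N_refl) · C^(−1/3) · d_min · R

with R the free R-factor when available (the report notes the fallback),
C completeness and d_min the nominal resolution.  The theoretical floor
at a given resolution evaluates the same expression under ideal data — a
full sphere of unique reflections to d_min, approximated as one heavy
atom per 20 Å³ of crystal so N_atoms/N_refl = d_min³/20, completeness 1 —
with an empirical best-case free R line R_best(d) = 0.03 + 0.05·d.  Both
constants live in `quality.py`; the floor is monotone in d_min and stays
below the computed DPI whenever the achieved free R exceeds the
best-case line.  Metadata comes from mmCIF refine/reflns categories or a
key–value TSV sidecar; reflection data are never parsed, and missing
fields give an explicit "not computable" error, never a guess.

Boolean quality flags report missing heavy atoms in residues lining
binding sites, and in interfaces with at least 10 interacting residues
per side (smaller interfaces do not raise the flag).

## Fragmentation and fragment contact density

Ligand chemistry (from a component template or SMILES) is cleaved
recursively at rule-defined acyclic bonds: the eleven classic
retrosynthetic bond classes plus a phosphate-ester extension for
phosphate-containing natural products.  Rules are SMARTS patterns with
the cleaved atom pair, shipped as versioned package data; matching and
bond cleavage use RDKit, with single dummy-atom caps marking cut points.
Fragmentation is deterministic (lowest cleavable bond first) and leaves
partition the parent's heavy atoms exactly; caps are excluded from all
counts and from the atom map back onto structure atoms (by atom name,
hence independent of input atom order; multi-residue ligands are not
fragmented).

Fragment contact density is

    FCD = (C_f / A_f) / (C_l / A_l)

where C_f and C_l count contact *endpoints* on fragment and ligand atoms
(an atom in k contacts contributes k) and A_f, A_l are heavy-atom
counts.  By default only inter-entity contacts carrying at least one
feature flag count; an all-contacts mode counts every stored contact
(the original definition does not qualify "contacts", so both modes are
exposed).  FCD is exactly 1 for the whole ligand, Σ (A_f/A_l)·FCD_f = 1
over any leaf partition, C_l = 0 gives an explicit undefined marker
rather than 0, and uniform duplication of contacts cancels.

## Binding-site and shape descriptors

**Cavity fingerprints** (FuzCav-style).  Each site residue contributes
one anchor atom — Cα, or a designated representative side-chain atom per
residue type — and a set of up to six residue-level pharmacophoric
features (donor, acceptor, positive, negative, aromatic, aliphatic; both
tables are package data).  For every anchor triple and every combination
of one feature per vertex, a count is incremented at the key
(feature multiset, multiset of binned edge lengths) with distance bin
edges 4/6/9/13/18 Å, giving a fixed 3136-long integer vector.  The exact
bin layout of the original cavity fingerprint is not reproducible from
public descriptions, so this scheme is the package's own documented
canonicalisation; it is permutation- and rigid-motion-invariant and
validated against a brute-force triple loop.  Three similarity metrics
are provided (count Tanimoto for global profile, shared-support over
union, shared-support over the smaller support for local similarity);
all are symmetric, in [0, 1], and 1 on identical non-empty prints.
Sites are fingerprinted only for ligands with ≥ 7 heavy atoms and no
clash-flagged contact.

**Shape moments** (USRCAT).  For one conformer, four reference points
are taken from the full heavy-atom set (centroid, closest atom to it,
farthest from it, farthest from the farthest); for the all-atom set and
four pharmacophoric subsets (hydrophobic, aromatic, donor, acceptor) the
first three moments of the distance distribution to each reference point
are recorded — mean, population σ, cube root of the third central
moment — giving 5 × 4 × 3 = 60 numbers, rotation/translation-invariant;
empty subsets produce zero blocks.  Similarity is the inverse scaled
Manhattan deviation S = 1/(1 + (1/12) Σ_s w_s‖Δ_s‖₁) with unit subset
weights, so S ∈ (0, 1] and S = 1 iff the descriptors are identical.  At
most 25 conformers per molecule enter ensemble comparisons.

**Interaction matrices and clustering.**  Per-ligand contact flags are
stacked into a binary matrix whose columns are aligned
reference-sequence positions × the 13 SIFt flags ("a 13-wide block per
position"), so the same binding site produces identical rows regardless
of author numbering.  Residue-to-reference mappings are consumed as TSV;
residues without a mapping are dropped with a warning, and two residues
of one structure mapping to the same position is an error.  Rows are
clustered agglomeratively with Jaccard distance and average linkage
(both configurable — no linkage/metric is documented for the original
resource); the tree supports a top-split query, nearest-neighbour lookup
(self excluded) and Newick export.

## Synthetic fixtures

The `fixtures` module generates small legal single-model PDB files with
declared ground truth: posed benzene pairs (requested centroid distance,
dihedral, θ accurate to < 0.1° after coordinate rounding), typed probe
pairs at set distances/angles, a halogen probe over a ring, a two-chain
poly-alanine complex with a benzamide ligand (planted N–H···O=C hydrogen
bond), a stacked benzene (planted face-to-face aromatic ligand–ligand
interaction) and a chain–chain hydrophobic interface, a cofactor + drug
arrangement in which the drug touches protein and cofactor, gapped
chains with SEQRES references, and plausible refinement-statistics
sidecars.  Ground truths are declared from the generators' own constants
— the contact engine is never consulted at generation time — so
closed-loop tests compare two independent routes.  Output is
byte-identical for a given seed.

The fixtures are idealized: geometry is constructed, not physically
relaxed; proteins are poly-alanine rods, not folds; occupancies and
B-factors are uniform.  Passing tests therefore demonstrate the
correctness of the geometric and combinatorial machinery under
controlled conditions, not robustness to real-world crystallographic
pathology (disorder, microheterogeneity, covalent modifications), which
only curated real structures can probe.  One suite test downloads a real
kinase entry to reproduce a published strand-fragment example end to
end; it requires network access and a DSSP-style assignment at run time.

## Numerical choices and degenerate inputs

Angles are computed through clipped arccos and folded to [0, 90°];
coincident ring centroids, < 3 or collinear shape atoms, zero-length
fingerprints and zero ligand contacts all raise or mark explicitly
rather than returning silent zeros.  Distance-bin arithmetic uses the
package vdW table with gemmi's tabulated radii as fallback.  Residue
ordering is (number, insertion code) with the empty code first.  All
randomness in tests and scripts flows from explicit seeds.

## Known limitations

Polysaccharide chains deposited as HETATM are perceived as ligands
rather than polymer chains unless the mmCIF entity record says
otherwise.  Fragmentation maps cover single-residue ligands only.
Protonation states, tautomers and partial charges are out of scope, as
are water-mediated networks, energy scoring, NMR multi-model handling
beyond the first model, and generating assemblies from symmetry
operators.
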