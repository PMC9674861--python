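# Methods

## Problem and scope

Enzyme-recruiting bifunctional compounds (PROTACs and other ProxPharm
molecules) need chemical handles that bind a protein-modifying enzyme
without occupying its active site. Given one or more 3-D structures of an
enzyme and a residue-level curation file, `pocketsieve` detects surface and
interior cavities, measures their druggability, removes everything that is
(or depends on) the catalytic machinery, and emits one confidence-scored
record per surviving pocket. Pockets fall into three categories:
non-catalytic domains, non-catalytic sites of the catalytic domain, and
protein–protein interface sites of multi-entity assemblies.

The package operates entirely on files: structures in PDB or mmCIF, one
annotation document per enzyme (UniProt-indexed), and an optional DLID
reference table. It does not query InterPro/UniProt/M-CSA, does not align
sequences (the author→UniProt residue map is an input), and does not
curate which domains are catalytic.

## Cavity detection

A lattice of spacing *s* (default 0.8 Å, valid 0.4–1.5 Å) covers the
assembly plus padding (default 5 Å). A cell is **protein** when its center
lies within (vdW radius + 1.4 Å probe) of any heavy atom; a Bondi-style
radius table is packaged and unknown elements fall back to carbon's
1.70 Å. Bulk solvent is the 6-connected flood fill of non-protein cells
from the lattice boundary. Pocket candidate cells are

* enclosed voids: non-protein, not reachable from the boundary; or
* buried open cells: solvent cells with protein on **both** sides along at
  least ⌈θ·7⌉ of the seven scan directions (x, y, z and the four body
  diagonals), θ = 5/7 by default — the classic scan-line burial criterion
  of grid pocket finders.

Candidates are grouped into 6-connected components; components smaller
than the cell equivalent of 50 Å³ are dropped; the rest become pockets
ordered by size. Each pocket's **envelope** is the set of boundary faces
of its cell set, split into protein-facing and solvent-facing; the face
corner vertices serve as the pocket surface mesh for all distance rules.
This detector is an openly documented surrogate for proprietary pocket
finders; everything downstream consumes only the pocket contract (cells,
envelope, lining) and is detector-agnostic.

Geometry conventions: heavy atoms only (structures are neither protonated
nor minimized before gridding); waters discarded; altloc duplicates keep
the highest-occupancy conformer (ties → alphabetically first); model 1 of
multi-model files; deposited assembly operators of assembly "1" applied by
default for mmCIF inputs, identity for PDB inputs.

## Descriptors

* **Volume** = cell count × s³.
* **Area** = marching-cubes surface of the pocket occupancy field at
  iso-level 0.5 (scikit-image). A face-count fallback
  (boundary faces × s² × 2/3 staircase correction) exists as an analytic
  oracle for tests; the 2/3 factor is the classical surface-area
  correction for voxelized staircase surfaces.
* **Buriedness** = protein-facing boundary faces / all boundary faces.
  Fully enclosed voids score exactly 1.0 — deliberately *outside* the
  ligandability window below, since a solvent-inaccessible void cannot be
  reached by a ligand.
* **Hydrophobicity** = fraction of apolar atoms among lining heavy atoms
  within 4.5 Å of the envelope. Apolar = carbon not bonded to N/O per the
  packaged amino-acid topology table, or sulfur; non-standard residues
  fall back to an element rule (C or S = apolar). A residue-level
  alternative (mean Kyte–Doolittle index of the lining, rescaled to
  [0, 1]) is provided; the atom-based definition is the default. Both are
  plausible readings of "pocket hydrophobicity"; neither is asserted to
  be the scale used by proprietary tools.
* **DLID** (drug-like density): the query pocket and a reference table of
  drug-like / non-drug-like pockets are embedded in z-normalized
  (log volume, buriedness, hydrophobicity) space; among the k = 20 nearest
  references, DLID = log10((n₊ + ½)/(n₋ + ½)). The packaged reference
  table is **synthetic** (generated from two labelled Gaussian clusters
  emulating mid-size buried apolar pockets vs small shallow polar ones;
  the file header says so) and is swappable for a curated table of real
  pockets via `dlid_reference`. The construction preserves the score's
  semantics — positive in drug-like neighbourhoods, the filter cut at
  > −1 — without pretending to reproduce any proprietary coefficients.

## Classification rules

All residue-level rules operate in UniProt numbering via the annotation
residue map; geometry uses author numbering. Distances are measured from
the envelope vertices (config-switchable to the pocket centroid).

* **Lining**: residues with any heavy atom within 2.8 Å of an envelope
  vertex.
* **Catalytic proximity**: strictly more than 7 Å from the nearest
  catalytic-residue heavy atom → non-catalytic; at or under 7 Å →
  rejected as the active site. An empty catalytic list makes the rule
  vacuous; a non-empty list with no resolved member excludes the whole
  structure (as does a catalytic residue among the unresolved residues).
* **Cofactor proximity**: strictly less than 7 Å from nucleotide/cofactor
  binding residues → rejected (these are the ATP/acetyl-CoA-type sites).
* **Missing density**: unresolved residues are localized at the midpoint
  of the Cα atoms of their nearest resolved flanking residues (single
  flank for terminal gaps; unlocalizable gaps are skipped); pockets
  strictly closer than 5 Å are rejected. Annotated missing residues are
  only treated as missing in structures where they are actually
  unresolved, so one annotation document serves a multi-structure series.
* **Pseudo-sequence and domain**: per chain, the (min, max) UniProt
  numbers of the lining define the pocket's pseudo-sequence; the domain
  containing the majority (≥ 50%) of mapped lining residues is assigned,
  ties going to the earlier interval. Pockets in a curated non-catalytic
  domain are category `non_catalytic_domain`; everything else that is not
  an interface — including pockets no domain covers — is
  `non_catalytic_site_catalytic_domain` (an unannotated region is treated
  as part of the catalytic unit rather than invent a fourth category).
* **Interfaces**: a pocket whose lining comes from ≥ 2 entities, each
  contributing ≥ 20% of lining residues, is an interface pocket; if one
  such side is an inhibitor protein the pocket is rejected (inhibitor
  complexes do not represent recruitable surfaces). The 20% minority
  share keeps a single stray residue from flipping the call.
* **Duplicates**: across structures of one enzyme, pockets with lining-set
  Jaccard ≥ 0.5 cluster by single linkage; the largest pocket (volume,
  then area, then lexicographically first structure id) survives. Jaccard
  over UniProt lining sets was chosen because it needs no structure
  superposition.
* **Ligandability**: volume ∈ [155.7, 661.1] Å³, area ∈ [155, 655] Å²,
  hydrophobicity > 0.44, buriedness ∈ [0.6, 0.95], DLID > −1. Range ends
  inclusive; the wording "more than", "<" and ">" of the distance and
  score cuts is taken literally strict, and every boundary case is
  unit-tested (7.0 Å → catalytic, 7.5 Å → non-catalytic; 6.9 Å cofactor →
  rejected, 7.0 Å → kept; 4.9 Å gap → rejected, 5.0 Å → kept).
* **Confidence**: high-affinity ligand → 1, weak ligand → 2, ligandable
  homologous domain → 3, none → 4. Evidence is looked up per record by
  the most specific site key first (`structure:pocket`, then domain id,
  then enzyme-wide `*`). Non-catalytic domains with a ligandable exemplar
  can be transferred to enzymes without structures as structure-less
  confidence-3 stub records.

Pipeline order is fixed: detection → descriptors → catalytic → cofactor →
missing density → inhibitor interface → duplicate collapse → ligandability
→ confidence → cysteines. Every detected pocket ends with exactly one
category or one rejection reason, and the run report's per-reason counts
sum to detected − emitted.

## Reactive cysteines

Cysteines lining accepted pockets (residue within the 2.8 Å lining cutoff
of the envelope) are scored with a logistic surrogate:
score = σ(w₀ + w_exp·(1 − SG exposure) + w_pol·n_polar + w_pocket), with
defaults (−2.0, 1.5, 0.6, 0.5) and a 0.5 reactivity cutoff. SG exposure is
Shrake–Rupley SASA (biotite) normalized by the isolated-sphere SASA of an
SG atom; n_polar counts N/O atoms within 6 Å of SG from other residues
(thiolate stabilization); disulfide pairs (SG–SG < 2.5 Å) are excluded.
The weights are heuristic: buried thiols in polar microenvironments are
enriched among proteomically reactive cysteines. This scorer is **not**
the proprietary model trained on isoTOP-ABPP data that motivates the
feature choice; `fit_weights` re-fits the logistic coefficients on any
user-supplied labelled feature table.

## Synthetic fixtures

The generator emits deterministic (seed → byte-identical) PDB
pseudo-proteins made of 3-atom all-carbon UNK residues, so hydrophobicity
is analytically 1.0 and PDB writing stays trivial:

* `hollow_shell` — concentric Fibonacci-lattice spheres (point spacing
  ≈ 0.9 Å, 4 shells 1.1 Å apart) enclosing a void of exactly known radius;
  void volume/area are sphere formulas. Wall integrity is verified by
  flood fill at generation time; a leaking wall is a hard generator error.
* `solid_sphere`, `two_void`, `dimer_interface` (hemispheres on two
  chains around one void, exercising interface logic), `open_groove` (a
  cylindrical well in a lattice block: an open pocket with buriedness
  ≈ 0.77, bracketed by cylinder-volume bounds).
* `enzyme_series` — three structures of one synthetic enzyme, each
  geometric site on its own chain with its own UniProt numbering block:
  a catalytic-site shell present in all structures, a cofactor shell
  (structure 1), a gap-flanked shell (structure 2, with an annotated
  unresolved run localized between two embedded flank residues), a
  duplicate pair of enclosed shells whose different void radii emulate
  two conformations (shell-index-stable numbering keeps their lining
  Jaccard ≈ 0.85), and one open well that survives every filter. The
  scripted truth file (counts, rejection reasons, survivor, volume
  brackets) is reproduced exactly by the pipeline in the golden test.

What the fixtures do **not** emulate: real protein chemistry (mixed
element composition, charged lining, realistic folds and B-factors),
crystallographic artefacts beyond scripted missing ranges, and ICM-style
pocket boundaries. Passing tests therefore demonstrate the correctness of
the geometry, descriptors and rule logic under controlled conditions, not
agreement with any proprietary tool's numeric output on real structures.

## Numerical choices and limitations

* Grid spacing defaults to 0.8 Å (0.5 Å in the analytic-recovery tests);
  voxel-count volume error at one alignment oscillates around the
  analytic value, so the convergence test averages over four lattice
  phases (mean error 1.18% → 0.96% → 0.60% at 1.0 → 0.75 → 0.5 Å).
  Translation invariance is exact (the lattice is anchored to the atom
  bounding box); rotations at 0.5 Å spacing move volumes by < 5%.
* Burial threshold 5/7, probe 1.4 Å, 50 Å³ minimum pocket volume —
  standard values in the grid-pocket literature, all exposed in config.
* Ties: altloc → alphabetical; duplicate collapse → volume, area,
  structure id; domain assignment → earlier interval; pocket ordering →
  cell count, then first cell index.
* Degenerate inputs: empty structure, unreadable file, non-orthonormal
  assembly operators, chains without entity roles, an all-unmapped pocket
  lining, and a reference table with a single class are all hard errors;
  an empty input list produces a clean empty compendium.
* Problem sizes in tests and the acceptance script (shell fixtures of
  ~5–7 k atoms, series structures of ~15 k atoms, 200 random 20³ masks)
  were chosen so a full run completes in well under a minute while keeping
  discretization error a few percent — small enough to iterate on, large
  enough that the analytic checks are meaningful.
* The catalytic/cofactor distance is measured from envelope vertices; a
  centroid mode exists but shifts the effective thresholds by roughly the
  pocket radius and is off by default.
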