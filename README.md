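# pocketsieve

Mapping putative ligandable **non-catalytic** binding pockets on
protein-modifying enzymes (kinases, phosphatases, acetyltransferases,
deubiquitinases, …). Proximity-induced pharmacology (ProxPharm/PROTAC)
compounds do not need to inhibit the enzyme they recruit — they only need a
chemical handle that binds *away* from the active site. `pocketsieve` turns
a set of 3-D structures plus a residue-level annotation file into a
compendium of candidate handle sites, each with druggability descriptors
and a 1–4 confidence level.

## What it computes

1. **Cavity detection** — a 3-D lattice (default 0.8 Å) is laid over each
   biological assembly; cells within vdW + 1.4 Å probe of a heavy atom are
   protein, bulk solvent is flood-filled from the boundary, and pocket
   cells are enclosed voids or solvent cells buried along ≥ 5 of the 7
   LIGSITE scan directions (3 axes + 4 body diagonals). 6-connected
   components become pockets with an explicit cell envelope.
2. **Descriptors** — volume (cells × spacing³), marching-cubes surface
   area, buriedness (protein-facing fraction of the envelope),
   hydrophobicity (apolar fraction of lining contact atoms), and DLID, a
   k-nearest-neighbour log-odds of drug-likeness in
   (log V, buriedness, hydrophobicity) space against a reference pocket
   table.
3. **Classification and filters** — residues within 2.8 Å of the envelope
   line the pocket; a pocket more than 7 Å from the curated catalytic
   residues is non-catalytic, otherwise it is the active site and is
   rejected. Pockets < 7 Å from nucleotide/cofactor-binding residues,
   < 5 Å from unresolved-density gaps, or at an enzyme/inhibitor-protein
   interface are rejected; structures whose catalytic residues are
   unresolved are dropped whole. Duplicates across structures of one
   enzyme (lining-set Jaccard ≥ 0.5) collapse to the largest pocket.
   Survivors must pass the ligandability windows
   (volume 155.7–661.1 Å³, area 155–655 Å², hydrophobicity > 0.44,
   buriedness 0.6–0.95, DLID > −1).
4. **Confidence** — 1 = reported high-affinity ligand, 2 = weak ligand,
   3 = ligandable in a homologous domain (including structure-less
   domain-transfer records), 4 = geometry-only prediction. Pocket-lining
   cysteines are additionally scored for predicted electrophile reactivity
   (covalent-handle discovery).

Annotations (UniProt-indexed catalytic/cofactor residues, domain
intervals, entity roles, ligand evidence) are consumed as YAML files; no
online database access is performed.

## Worked example

The packaged generator builds a three-structure synthetic enzyme in which
every filter branch fires exactly once around one scripted survivor:

```sh
pocketsieve fixture --kind enzyme_series --out demo
cat > demo/run.yaml <<EOF
structures: [demo/SYNENZ1_s1.pdb, demo/SYNENZ1_s2.pdb, demo/SYNENZ1_s3.pdb]
annotation: demo/SYNENZ1_annotation.yaml
out_dir: demo/out
EOF
pocketsieve run --config demo/run.yaml
```

prints per-structure progress to stderr, e.g.

```
INFO SYNENZ1_s2/P3 rejected: catalytic site (3.4 Å)
INFO SYNENZ1_s2/P4 rejected: near unresolved residues (3.4 Å)
INFO SYNENZ1_s1/P1 rejected: duplicate pocket
INFO SYNENZ1_s2/P2 rejected: outside ligandability windows
8 pockets detected, 1 records emitted -> demo/out
```

and `demo/out/compendium.tsv` holds the surviving record:

```
enzyme_id  structure_id  pocket_id  category                             domain_id  confidence  volume  area   hydrophobicity  buriedness  dlid
SYNENZ1    SYNENZ1_s2    P1         non_catalytic_site_catalytic_domain  CATD       1           404.5   340.1  1.000           0.762       1.613
```

Eight pockets were detected across the three structures; three are the
active site (≤ 7 Å from catalytic residues), one is the cofactor site, one
sits next to an unresolved-density gap, one is a cross-structure duplicate
(the smaller of a pair), and one is too buried to pass the ligandability
windows. The survivor is an open pocket on the catalytic domain, 41.3 Å
from the catalytic residues, with all five descriptors inside the windows
and confidence 1 because the annotation reports a high-affinity ligand at
the site. `pocketsieve props <structure.pdb>` prints the descriptor table
for any single structure.

## Layout

| module | contents |
| --- | --- |
| `pocketsieve.structure_io` | PDB/mmCIF parsing (gemmi), assembly expansion, PDB writing |
| `pocketsieve.cavity_grid` | occupancy lattice, LIGSITE-style burial, pocket components, lining residues |
| `pocketsieve.pocket_props` | the five ligandability descriptors and the DLID reference table |
| `pocketsieve.classify` | annotation model, all proximity/interface/duplicate/ligandability rules, confidence |
| `pocketsieve.cys_react` | logistic reactive-cysteine surrogate scorer |
| `pocketsieve.synthetic_fixtures` | deterministic generators for all test geometries |
| `pocketsieve.pipeline` / `pocketsieve.cli` | orchestration, config, outputs, `pocketsieve` command |

See `docs/methods.md` for the model, parameter defaults, and limitations.
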