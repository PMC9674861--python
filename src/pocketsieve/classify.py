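"""Annotation-driven pocket classification and filtering.

Implements the rule set that turns raw cavities into compendium records:

* catalytic proximity — a pocket more than 7 Å from the nearest catalytic
  residue is non-catalytic; at or under 7 Å it is rejected as catalytic;
* cofactor proximity — pockets closer than 7 Å to nucleotide/cofactor
  binding residues are rejected (they are the ATP/acetyl-CoA sites);
* missing density — pockets closer than 5 Å to unresolved residues are
  rejected; a structure whose catalytic residues are unresolved is dropped
  entirely;
* inhibitor interface — pockets at an enzyme/inhibitor-protein interface
  are rejected, while enzyme/cofactor-protein interface pockets form their
  own category;
* pocket pseudo-sequence and domain assignment against curated catalytic /
  non-catalytic domain intervals;
* duplicate collapse across structures of one enzyme (lining-set Jaccard,
  largest pocket kept);
* the five-descriptor ligandability window; and
* confidence levels 1–4 from ligand-evidence classes, including level-3
  transfer of domain ligandability to enzymes without structures.

Residue-level annotations are UniProt-indexed; the annotation residue map
translates author numbering of each structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .cavity_grid import Pocket
from .pocket_props import LigandabilityThresholds, PocketProperties
from .structure_io import Residue, StructureModel

__all__ = [
    "AnnotationSet",
    "PocketRecord",
    "AnnotationError",
    "NotMeasurable",
    "load_annotations",
    "annotate_model",
    "min_distance",
    "classify_catalytic",
    "filter_cofactor",
    "filter_missing_density",
    "missing_residue_proxies",
    "pseudo_sequence",
    "assign_domain",
    "classify_interface",
    "dedupe",
    "is_ligandable",
    "assign_confidence",
    "transfer_domain_ligandability",
]

EVIDENCE_CLASSES = ("high_affinity_ligand", "weak_ligand", "homolog_domain_ligand", "none")
ENTITY_ROLES = ("enzyme", "cofactor_protein", "inhibitor_protein", "other")
CONFIDENCE_OF_EVIDENCE = {
    "high_affinity_ligand": 1,
    "weak_ligand": 2,
    "homolog_domain_ligand": 3,
    "none": 4,
}


class AnnotationError(ValueError):
    pass


class NotMeasurable(ValueError):
    """No listed residue is resolved in the structure: the distance does not exist."""


@dataclass
class Domain:
    start: int  # uniprot numbering, inclusive
    end: int
    domain_id: str
    is_catalytic: bool

    def __post_init__(self):
        if self.start > self.end:
            raise AnnotationError(f"domain {self.domain_id}: start > end")

    def __contains__(self, uniprot_num: int) -> bool:
        return self.start <= uniprot_num <= self.end


@dataclass
class AnnotationSet:
    """Residue- and domain-level curation for one enzyme."""

    enzyme_id: str
    residue_map: dict[tuple[str, int], int]  # (chain, author num) -> uniprot num
    catalytic_residues: list[int] = field(default_factory=list)
    cofactor_residues: list[int] = field(default_factory=list)
    missing_residues: dict[str, list[int]] = field(default_factory=dict)
    domains: list[Domain] = field(default_factory=list)
    entity_roles: dict[str, str] = field(default_factory=dict)
    ligand_evidence: dict[str, str] = field(default_factory=dict)  # site_key -> class

    def __post_init__(self):
        for role in self.entity_roles.values():
            if role not in ENTITY_ROLES:
                raise AnnotationError(f"unknown entity role {role!r}")
        for cls in self.ligand_evidence.values():
            if cls not in EVIDENCE_CLASSES:
                raise AnnotationError(f"unknown evidence class {cls!r}")

    def uniprot_of(self, res: Residue) -> int | None:
        return self.residue_map.get((res.chain_id, res.author_seq_num))

    def missing_for(self, structure_id: str) -> list[int]:
        return sorted(set(self.missing_residues.get(structure_id, []))
                      | set(self.missing_residues.get("*", [])))

    def resolved_residues(self, model: StructureModel, uniprot_nums) -> list[Residue]:
        wanted = set(uniprot_nums)
        return [r for r in model.residues if self.uniprot_of(r) in wanted]


def _parse_residue_map(raw) -> dict[tuple[str, int], int]:
    """Residue map entries are ranges {chain, author_start, author_end,
    uniprot_start} or single pairs {chain, author, uniprot}."""
    out: dict[tuple[str, int], int] = {}
    for entry in raw:
        chain = str(entry["chain"])
        if "author" in entry:
            out[(chain, int(entry["author"]))] = int(entry["uniprot"])
            continue
        a0, a1 = int(entry["author_start"]), int(entry["author_end"])
        u0 = int(entry["uniprot_start"])
        for off in range(a1 - a0 + 1):
            out[(chain, a0 + off)] = u0 + off
    return out


def load_annotations(path: str | Path) -> AnnotationSet:
    """Read a per-enzyme annotation document (YAML)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "enzyme_id" not in doc:
        raise AnnotationError(f"{path}: not an enzyme annotation document")
    missing = doc.get("missing_residues", [])
    if isinstance(missing, list):
        missing = {"*": [int(x) for x in missing]}
    else:
        missing = {str(k): [int(x) for x in v] for k, v in missing.items()}
    domains = [
        Domain(int(d["start"]), int(d["end"]), str(d["domain_id"]), bool(d["is_catalytic"]))
        for d in doc.get("domains", [])
    ]
    evidence = {}
    for e in doc.get("ligand_evidence", []):
        evidence[str(e["site_key"])] = str(e["evidence_class"])
    return AnnotationSet(
        enzyme_id=str(doc["enzyme_id"]),
        residue_map=_parse_residue_map(doc.get("residue_map", [])),
        catalytic_residues=[int(x) for x in doc.get("catalytic_residues", [])],
        cofactor_residues=[int(x) for x in doc.get("cofactor_residues", [])],
        missing_residues=missing,
        domains=domains,
        entity_roles={str(k): str(v) for k, v in doc.get("entity_roles", {}).items()},
        ligand_evidence=evidence,
    )


def annotate_model(model: StructureModel, annot: AnnotationSet) -> None:
    """Attach uniprot_num to every mapped residue of the model (in place).

    Assembly copies (chain ``A_1`` etc.) inherit the mapping of their source
    chain."""
    for res in model.residues:
        chain = res.chain_id.split("_", 1)[0]
        res.uniprot_num = annot.residue_map.get((chain, res.author_seq_num))
        if res.uniprot_num is None:
            res.uniprot_num = annot.residue_map.get((res.chain_id, res.author_seq_num))


@dataclass
class PocketRecord:
    """One classified pocket: the compendium row."""

    enzyme_id: str
    structure_id: str
    pocket_id: str
    category: str | None = None  # non_catalytic_domain | non_catalytic_site_catalytic_domain | interface
    rejected_reason: str = "none"  # catalytic | cofactor | missing_density | catalytic_missing | inhibitor_interface | duplicate | unligandable | none
    properties: PocketProperties | None = None
    pseudo_sequence: dict[str, tuple[int, int]] = field(default_factory=dict)
    domain_id: str | None = None
    domain_is_catalytic: bool | None = None
    min_dist_catalytic: float | None = None
    confidence: int | None = None
    site_label: str = ""
    lining_uniprot: frozenset[int] = frozenset()
    structure_less: bool = False

    def validate(self) -> None:
        if (self.rejected_reason == "none") != (self.category is not None):
            raise AnnotationError(
                f"{self.structure_id}/{self.pocket_id}: category iff not rejected"
            )
        if (self.confidence is not None) and self.rejected_reason != "none":
            raise AnnotationError(
                f"{self.structure_id}/{self.pocket_id}: confidence on a rejected pocket"
            )


# ---------------------------------------------------------------------------
# proximity rules

def min_distance(
    pocket: Pocket,
    uniprot_nums,
    model: StructureModel,
    annot: AnnotationSet,
) -> float:
    """Minimum distance (Å) between the pocket envelope vertices and any heavy
    atom of the listed residues. Raises :class:`NotMeasurable` when none of
    the residues is resolved in the model."""
    residues = annot.resolved_residues(model, uniprot_nums)
    if not residues:
        raise NotMeasurable(
            f"none of residues {sorted(set(uniprot_nums))} resolved in {model.structure_id}"
        )
    coords = np.vstack([r.heavy_coords() for r in residues])
    tree = cKDTree(coords)
    d, _ = tree.query(pocket.envelope_vertices, k=1)
    return float(np.min(d))


def classify_catalytic(dist: float, threshold: float = 7.0) -> str:
    """Non-catalytic iff strictly more than ``threshold`` Å from the catalytic
    residues; at or under the threshold the pocket is the active site."""
    if dist < 0:
        raise ValueError("distance must be non-negative")
    return "non_catalytic" if dist > threshold else "catalytic"


def filter_cofactor(dist: float, threshold: float = 7.0) -> bool:
    """Keep iff the pocket is at least ``threshold`` Å from nucleotide /
    cofactor binding residues (strictly closer pockets are those sites)."""
    if dist < 0:
        raise ValueError("distance must be non-negative")
    return dist >= threshold


def missing_residue_proxies(
    model: StructureModel, annot: AnnotationSet, structure_id: str | None = None
) -> np.ndarray:
    """Proxy positions for unresolved residues.

    Each annotated-missing residue that is indeed unresolved in the model is
    localized at the midpoint of the Cα atoms of its nearest resolved
    flanking residues on the same chain (terminal gaps use the single
    flank). Residues with no resolved flank on any chain yield no proxy.
    Returns an (n, 3) array (possibly empty).
    """
    sid = structure_id or model.structure_id
    resolved_uniprot = {
        annot.uniprot_of(r) for r in model.residues if annot.uniprot_of(r) is not None
    }
    by_chain: dict[str, list[tuple[int, Residue]]] = {}
    for r in model.residues:
        u = annot.uniprot_of(r)
        if u is not None:
            by_chain.setdefault(r.chain_id, []).append((u, r))
    for lst in by_chain.values():
        lst.sort(key=lambda t: t[0])

    proxies = []
    for m in annot.missing_for(sid):
        if m in resolved_uniprot:
            continue
        for chain, lst in by_chain.items():
            nums = [u for u, _ in lst]
            below = [r for u, r in lst if u < m]
            above = [r for u, r in lst if u > m]
            if not below and not above:
                continue

            def anchor(res: Residue) -> np.ndarray:
                ca = res.atom("CA")
                return ca.position if ca is not None else res.atoms[0].position

            if below and above:
                proxies.append((anchor(below[-1]) + anchor(above[0])) / 2.0)
            elif below:
                proxies.append(anchor(below[-1]))
            else:
                proxies.append(anchor(above[0]))
    return np.array(proxies, dtype=float) if proxies else np.empty((0, 3))


def filter_missing_density(
    dist_to_missing: float, threshold: float = 5.0, catalytic_missing: bool = False
) -> str:
    """``"structure_excluded"`` when a catalytic residue is unresolved,
    ``"drop"`` when the pocket is strictly closer than ``threshold`` to a
    localized gap, else ``"keep"``."""
    if catalytic_missing:
        return "structure_excluded"
    return "drop" if dist_to_missing < threshold else "keep"


# ---------------------------------------------------------------------------
# pseudo-sequence and domain assignment

def pseudo_sequence(
    lining: list[Residue], annot: AnnotationSet
) -> dict[str, tuple[int, int]]:
    """Per-chain (N-terminal, C-terminal) UniProt boundaries of the lining
    selection. Unmapped residues are skipped; an entirely unmapped lining is
    an error."""
    if not lining:
        raise AnnotationError("empty lining")
    per_chain: dict[str, list[int]] = {}
    for res in lining:
        u = res.uniprot_num if res.uniprot_num is not None else annot.uniprot_of(res)
        if u is None:
            continue
        per_chain.setdefault(res.chain_id, []).append(u)
    if not per_chain:
        raise AnnotationError("no lining residue maps to UniProt numbering")
    return {c: (min(v), max(v)) for c, v in sorted(per_chain.items())}


def assign_domain(
    bounds: dict[str, tuple[int, int]],
    domains: list[Domain],
    lining: list[Residue],
) -> tuple[str, bool] | None:
    """Domain holding the majority (≥ 50%) of mapped lining residues.

    Ties go to the domain with the smaller start; returns ``None`` when no
    domain covers at least half of the lining."""
    mapped = [r.uniprot_num for r in lining if r.uniprot_num is not None]
    if not mapped or not domains:
        return None
    best: tuple[int, int, Domain] | None = None  # (-count, start, domain)
    for dom in domains:
        count = sum(1 for u in mapped if u in dom)
        if count == 0:
            continue
        key = (-count, dom.start)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], dom)
    if best is None:
        return None
    count = -best[0]
    if count * 2 < len(mapped):
        return None
    return (best[2].domain_id, best[2].is_catalytic)


def classify_interface(
    pocket: Pocket,
    annot: AnnotationSet,
    entity_of_chain: dict[str, str],
    minority_share: float = 0.2,
) -> tuple[str, bool]:
    """(``"interface"`` | ``"single_entity"``, inhibitor_reject).

    A pocket is at an interface when its lining comes from at least two
    entities each contributing ≥ ``minority_share`` of the lining residues;
    it is rejected when one of those sides is an inhibitor protein.
    """
    lining = pocket.lining_residues
    if not lining:
        raise AnnotationError("pocket has no lining residues")
    counts: dict[str, int] = {}
    for res in lining:
        chain = res.chain_id
        entity = entity_of_chain.get(chain) or entity_of_chain.get(chain.split("_", 1)[0])
        if entity is None:
            raise AnnotationError(f"chain {chain} has no entity label")
        if entity not in annot.entity_roles:
            raise AnnotationError(f"entity {entity} has no role annotation")
        counts[entity] = counts.get(entity, 0) + 1
    total = sum(counts.values())
    sides = [e for e, c in counts.items() if c / total >= minority_share]
    if len(sides) < 2:
        return ("single_entity", False)
    inhibitor = any(annot.entity_roles[e] == "inhibitor_protein" for e in sides)
    return ("interface", inhibitor)


# ---------------------------------------------------------------------------
# cross-structure steps

def _jaccard(a: frozenset[int], b: frozenset[int]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def dedupe(records: list[PocketRecord], jaccard_min: float = 0.5) -> list[PocketRecord]:
    """Collapse similar pockets across structures of one enzyme.

    Similarity is the Jaccard index of UniProt lining sets; clusters are
    single-linkage at ≥ ``jaccard_min``; the largest pocket (by volume, then
    area, then lexicographically first structure id) survives, the rest are
    marked ``duplicate``. Order-invariant and idempotent.
    """
    enzymes = {r.enzyme_id for r in records}
    if len(enzymes) > 1:
        raise AnnotationError(f"dedupe across enzymes {sorted(enzymes)}")
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _jaccard(records[i].lining_uniprot, records[j].lining_uniprot) >= jaccard_min:
                parent[find(i)] = find(j)

    clusters: dict[int, list[PocketRecord]] = {}
    for i, rec in enumerate(records):
        clusters.setdefault(find(i), []).append(rec)

    out: list[PocketRecord] = []
    for group in clusters.values():
        def rank(rec: PocketRecord):
            p = rec.properties
            vol = p.volume if p else 0.0
            area = p.area if p else 0.0
            return (-vol, -area, rec.structure_id, rec.pocket_id)

        group.sort(key=rank)
        out.append(group[0])
        for rec in group[1:]:
            rec.category = None
            rec.confidence = None
            rec.rejected_reason = "duplicate"
            out.append(rec)
    out.sort(key=lambda r: (r.structure_id, r.pocket_id))
    return out


def is_ligandable(
    props: PocketProperties, t: LigandabilityThresholds = LigandabilityThresholds()
) -> bool:
    """Five-clause druggability window; range ends inclusive, the
    hydrophobicity and DLID cuts strict."""
    if props is None:
        raise AnnotationError("properties not computed")
    return (
        t.volume_range[0] <= props.volume <= t.volume_range[1]
        and t.area_range[0] <= props.area <= t.area_range[1]
        and props.hydrophobicity > t.hydrophobicity_min
        and t.buriedness_range[0] <= props.buriedness <= t.buriedness_range[1]
        and props.dlid > t.dlid_min
    )


def assign_confidence(evidence_class: str) -> int:
    """1 = reported high-affinity ligand, 2 = weak ligand, 3 = ligandable in a
    homologous domain, 4 = geometry-only prediction."""
    try:
        return CONFIDENCE_OF_EVIDENCE[evidence_class]
    except KeyError:
        raise AnnotationError(f"unknown evidence class {evidence_class!r}") from None


def evidence_for(annot: AnnotationSet, record: PocketRecord) -> str:
    """Evidence class for a record: most specific site key first
    (structure:pocket, then domain, then enzyme-wide '*'), default none."""
    for key in (f"{record.structure_id}:{record.pocket_id}", record.domain_id, "*"):
        if key is not None and key in annot.ligand_evidence:
            return annot.ligand_evidence[key]
    return "none"


def transfer_domain_ligandability(
    domain_id: str,
    ligandable_domain_catalog: set[str],
    target_enzyme_id: str,
) -> PocketRecord | None:
    """Level-3 stub record for an enzyme without structures whose annotated
    domain has a ligandable exemplar elsewhere; ``None`` when the domain has
    no such exemplar."""
    if domain_id not in ligandable_domain_catalog:
        return None
    return PocketRecord(
        enzyme_id=target_enzyme_id,
        structure_id="-",
        pocket_id=f"domain:{domain_id}",
        category="non_catalytic_domain",
        rejected_reason="none",
        domain_id=domain_id,
        domain_is_catalytic=False,
        confidence=3,
        structure_less=True,
    )
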