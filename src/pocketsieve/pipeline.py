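"""End-to-end orchestration: structures + annotation in, compendium out.

Stages run in a fixed order: parse → assembly expansion → cavity detection
→ descriptors → annotation filters (catalytic, cofactor, missing density,
inhibitor interface) → duplicate collapse across structures → ligandability
→ confidence → cysteine scoring. Every detected pocket is accounted for in
the run report with its fate; surviving pockets (plus optional
domain-transfer stubs) form the compendium TSV / JSON-lines output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import classify as cl
from . import cavity_grid as cg
from . import cys_react as cr
from . import pocket_props as pp
from . import structure_io as sio

__all__ = ["RunConfig", "RunResult", "run_pipeline", "load_config"]

log = logging.getLogger("pocketsieve")


@dataclass
class RunConfig:
    """All tunables of one run; serialized next to the results so a run can
    be reproduced from its own output directory."""

    structures: list[str]
    annotation: str
    out_dir: str = "pocketsieve_out"
    # grid
    spacing: float = cg.DEFAULT_SPACING
    padding: float = 5.0
    probe_radius: float = cg.PROBE_RADIUS
    burial_threshold: float = cg.DEFAULT_BURIAL_THRESHOLD
    min_pocket_volume: float = cg.MIN_POCKET_VOLUME
    # distance rules (Å)
    lining_cutoff: float = 2.8
    catalytic_threshold: float = 7.0
    cofactor_threshold: float = 7.0
    missing_threshold: float = 5.0
    dedupe_jaccard: float = 0.5
    interface_minority: float = 0.2
    distance_mode: str = "envelope"  # envelope | centroid
    # ligandability
    volume_range: tuple[float, float] = (155.7, 661.1)
    area_range: tuple[float, float] = (155.0, 655.0)
    hydrophobicity_min: float = 0.44
    buriedness_range: tuple[float, float] = (0.6, 0.95)
    dlid_min: float = -1.0
    dlid_reference: str | None = None
    area_method: str = "marching_cubes"
    # assembly / cysteines / misc
    assembly_id: str = "1"
    cys_weights: tuple[float, float, float, float] = cr.DEFAULT_WEIGHTS
    cys_cutoff: float = 0.5
    transfer_targets: list[dict] = field(default_factory=list)
    seed: int = 0

    def thresholds(self) -> pp.LigandabilityThresholds:
        return pp.LigandabilityThresholds(
            volume_range=tuple(self.volume_range),
            area_range=tuple(self.area_range),
            hydrophobicity_min=self.hydrophobicity_min,
            buriedness_range=tuple(self.buriedness_range),
            dlid_min=self.dlid_min,
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


@dataclass
class RunResult:
    records: list[cl.PocketRecord]
    cysteines: dict[tuple[str, str], list[cr.CysteineSite]]  # (structure, pocket) -> sites
    report: dict

    @property
    def survivors(self) -> list[cl.PocketRecord]:
        return [r for r in self.records if r.rejected_reason == "none"]


def _pocket_distance(pocket: cg.Pocket, coords, mode: str) -> float:
    import numpy as np
    from scipy.spatial import cKDTree

    if mode == "centroid":
        return float(np.min(np.linalg.norm(coords - pocket.centroid, axis=1)))
    d, _ = cKDTree(coords).query(pocket.envelope_vertices, k=1)
    return float(np.min(d))


def _min_dist(pocket, uniprot_nums, model, annot, mode):
    import numpy as np

    residues = annot.resolved_residues(model, uniprot_nums)
    if not residues:
        raise cl.NotMeasurable("no listed residue resolved")
    coords = np.vstack([r.heavy_coords() for r in residues])
    return _pocket_distance(pocket, coords, mode)


def run_pipeline(config: RunConfig) -> RunResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annot = cl.load_annotations(config.annotation)
    reference = pp.load_dlid_reference(config.dlid_reference)
    thresholds = config.thresholds()

    records: list[cl.PocketRecord] = []
    cys_by_pocket: dict[tuple[str, str], list[cr.CysteineSite]] = {}
    fates: list[dict] = []
    extra_drops = {"no_lining": 0}
    models: dict[str, sio.StructureModel] = {}
    pockets_by_key: dict[tuple[str, str], cg.Pocket] = {}
    n_detected = 0

    for spath in config.structures:
        model = sio.parse_structure(spath)
        ops = sio.assembly_operators(spath, config.assembly_id)
        if len(ops) > 1:
            model = sio.expand_assembly(model, ops)
        cl.annotate_model(model, annot)
        sid = model.structure_id
        models[sid] = model
        log.info("structure %s: %d residues", sid, len(model.residues))

        grid = cg.build_grid(model, config.spacing, config.padding, config.probe_radius)
        min_cells = int(-(-config.min_pocket_volume // config.spacing**3))
        pockets = cg.detect_cavities(grid, config.burial_threshold, min_cells)
        n_detected += len(pockets)
        log.info("structure %s: %d candidate pockets", sid, len(pockets))

        # structure-level exclusion: catalytic residues unresolved
        missing_now = set(annot.missing_for(sid))
        resolved_uniprot = {
            annot.uniprot_of(r) for r in model.residues if annot.uniprot_of(r) is not None
        }
        catalytic_missing = bool(annot.catalytic_residues) and (
            any(c in missing_now and c not in resolved_uniprot for c in annot.catalytic_residues)
            or not any(c in resolved_uniprot for c in annot.catalytic_residues)
        )

        gap_proxies = cl.missing_residue_proxies(model, annot, sid)

        for pocket in pockets:
            cg.lining_residues(pocket, model, config.lining_cutoff)
            rec = cl.PocketRecord(
                enzyme_id=annot.enzyme_id, structure_id=sid, pocket_id=pocket.pocket_id
            )
            records.append(rec)
            pockets_by_key[(sid, pocket.pocket_id)] = pocket
            if not pocket.lining_residues:
                rec.rejected_reason = "no_lining"
                extra_drops["no_lining"] += 1
                log.warning("%s/%s rejected: no lining residues", sid, pocket.pocket_id)
                continue
            rec.lining_uniprot = frozenset(
                r.uniprot_num for r in pocket.lining_residues if r.uniprot_num is not None
            )
            try:
                rec.pseudo_sequence = cl.pseudo_sequence(pocket.lining_residues, annot)
            except cl.AnnotationError:
                rec.pseudo_sequence = {}
            dom = cl.assign_domain(rec.pseudo_sequence, annot.domains, pocket.lining_residues)
            if dom is not None:
                rec.domain_id, rec.domain_is_catalytic = dom
            rec.properties = pp.compute_properties(
                pocket, grid, model, reference, config.area_method
            )

            if catalytic_missing:
                rec.rejected_reason = "catalytic_missing"
                log.warning("%s/%s rejected: catalytic residues unresolved", sid, pocket.pocket_id)
                continue

            # catalytic proximity (vacuous when no catalytic residues annotated)
            if annot.catalytic_residues:
                rec.min_dist_catalytic = _min_dist(
                    pocket, annot.catalytic_residues, model, annot, config.distance_mode
                )
                if (
                    cl.classify_catalytic(rec.min_dist_catalytic, config.catalytic_threshold)
                    == "catalytic"
                ):
                    rec.rejected_reason = "catalytic"
                    log.info("%s/%s rejected: catalytic site (%.1f Å)",
                             sid, pocket.pocket_id, rec.min_dist_catalytic)
                    continue

            if annot.cofactor_residues:
                try:
                    d = _min_dist(pocket, annot.cofactor_residues, model, annot,
                                  config.distance_mode)
                except cl.NotMeasurable:
                    d = None
                if d is not None and not cl.filter_cofactor(d, config.cofactor_threshold):
                    rec.rejected_reason = "cofactor"
                    log.info("%s/%s rejected: cofactor site (%.1f Å)", sid, pocket.pocket_id, d)
                    continue

            if len(gap_proxies):
                d = _pocket_distance(pocket, gap_proxies, config.distance_mode)
                if cl.filter_missing_density(d, config.missing_threshold) == "drop":
                    rec.rejected_reason = "missing_density"
                    log.info("%s/%s rejected: near unresolved residues (%.1f Å)",
                             sid, pocket.pocket_id, d)
                    continue

            interface, inhibitor = cl.classify_interface(
                pocket, annot, model.entity_of_chain, config.interface_minority
            )
            if inhibitor:
                rec.rejected_reason = "inhibitor_interface"
                log.info("%s/%s rejected: inhibitor interface", sid, pocket.pocket_id)
                continue
            if interface == "interface":
                rec.category = "interface"
            elif rec.domain_id is not None and rec.domain_is_catalytic is False:
                rec.category = "non_catalytic_domain"
            else:
                rec.category = "non_catalytic_site_catalytic_domain"

    # duplicate collapse across structures of the enzyme
    alive = [r for r in records if r.rejected_reason == "none"]
    deduped = cl.dedupe(alive, config.dedupe_jaccard)
    for r in deduped:
        if r.rejected_reason == "duplicate":
            log.info("%s/%s rejected: duplicate pocket", r.structure_id, r.pocket_id)

    # ligandability window, then confidence
    for r in records:
        if r.rejected_reason != "none":
            continue
        if not cl.is_ligandable(r.properties, thresholds):
            r.category = None
            r.rejected_reason = "unligandable"
            log.info("%s/%s rejected: outside ligandability windows", r.structure_id, r.pocket_id)
            continue
        r.confidence = cl.assign_confidence(cl.evidence_for(annot, r))
        r.validate()

    # domain-transfer stubs for enzymes without structures
    catalog = {
        r.domain_id
        for r in records
        if r.rejected_reason == "none" and r.category == "non_catalytic_domain" and r.domain_id
    }
    for target in config.transfer_targets:
        for dom in target.get("domain_ids", []):
            stub = cl.transfer_domain_ligandability(dom, catalog, target["enzyme_id"])
            if stub is not None:
                records.append(stub)

    # cysteine reactivity on accepted pockets, per structure
    for sid, model in models.items():
        accepted = [
            pockets_by_key[(sid, r.pocket_id)]
            for r in records
            if r.structure_id == sid and r.rejected_reason == "none" and not r.structure_less
        ]
        if not accepted:
            continue
        for site in cr.score_cysteines(model, accepted, config.cys_weights, config.cys_cutoff):
            cys_by_pocket.setdefault((sid, site.pocket_id), []).append(site)

    for r in records:
        fates.append(
            {
                "structure_id": r.structure_id,
                "pocket_id": r.pocket_id,
                "fate": r.category if r.rejected_reason == "none" else "rejected",
                "rejected_reason": r.rejected_reason,
                "volume": r.properties.volume if r.properties else None,
            }
        )
    counts: dict[str, int] = {}
    for r in records:
        if r.rejected_reason != "none" and not r.structure_less:
            counts[r.rejected_reason] = counts.get(r.rejected_reason, 0) + 1
    report = {
        "enzyme_id": annot.enzyme_id,
        "n_structures": len(models),
        "n_pockets_detected": n_detected,
        "n_records_emitted": sum(1 for r in records if r.rejected_reason == "none"),
        "rejection_counts": counts,
        "pockets": fates,
    }

    _write_outputs(out_dir, config, records, cys_by_pocket, report)
    return RunResult(records=records, cysteines=cys_by_pocket, report=report)


def _record_row(r: cl.PocketRecord, cys: list[cr.CysteineSite]) -> dict:
    p = r.properties
    return {
        "enzyme_id": r.enzyme_id,
        "structure_id": r.structure_id,
        "pocket_id": r.pocket_id,
        "category": r.category or "",
        "domain_id": r.domain_id or "",
        "confidence": "" if r.confidence is None else r.confidence,
        "volume": "" if p is None else f"{p.volume:.1f}",
        "area": "" if p is None else f"{p.area:.1f}",
        "hydrophobicity": "" if p is None else f"{p.hydrophobicity:.3f}",
        "buriedness": "" if p is None else f"{p.buriedness:.3f}",
        "dlid": "" if p is None else f"{p.dlid:.3f}",
        "min_dist_catalytic": ""
        if r.min_dist_catalytic is None
        else f"{r.min_dist_catalytic:.2f}",
        "pseudo_sequence": ";".join(
            f"{c}:{lo}-{hi}" for c, (lo, hi) in sorted(r.pseudo_sequence.items())
        ),
        "site_label": r.site_label,
        "structure_less": str(r.structure_less).lower(),
        "reactive_cysteines": ";".join(
            f"{s.residue.chain_id}{s.residue.author_seq_num}:{s.score:.3f}"
            for s in cys
            if s.reactive
        ),
    }


def _write_outputs(out_dir: Path, config: RunConfig, records, cys_by_pocket, report) -> None:
    import csv

    rows = [
        _record_row(r, cys_by_pocket.get((r.structure_id, r.pocket_id), []))
        for r in records
        if r.rejected_reason == "none"
    ]
    rows.sort(key=lambda d: (d["structure_id"], d["pocket_id"]))
    columns = list(_record_row(cl.PocketRecord("x", "x", "x", category="interface"), []).keys())
    with open(out_dir / "compendium.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
    with open(out_dir / "compendium.jsonl", "w") as fh:
        for row in rows:
            fh.write(json.dumps(row) + "\n")
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=1))
    cfg = dataclasses.asdict(config)
    (out_dir / "run_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
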