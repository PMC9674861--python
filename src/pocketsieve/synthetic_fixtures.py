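"""Synthetic structure and annotation generator.

Emits PDB-format pseudo-proteins with analytically known cavities plus the
matching annotation and truth files, so every pipeline stage can be tested
without downloading real structures. Two building blocks are used:

* **hollow shells** — concentric Fibonacci-lattice spheres of carbon
  pseudo-atoms whose solvent-impermeable wall encloses a spherical void of
  radius ``R_inner − (r_C + r_probe)``; void volume and surface are exact
  sphere formulas;
* **well blocks** — a cubic carbon lattice with a cylindrical well open to
  solvent, giving a deep but partially open pocket (buriedness < 1) whose
  volume is bracketed by cylinder formulas.

Atoms are grouped three per residue into UNK residues (plain carbons, so
pocket hydrophobicity is analytically 1.0) and each geometric site sits on
its own chain with its own UniProt numbering block, which lets one
annotation document drive multi-structure series. The ``enzyme_series``
fixture emits three structures of one synthetic enzyme whose pockets each
exercise exactly one rejection branch (catalytic, cofactor, missing
density, duplicate, unligandable) around a single scripted survivor.

Generation is deterministic: a fixed spec and seed reproduce identical
bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cavity_grid import PROBE_RADIUS, VDW_RADII, build_grid
from .structure_io import Atom, Residue, StructureModel, write_pdb

__all__ = ["FixtureSpec", "FixtureResult", "make_fixture", "GeneratorError"]

CARBON_CLEARANCE = VDW_RADII["C"] + PROBE_RADIUS  # 3.1 Å: atom center to void surface
SHELL_STEP = 1.1  # Å between concentric shells
N_SHELLS = 4
POINT_DENSITY = 17.9  # Fibonacci points per Å² of shell: ~0.9 Å point spacing
BLOCK_LATTICE = 1.05  # Å cubic lattice of well blocks


class GeneratorError(RuntimeError):
    pass


@dataclass
class FixtureSpec:
    kind: str  # hollow_shell | solid_sphere | open_groove | two_void | dimer_interface | enzyme_series
    params: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class FixtureResult:
    structure_paths: list[Path]
    annotation_path: Path
    truth_path: Path
    truth: dict


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _shell_points(radius: float) -> np.ndarray:
    n = max(32, int(np.ceil(POINT_DENSITY * radius**2)))
    return radius * fibonacci_sphere(n)


def shell_site(
    center: np.ndarray,
    r_void: float,
    chain_id: str,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[Residue]:
    """Concentric-shell wall enclosing a void of radius ``r_void``.

    Residue numbering is by (shell index, point triple), so two sites of the
    same chain built with different void radii still number the shared inner
    wall consistently — emulating two conformations of one protein."""
    center = np.asarray(center, dtype=float)
    residues: list[Residue] = []
    for s in range(N_SHELLS):
        pts = _shell_points(r_void + CARBON_CLEARANCE + s * SHELL_STEP)
        if jitter > 0 and rng is not None:
            pts = pts + rng.uniform(-jitter, jitter, pts.shape)
        for t in range(0, len(pts), 3):
            group = pts[t : t + 3]
            num = s * 2000 + t // 3 + 1
            residues.append(
                Residue(
                    chain_id=chain_id,
                    author_seq_num=num,
                    name="UNK",
                    atoms=[
                        Atom(name=f"C{k + 1}", element="C", position=center + p)
                        for k, p in enumerate(group)
                    ],
                )
            )
    return residues


def well_block(
    center: np.ndarray,
    chain_id: str,
    well_radius: float = 7.3,
    well_depth: float = 11.0,
    half_width: float = 10.5,
    floor: float = 4.0,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[Residue]:
    """Cubic carbon lattice with a cylindrical well carved from the top face.

    ``center`` is the middle of the top face; the well axis is −z. Residue
    numbering enumerates the *uncarved* lattice, so blocks that differ only
    in the carve share residue identities."""
    center = np.asarray(center, dtype=float)
    xs = np.arange(-half_width, half_width + 1e-9, BLOCK_LATTICE)
    zs = np.arange(-(well_depth + floor), 1e-9, BLOCK_LATTICE)
    residues: list[Residue] = []
    pending: list[np.ndarray] = []
    num = 0
    count = 0
    for x in xs:
        for y in xs:
            for z in zs:
                count += 1
                if count % 3 == 1:
                    num += 1
                    pending = []
                in_well = (x * x + y * y) <= well_radius**2 and z > -well_depth
                if in_well:
                    continue
                p = np.array([x, y, z])
                if jitter > 0 and rng is not None:
                    p = p + rng.uniform(-jitter, jitter, 3)
                pending.append(center + p)
                if not residues or residues[-1].author_seq_num != num:
                    residues.append(
                        Residue(chain_id=chain_id, author_seq_num=num, name="UNK", atoms=[])
                    )
                residues[-1].atoms.append(
                    Atom(name=f"C{len(residues[-1].atoms) + 1}", element="C", position=pending[-1])
                )
    return [r for r in residues if r.atoms]


def _model(structure_id: str, residues: list[Residue]) -> StructureModel:
    residues = sorted(residues, key=lambda r: (r.chain_id, r.author_seq_num))
    chains = {r.chain_id for r in residues}
    return StructureModel(
        structure_id=structure_id,
        residues=residues,
        entity_of_chain={c: c for c in sorted(chains)},
    )


def _check_enclosed(model: StructureModel, void_centers: list[np.ndarray]) -> None:
    """Fail loudly when a nominally enclosed void leaks to bulk solvent."""
    grid = build_grid(model, spacing=0.8, padding=5.0)
    for c in void_centers:
        idx = np.rint((np.asarray(c) - grid.origin) / grid.spacing).astype(int)
        idx = np.clip(idx, 0, np.array(grid.dims) - 1)
        if grid.protein_mask[tuple(idx)]:
            raise GeneratorError(f"void center {c} fell inside the protein mask")
        if grid.exterior_mask[tuple(idx)]:
            raise GeneratorError(f"void at {c} leaks to the exterior (wall too coarse)")


def _sphere_truth(r_void: float) -> dict:
    return {
        "void_volume": 4.0 / 3.0 * np.pi * r_void**3,
        "void_area": 4.0 * np.pi * r_void**2,
        "volume_tolerance": 0.10,
        "area_tolerance": 0.15,
    }


def _well_truth(well_radius: float, well_depth: float) -> dict:
    """Detected volume bracket for a cylindrical well.

    The effective void cylinder has radius a = well_radius − clearance and
    depth h = well_depth − clearance; scan-line burial prunes the open top
    over roughly one radius, so the detected volume lies between
    π a² (h − 1.5 a) and π a² h."""
    a = well_radius - CARBON_CLEARANCE
    h = well_depth - CARBON_CLEARANCE
    return {
        "well_void_radius": a,
        "well_void_depth": h,
        "volume_min": np.pi * a * a * max(h - 1.5 * a, 0.0),
        "volume_max": np.pi * a * a * h,
        "buriedness_min": 0.6,
        "buriedness_max": 0.97,
    }


def _residue_map_ranges(residues: list[Residue], uniprot_base: dict[str, int]) -> list[dict]:
    """Compact identity-with-offset residue-map ranges per chain."""
    out = []
    per_chain: dict[str, list[int]] = {}
    for r in residues:
        per_chain.setdefault(r.chain_id, []).append(r.author_seq_num)
    for chain, nums in sorted(per_chain.items()):
        nums = sorted(set(nums))
        base = uniprot_base[chain]
        start = prev = nums[0]
        for n in nums[1:] + [None]:
            if n is not None and n == prev + 1:
                prev = n
                continue
            out.append(
                {
                    "chain": chain,
                    "author_start": start,
                    "author_end": prev,
                    "uniprot_start": base + start,
                }
            )
            if n is not None:
                start = prev = n
    return out


def _write_annotation(path: Path, doc: dict) -> None:
    import yaml

    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureResult:
    """Generate the structure file(s), annotation file and truth file of one
    fixture kind under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    kind = spec.kind

    if kind == "hollow_shell":
        r_void = float(p.get("r_void", 5.0))
        jitter = float(p.get("jitter", 0.0))
        res = shell_site(np.zeros(3), r_void, "A", jitter, rng)
        model = _model("hollow_shell", res)
        _check_enclosed(model, [np.zeros(3)])
        truth = {"kind": kind, "n_pockets": 1, "pockets": [_sphere_truth(r_void)]}
        sites = {"A": 0}

    elif kind == "solid_sphere":
        radius = float(p.get("radius", 8.0))
        pts = []
        ax = np.arange(-radius, radius + 1e-9, BLOCK_LATTICE)
        for x in ax:
            for y in ax:
                for z in ax:
                    if x * x + y * y + z * z <= radius**2:
                        pts.append(np.array([x, y, z]))
        residues = []
        for t in range(0, len(pts), 3):
            residues.append(
                Residue(
                    chain_id="A",
                    author_seq_num=t // 3 + 1,
                    name="UNK",
                    atoms=[
                        Atom(name=f"C{k + 1}", element="C", position=q)
                        for k, q in enumerate(pts[t : t + 3])
                    ],
                )
            )
        model = _model("solid_sphere", residues)
        truth = {"kind": kind, "n_pockets": 0, "pockets": []}
        sites = {"A": 0}

    elif kind == "open_groove":
        well_radius = float(p.get("well_radius", 7.3))
        well_depth = float(p.get("well_depth", 11.0))
        res = well_block(np.zeros(3), "A", well_radius, well_depth)
        model = _model("open_groove", res)
        truth = {
            "kind": kind,
            "n_pockets": 1,
            "pockets": [_well_truth(well_radius, well_depth)],
        }
        sites = {"A": 0}

    elif kind == "two_void":
        r1 = float(p.get("r_void_1", 4.0))
        r2 = float(p.get("r_void_2", 3.5))
        sep = float(p.get("separation", 30.0))
        c1 = np.array([-sep / 2, 0.0, 0.0])
        c2 = np.array([sep / 2, 0.0, 0.0])
        res = shell_site(c1, r1, "A") + shell_site(c2, r2, "B")
        model = _model("two_void", res)
        _check_enclosed(model, [c1, c2])
        truth = {
            "kind": kind,
            "n_pockets": 2,
            "pockets": [_sphere_truth(r1), _sphere_truth(r2)],
        }
        sites = {"A": 0, "B": 10000}

    elif kind == "dimer_interface":
        r_void = float(p.get("r_void", 4.0))
        partner_role = str(p.get("partner_role", "cofactor_protein"))
        res = shell_site(np.zeros(3), r_void, "A")
        # upper hemisphere of the wall belongs to the partner chain
        for r in res:
            if np.mean([a.position[2] for a in r.atoms]) > 0:
                r.chain_id = "B"
        merged: dict[tuple[str, int], Residue] = {}
        for r in res:
            merged[(r.chain_id, r.author_seq_num)] = r
        model = _model("dimer_interface", list(merged.values()))
        _check_enclosed(model, [np.zeros(3)])
        truth = {
            "kind": kind,
            "n_pockets": 1,
            "pockets": [_sphere_truth(r_void)],
            "interface": True,
            "inhibitor_reject": partner_role == "inhibitor_protein",
        }
        sites = {"A": 0, "B": 10000}

    elif kind == "enzyme_series":
        return _enzyme_series(spec, out_dir, rng)

    else:
        raise GeneratorError(f"unknown fixture kind {spec.kind!r}")

    struct_path = out_dir / f"{kind}.pdb"
    write_pdb(model, struct_path)
    annot_path = out_dir / f"{kind}_annotation.yaml"
    doc = {
        "enzyme_id": f"SYN_{kind.upper()}",
        "residue_map": _residue_map_ranges(model.residues, sites),
        "entity_roles": {c: "enzyme" for c in model.chain_ids},
    }
    if kind == "dimer_interface":
        doc["entity_roles"]["B"] = str(p.get("partner_role", "cofactor_protein"))
    _write_annotation(annot_path, doc)
    truth_path = out_dir / f"{kind}_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return FixtureResult([struct_path], annot_path, truth_path, truth)


# site centers of the enzyme_series layout (Å)
_SERIES_CENTERS = {
    "D": np.array([0.0, 0.0, 0.0]),  # catalytic pocket, in every structure
    "A": np.array([0.0, 46.0, 0.0]),  # survivor well (s2)
    "E": np.array([46.0, 46.0, 0.0]),  # duplicate pair (s1 small, s2 large)
    "B": np.array([46.0, 0.0, 0.0]),  # cofactor pocket (s1)
    "C": np.array([46.0, 0.0, 0.0]),  # gap-flanked pocket (s2; B and C never co-occur)
}
_SERIES_UNIPROT_BASE = {"D": 0, "A": 10000, "E": 20000, "B": 30000, "C": 40000}
_GAP_FLANKS = (45001, 45007)  # uniprot numbers of the two resolved gap flanks
_GAP_MISSING = [45002, 45003, 45004, 45005, 45006]


def _gap_flank_residues(center: np.ndarray, r_void: float) -> list[Residue]:
    """Two single-atom residues embedded in the inner wall of the gap site;
    the unresolved run between them localizes at their midpoint."""
    radius = r_void + CARBON_CLEARANCE
    out = []
    for author, theta in ((9001, 0.0), (9002, 0.15)):
        pos = center + radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        out.append(
            Residue(
                chain_id="C",
                author_seq_num=author,
                name="UNK",
                atoms=[Atom(name="CA", element="C", position=pos)],
            )
        )
    return out


def _enzyme_series(spec: FixtureSpec, out_dir: Path, rng: np.random.Generator) -> FixtureResult:
    p = spec.params
    jitter = float(p.get("jitter", 0.0))
    enzyme_id = str(p.get("enzyme_id", "SYNENZ1"))
    r_cat = 3.2  # void radii (Å) of the scripted sites
    r_dup_small, r_dup_large = 3.6, 4.2
    well_radius, well_depth = 7.3, 11.0

    def site_shell(tag: str, r_void: float) -> list[Residue]:
        return shell_site(_SERIES_CENTERS[tag], r_void, tag, jitter, rng)

    models: dict[str, StructureModel] = {}
    models["s1"] = _model(
        f"{enzyme_id}_s1",
        site_shell("D", r_cat) + site_shell("E", r_dup_small) + site_shell("B", r_cat),
    )
    models["s2"] = _model(
        f"{enzyme_id}_s2",
        site_shell("D", r_cat)
        + well_block(_SERIES_CENTERS["A"], "A", well_radius, well_depth)
        + site_shell("E", r_dup_large)
        + site_shell("C", r_cat)
        + _gap_flank_residues(_SERIES_CENTERS["C"], r_cat),
    )
    models["s3"] = _model(f"{enzyme_id}_s3", site_shell("D", r_cat))

    _check_enclosed(models["s1"], [_SERIES_CENTERS[t] for t in ("D", "E", "B")])
    _check_enclosed(models["s2"], [_SERIES_CENTERS[t] for t in ("D", "E", "C")])

    struct_paths = []
    for sid, model in models.items():
        path = out_dir / f"{enzyme_id}_{sid}.pdb"
        write_pdb(model, path)
        struct_paths.append(path)

    # annotation: identity-with-offset numbering per chain; gap flanks get
    # dedicated uniprot numbers bracketing the unresolved run
    all_residues = [r for m in models.values() for r in m.residues if r.chain_id != "C" or r.author_seq_num < 9000]
    ranges = _residue_map_ranges(all_residues, _SERIES_UNIPROT_BASE)
    ranges.append({"chain": "C", "author": 9001, "uniprot": _GAP_FLANKS[0]})
    ranges.append({"chain": "C", "author": 9002, "uniprot": _GAP_FLANKS[1]})

    catalytic = [1, 2, 3]  # first inner-shell residues of site D
    cofactor = [30001, 30002, 30003]  # inner shell of site B
    doc = {
        "enzyme_id": enzyme_id,
        "residue_map": ranges,
        "catalytic_residues": catalytic,
        "cofactor_residues": cofactor,
        "missing_residues": _GAP_MISSING,
        "domains": [
            {"start": 1, "end": 46000, "domain_id": "CATD", "is_catalytic": True}
        ],
        "entity_roles": {c: "enzyme" for c in "DABEC"},
        "ligand_evidence": [{"site_key": "*", "evidence_class": "high_affinity_ligand"}],
    }
    annot_path = out_dir / f"{enzyme_id}_annotation.yaml"
    _write_annotation(annot_path, doc)

    truth = {
        "kind": "enzyme_series",
        "enzyme_id": enzyme_id,
        "structures": {m.structure_id: sorted({r.chain_id for r in m.residues}) for m in models.values()},
        "n_pockets_total": 8,
        "site_uniprot_base": _SERIES_UNIPROT_BASE,
        "site_volumes": {
            "D": _sphere_truth(r_cat),
            "B": _sphere_truth(r_cat),
            "C": _sphere_truth(r_cat),
            "E_s1": _sphere_truth(r_dup_small),
            "E_s2": _sphere_truth(r_dup_large),
            "A": _well_truth(well_radius, well_depth),
        },
        "expected": {
            "survivors": [
                {
                    "structure_id": f"{enzyme_id}_s2",
                    "site_chain": "A",
                    "category": "non_catalytic_site_catalytic_domain",
                    "domain_id": "CATD",
                    "confidence": 1,
                }
            ],
            "rejections": {
                "catalytic": 3,  # site D in s1, s2, s3
                "cofactor": 1,  # site B in s1
                "missing_density": 1,  # site C in s2
                "duplicate": 1,  # smaller E pocket (s1)
                "unligandable": 1,  # larger E pocket (s2): fully enclosed, buriedness 1
            },
            "duplicate_winner": {"structure_id": f"{enzyme_id}_s2", "site_chain": "E"},
        },
    }
    truth_path = out_dir / f"{enzyme_id}_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return FixtureResult(struct_paths, annot_path, truth_path, truth)
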