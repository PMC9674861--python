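"""Structure ingestion: PDB/mmCIF parsing and biological-assembly expansion.

Parses a deposited structure into a light-weight model holding heavy atoms
only, keyed by author chain/residue numbering. Waters are discarded, altloc
duplicates are collapsed to the highest-occupancy conformer, and only the
first model of multi-model (NMR-style) files is read. The biologically
relevant oligomeric state is produced by applying deposited (or caller
supplied) rotation/translation operators to a chain subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

import gemmi

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "StructureError",
    "parse_structure",
    "expand_assembly",
    "assembly_operators",
    "write_pdb",
]


class StructureError(ValueError):
    """Raised for unreadable files, empty structures or bad operators."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of the model."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name}: non-finite position {pos}")
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )


@dataclass
class Residue:
    """A residue identified by author numbering; uniprot_num is attached later
    from the annotation residue map."""

    chain_id: str
    author_seq_num: int
    insertion_code: str = ""
    name: str = "UNK"
    uniprot_num: int | None = None
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.author_seq_num, self.insertion_code)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """All residues of one biological assembly of one structure."""

    structure_id: str
    residues: list[Residue]
    entity_of_chain: dict[str, str]
    assembly_id: str = "1"

    def __post_init__(self):
        if not self.residues:
            raise StructureError(f"{self.structure_id}: empty structure model")
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            if not r.atoms:
                raise StructureError(f"{self.structure_id}: residue {r.key} has no atoms")
            if r.key in seen:
                raise StructureError(f"{self.structure_id}: duplicate residue {r.key}")
            seen.add(r.key)
        for cid in {r.chain_id for r in self.residues}:
            if cid not in self.entity_of_chain:
                raise StructureError(f"{self.structure_id}: chain {cid} has no entity label")

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def heavy_coords(self) -> np.ndarray:
        return np.vstack([r.heavy_coords() for r in self.residues])

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def residue_by_key(self, chain_id: str, author_seq_num: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.key == (chain_id, author_seq_num, icode):
                return r
        return None


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def _pick_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    # Keep one conformer per atom name: highest occupancy, ties -> first altloc
    # alphabetically (the empty altloc sorts first and wins ties by convention).
    by_name: dict[str, list[Atom]] = {}
    for a in raw_atoms:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occupancy, a.altloc))
        kept.append(group[0])
    return kept


def parse_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``format`` is ``"pdb"`` or ``"mmcif"``; when omitted it is inferred from
    the file extension. Hydrogens and waters are dropped; duplicated altloc
    atoms keep only the highest-occupancy conformer; only model 1 is used.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if format is None:
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if format not in {"pdb", "mmcif"}:
        raise StructureError(f"unknown structure format: {format!r}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    st.setup_entities()
    model = st[0]

    residues: list[Residue] = []
    entity_of_chain: dict[str, str] = {}
    for chain in model:
        cid = chain.name
        entity_of_chain.setdefault(cid, cid)
        for res in chain:
            if res.name.strip() in _WATER_NAMES or res.is_water():
                continue
            raw: list[Atom] = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                raw.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(float(at.occ), 0.0), 1.0),
                        altloc=at.altloc if at.altloc != "\x00" else "",
                        is_hetero=res.het_flag == "H",
                    )
                )
            if not raw:
                continue
            residues.append(
                Residue(
                    chain_id=cid,
                    author_seq_num=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    name=res.name.strip(),
                    atoms=_pick_altlocs(raw),
                )
            )
    polymer_atoms = sum(len(r.atoms) for r in residues if not r.atoms[0].is_hetero)
    if polymer_atoms == 0:
        raise StructureError(f"{path}: zero polymer atoms after filtering")
    return StructureModel(
        structure_id=st.name or path.stem,
        residues=residues,
        entity_of_chain=entity_of_chain,
    )


def assembly_operators(
    path: str | Path, assembly_id: str = "1"
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Extract (rotation, translation) operators of one deposited assembly
    from an mmCIF file; PDB files (no operator categories) yield the identity."""
    path = Path(path)
    if path.suffix.lower() not in {".cif", ".mmcif"}:
        return [(np.eye(3), np.zeros(3))]
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    for asm in st.assemblies:
        if asm.name == assembly_id:
            ops = []
            for gen in asm.generators:
                for oper in gen.operators:
                    t = np.array(oper.transform.mat.tolist(), dtype=float)
                    vec = oper.transform.vec
                    ops.append((t, np.array([vec.x, vec.y, vec.z])))
            if ops:
                return ops
    return [(np.eye(3), np.zeros(3))]


def _check_rotation(rot: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3):
        raise StructureError(f"rotation must be 3x3, got {rot.shape}")
    if not np.allclose(rot @ rot.T, np.eye(3), atol=tol):
        raise StructureError("rotation matrix is not orthonormal within 1e-6")
    return rot


def expand_assembly(
    model: StructureModel,
    ops: Sequence[tuple[np.ndarray, np.ndarray]],
    chain_subset: Iterable[str] | None = None,
) -> StructureModel:
    """Apply rigid-body operators to a chain subset, producing the oligomeric
    assembly. Copy *i* > 0 of chain ``A`` becomes chain ``A_i``; entity labels
    are inherited from the source chain."""
    if not ops:
        raise StructureError("empty operator list")
    chains = list(chain_subset) if chain_subset is not None else model.chain_ids
    missing = set(chains) - set(model.chain_ids)
    if missing:
        raise StructureError(f"chain subset not in model: {sorted(missing)}")

    residues: list[Residue] = []
    entity_of_chain: dict[str, str] = {}
    for i, (rot, trans) in enumerate(ops):
        rot = _check_rotation(rot)
        trans = np.asarray(trans, dtype=float).reshape(3)
        suffix = "" if i == 0 else f"_{i}"
        for r in model.residues:
            if r.chain_id not in chains:
                continue
            new_cid = r.chain_id + suffix
            entity_of_chain[new_cid] = model.entity_of_chain[r.chain_id]
            residues.append(
                Residue(
                    chain_id=new_cid,
                    author_seq_num=r.author_seq_num,
                    insertion_code=r.insertion_code,
                    name=r.name,
                    uniprot_num=r.uniprot_num,
                    atoms=[
                        replace(a, position=rot @ a.position + trans) for a in r.atoms
                    ],
                )
            )
    return StructureModel(
        structure_id=model.structure_id,
        residues=residues,
        entity_of_chain=entity_of_chain,
        assembly_id=model.assembly_id,
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a minimal PDB file (ATOM/HETATM/TER/END records).

    Coordinates are emitted at the PDB format precision of 1e-3 Å; chain ids
    longer than one character are truncated to their first character, so
    fixture generators should use single-letter chains.
    """
    path = Path(path)
    lines = []
    serial = 1
    last_chain = None
    for r in model.residues:
        if last_chain is not None and r.chain_id != last_chain:
            lines.append("TER")
        last_chain = r.chain_id
        for a in r.atoms:
            rec = "HETATM" if a.is_hetero else "ATOM  "
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.position
            lines.append(
                f"{rec}{serial % 100000:5d} {name:<4.4s}{a.altloc or ' '}"
                f"{r.name:<3.3s} {r.chain_id[:1]}{r.author_seq_num % 10000:4d}"
                f"{r.insertion_code or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2.2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
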