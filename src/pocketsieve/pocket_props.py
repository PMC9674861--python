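"""Ligandability descriptors: volume, area, hydrophobicity, buriedness, DLID.

These are the five properties the downstream filter thresholds act on
(volume 155.7–661.1 Å³, area 155–655 Å², hydrophobicity > 0.44, buriedness
0.6–0.95, DLID > −1). Volume and buriedness come straight from the pocket
cell set; area from a marching-cubes surface of the cell field (with a
face-count fallback); hydrophobicity as the apolar fraction of lining
contact atoms; DLID as a k-nearest-neighbour log-odds of drug-likeness in
(log volume, buriedness, hydrophobicity) space against a reference table of
known drug-like and non-drug-like pockets. The packaged reference table is
synthetic (see its header) and swappable for a user-curated one.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure

from .cavity_grid import CavityGrid, Pocket
from .structure_io import StructureModel

__all__ = [
    "PocketProperties",
    "LigandabilityThresholds",
    "PropertyError",
    "compute_volume",
    "compute_area",
    "compute_buriedness",
    "compute_hydrophobicity",
    "compute_dlid",
    "compute_properties",
    "load_dlid_reference",
    "kyte_doolittle_hydrophobicity",
]


class PropertyError(ValueError):
    pass


@dataclass
class PocketProperties:
    volume: float  # Å³
    area: float  # Å²
    hydrophobicity: float  # fraction of apolar contact atoms, [0, 1]
    buriedness: float  # fraction of boundary in protein contact, [0, 1]
    dlid: float  # drug-like density log-odds

    def __post_init__(self):
        if self.volume <= 0 or self.area <= 0:
            raise PropertyError("volume and area must be positive")
        if not (0.0 <= self.hydrophobicity <= 1.0 and 0.0 <= self.buriedness <= 1.0):
            raise PropertyError("hydrophobicity and buriedness must lie in [0, 1]")


@dataclass(frozen=True)
class LigandabilityThresholds:
    """Descriptor windows of experimentally druggable pockets; range ends are
    inclusive, the hydrophobicity and DLID cuts are strict."""

    volume_range: tuple[float, float] = (155.7, 661.1)
    area_range: tuple[float, float] = (155.0, 655.0)
    hydrophobicity_min: float = 0.44
    buriedness_range: tuple[float, float] = (0.6, 0.95)
    dlid_min: float = -1.0

    def __post_init__(self):
        for lo, hi in (self.volume_range, self.area_range, self.buriedness_range):
            if not lo < hi:
                raise PropertyError(f"degenerate range ({lo}, {hi})")


def compute_volume(pocket: Pocket, grid: CavityGrid | None = None) -> float:
    """Pocket volume = cell count × spacing³."""
    if pocket.n_cells == 0:
        raise PropertyError("empty pocket")
    spacing = grid.spacing if grid is not None else pocket.spacing
    return pocket.n_cells * spacing**3


def compute_buriedness(pocket: Pocket, grid: CavityGrid | None = None) -> float:
    """Fraction of the pocket's boundary faces in contact with protein."""
    if pocket.boundary_faces == 0:
        raise PropertyError("pocket has no boundary faces")
    return pocket.protein_faces / pocket.boundary_faces


def compute_area(
    pocket: Pocket, grid: CavityGrid | None = None, method: str = "marching_cubes"
) -> float:
    """Surface area of the pocket cell field.

    ``marching_cubes`` triangulates the 0.5 iso-surface of the occupancy
    field (less staircase bias); ``face_count`` multiplies the boundary face
    area by a 2/3 staircase correction and exists as an analytic oracle.
    """
    if pocket.n_cells == 0:
        raise PropertyError("empty pocket")
    spacing = grid.spacing if grid is not None else pocket.spacing
    if method == "face_count":
        return pocket.boundary_faces * spacing**2 * (2.0 / 3.0)
    if method != "marching_cubes":
        raise PropertyError(f"unknown area method {method!r}")
    idx = pocket.cells - pocket.cells.min(axis=0)
    shape = tuple(idx.max(axis=0) + 1)
    field = np.zeros(shape, dtype=float)
    field[tuple(idx.T)] = 1.0
    field = np.pad(field, 1)
    verts, faces, _, _ = measure.marching_cubes(
        field, level=0.5, spacing=(spacing,) * 3
    )
    return float(measure.mesh_surface_area(verts, faces))


# Side-chain heavy atoms that are carbon not bonded to N/O, or sulfur,
# per standard amino-acid topology. Backbone CA and C are bonded to N/O
# and therefore polar under this rule.
APOLAR_ATOMS: dict[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "ARG": frozenset({"CB", "CG"}),
    "ASN": frozenset({"CB"}),
    "ASP": frozenset({"CB"}),
    "CYS": frozenset({"CB", "SG"}),
    "GLN": frozenset({"CB", "CG"}),
    "GLU": frozenset({"CB", "CG"}),
    "GLY": frozenset(),
    "HIS": frozenset({"CB"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "LYS": frozenset({"CB", "CG", "CD"}),
    "MET": frozenset({"CB", "CG", "SD", "CE"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "PRO": frozenset({"CB", "CG"}),
    "SER": frozenset(),
    "THR": frozenset({"CG2"}),
    "TRP": frozenset({"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
}

KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


def _atom_is_apolar(res_name: str, atom_name: str, element: str) -> bool:
    table = APOLAR_ATOMS.get(res_name)
    if table is not None:
        return atom_name in table
    # Non-standard residue: fall back to the element rule.
    return element.upper() in {"C", "S"}


def compute_hydrophobicity(
    pocket: Pocket,
    model: StructureModel | None = None,
    contact_cutoff: float = 4.5,
    side_chain_only: bool = False,
) -> float:
    """Apolar fraction of lining heavy atoms within ``contact_cutoff`` of the
    pocket envelope. Apolar = carbon not bonded to N/O (by residue topology)
    or sulfur. ``side_chain_only`` drops backbone atoms from the contact set."""
    if not pocket.lining_residues:
        raise PropertyError("pocket has no lining residues")
    tree = cKDTree(pocket.envelope_vertices)
    backbone = {"N", "CA", "C", "O", "OXT"}
    n_contact = 0
    n_apolar = 0
    for res in pocket.lining_residues:
        for atom in res.atoms:
            if side_chain_only and atom.name in backbone:
                continue
            d, _ = tree.query(atom.position, k=1)
            if d <= contact_cutoff:
                n_contact += 1
                if _atom_is_apolar(res.name, atom.name, atom.element):
                    n_apolar += 1
    if n_contact == 0:
        raise PropertyError("no lining atoms within the contact cutoff")
    return n_apolar / n_contact


def kyte_doolittle_hydrophobicity(pocket: Pocket) -> float:
    """Alternative residue-level scale: mean Kyte–Doolittle index of the
    lining residues, rescaled from [−4.5, 4.5] to [0, 1]."""
    if not pocket.lining_residues:
        raise PropertyError("pocket has no lining residues")
    vals = [KYTE_DOOLITTLE.get(r.name, 0.0) for r in pocket.lining_residues]
    return float(np.clip((np.mean(vals) + 4.5) / 9.0, 0.0, 1.0))


def load_dlid_reference(path: str | Path | None = None) -> pd.DataFrame:
    """Reference pocket table for DLID: columns volume, buriedness,
    hydrophobicity, is_druglike. Defaults to the packaged synthetic table."""
    if path is None:
        src = resources.files("pocketsieve").joinpath("data/dlid_reference_synthetic.tsv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    required = {"volume", "buriedness", "hydrophobicity", "is_druglike"}
    if not required.issubset(table.columns):
        raise PropertyError(
            f"DLID reference needs columns {sorted(required)}, got {list(table.columns)}"
        )
    table = table.astype(
        {"volume": float, "buriedness": float, "hydrophobicity": float, "is_druglike": bool}
    )
    if table["is_druglike"].all() or (~table["is_druglike"]).all():
        raise PropertyError("DLID reference needs both drug-like and non-drug-like rows")
    return table


def compute_dlid(
    volume: float,
    buriedness: float,
    hydrophobicity: float,
    reference: pd.DataFrame | None = None,
    k: int = 20,
    epsilon: float = 0.5,
) -> float:
    """Drug-like density score.

    The query and reference pockets are embedded in z-normalized
    (log volume, buriedness, hydrophobicity) space; among the k nearest
    reference pockets, DLID = log10((n_druglike + ε) / (n_nondruglike + ε)).
    Positive values mean the pocket sits in a drug-like neighbourhood; the
    downstream filter cut is > −1.
    """
    if reference is None:
        reference = load_dlid_reference()
    feats = np.column_stack(
        [np.log(reference["volume"]), reference["buriedness"], reference["hydrophobicity"]]
    )
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z_ref = (feats - mu) / sd
    q = (np.array([np.log(volume), buriedness, hydrophobicity]) - mu) / sd
    d = np.linalg.norm(z_ref - q, axis=1)
    k = min(k, len(reference))
    nearest = np.argsort(d, kind="stable")[:k]
    labels = reference["is_druglike"].to_numpy()[nearest]
    n_pos = int(labels.sum())
    n_neg = k - n_pos
    return float(np.log10((n_pos + epsilon) / (n_neg + epsilon)))


def compute_properties(
    pocket: Pocket,
    grid: CavityGrid,
    model: StructureModel,
    reference: pd.DataFrame | None = None,
    area_method: str = "marching_cubes",
) -> PocketProperties:
    """All five descriptors for one pocket (lining residues must be set)."""
    volume = compute_volume(pocket, grid)
    area = compute_area(pocket, grid, method=area_method)
    buriedness = compute_buriedness(pocket, grid)
    hydrophobicity = compute_hydrophobicity(pocket, model)
    dlid = compute_dlid(volume, buriedness, hydrophobicity, reference)
    return PocketProperties(
        volume=volume,
        area=area,
        hydrophobicity=hydrophobicity,
        buriedness=buriedness,
        dlid=dlid,
    )
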