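"""Reactive-cysteine scoring for pocket-lining cysteines.

Covalent chemical handles need a nucleophilic cysteine in or near the
pocket. This module scores each cysteine whose residue lies within the
lining cutoff of an accepted pocket with a logistic surrogate model over
three structure-derived features: burial of the SG thiol (buried thiols in
polar microenvironments are more frequently reactive in proteomic
profiling), the count of polar N/O atoms near SG from other residues
(hydrogen-bond stabilization of the thiolate), and pocket membership.
Disulfide-bonded cysteines (SG–SG < 2.5 Å) are excluded outright.

This scorer is NOT the proprietary model trained on isoTOP-ABPP data that
inspired it; the default weights are heuristic and an optional re-fit entry
point accepts a user-supplied labelled feature table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cavity_grid import Pocket
from .structure_io import Residue, StructureModel

__all__ = [
    "CysteineSite",
    "DEFAULT_WEIGHTS",
    "score_cysteines",
    "sg_exposure",
    "fit_weights",
]

# (w0, w_exposure, w_polar, w_pocket): intercept, burial term (applied to
# 1 - exposure), polar-neighbour count term, pocket-membership term.
DEFAULT_WEIGHTS: tuple[float, float, float, float] = (-2.0, 1.5, 0.6, 0.5)
DISULFIDE_CUTOFF = 2.5  # Å, SG–SG
POLAR_NEIGHBOR_CUTOFF = 6.0  # Å around SG
_SG_SPHERE_SASA = 4.0 * np.pi * (1.8 + 1.4) ** 2  # isolated SG + probe, Å²


@dataclass
class CysteineSite:
    residue: Residue
    sg_exposure: float  # fraction of free-atom SASA retained, [0, 1]
    n_polar_neighbors: int
    dist_to_pocket: float  # Å, SG to nearest envelope vertex
    pocket_id: str
    score: float  # probability, [0, 1]
    reactive: bool


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def sg_exposure(model: StructureModel, sg_index: int, coords=None, elements=None) -> float:
    """Solvent exposure of one SG atom: Shrake–Rupley SASA in the context of
    all heavy atoms, normalized by the SASA of an isolated SG sphere."""
    import biotite.structure as struc

    if coords is None:
        coords = model.heavy_coords()
        elements = [a.element for r in model.residues for a in r.atoms]
    arr = struc.AtomArray(len(coords))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.element = np.array([e.upper() for e in elements])
    arr.res_id = np.arange(len(coords))
    arr.atom_name = np.array(["X"] * len(coords))
    arr.res_name = np.array(["UNK"] * len(coords))
    arr.chain_id = np.array(["A"] * len(coords))
    mask = np.zeros(len(coords), dtype=bool)
    mask[sg_index] = True
    sasa = struc.sasa(arr, probe_radius=1.4, atom_filter=mask, vdw_radii="Single")
    return float(np.clip(np.nansum(sasa) / _SG_SPHERE_SASA, 0.0, 1.0))


def score_cysteines(
    model: StructureModel,
    pockets: list[Pocket],
    weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS,
    cutoff: float = 0.5,
    pocket_cutoff: float = 2.8,
) -> list[CysteineSite]:
    """Score every cysteine lining an accepted pocket.

    score = logistic(w0 + w_exposure·(1 − sg_exposure) + w_polar·n_polar
    + w_pocket); ``reactive`` iff score ≥ ``cutoff``. Cysteines further than
    ``pocket_cutoff`` from every pocket envelope, and disulfide-bonded
    pairs, are not scored.
    """
    if not all(np.isfinite(weights)):
        raise ValueError("weights must be finite")
    w0, w_exp, w_pol, w_pocket = weights

    cys = [(r, r.atom("SG")) for r in model.residues if r.name == "CYS"]
    cys = [(r, sg) for r, sg in cys if sg is not None]
    if not cys or not pockets:
        return []

    # disulfide exclusion
    sg_pos = np.array([sg.position for _, sg in cys])
    tree = cKDTree(sg_pos)
    disulfide = set()
    for i, j in tree.query_pairs(DISULFIDE_CUTOFF):
        disulfide.update((i, j))

    coords = model.heavy_coords()
    elements = [a.element for r in model.residues for a in r.atoms]
    flat_residues = [r for r in model.residues for _ in r.atoms]
    polar = np.array([e.upper() in {"N", "O"} for e in elements])
    atom_tree = cKDTree(coords)
    pocket_trees = [(p, cKDTree(p.envelope_vertices)) for p in pockets]

    sites: list[CysteineSite] = []
    for i, (res, sg) in enumerate(cys):
        if i in disulfide:
            continue
        # nearest accepted pocket: membership requires any heavy atom of the
        # residue within pocket_cutoff of the envelope (the lining rule)
        best = None
        res_coords = res.heavy_coords()
        for p, ptree in pocket_trees:
            d_res = float(np.min(ptree.query(res_coords, k=1)[0]))
            d_sg = float(ptree.query(sg.position, k=1)[0])
            if d_res <= pocket_cutoff and (best is None or d_sg < best[1]):
                best = (p, d_sg)
        if best is None:
            continue

        sg_idx = None
        # locate SG in the flat atom order for SASA and neighbour lookups
        offset = 0
        for r in model.residues:
            if r is res:
                for k, a in enumerate(r.atoms):
                    if a.name == "SG":
                        sg_idx = offset + k
                break
            offset += len(r.atoms)
        exposure = sg_exposure(model, sg_idx, coords, elements)
        neighbors = atom_tree.query_ball_point(sg.position, POLAR_NEIGHBOR_CUTOFF)
        n_polar = sum(
            1 for k in neighbors if polar[k] and flat_residues[k] is not res
        )
        score = _logistic(w0 + w_exp * (1.0 - exposure) + w_pol * n_polar + w_pocket)
        sites.append(
            CysteineSite(
                residue=res,
                sg_exposure=exposure,
                n_polar_neighbors=n_polar,
                dist_to_pocket=best[1],
                pocket_id=best[0].pocket_id,
                score=score,
                reactive=score >= cutoff,
            )
        )
    return sites


def fit_weights(features: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float]:
    """Re-fit the logistic weights on a labelled table.

    ``features`` columns: (1 − sg_exposure, n_polar_neighbors, in_pocket);
    ``labels``: 1 = reactive, 0 = unreactive. Returns (w0, w_exposure,
    w_polar, w_pocket)."""
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=np.inf, max_iter=1000)
    clf.fit(np.asarray(features, dtype=float), np.asarray(labels, dtype=int))
    w = clf.coef_[0]
    return (float(clf.intercept_[0]), float(w[0]), float(w[1]), float(w[2]))
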