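import numpy as np
import pytest

from pocketsieve import cavity_grid as cg
from pocketsieve import pocket_props as pp
from pocketsieve import structure_io as sio
from pocketsieve import synthetic_fixtures as sf

from conftest import make_residue, single_vertex_pocket


def naive_flood_fill(mask):
    """Independent 6-connected component labelling by explicit stack-based
    flood fill (the oracle the fast labelling is checked against)."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                n = (i + di, j + dj, k + dk)
                if all(0 <= n[a] < mask.shape[a] for a in range(3)) and mask[n] and not labels[n]:
                    labels[n] = nxt
                    stack.append(n)
    return labels


def same_partition(a, b):
    """Two labelings agree up to label permutation."""
    pairs = set(zip(a.ravel(), b.ravel()))
    return (
        len({p for p in pairs if p[0] != 0}) == len({p[0] for p in pairs if p[0] != 0})
        and all((x == 0) == (y == 0) for x, y in pairs)
    )


def test_component_labels_match_naive_flood_fill():
    rng = np.random.default_rng(11)
    for _ in range(25):
        mask = rng.random((20, 20, 20)) < rng.uniform(0.1, 0.6)
        assert same_partition(cg.flood_fill_components(mask), naive_flood_fill(mask))


def _one_atom_model():
    res = make_residue("A", 1, "UNK", [("C1", "C", (0.0, 0.0, 0.0))])
    return sio.StructureModel("one", [res], {"A": "A"})


def test_single_atom_grid_masks():
    """Protein cells are exactly those within vdW+probe of the atom; all
    other cells are exterior (one atom encloses nothing)."""
    model = _one_atom_model()
    grid = cg.build_grid(model, spacing=1.0, padding=5.0)
    centers = np.stack(
        np.meshgrid(*[grid.origin[i] + np.arange(grid.dims[i]) for i in range(3)],
                    indexing="ij"), axis=-1)
    dist = np.linalg.norm(centers, axis=-1)
    expected_protein = dist <= cg.VDW_RADII["C"] + cg.PROBE_RADIUS + 1e-9
    assert np.array_equal(grid.protein_mask, expected_protein)
    assert np.array_equal(grid.exterior_mask, ~expected_protein)
    assert cg.detect_cavities(grid) == []


def test_exterior_connects_between_distant_atoms():
    res = [
        make_residue("A", 1, "UNK", [("C1", "C", (0.0, 0.0, 0.0))]),
        make_residue("A", 2, "UNK", [("C1", "C", (20.0, 0.0, 0.0))]),
    ]
    model = sio.StructureModel("two", res, {"A": "A"})
    grid = cg.build_grid(model, spacing=1.0, padding=5.0)
    free = ~grid.protein_mask
    assert np.array_equal(grid.exterior_mask, free)  # everything open is one bath


def test_spacing_out_of_range_rejected(hollow_shell):
    with pytest.raises(cg.GridError):
        cg.build_grid(hollow_shell["model"], spacing=0.2)
    with pytest.raises(cg.GridError):
        cg.build_grid(hollow_shell["model"], spacing=2.0)


def test_hollow_shell_interior_is_cavity(hollow_shell):
    """Cells well inside the void are neither protein nor exterior; the void
    is detected as exactly one pocket."""
    grid = hollow_shell["grid"]
    center_idx = np.rint((np.zeros(3) - grid.origin) / grid.spacing).astype(int)
    assert not grid.protein_mask[tuple(center_idx)]
    assert not grid.exterior_mask[tuple(center_idx)]
    assert len(hollow_shell["pockets"]) == 1


def test_two_void_partition_matches_bruteforce(fixture_dir):
    res = sf.make_fixture(sf.FixtureSpec("two_void", {}), fixture_dir / "tv")
    model = sio.parse_structure(res.structure_paths[0])
    grid = cg.build_grid(model, spacing=0.8)
    pockets = cg.detect_cavities(grid)
    assert len(pockets) == 2
    # cell partition equals an independent flood fill of the candidate mask
    candidates = np.zeros(grid.dims, dtype=bool)
    for p in pockets:
        candidates[tuple(p.cells.T)] = True
    oracle = naive_flood_fill(candidates)
    for p in pockets:
        labels = {oracle[tuple(c)] for c in p.cells}
        assert len(labels) == 1


def test_pockets_ordered_by_size_and_min_cells(fixture_dir):
    res = sf.make_fixture(sf.FixtureSpec("two_void", {}), fixture_dir / "tv2")
    model = sio.parse_structure(res.structure_paths[0])
    grid = cg.build_grid(model, spacing=0.8)
    pockets = cg.detect_cavities(grid)
    assert pockets[0].n_cells >= pockets[1].n_cells
    assert [p.pocket_id for p in pockets] == ["P1", "P2"]
    # raising min_cells above the smaller void suppresses it
    bigger_only = cg.detect_cavities(grid, min_cells=pockets[1].n_cells + 1)
    assert len(bigger_only) == 1


def test_volume_error_shrinks_with_spacing(fixture_dir):
    """Mean |detected − analytic| / analytic over several grid alignments
    decreases monotonically as the grid is refined 1.0 → 0.75 → 0.5 Å.
    (Single-alignment voxel counts oscillate around the analytic value, so
    convergence is asserted on the alignment-averaged error.)"""
    res = sf.make_fixture(sf.FixtureSpec("hollow_shell", {"r_void": 5.0}), fixture_dir / "conv")
    model = sio.parse_structure(res.structure_paths[0])
    analytic = res.truth["pockets"][0]["void_volume"]
    mean_errors = []
    for spacing in (1.0, 0.75, 0.5):
        errs = []
        for pad_extra in (0.0, 0.29, 0.61, 0.83):  # shifts lattice phase
            grid = cg.build_grid(model, spacing=spacing, padding=5.0 + pad_extra)
            pockets = cg.detect_cavities(grid)
            assert len(pockets) == 1
            vol = pp.compute_volume(pockets[0], grid)
            errs.append(abs(vol - analytic) / analytic)
        mean_errors.append(np.mean(errs))
    assert mean_errors[0] >= mean_errors[1] >= mean_errors[2]
    assert mean_errors[2] < 0.05


def test_rotation_changes_volume_under_5_percent(hollow_shell):
    rng = np.random.default_rng(3)
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=7).as_matrix()
    model = hollow_shell["model"]
    rotated = sio.expand_assembly(model, [(rot, np.zeros(3))])
    grid = cg.build_grid(rotated, spacing=0.5)
    pockets = cg.detect_cavities(grid)
    assert len(pockets) == 1
    v0 = pp.compute_volume(hollow_shell["pockets"][0], hollow_shell["grid"])
    v1 = pp.compute_volume(pockets[0], grid)
    assert abs(v1 - v0) / v0 < 0.05


def test_pocket_cells_respect_masks(hollow_shell):
    grid = hollow_shell["grid"]
    counts = cg.burial_counts(grid)
    for p in hollow_shell["pockets"]:
        cells = tuple(p.cells.T)
        assert not grid.protein_mask[cells].any()
        exterior = grid.exterior_mask[cells]
        assert (counts[cells][exterior] >= 5).all()


class TestLiningResidues:
    def _model_with_atom_at(self, dist):
        res = make_residue("A", 1, "ALA", [("CB", "C", (dist, 0.0, 0.0))])
        return sio.StructureModel("m", [res], {"A": "A"})

    def test_atom_inside_cutoff_included(self):
        pocket = single_vertex_pocket()
        model = self._model_with_atom_at(2.7)
        assert [r.author_seq_num for r in cg.lining_residues(pocket, model)] == [1]

    def test_atom_outside_cutoff_excluded(self):
        pocket = single_vertex_pocket()
        model = self._model_with_atom_at(2.9)
        assert cg.lining_residues(pocket, model) == []

    def test_far_structure_gives_empty_lining(self):
        pocket = single_vertex_pocket()
        model = self._model_with_atom_at(55.0)
        assert cg.lining_residues(pocket, model) == []
        assert pocket.chains_touched == set()

    def test_empty_pocket_rejected(self, hollow_shell):
        empty = single_vertex_pocket()
        empty.cells = np.empty((0, 3), dtype=int)
        with pytest.raises(cg.GridError):
            cg.lining_residues(empty, hollow_shell["model"])
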