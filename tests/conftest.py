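import numpy as np
import pytest

from pocketsieve import cavity_grid as cg
from pocketsieve import pipeline as pl
from pocketsieve import structure_io as sio
from pocketsieve import synthetic_fixtures as sf


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("fixtures")


@pytest.fixture(scope="session")
def hollow_shell(fixture_dir):
    """Shell fixture (void radius 5 Å) parsed, gridded at 0.5 Å and detected."""
    res = sf.make_fixture(sf.FixtureSpec("hollow_shell", {"r_void": 5.0}), fixture_dir)
    model = sio.parse_structure(res.structure_paths[0])
    grid = cg.build_grid(model, spacing=0.5, padding=5.0)
    pockets = cg.detect_cavities(grid)
    for p in pockets:
        cg.lining_residues(p, model)
    return {"result": res, "model": model, "grid": grid, "pockets": pockets}


@pytest.fixture(scope="session")
def enzyme_series(fixture_dir):
    res = sf.make_fixture(sf.FixtureSpec("enzyme_series", {}), fixture_dir / "series")
    return res


@pytest.fixture(scope="session")
def enzyme_series_run(enzyme_series, tmp_path_factory):
    out = tmp_path_factory.mktemp("series_out")
    cfg = pl.RunConfig(
        structures=[str(p) for p in enzyme_series.structure_paths],
        annotation=str(enzyme_series.annotation_path),
        out_dir=str(out),
    )
    return pl.run_pipeline(cfg), cfg


def make_residue(chain, num, name, atom_specs):
    """atom_specs: list of (atom_name, element, xyz)."""
    return sio.Residue(
        chain_id=chain,
        author_seq_num=num,
        name=name,
        atoms=[sio.Atom(n, e, np.asarray(p, dtype=float)) for n, e, p in atom_specs],
    )


def single_vertex_pocket(vertex=(0.0, 0.0, 0.0)):
    """Minimal pocket whose envelope is one vertex, for distance-rule tests."""
    return cg.Pocket(
        pocket_id="T1",
        cells=np.array([[0, 0, 0]]),
        centroid=np.asarray(vertex, dtype=float),
        spacing=1.0,
        protein_faces=6,
        solvent_faces=0,
        envelope_vertices=np.asarray([vertex], dtype=float),
    )
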