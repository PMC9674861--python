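import random

import numpy as np
import pytest

from pocketsieve import classify as cl
from pocketsieve import pocket_props as pp
from pocketsieve import structure_io as sio

from conftest import make_residue, single_vertex_pocket


def annotation(**kw):
    base = dict(enzyme_id="E1", residue_map={})
    base.update(kw)
    return cl.AnnotationSet(**base)


def model_with(residues):
    chains = {r.chain_id for r in residues}
    return sio.StructureModel("S1", residues, {c: c for c in chains})


class TestMinDistance:
    def test_three_four_five_triangle(self):
        res = make_residue("A", 1, "ALA", [("CB", "C", (3.0, 4.0, 0.0))])
        model = model_with([res])
        annot = annotation(residue_map={("A", 1): 10})
        pocket = single_vertex_pocket((0.0, 0.0, 0.0))
        assert cl.min_distance(pocket, [10], model, annot) == pytest.approx(5.0)

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(5)
        verts = rng.uniform(-20, 20, (50, 3))
        atoms = rng.uniform(-20, 20, (50, 3))
        residues = [
            make_residue("A", i + 1, "ALA", [("CB", "C", tuple(a))])
            for i, a in enumerate(atoms)
        ]
        model = model_with(residues)
        annot = annotation(residue_map={("A", i + 1): i + 1 for i in range(50)})
        pocket = single_vertex_pocket()
        pocket.envelope_vertices = verts
        brute = min(
            np.linalg.norm(v - a) for v in verts for a in atoms
        )
        d = cl.min_distance(pocket, list(range(1, 51)), model, annot)
        assert d == pytest.approx(brute, abs=1e-12)

    def test_unresolved_residues_not_measurable(self):
        model = model_with([make_residue("A", 1, "ALA", [("CB", "C", (0, 0, 0))])])
        annot = annotation(residue_map={("A", 1): 10})
        with pytest.raises(cl.NotMeasurable):
            cl.min_distance(single_vertex_pocket(), [99], model, annot)
        with pytest.raises(cl.NotMeasurable):
            cl.min_distance(single_vertex_pocket(), [], model, annot)


@pytest.mark.parametrize(
    "dist,expected",
    [(7.5, "non_catalytic"), (7.0, "catalytic"), (0.0, "catalytic")],
)
def test_catalytic_rule_strict_at_seven(dist, expected):
    assert cl.classify_catalytic(dist) == expected


@pytest.mark.parametrize("dist,keep", [(6.9, False), (7.0, True), (25.0, True)])
def test_cofactor_rule_strict_below_seven(dist, keep):
    assert cl.filter_cofactor(dist) is keep


@pytest.mark.parametrize(
    "dist,outcome", [(4.9, "drop"), (5.0, "keep"), (12.0, "keep")]
)
def test_missing_density_rule(dist, outcome):
    assert cl.filter_missing_density(dist) == outcome


def test_missing_catalytic_excludes_structure():
    assert cl.filter_missing_density(99.0, catalytic_missing=True) == "structure_excluded"


class TestMissingResidueProxies:
    def _model(self, nums):
        residues = [
            make_residue("A", n, "GLY", [("CA", "C", (float(n), 0.0, 0.0))])
            for n in nums
        ]
        return model_with(residues)

    def test_gap_localized_at_flank_midpoint(self):
        model = self._model([4, 6])
        annot = annotation(
            residue_map={("A", 4): 4, ("A", 6): 6}, missing_residues={"*": [5]}
        )
        proxies = cl.missing_residue_proxies(model, annot)
        np.testing.assert_allclose(proxies, [[5.0, 0.0, 0.0]])

    def test_terminal_gap_uses_single_flank(self):
        model = self._model([4, 6])
        annot = annotation(
            residue_map={("A", 4): 4, ("A", 6): 6}, missing_residues={"*": [99]}
        )
        proxies = cl.missing_residue_proxies(model, annot)
        np.testing.assert_allclose(proxies, [[6.0, 0.0, 0.0]])

    def test_resolved_residue_yields_no_proxy(self):
        model = self._model([4, 5, 6])
        annot = annotation(
            residue_map={("A", n): n for n in (4, 5, 6)},
            missing_residues={"*": [5]},
        )
        assert len(cl.missing_residue_proxies(model, annot)) == 0


class TestPseudoSequence:
    def _lining(self, chain_nums):
        out = []
        for chain, num in chain_nums:
            r = make_residue(chain, num, "ALA", [("CB", "C", (0, 0, 0))])
            r.uniprot_num = num
            out.append(r)
        return out

    def test_boundaries_of_selection(self):
        annot = annotation()
        lining = self._lining([("A", 45), ("A", 47), ("A", 52)])
        assert cl.pseudo_sequence(lining, annot) == {"A": (45, 52)}

    def test_single_residue(self):
        assert cl.pseudo_sequence(self._lining([("A", 100)]), annotation()) == {
            "A": (100, 100)
        }

    def test_per_chain_decomposition(self):
        lining = self._lining([("A", 45), ("A", 52), ("B", 200), ("B", 210)])
        assert cl.pseudo_sequence(lining, annotation()) == {
            "A": (45, 52),
            "B": (200, 210),
        }

    def test_fully_unmapped_is_error(self):
        lining = self._lining([("A", 45)])
        lining[0].uniprot_num = None
        with pytest.raises(cl.AnnotationError):
            cl.pseudo_sequence(lining, annotation())


class TestAssignDomain:
    def _lining(self, nums):
        out = []
        for n in nums:
            r = make_residue("A", n, "ALA", [("CB", "C", (0, 0, 0))])
            r.uniprot_num = n
            out.append(r)
        return out

    def test_bounds_inside_noncatalytic_domain(self):
        doms = [cl.Domain(40, 120, "PWWP", False)]
        lining = self._lining(range(45, 53))
        assert cl.assign_domain({"A": (45, 52)}, doms, lining) == ("PWWP", False)

    def test_majority_vote(self):
        doms = [cl.Domain(1, 6, "X", False), cl.Domain(7, 100, "Y", True)]
        lining = self._lining([1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        assert cl.assign_domain({}, doms, lining)[0] == "X"

    def test_tie_prefers_earlier_interval(self):
        doms = [cl.Domain(6, 10, "LATE", False), cl.Domain(1, 5, "EARLY", True)]
        lining = self._lining([1, 2, 6, 7])
        assert cl.assign_domain({}, doms, lining)[0] == "EARLY"

    def test_under_half_coverage_unassigned(self):
        doms = [cl.Domain(1, 2, "X", False)]
        lining = self._lining([1, 2, 10, 11, 12])
        assert cl.assign_domain({}, doms, lining) is None

    def test_no_overlap_unassigned(self):
        doms = [cl.Domain(500, 600, "X", False)]
        assert cl.assign_domain({}, doms, self._lining([1, 2])) is None


class TestInterface:
    def _pocket(self, chain_counts):
        pocket = single_vertex_pocket()
        lining = []
        i = 0
        for chain, count in chain_counts.items():
            for _ in range(count):
                i += 1
                lining.append(make_residue(chain, i, "ALA", [("CB", "C", (0, 0, 0))]))
        pocket.lining_residues = lining
        return pocket

    def test_balanced_split_is_interface(self):
        annot = annotation(entity_roles={"A": "enzyme", "B": "cofactor_protein"})
        pocket = self._pocket({"A": 6, "B": 4})
        assert cl.classify_interface(pocket, annot, {"A": "A", "B": "B"}) == (
            "interface",
            False,
        )

    def test_inhibitor_side_rejects(self):
        annot = annotation(entity_roles={"A": "enzyme", "B": "inhibitor_protein"})
        pocket = self._pocket({"A": 6, "B": 4})
        assert cl.classify_interface(pocket, annot, {"A": "A", "B": "B"}) == (
            "interface",
            True,
        )

    def test_tiny_minority_is_single_entity(self):
        annot = annotation(entity_roles={"A": "enzyme", "B": "inhibitor_protein"})
        pocket = self._pocket({"A": 19, "B": 1})
        assert cl.classify_interface(pocket, annot, {"A": "A", "B": "B"}) == (
            "single_entity",
            False,
        )

    def test_missing_role_is_error(self):
        annot = annotation(entity_roles={"A": "enzyme"})
        pocket = self._pocket({"A": 3, "B": 3})
        with pytest.raises(cl.AnnotationError):
            cl.classify_interface(pocket, annot, {"A": "A", "B": "B"})


def record(structure_id, pocket_id, lining, volume, area=100.0):
    return cl.PocketRecord(
        enzyme_id="E1",
        structure_id=structure_id,
        pocket_id=pocket_id,
        category="non_catalytic_domain",
        properties=pp.PocketProperties(
            volume=volume, area=area, hydrophobicity=0.5, buriedness=0.8, dlid=0.0
        ),
        lining_uniprot=frozenset(lining),
    )


class TestDedupe:
    def test_similar_pair_keeps_larger_volume(self):
        a = record("s1", "P1", range(10), volume=300.0)
        b = record("s2", "P1", range(2, 12), volume=400.0)  # Jaccard 8/12 ≈ 0.67
        out = cl.dedupe([a, b])
        survivors = [r for r in out if r.rejected_reason == "none"]
        assert [s.properties.volume for s in survivors] == [400.0]
        assert a.rejected_reason == "duplicate"

    def test_dissimilar_pair_both_kept(self):
        a = record("s1", "P1", range(10), volume=300.0)
        b = record("s2", "P1", range(100, 110), volume=400.0)
        out = cl.dedupe([a, b])
        assert all(r.rejected_reason == "none" for r in out)

    def test_single_linkage_chain_one_survivor(self):
        """A~B~C each at Jaccard 0.6 though A and C are less similar: one
        cluster, max-volume member survives."""
        a = record("s1", "P1", range(0, 10), volume=200.0)
        b = record("s2", "P1", range(2, 12), volume=350.0)
        c = record("s3", "P1", range(4, 14), volume=300.0)
        out = cl.dedupe([a, b, c])
        survivors = [r for r in out if r.rejected_reason == "none"]
        assert len(survivors) == 1 and survivors[0].properties.volume == 350.0

    def test_order_invariant_and_idempotent(self):
        recs = [
            record(f"s{i}", "P1", range(i, i + 10), volume=100.0 + i) for i in range(6)
        ]
        baseline = None
        for seed in range(4):
            shuffled = [
                record(r.structure_id, r.pocket_id, r.lining_uniprot, r.properties.volume)
                for r in recs
            ]
            random.Random(seed).shuffle(shuffled)
            out = cl.dedupe(shuffled)
            key = sorted(
                (r.structure_id, r.rejected_reason) for r in out
            )
            if baseline is None:
                baseline = key
            assert key == baseline
        again = cl.dedupe(out)
        assert sorted((r.structure_id, r.rejected_reason) for r in again) == baseline

    def test_mixed_enzymes_rejected(self):
        a = record("s1", "P1", range(10), volume=300.0)
        b = record("s2", "P1", range(10), volume=400.0)
        b.enzyme_id = "OTHER"
        with pytest.raises(cl.AnnotationError):
            cl.dedupe([a, b])


def props(volume=400.0, area=400.0, hyd=0.60, bur=0.80, dlid=0.0):
    return pp.PocketProperties(
        volume=volume, area=area, hydrophobicity=hyd, buriedness=bur, dlid=dlid
    )


class TestLigandability:
    def test_centre_of_all_windows_passes(self):
        assert cl.is_ligandable(props()) is True

    @pytest.mark.parametrize(
        "kw",
        [
            {"volume": 155.0},  # below the 155.7 floor
            {"hyd": 0.44},  # strict >
            {"bur": 0.59},
            {"bur": 0.96},
            {"dlid": -1.0},  # strict >
            {"area": 700.0},
        ],
    )
    def test_single_out_of_window_descriptor_fails(self, kw):
        assert cl.is_ligandable(props(**kw)) is False

    def test_range_ends_inclusive(self):
        assert cl.is_ligandable(props(volume=155.7)) is True
        assert cl.is_ligandable(props(volume=661.1)) is True
        assert cl.is_ligandable(props(bur=0.95)) is True
        assert cl.is_ligandable(props(bur=0.6)) is True

    def test_agrees_with_bruteforce_clauses(self):
        """1,000 random descriptor vectors against a literal five-clause
        re-statement of the windows."""
        rng = np.random.default_rng(17)
        t = pp.LigandabilityThresholds()
        for _ in range(1000):
            v = rng.uniform(50, 900)
            a = rng.uniform(50, 900)
            h = rng.uniform(0, 1)
            b = rng.uniform(0.01, 1)
            d = rng.uniform(-3, 3)
            expected = (
                155.7 <= v <= 661.1
                and 155 <= a <= 655
                and h > 0.44
                and 0.6 <= b <= 0.95
                and d > -1
            )
            got = cl.is_ligandable(props(volume=v, area=a, hyd=h, bur=b, dlid=d), t)
            assert got == expected


def test_confidence_mapping_and_unknown_class():
    assert [
        cl.assign_confidence(c)
        for c in ("high_affinity_ligand", "weak_ligand", "homolog_domain_ligand", "none")
    ] == [1, 2, 3, 4]
    with pytest.raises(cl.AnnotationError):
        cl.assign_confidence("mystery")


class TestDomainTransfer:
    def test_catalog_domain_yields_level3_stub(self):
        stub = cl.transfer_domain_ligandability("PWWP", {"PWWP", "WDR"}, "Q_TARGET")
        assert stub is not None
        assert stub.confidence == 3 and stub.structure_less
        assert stub.domain_id == "PWWP" and stub.properties is None
        stub.validate()

    def test_uncatalogued_domain_yields_nothing(self):
        assert cl.transfer_domain_ligandability("SH2", {"PWWP"}, "Q_TARGET") is None


def test_annotation_loader_roundtrip(tmp_path):
    doc = """
enzyme_id: TESTENZ
residue_map:
  - {chain: A, author_start: 1, author_end: 5, uniprot_start: 101}
  - {chain: B, author: 9, uniprot: 300}
catalytic_residues: [103]
cofactor_residues: [104, 105]
missing_residues:
  S1: [110]
domains:
  - {start: 100, end: 200, domain_id: KINASE, is_catalytic: true}
entity_roles: {A: enzyme, B: inhibitor_protein}
ligand_evidence:
  - {site_key: "KINASE", evidence_class: weak_ligand}
"""
    path = tmp_path / "annot.yaml"
    path.write_text(doc)
    annot = cl.load_annotations(path)
    assert annot.residue_map[("A", 3)] == 103
    assert annot.residue_map[("B", 9)] == 300
    assert annot.missing_for("S1") == [110] and annot.missing_for("S2") == []
    assert annot.domains[0].is_catalytic
    assert annot.ligand_evidence == {"KINASE": "weak_ligand"}
    with pytest.raises(cl.AnnotationError):
        cl.AnnotationSet("X", {}, entity_roles={"A": "sidekick"})
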