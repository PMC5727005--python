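"""Surfaces, Hausdorff distances, mining and persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoswap import fixtures as fx
from isoswap.errors import (
    EmptySubsetError,
    SchemaVersionError,
    UndefinedInputError,
)
from isoswap.fragmenter import fragment_molecule
from isoswap.pairminer import (
    PairRecord,
    fibonacci_sphere,
    fragment_hd,
    hausdorff,
    load_db,
    match_join_atoms,
    mine_pairs,
    one_sided_hd,
    save_db,
    surface_points,
)


def brute_force_hd(A, B):
    """Exhaustive all-pairs oracle: full distance matrix, max of row/col minima."""
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestSurfacePoints:
    def test_single_atom_sphere(self, benzene_fragment):
        from isoswap.fragmenter import Fragment
        atom = benzene_fragment.core_atoms[0].copy()
        frag = Fragment(core_atoms=[atom], join_atoms=[], bonds=[])
        s = surface_points(frag, "all", density=64)
        assert len(s.points) == 64
        r = np.linalg.norm(s.points - atom.position, axis=1)
        assert np.allclose(r, atom.vdw_radius, atol=1e-9)

    def test_coincident_spheres_keep_surface(self):
        from isoswap.chemio import Atom, Bond, Molecule, perceive_and_type
        from isoswap.fragmenter import Fragment
        a = Atom(0, "C", np.zeros(3))
        b = Atom(1, "C", np.zeros(3))
        mol = perceive_and_type(Molecule(atoms=[a, b], bonds=[Bond(0, 1, 1)]))
        frag = Fragment(core_atoms=mol.atoms, join_atoms=[], bonds=mol.bonds)
        s = surface_points(frag, "all", density=32)
        # points lie at exactly the other sphere's radius: not buried
        assert len(s.points) == 64

    def test_buried_points_culled(self, benzene_fragment):
        s_all = surface_points(benzene_fragment, "all", 64)
        n_atoms = len(benzene_fragment.atoms)
        assert len(s_all.points) < 64 * n_atoms
        # every kept point is outside all other spheres (minus tolerance)
        centers = np.array([a.position for a in benzene_fragment.atoms])
        radii = np.array([a.vdw_radius for a in benzene_fragment.atoms])
        d = np.linalg.norm(s_all.points[:, None, :] - centers[None], axis=2)
        assert np.all((d >= radii[None] - 1e-5).sum(axis=1) >= len(centers) - 1)

    def test_apolar_fragment_has_no_hbond_subset(self, benzene_fragment):
        with pytest.raises(EmptySubsetError):
            surface_points(benzene_fragment, "hbond", 32)
        assert fragment_hd(benzene_fragment, benzene_fragment, "hbond") is None

    def test_core_subset_excludes_join_atoms(self, benzene_fragment):
        # every core-mode point lies exactly on some *core* atom sphere;
        # the join atom neither contributes nor occludes points
        s_core = surface_points(benzene_fragment, "core", 32)
        centers = np.array([a.position for a in benzene_fragment.core_atoms])
        radii = np.array([a.vdw_radius for a in benzene_fragment.core_atoms])
        d = np.linalg.norm(s_core.points[:, None] - centers[None], axis=2)
        assert np.all(np.min(np.abs(d - radii[None]), axis=1) < 1e-6)
        s_all = surface_points(benzene_fragment, "all", 32)
        assert len(s_all.points) != len(s_core.points)

    def test_density_floor(self, benzene_fragment):
        with pytest.raises(ValueError):
            surface_points(benzene_fragment, "all", 4)

    def test_fibonacci_lattice_is_unit_and_deterministic(self):
        p = fibonacci_sphere(128)
        assert np.allclose(np.linalg.norm(p, axis=1), 1.0, atol=1e-12)
        assert np.array_equal(p, fibonacci_sphere(128))


class TestHausdorff:
    def test_hand_cases(self):
        A = np.array([[0.0, 0, 0], [10, 0, 0]])
        B = np.array([[0.0, 0, 0]])
        assert one_sided_hd(A, B) == pytest.approx(10.0)
        assert one_sided_hd(B, A) == pytest.approx(0.0)
        assert hausdorff(A, B) == pytest.approx(10.0)
        assert hausdorff(A, A) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(UndefinedInputError):
            one_sided_hd(np.empty((0, 3)), np.zeros((1, 3)))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            A = rng.uniform(-5, 5, size=(int(rng.integers(1, 60)), 3))
            B = rng.uniform(-5, 5, size=(int(rng.integers(1, 60)), 3))
            assert hausdorff(A, B) == brute_force_hd(A, B)
            assert one_sided_hd(A, B) == pytest.approx(
                np.linalg.norm(A[:, None] - B[None], axis=2)
                .min(axis=1).max())

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.tuples(*[st.floats(-50, 50)] * 3), min_size=1,
                    max_size=25),
           st.lists(st.tuples(*[st.floats(-50, 50)] * 3), min_size=1,
                    max_size=25))
    def test_metric_axioms_hold_on_arbitrary_point_sets(self, a, b):
        A, B = np.array(a), np.array(b)
        hd = hausdorff(A, B)
        assert hd >= 0
        assert hd == hausdorff(B, A)
        assert hausdorff(A, A) == 0.0
        assert hd == brute_force_hd(A, B)

    def test_symmetry_and_isometry_invariance(self, rng):
        from isoswap.sitealign import Transform
        from scipy.spatial.transform import Rotation
        A = rng.uniform(-3, 3, (40, 3))
        B = rng.uniform(-3, 3, (30, 3))
        assert hausdorff(A, B) == hausdorff(B, A)
        t = Transform(Rotation.random(random_state=rng).as_matrix(),
                      rng.uniform(-5, 5, 3))
        assert abs(hausdorff(t.apply(A), t.apply(B))
                   - hausdorff(A, B)) <= 1e-9


class TestJoinMatching:
    def test_superposed_fragments_match_all_joins(self, benzene_fragment):
        corr = match_join_atoms(benzene_fragment, benzene_fragment)
        assert len(corr) == 1
        assert corr[0][0] == corr[0][1]

    def test_far_joins_unmatched(self, benzene_fragment, ethylbenzene):
        far = fragment_molecule(ethylbenzene)[1]  # ethyl piece, join on ring
        moved = far
        for a in moved.join_atoms:
            a.position = a.position + np.array([50.0, 0, 0])
        assert match_join_atoms(benzene_fragment, moved, tol=1.5) == []

    def test_greedy_ascending_distance(self):
        from isoswap.chemio import Atom, Bond
        from isoswap.fragmenter import Fragment

        def frag_with_joins(core_pos, join_positions, base=0):
            core = [Atom(base, "C", np.asarray(core_pos))]
            joins = [Atom(base + 1 + k, "C", np.asarray(p))
                     for k, p in enumerate(join_positions)]
            bonds = [Bond(base, j.index, 1) for j in joins]
            for a in core + joins:
                a.vdw_radius = 1.7
            return Fragment(core_atoms=core, join_atoms=joins, bonds=bonds)

        q = frag_with_joins([0, 0, 0], [[0, 1, 0], [1, 0, 0]], base=0)
        p = frag_with_joins([0, 0, 0], [[0, 1.2, 0], [0.9, 0, 0]], base=10)
        corr = match_join_atoms(q, p, tol=1.5)
        # nearest pair first: (2 <-> 12) at 0.1, then (1 <-> 11) at 0.2
        assert set(corr) == {(2, 12), (1, 11)}


class TestMining:
    def test_planted_pair_recovered(self, complex_pair):
        recs = mine_pairs([complex_pair.complex_a, complex_pair.complex_b],
                          zthr=None)
        assert len(recs) == 2  # both orientations
        assert recs[0].hd_overall <= 0.3
        assert recs[0].hd_core <= 0.3
        assert recs[0].join_correspondences  # congruent join geometry
        assert recs[0].family_relation == "unknown"

    def test_displaced_pair_absent_at_cutoff(self):
        pair = fx.make_complex_pair(11, planted_overlap=6.0)
        recs = mine_pairs([pair.complex_a, pair.complex_b], zthr=None)
        assert recs == []

    def test_hd_cutoff_monotone(self):
        pair = fx.make_complex_pair(5, planted_overlap=1.0)
        args = dict(zthr=None)
        sets = [len(mine_pairs([pair.complex_a, pair.complex_b],
                               hd_cutoff=c, **args))
                for c in (3.0, 1.5, 0.5, 0.1)]
        assert sets == sorted(sets, reverse=True)

    def test_zfilter_dominates_uniform_batch(self):
        # >= 3 complexes with congruent pockets: all alignment scores equal,
        # population sd is zero, nothing passes z >= 2
        pairs = [fx.make_complex_pair(s) for s in (1, 2, 3)]
        complexes = [pairs[0].complex_a, pairs[1].complex_b,
                     pairs[2].complex_b]
        assert mine_pairs(complexes, zthr=2.0) == []
        assert len(mine_pairs(complexes, zthr=None)) > 0

    def test_scop_families_label_relation(self, complex_pair):
        a, b = complex_pair.complex_a, complex_pair.complex_b
        intra = mine_pairs([a, b], zthr=None,
                           scop={a.name: "f.1", b.name: "f.1"})
        inter = mine_pairs([a, b], zthr=None,
                           scop={a.name: "f.1", b.name: "f.2"})
        assert {r.family_relation for r in intra} == {"intra"}
        assert {r.family_relation for r in inter} == {"inter"}

    def test_external_transforms_bypass_aligner(self, complex_pair):
        a, b = complex_pair.complex_a, complex_pair.complex_b
        recs = mine_pairs([a, b], zthr=2.0,
                          transforms={(a.name, b.name):
                                      complex_pair.transform})
        assert len(recs) == 2
        assert recs[0].hd_overall <= 0.3

    def test_needs_two_complexes(self, complex_pair):
        with pytest.raises(ValueError):
            mine_pairs([complex_pair.complex_a])


class TestDatabase:
    @pytest.fixture
    def records(self, complex_pair):
        return mine_pairs([complex_pair.complex_a, complex_pair.complex_b],
                          zthr=None,
                          scop={complex_pair.complex_a.name: "f.1",
                                complex_pair.complex_b.name: "f.1"})

    def test_round_trip_field_identical(self, tmp_path, records):
        path = tmp_path / "pairs.db"
        save_db(records, path).close()
        back = load_db(path).records()
        assert len(back) == len(records)
        for orig, got in zip(records, back):
            assert got.hd_overall == orig.hd_overall
            assert got.hd_core == orig.hd_core
            assert got.hd_hbond == orig.hd_hbond
            assert got.join_correspondences == orig.join_correspondences
            assert got.source == orig.source
            assert got.family_relation == orig.family_relation
            assert ([a.index for a in got.query_fragment.core_atoms]
                    == [a.index for a in orig.query_fragment.core_atoms])
            assert np.allclose(
                np.array([a.position for a in got.partner_fragment.atoms]),
                np.array([a.position for a in orig.partner_fragment.atoms]))

    def test_version_mismatch_rejected(self, tmp_path, records):
        path = tmp_path / "pairs.db"
        db = save_db(records, path)
        db.conn.execute("UPDATE meta SET value='999' "
                        "WHERE key='schema_version'")
        db.conn.commit()
        db.close()
        with pytest.raises(SchemaVersionError):
            load_db(path)
        with pytest.raises(SchemaVersionError):
            load_db(tmp_path / "notadb.sqlite") if (
                (tmp_path / "notadb.sqlite").write_text("junk") or True) \
                else None

    def test_core_key_index_agrees_with_scan(self, tmp_path, records):
        path = tmp_path / "pairs.db"
        db = save_db(records, path)
        from isoswap.fragmenter import core_key
        key = "c1ccccc1"
        via_index = db.records_by_core_key(key)
        via_scan = [r for r in db.records()
                    if core_key(r.query_fragment) == key]
        assert len(via_index) == len(via_scan) == len(records)

    def test_bad_family_relation_rejected(self, records):
        with pytest.raises(ValueError):
            PairRecord(records[0].query_fragment,
                       records[0].partner_fragment,
                       0.1, 0.1, None, [], ("a", "b", "l1", "l2"), "sibling")
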