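"""Query modes, filtering rules and result presentation."""

import importlib.resources as ir

import numpy as np
import pytest

from isoswap import chemio, fixtures as fx
from isoswap.errors import SelectionRequiredError, ValidationError
from isoswap.fragmenter import core_key, fragment_molecule, same_core
from isoswap.pairminer import mine_pairs, save_db
from isoswap.queryengine import (
    QueryOptions,
    find_replacements,
    join_types_compatible,
    query_by_core,
    query_by_molecule,
    query_by_properties,
)


@pytest.fixture(scope="module")
def fixture_db(tmp_path_factory):
    """Pair DB mined from three planted fixture pairs: one intra-family
    benzene/benzene, one inter-family, one unknown-family, plus a
    pyridine-containing pair for substructure queries."""
    records = []
    specs = [
        (21, "biphenyl", "ethylbenzene", {"FIXA0021": "f.1", "FIXB0021": "f.1"}),
        (22, "biphenyl", "ethylbenzene", {"FIXA0022": "f.1", "FIXB0022": "f.2"}),
        (23, "biphenyl", "ethylbenzene", None),
        (24, "pyridine", "pyridine", {"FIXA0024": "f.1", "FIXB0024": "f.1"}),
    ]
    for seed, la, lb, scop in specs:
        pair = fx.make_complex_pair(seed, lig_a=la, lig_b=lb)
        records += mine_pairs([pair.complex_a, pair.complex_b], zthr=None,
                              scop=scop)
    path = tmp_path_factory.mktemp("db") / "pairs.db"
    save_db(records, path).close()
    from isoswap.pairminer import load_db
    return load_db(path)


class TestQueryModes:
    def test_inhibitor_yields_five_selectable_fragments(self):
        with ir.as_file(ir.files("isoswap.data") / "murf_inhibitor.mol") as p:
            mol = chemio.read_mol(p, name="inhibitor")
        frags = query_by_molecule(mol)
        assert len(frags) == 5

    def test_benzene_single_fragment(self, benzene):
        assert len(query_by_molecule(benzene)) == 1

    def test_disconnected_salt_rejected(self, benzene):
        from isoswap.chemio import Atom, Molecule, perceive_and_type
        atoms = [a.copy() for a in benzene.atoms]
        atoms.append(Atom(6, "O", np.array([40.0, 0, 0])))
        salt = perceive_and_type(
            Molecule(atoms=atoms, bonds=list(benzene.bonds)))
        with pytest.raises(ValidationError, match="component"):
            query_by_molecule(salt)

    def test_query_by_core_aromatic_nitrogen(self, fixture_db):
        sub = fx.make_ligand("pyridine")
        hits = query_by_core(sub, fixture_db)
        assert hits
        assert all(key == "c1ccncc1" for key, _ in hits)

    def test_query_by_core_benzene_matches_benzene_cores(self, fixture_db):
        hits = query_by_core(fx.make_ligand("benzene"), fixture_db)
        # benzene is a subgraph of benzene cores but not of pyridine
        assert hits and all(key == "c1ccccc1" for key, _ in hits)

    def test_query_by_core_oversized_substructure_empty(self, fixture_db):
        assert query_by_core(fx.make_ligand("biphenyl"), fixture_db) == []

    def test_query_by_properties_scan(self, fixture_db):
        hits = query_by_properties({"n_heavy": (7, 7),
                                    "n_ring_atoms": (6, 6)}, fixture_db)
        assert hits
        oracle = [(k, f) for k, f in fixture_db.query_fragments()
                  if len(f.atoms) == 7
                  and sum(a.in_ring for a in f.atoms) == 6]
        assert len(hits) == len(oracle)

    def test_query_by_properties_multi_join_only(self, fixture_db):
        hits = query_by_properties({"n_join": (2, None)}, fixture_db)
        assert all(len(f.join_atoms) >= 2 for _, f in hits)

    def test_contradictory_bounds_rejected(self, fixture_db):
        with pytest.raises(ValidationError):
            query_by_properties({"n_heavy": (5, 3)}, fixture_db)


class TestJoinTypeCompatibility:
    @pytest.mark.parametrize("t1,t2,inter,expected", [
        ("N.2", "N.pl3", True, True),    # sp2 N exchangeable with planar N
        ("N.2", "N.pl3", False, False),  # strict equality
        ("N.2", "O.2", True, False),     # element gate
        ("C.ar", "C.2", True, True),     # both trigonal-planar carbons
        ("C.3", "C.2", True, False),     # geometry class differs
        ("C.3", "C.3", False, True),
        ("Cl", "Cl", True, True),
    ])
    def test_cases(self, t1, t2, inter, expected):
        assert join_types_compatible(t1, t2, inter) is expected


class TestFindReplacements:
    def _rows(self, frag, db, opts, join=None):
        pages = find_replacements(frag, join, db, opts)
        return [r for page in pages for r in page]

    def test_rigorous_subset_of_loose(self, fixture_db, benzene_fragment):
        loose = self._rows(benzene_fragment, fixture_db,
                           QueryOptions.loose())
        rigorous = self._rows(benzene_fragment, fixture_db,
                              QueryOptions.rigorous())
        assert len(rigorous) <= len(loose)
        loose_srcs = {r.source for r in loose}
        assert all(r.source in loose_srcs for r in rigorous)

    def test_family_chain_subset_relation(self, fixture_db, benzene_fragment):
        base = dict(common_core_query=True)
        intra = self._rows(benzene_fragment, fixture_db,
                           QueryOptions(family="intra", **base))
        both = self._rows(benzene_fragment, fixture_db,
                          QueryOptions(family="both", **base))
        inter = self._rows(benzene_fragment, fixture_db,
                           QueryOptions(family="inter", **base))
        assert len(intra) + len(inter) == len(both)
        assert {r.family_relation for r in intra} <= {"intra"}
        # unspecified families count as inter-family
        assert {r.family_relation for r in inter} <= {"inter", "unknown"}
        assert any(r.family_relation == "unknown" for r in inter)

    def test_posthoc_scan_cutoff_and_family(self, fixture_db,
                                            benzene_fragment):
        opts = QueryOptions.loose(hd_cutoff=0.4, family="intra")
        for r in self._rows(benzene_fragment, fixture_db, opts):
            assert r.hd_overall <= 0.4
            assert r.family_relation == "intra"

    def test_specific_mode_requires_join_selection(self, fixture_db,
                                                   murf_mock):
        central = next(f for f in fragment_molecule(murf_mock)
                       if len(f.join_atoms) == 2)
        with pytest.raises(SelectionRequiredError):
            find_replacements(central, None, fixture_db,
                              QueryOptions.rigorous())

    def test_specific_mode_needs_a_join_atom(self, fixture_db, benzene):
        frag = fragment_molecule(benzene)[0]
        with pytest.raises(ValidationError):
            find_replacements(frag, None, fixture_db,
                              QueryOptions.rigorous())

    def test_rule3_isomorphic_cores_get_identical_results(
            self, fixture_db, benzene_fragment, ethylbenzene):
        other = fragment_molecule(ethylbenzene)[0]  # same core, sp3 join
        assert same_core(benzene_fragment, other)
        opts = QueryOptions.loose()
        rows_a = self._rows(benzene_fragment, fixture_db, opts)
        rows_b = self._rows(other, fixture_db, opts)
        assert [(r.source, r.hd_overall) for r in rows_a] \
            == [(r.source, r.hd_overall) for r in rows_b]

    def test_common_core_rows_are_core_only_with_remapped_join(
            self, fixture_db, benzene_fragment):
        opts = QueryOptions.loose()
        join = benzene_fragment.join_atoms[0].index
        rows = self._rows(benzene_fragment, fixture_db, opts, join=join)
        assert rows
        for r in rows:
            assert r.partner_fragment.join_atoms == []
            assert r.remapped_join_anchor is not None
            core_ids = {a.index for a in r.partner_fragment.core_atoms}
            assert r.remapped_join_anchor in core_ids

    def test_sorting_stable_and_reversible(self, fixture_db,
                                           benzene_fragment):
        asc = self._rows(benzene_fragment, fixture_db,
                         QueryOptions.loose(sort_order="asc"))
        desc = self._rows(benzene_fragment, fixture_db,
                          QueryOptions.loose(sort_order="desc"))
        assert [r.hd_core for r in asc] == sorted(r.hd_core for r in asc)
        assert [(r.source, r.hd_core) for r in desc] \
            == [(r.source, r.hd_core) for r in reversed(asc)]

    def test_duplicate_bioisostere_from_two_superpositions(
            self, fixture_db, benzene_fragment):
        # the same replacement mined from different complex pairs appears
        # as distinct rows with their own HDs and sources
        rows = self._rows(benzene_fragment, fixture_db, QueryOptions.loose())
        keys = [core_key(r.partner_fragment) for r in rows]
        assert keys.count("c1ccccc1") >= 2
        srcs = {r.source for r in rows
                if core_key(r.partner_fragment) == "c1ccccc1"}
        assert len(srcs) >= 2

    def test_pagination_default_ten(self, fixture_db, benzene_fragment):
        pages = find_replacements(benzene_fragment, None, fixture_db,
                                  QueryOptions.loose(page_size=2))
        assert all(len(p) <= 2 for p in pages)
        total = sum(len(p) for p in pages)
        one_page = find_replacements(benzene_fragment, None, fixture_db,
                                     QueryOptions.loose(page_size=1000))
        assert total == len(one_page[0])


class TestPresets:
    def test_table_presets(self):
        loose = QueryOptions.loose()
        rig = QueryOptions.rigorous()
        assert loose.family == "both" and loose.common_core_query
        assert rig.family == "intra" and not rig.common_core_query
        assert not rig.interchangeable_join_types

    def test_invalid_options_rejected(self):
        with pytest.raises(ValidationError):
            QueryOptions(family="cousins")
        with pytest.raises(ValidationError):
            QueryOptions(sort_key="alphabetical")
        with pytest.raises(ValidationError):
            QueryOptions(page_size=0)
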