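"""Bioisostere queries over the mined pair database.

Three query modes mirror the mining tool's front end: submit a whole
molecule (it is fragmented and a fragment is selected), draw a core
structure (substructure search over database core graphs), or give
descriptor bounds.  Replacement search then applies the filtering rules:

* Rule 1 — *interchangeable join atom types*: join atoms may match by
  element + geometry class (e.g. N.2 with N.pl3) instead of exact Sybyl
  type equality.
* Rules 3+4 — *common core query*: join atoms are stripped from the query,
  any database fragment with an isomorphic core matches, and the selected
  join atom is re-defined on the bioisostere at the nearest core position.
* Rule 5 — the rules combine; presets ``loose`` and ``rigorous`` bundle
  them with the SCOP-family filter (loose: both families, common-core;
  rigorous: intra-family, exact join types, specific structure).

Rule 2 (promoting overlapping join atoms to core atoms) is intentionally
not implemented; join atoms outside the selected reconnection pair are
always ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .chemio import Molecule
from .errors import SelectionRequiredError, ValidationError
from .fragmenter import (
    Fragment,
    FragmentDescriptor,
    contains_core_substructure,
    core_graph,
    core_key,
    describe_fragment,
    fragment_molecule,
    same_core,
)
from .pairminer import PairDatabase, PairRecord

#: geometry classes for Rule 1 join-type interchange
_GEOMETRY_CLASS = {
    ".3": "sp3", ".o": "sp3", ".o2": "sp3",
    ".2": "trigonal", ".pl3": "trigonal", ".ar": "trigonal",
    ".am": "trigonal", ".cat": "trigonal",
    ".1": "linear",
}


@dataclass
class QueryOptions:
    """Mirror of the screening options table (loose/rigorous presets)."""

    filtering: str = "custom"            # loose | rigorous | custom
    interchangeable_join_types: bool = False   # Rule 1
    common_core_query: bool = False            # Rules 3+4
    family: str = "both"                 # intra | inter | both
    hd_cutoff: float = 1.50
    sort_key: str = "overall"            # overall | core | hbond
    sort_order: str = "asc"
    page_size: int = 10

    def __post_init__(self):
        if self.family not in ("intra", "inter", "both"):
            raise ValidationError(f"bad family filter {self.family!r}")
        if self.sort_key not in ("overall", "core", "hbond"):
            raise ValidationError(f"bad sort key {self.sort_key!r}")
        if self.sort_order not in ("asc", "desc"):
            raise ValidationError(f"bad sort order {self.sort_order!r}")
        if self.page_size < 1:
            raise ValidationError("page_size must be >= 1")

    @classmethod
    def loose(cls, **overrides) -> "QueryOptions":
        base = dict(filtering="loose", family="both", common_core_query=True,
                    interchangeable_join_types=True, sort_key="core")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def rigorous(cls, **overrides) -> "QueryOptions":
        base = dict(filtering="rigorous", family="intra",
                    common_core_query=False,
                    interchangeable_join_types=False)
        base.update(overrides)
        return cls(**base)


@dataclass
class ResultRow:
    query_fragment: Fragment
    partner_fragment: Fragment           # reduced to core in common-core mode
    hd_overall: float
    hd_core: float
    hd_hbond: float | None
    source: tuple
    family_relation: str
    join_correspondences: list = field(default_factory=list)
    remapped_join_anchor: int | None = None   # partner core atom (Rule 4)


# ---------------------------------------------------------------------------
# query modes


def query_by_molecule(mol: Molecule) -> list:
    """Fragment the input; returns (Fragment, FragmentDescriptor) pairs
    for user selection."""
    g = mol.graph()
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ValidationError(
            "disconnected input (salt/mixture); select the largest component")
    frags = fragment_molecule(mol)
    return [(f, describe_fragment(f)) for f in frags]


def query_by_core(sub: Molecule, db: PairDatabase) -> list:
    """Database query fragments whose core contains ``sub`` as a labelled
    subgraph."""
    sub_graph = sub.graph()
    if sub_graph.number_of_nodes() == 0 or not nx.is_connected(sub_graph):
        raise ValidationError("core substructure must be connected")
    out = []
    for key, frag in db.query_fragments():
        if contains_core_substructure(frag, sub_graph):
            out.append((key, frag))
    return out


def query_by_properties(bounds: dict, db: PairDatabase) -> list:
    """Database query fragments whose descriptors fall inside all closed
    ``{name: (lo, hi)}`` intervals; ``hi=None`` means unbounded."""
    valid = set(FragmentDescriptor.__dataclass_fields__)
    for name, (lo, hi) in bounds.items():
        if name not in valid:
            raise ValidationError(f"unknown descriptor {name!r}")
        if hi is not None and lo > hi:
            raise ValidationError(f"contradictory bounds for {name}: "
                                  f"[{lo}, {hi}]")
    out = []
    for key, frag in db.query_fragments():
        d = describe_fragment(frag).as_dict()
        if all(d[n] >= lo and (hi is None or d[n] <= hi)
               for n, (lo, hi) in bounds.items()):
            out.append((key, frag))
    return out


# ---------------------------------------------------------------------------
# Rule 1


def join_types_compatible(t1: str, t2: str, interchangeable: bool) -> bool:
    """Exact Sybyl equality, or — when interchange is allowed — same
    element and same geometry class (sp3 / trigonal-planar / linear)."""
    if not interchangeable:
        return t1 == t2
    e1, _, s1 = t1.partition(".")
    e2, _, s2 = t2.partition(".")
    if e1 != e2:
        return False
    c1 = _GEOMETRY_CLASS.get("." + s1 if s1 else s1, t1)
    c2 = _GEOMETRY_CLASS.get("." + s2 if s2 else s2, t2)
    return c1 == c2


# ---------------------------------------------------------------------------
# replacement search


def _full_graph(frag: Fragment) -> nx.Graph:
    g = nx.Graph()
    core = {a.index for a in frag.core_atoms}
    for a in frag.atoms:
        g.add_node(a.index, kind="core" if a.index in core else "join",
                   element=a.element, aromatic=a.aromatic,
                   sybyl=a.sybyl_type)
    for b in frag.bonds:
        g.add_edge(b.i, b.j, order=b.order)
    return g


def _specific_match(frag: Fragment, candidate: Fragment,
                    interchangeable: bool) -> bool:
    """Exact structure match: core atoms on (element, aromaticity), join
    atoms under Rule 1 compatibility, bond orders equal."""
    def node_match(a, b):
        if a["kind"] != b["kind"]:
            return False
        if a["kind"] == "core":
            return a["element"] == b["element"] and a["aromatic"] == b["aromatic"]
        return join_types_compatible(a["sybyl"], b["sybyl"], interchangeable)

    return nx.is_isomorphic(_full_graph(frag), _full_graph(candidate),
                            node_match=node_match,
                            edge_match=lambda x, y: x["order"] == y["order"])


def _core_isomorphism(frag: Fragment, candidate: Fragment) -> dict | None:
    """Deterministic core-atom mapping frag -> candidate, or None."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        core_graph(frag), core_graph(candidate),
        node_match=lambda a, b: (a["element"] == b["element"]
                                 and a["aromatic"] == b["aromatic"]),
        edge_match=lambda a, b: a["order"] == b["order"])
    best = None
    for mapping in gm.isomorphisms_iter():
        key = tuple(sorted(mapping.items()))
        if best is None or key < best[0]:
            best = (key, dict(mapping))
    return best[1] if best else None


def _remap_join(frag: Fragment, selected_join: int,
                record: PairRecord) -> int | None:
    """Rule 4: carry the selected query join atom onto the bioisostere by
    nearest core position in the record's common frame."""
    mapping = _core_isomorphism(frag, record.query_fragment)
    if mapping is None:
        return None
    anchor = frag.join_anchor(selected_join)
    record_anchor = record.query_fragment.atom_by_index(mapping[anchor])
    partner_core = record.partner_fragment.core_atoms
    d = [np.linalg.norm(a.position - record_anchor.position)
         for a in partner_core]
    return partner_core[int(np.argmin(d))].index


def _reduce_to_core(frag: Fragment) -> Fragment:
    return Fragment(core_atoms=[a.copy() for a in frag.core_atoms],
                    join_atoms=[],
                    bonds=[b for b in frag.bonds
                           if {b.i, b.j} <= {a.index for a in frag.core_atoms}],
                    parent_name=frag.parent_name,
                    parent_source=frag.parent_source)


def _passes_family(relation: str, family: str) -> bool:
    # unspecified families count as inter-family
    if family == "both":
        return True
    if family == "intra":
        return relation == "intra"
    return relation in ("inter", "unknown")


def _sort_value(row: ResultRow, key: str):
    v = {"overall": row.hd_overall, "core": row.hd_core,
         "hbond": row.hd_hbond}[key]
    return (v is None, v if v is not None else 0.0)


def find_replacements(frag: Fragment, selected_join: int | None,
                      db: PairDatabase, opts: QueryOptions) -> list:
    """Search the database for replacements of ``frag``; returns a list of
    pages, each a list of :class:`ResultRow`.

    Specific-structure mode matches the whole fragment (join atoms under
    Rule 1); common-core mode matches cores only, reduces results to their
    core and remaps the selected join atom (Rules 3+4).
    """
    n_join = len(frag.join_atoms)
    if not opts.common_core_query:
        if n_join == 0:
            raise ValidationError(
                "fragment has no join atom; use a common-core query")
        if n_join > 1 and selected_join is None:
            raise SelectionRequiredError(
                f"fragment has {n_join} join atoms; one must be selected")
        if selected_join is None:
            selected_join = frag.join_atoms[0].index

    rows = []
    for record in db.records():
        if record.hd_overall > opts.hd_cutoff:
            continue
        if not _passes_family(record.family_relation, opts.family):
            continue
        if opts.common_core_query:
            if not same_core(frag, record.query_fragment):
                continue
            remapped = (None if selected_join is None
                        else _remap_join(frag, selected_join, record))
            rows.append(ResultRow(
                query_fragment=frag,
                partner_fragment=_reduce_to_core(record.partner_fragment),
                hd_overall=record.hd_overall, hd_core=record.hd_core,
                hd_hbond=record.hd_hbond, source=record.source,
                family_relation=record.family_relation,
                join_correspondences=[],
                remapped_join_anchor=remapped))
        else:
            if not _specific_match(frag, record.query_fragment,
                                   opts.interchangeable_join_types):
                continue
            rows.append(ResultRow(
                query_fragment=frag,
                partner_fragment=record.partner_fragment,
                hd_overall=record.hd_overall, hd_core=record.hd_core,
                hd_hbond=record.hd_hbond, source=record.source,
                family_relation=record.family_relation,
                join_correspondences=record.join_correspondences))

    sort_key = "core" if opts.common_core_query else opts.sort_key
    rows.sort(key=lambda r: (_sort_value(r, sort_key), r.source,
                             core_key(r.partner_fragment)))
    if opts.sort_order == "desc":
        rows.reverse()
    return [rows[i:i + opts.page_size]
            for i in range(0, len(rows), opts.page_size)] or [[]]
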