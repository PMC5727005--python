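"""Rotatable-bond fragmentation into core + join atoms.

A molecule is cut at every rotatable bond — single, acyclic, non-aromatic,
with both endpoints bonded to at least two heavy atoms.  Each connected
component of the cut graph becomes a fragment whose *core atoms* are its
own atoms; for every broken bond the fragment additionally retains a copy
of the atom across the cut (a *join atom*), with the original coordinates
and Sybyl type.  Join atoms record where and how a fragment reattaches;
the *core structure* (fragment minus join atoms) is what two fragments
must share to be considered the "same" chemotype during querying.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .chemio import Bond, Molecule, to_rdkit
from rdkit import Chem


@dataclass
class Fragment:
    """Core atoms + join-atom copies retained from broken rotatable bonds.

    Atom ``index`` values refer to the parent molecule's numbering; join
    atoms duplicate core atoms of adjacent fragments (same index, same
    coordinates).
    """

    core_atoms: list
    join_atoms: list
    bonds: list                    # core-core bonds + core-join attachment bonds
    parent_name: str = ""
    parent_source: tuple | None = None
    broken_bonds: list = field(default_factory=list)

    def __post_init__(self):
        core = {a.index for a in self.core_atoms}
        join = {a.index for a in self.join_atoms}
        if core & join:
            raise ValueError("core and join atom index sets overlap")
        for j in self.join_atoms:
            partners = [
                b for b in self.bonds
                if j.index in (b.i, b.j)
                and (b.i in core or b.j in core)
            ]
            if len(partners) != 1:
                raise ValueError(
                    f"join atom {j.index} must attach to exactly one core atom")

    @property
    def atoms(self) -> list:
        return self.core_atoms + self.join_atoms

    def atom_by_index(self, index: int):
        for a in self.atoms:
            if a.index == index:
                return a
        raise KeyError(index)

    def join_anchor(self, join_index: int) -> int:
        """Parent index of the core atom a given join atom attaches to."""
        core = {a.index for a in self.core_atoms}
        for b in self.bonds:
            if join_index in (b.i, b.j):
                other = b.j if b.i == join_index else b.i
                if other in core:
                    return other
        raise KeyError(join_index)

    def as_molecule(self, include_join: bool = True) -> Molecule:
        """Re-number to a standalone Molecule (core first, then join atoms)."""
        atoms = self.core_atoms + (self.join_atoms if include_join else [])
        remap = {a.index: k for k, a in enumerate(atoms)}
        new_atoms = []
        for a in atoms:
            c = a.copy()
            c.index = remap[a.index]
            new_atoms.append(c)
        new_bonds = [
            Bond(remap[b.i], remap[b.j], b.order, b.in_ring)
            for b in self.bonds if b.i in remap and b.j in remap
        ]
        return Molecule(atoms=new_atoms, bonds=new_bonds, name=self.parent_name,
                        source=self.parent_source)


@dataclass
class FragmentDescriptor:
    n_heavy: int
    n_donor: int
    n_acceptor: int
    n_ring_atoms: int
    n_core: int
    n_join: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def find_rotatable_bonds(mol: Molecule, exempt_amides: bool = False) -> list:
    """Single, non-ring, non-aromatic bonds with both endpoints of heavy
    degree >= 2.  ``exempt_amides`` optionally keeps amide C-N bonds intact."""
    by_index = {a.index: a for a in mol.atoms}
    out = []
    for b in mol.bonds:
        if b.order != 1 or b.in_ring:
            continue
        ai, aj = by_index[b.i], by_index[b.j]
        if ai.heavy_degree < 2 or aj.heavy_degree < 2:
            continue
        if exempt_amides and {ai.sybyl_type, aj.sybyl_type} == {"N.am", "C.2"}:
            continue
        out.append(b)
    return out


def fragment_molecule(mol: Molecule, exempt_amides: bool = False) -> list:
    """Cut all rotatable bonds; each component becomes one Fragment.

    For every broken bond (a, b) the component holding ``a`` receives a
    join-atom copy of ``b`` and vice versa, so fragment count equals the
    number of broken bonds plus one.
    """
    g = mol.graph()
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ValueError("molecule is disconnected; fragment each component "
                         "separately")
    rotatable = find_rotatable_bonds(mol, exempt_amides=exempt_amides)
    cut = g.copy()
    cut.remove_edges_from((b.i, b.j) for b in rotatable)
    by_index = {a.index: a for a in mol.atoms}
    comp_of = {}
    components = []
    for comp in sorted(nx.connected_components(cut), key=min):
        for idx in comp:
            comp_of[idx] = len(components)
        components.append(sorted(comp))

    fragments = []
    for comp in components:
        core = [by_index[i].copy() for i in comp]
        comp_set = set(comp)
        joins, frag_bonds, broken = [], [], []
        for b in mol.bonds:
            if b.i in comp_set and b.j in comp_set:
                frag_bonds.append(Bond(b.i, b.j, b.order, b.in_ring))
        for b in rotatable:
            for inside, outside in ((b.i, b.j), (b.j, b.i)):
                if inside in comp_set and outside not in comp_set:
                    joins.append(by_index[outside].copy())
                    frag_bonds.append(Bond(inside, outside, b.order, False))
                    broken.append((b.i, b.j))
        fragments.append(Fragment(
            core_atoms=core, join_atoms=joins, bonds=frag_bonds,
            parent_name=mol.name, parent_source=mol.source,
            broken_bonds=broken,
        ))
    return fragments


def core_graph(frag: Fragment) -> nx.Graph:
    """Labelled graph over core atoms: nodes (element, aromatic), edges order."""
    g = nx.Graph()
    core = {a.index for a in frag.core_atoms}
    for a in frag.core_atoms:
        g.add_node(a.index, element=a.element, aromatic=a.aromatic)
    for b in frag.bonds:
        if b.i in core and b.j in core:
            g.add_edge(b.i, b.j, order=b.order)
    return g


def _node_match(a, b):
    return a["element"] == b["element"] and a["aromatic"] == b["aromatic"]


def _edge_match(a, b):
    return a["order"] == b["order"]


def same_core(a: Fragment, b: Fragment) -> bool:
    """True iff the two core graphs are isomorphic under node/edge labels."""
    return nx.is_isomorphic(core_graph(a), core_graph(b),
                            node_match=_node_match, edge_match=_edge_match)


def contains_core_substructure(frag: Fragment, sub: nx.Graph) -> bool:
    """True iff ``sub`` occurs as a labelled (monomorphic) subgraph of the
    fragment's core graph."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        core_graph(frag), sub, node_match=_node_match, edge_match=_edge_match)
    return gm.subgraph_is_monomorphic()


def core_key(frag: Fragment) -> str:
    """Canonical text key of the core structure (canonical SMILES)."""
    return Chem.MolToSmiles(to_rdkit(frag.as_molecule(include_join=False)))


def describe_fragment(frag: Fragment) -> FragmentDescriptor:
    atoms = frag.atoms
    return FragmentDescriptor(
        n_heavy=len(atoms),
        n_donor=sum(a.is_donor for a in atoms),
        n_acceptor=sum(a.is_acceptor for a in atoms),
        n_ring_atoms=sum(a.in_ring for a in atoms),
        n_core=len(frag.core_atoms),
        n_join=len(frag.join_atoms),
    )


def reassemble(fragments: list) -> Molecule:
    """Union of all cores re-joined at the recorded broken bonds; used to
    check the fragmentation round trip against the parent molecule."""
    atoms, bonds, seen_atoms, seen_bonds = [], [], set(), set()
    broken = set()
    for f in fragments:
        for a in f.core_atoms:
            if a.index not in seen_atoms:
                seen_atoms.add(a.index)
                atoms.append(a.copy())
        core = {a.index for a in f.core_atoms}
        for b in f.bonds:
            if b.i in core and b.j in core and b.key() not in seen_bonds:
                seen_bonds.add(b.key())
                bonds.append(Bond(b.i, b.j, b.order, b.in_ring))
        broken.update((min(i, j), max(i, j)) for i, j in f.broken_bonds)
    for i, j in sorted(broken):
        if (i, j) not in seen_bonds:
            seen_bonds.add((i, j))
            bonds.append(Bond(i, j, 1))
    remap = {a.index: k for k, a in enumerate(sorted(atoms, key=lambda x: x.index))}
    atoms = sorted(atoms, key=lambda x: x.index)
    for a in atoms:
        a.index = remap[a.index]
    for b in bonds:
        b.i, b.j = remap[b.i], remap[b.j]
    name = fragments[0].parent_name if fragments else ""
    return Molecule(atoms=atoms, bonds=bonds, name=name)
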