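"""Valence-aware fragment replacement.

Swapping a fragment of a molecule for a bioisosteric fragment needs two
things: a placement of the incoming fragment in the molecule's frame, and
a rule for re-forming the bonds severed by removing the old fragment.

Placement: the chosen join atom of the incoming fragment is superposed
onto the molecule's attachment atom and the join->core bond direction is
aligned with the (attachment -> removed core) direction of the original
geometry, via the minimal rotation between the two vectors.  The primary
bond is then formed at that attachment.  Every other severed attachment is
reconnected by the closest-feasible-pair rule: candidate (incoming-atom,
molecule-atom) pairs are taken in ascending distance order and a single
bond is formed whenever both partners still have free heavy valence —
e.g. a carbon accepts a new bond only while it has fewer than four bonds
to heavy atoms, bonds to hydrogens being ignored.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .chemio import Atom, Bond, Molecule, perceive_and_type, to_molblock, to_smiles
from .errors import (
    ConnectivityError,
    ReconnectionError,
    UnsupportedElementError,
    ValidationError,
)
from .fragmenter import Fragment

#: maximum number of bonds to heavy atoms, by element (S by Sybyl subtype)
_MAX_HEAVY = {"C": 4, "N": 3, "O": 2, "P": 4,
              "F": 1, "Cl": 1, "Br": 1, "I": 1, "H": 1}
_MAX_HEAVY_S = {"S.3": 2, "S.2": 2, "S.o": 3, "S.o2": 4}


def available_valence(atom: Atom, mol: Molecule) -> int:
    """Free heavy-bond slots: element maximum minus current heavy degree,
    never negative; hydrogens do not count against the maximum."""
    if atom.element == "S":
        limit = _MAX_HEAVY_S.get(atom.sybyl_type, 2)
    else:
        try:
            limit = _MAX_HEAVY[atom.element]
        except KeyError:
            raise UnsupportedElementError(atom.element) from None
    degree = sum(1 for b in mol.bonds if atom.index in (b.i, b.j))
    return max(0, limit - degree)


def _minimal_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees: rotate about a deterministic perpendicular axis
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / (s * s))


def replace_fragment(mol: Molecule, old: Fragment, new: Fragment,
                     join_choice: tuple) -> Molecule:
    """Replace ``old`` (a fragment of ``mol``) by ``new``.

    ``join_choice`` is ``(new_join_index, attachment_index)``: the join
    atom of the incoming fragment to bond through, and the molecule atom
    (formerly bonded to the removed core) that receives the primary bond.
    Exactly one explicit pair is allowed; all remaining severed
    attachments are reconnected by the closest valence-feasible pair rule.
    """
    new_join_index, attachment_index = join_choice
    mol_indices = {a.index for a in mol.atoms}
    old_core = {a.index for a in old.core_atoms}
    old_joins = {a.index for a in old.join_atoms}
    if not old_core <= mol_indices or not old_joins <= mol_indices:
        raise ValidationError("old fragment does not belong to the molecule")
    if attachment_index not in old_joins:
        raise ValidationError(
            f"atom {attachment_index} is not an attachment of the removed "
            "fragment")
    try:
        new_anchor = new.join_anchor(new_join_index)
    except KeyError:
        raise ValidationError(
            f"{new_join_index} is not a join atom of the new fragment") from None

    by_index = {a.index: a for a in mol.atoms}

    # --- placement: join atom onto attachment atom, bond direction aligned
    attach_pos = by_index[attachment_index].position
    old_anchor = old.join_anchor(attachment_index)
    v = by_index[old_anchor].position - attach_pos
    join_atom = new.atom_by_index(new_join_index)
    anchor_atom = new.atom_by_index(new_anchor)
    u = anchor_atom.position - join_atom.position
    R = _minimal_rotation(u, v)

    def place(p: np.ndarray) -> np.ndarray:
        return R @ (p - join_atom.position) + attach_pos

    # --- build the product: molecule minus old core, plus new core
    atoms, remap = [], {}
    for a in mol.atoms:
        if a.index in old_core:
            continue
        c = a.copy()
        remap[a.index] = len(atoms)
        c.index = len(atoms)
        atoms.append(c)
    new_core_map = {}
    new_core_set = {a.index for a in new.core_atoms}
    for a in new.core_atoms:
        c = a.copy()
        c.position = place(a.position)
        new_core_map[a.index] = len(atoms)
        c.index = len(atoms)
        atoms.append(c)

    bonds = []
    for b in mol.bonds:
        if b.i in old_core or b.j in old_core:
            continue
        bonds.append(Bond(remap[b.i], remap[b.j], b.order, b.in_ring))
    for b in new.bonds:
        if b.i in new_core_set and b.j in new_core_set:
            bonds.append(Bond(new_core_map[b.i], new_core_map[b.j],
                              b.order, b.in_ring))

    product = Molecule(atoms=atoms, bonds=bonds, name=mol.name + "_replaced",
                       source=mol.source)

    # pre-perceive types so sulfur valence limits resolve on the product
    perceive_and_type(product)

    def free(idx: int) -> int:
        return available_valence(product.atoms[idx], product)

    # --- primary bond
    p_attach = remap[attachment_index]
    p_anchor = new_core_map[new_anchor]
    if free(p_attach) < 1:
        raise ValidationError(
            f"attachment atom {attachment_index} has no free valence")
    product.bonds.append(Bond(p_attach, p_anchor, 1))

    # --- remaining severed attachments, closest feasible pair first
    severed = sorted(old_joins - {attachment_index})
    candidates = []
    for s in severed:
        ps = remap[s]
        for orig, pn in new_core_map.items():
            d = float(np.linalg.norm(product.atoms[ps].position
                                     - product.atoms[pn].position))
            candidates.append((d, ps, pn, s))
    candidates.sort()
    reconnected = set()
    for d, ps, pn, s in candidates:
        if s in reconnected:
            continue
        if free(ps) >= 1 and free(pn) >= 1:
            product.bonds.append(Bond(ps, pn, 1))
            reconnected.add(s)
    missing = [s for s in severed if s not in reconnected]
    if missing:
        raise ReconnectionError(missing[0])

    g = product.graph()
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ConnectivityError("replacement left a disconnected molecule")
    return perceive_and_type(product)


def export_product(mol: Molecule, fmt: str = "smiles") -> str:
    """Canonical SMILES or a MOL V2000 block with 3D coordinates."""
    if fmt == "smiles":
        return to_smiles(mol)
    if fmt == "mol":
        return to_molblock(mol)
    raise ValidationError(f"unknown export format {fmt!r}")
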