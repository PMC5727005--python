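"""Molecular structures: reading, writing, and chemical perception.

The in-memory model is deliberately small: heavy atoms only (explicit
hydrogens in the input are counted onto their heavy neighbour and dropped),
an explicit bond list, and per-atom chemical annotations assigned by
:func:`perceive_and_type` — Sybyl-style atom types, Bondi van der Waals
radii, hydrogen-bond donor/acceptor flags and ring membership.  PDB files
are parsed with gemmi; MOL/SDF and SMILES round-trip through RDKit.

Sybyl types are element + hybridisation/geometry labels (``C.3``, ``C.ar``,
``N.pl3`` ...).  They matter downstream because fragment attachment points
("join atoms") are compared by these types when deciding whether two mined
fragments are interchangeable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

from .errors import (
    EmptyLigandError,
    EmptySiteError,
    PdbFormatError,
    UnsupportedElementError,
)

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: sentinel bond order for aromatic bonds
AROMATIC = "ar"

#: Bondi (1964) van der Waals radii, Å.  Unsupported elements are rejected.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

#: single-bond covalent radii, Å — used only for bond perception fallback
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

#: default valence (bond-order sum) used to infer implicit hydrogens
DEFAULT_VALENCE = {
    "C": 4, "N": 3, "O": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1, "P": 3,
}

#: HETATM residue names dropped as solvent/buffer/ions by default
DEFAULT_EXCLUSIONS = frozenset({
    "HOH", "DOD", "WAT", "SO4", "GOL", "PEG", "EDO", "PO4", "ACT", "DMS",
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "CD",
    "BR", "IOD",
})

_BOND_TOL = 1.25          # bond iff d <= tol * (rcov_i + rcov_j)
_PLANARITY_RMS = 0.10     # Å, out-of-plane RMS below which a ring is flat


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Atom:
    """A heavy atom with coordinates and perceived chemical annotations."""

    index: int
    element: str
    position: np.ndarray
    sybyl_type: str = ""
    vdw_radius: float = 0.0
    is_donor: bool = False
    is_acceptor: bool = False
    heavy_degree: int = 0
    aromatic: bool = False
    in_ring: bool = False
    explicit_h: int = 0
    implicit_h: int = 0
    name: str = ""
    residue: tuple | None = None  # (chain, number, icode, resname)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)

    @property
    def n_hydrogens(self) -> int:
        return self.explicit_h + self.implicit_h

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class Bond:
    i: int
    j: int
    order: object = 1  # 1 | 2 | 3 | AROMATIC
    in_ring: bool = False

    def key(self) -> tuple:
        return (min(self.i, self.j), max(self.i, self.j))


@dataclass
class Molecule:
    """A small molecule: heavy atoms, bonds, provenance."""

    atoms: list
    bonds: list
    name: str = ""
    source: tuple | None = None  # (file, chain, resname, resnum)

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"bond {b.i}-{b.j} has invalid endpoints")
            if b.key() in seen:
                raise ValueError(f"duplicate bond {b.key()}")
            seen.add(b.key())

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, element=a.element, aromatic=a.aromatic)
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order)
        return g

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=[a.copy() for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
            name=self.name,
            source=self.source,
        )


@dataclass
class Residue:
    chain: str
    number: int
    icode: str
    name: str
    atoms: list = field(default_factory=list)

    @property
    def id(self) -> tuple:
        return (self.chain, self.number, self.icode)

    def atom(self, name: str):
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ProteinComplex:
    """Protein atoms plus the co-crystallized ligands of one PDB entry."""

    protein_atoms: list
    ligands: list
    name: str = ""
    source: str = ""

    def residues(self) -> list:
        out, index = [], {}
        for a in self.protein_atoms:
            chain, number, icode, resname = a.residue
            key = (chain, number, icode)
            if key not in index:
                index[key] = Residue(chain, number, icode, resname)
                out.append(index[key])
            index[key].atoms.append(a)
        return out


@dataclass
class BindingSite:
    """Residues with any heavy atom within ``cutoff`` Å of the ligand."""

    residues: list
    ligand: Molecule
    cutoff: float


# ---------------------------------------------------------------------------
# perception


def _ring_flags(mol: Molecule) -> None:
    """Mark bonds/atoms on cycles: an edge is in a ring iff it is not a bridge."""
    g = nx.Graph()
    g.add_nodes_from(a.index for a in mol.atoms)
    g.add_edges_from((b.i, b.j) for b in mol.bonds)
    bridges = {tuple(sorted(e)) for e in nx.bridges(g)}
    ring_atoms = set()
    for b in mol.bonds:
        b.in_ring = b.key() not in bridges
        if b.in_ring:
            ring_atoms.update(b.key())
    for a in mol.atoms:
        a.in_ring = a.index in ring_atoms


def _perceive_aromatic_rings(mol: Molecule) -> None:
    """Geometric aromaticity for bond graphs lacking order information.

    Applied only when no aromatic bond is already present: a 5- or 6-ring
    of C/N/O/S atoms that is planar (out-of-plane RMS < 0.1 Å) and whose
    carbons have at most 3 heavy neighbours is flagged aromatic.  PDB
    HETATM ligands carry no bond orders, so this is how e.g. a benzene
    read from a PDB file gets typed C.ar.
    """
    if any(b.order == AROMATIC for b in mol.bonds):
        return
    g = nx.Graph()
    g.add_nodes_from(a.index for a in mol.atoms)
    g.add_edges_from((b.i, b.j) for b in mol.bonds)
    pos = {a.index: a.position for a in mol.atoms}
    elem = {a.index: a.element for a in mol.atoms}
    deg = dict(g.degree())
    by_key = {b.key(): b for b in mol.bonds}
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        if not all(elem[i] in ("C", "N", "O", "S") for i in cycle):
            continue
        if any(elem[i] == "C" and deg[i] > 3 for i in cycle):
            continue
        pts = np.array([pos[i] for i in cycle])
        centred = pts - pts.mean(axis=0)
        sv = np.linalg.svd(centred, compute_uv=False)
        if sv[-1] / np.sqrt(len(cycle)) >= _PLANARITY_RMS:
            continue
        ring_edges = list(zip(cycle, cycle[1:] + cycle[:1]))
        for i, j in ring_edges:
            by_key[(min(i, j), max(i, j))].order = AROMATIC


def _bond_order_sum(atom: Atom, bonds: list) -> float:
    total = 0.0
    for b in bonds:
        total += 1.5 if b.order == AROMATIC else float(b.order)
    return total


def _sybyl_type(atom: Atom, nbr_bonds: list, mol: Molecule, by_index: dict) -> str:
    el = atom.element
    orders = [b.order for b in nbr_bonds]
    if el == "C":
        if atom.aromatic:
            return "C.ar"
        if 3 in orders:
            return "C.1"
        if 2 in orders:
            return "C.2"
        return "C.3"
    if el == "N":
        if atom.aromatic:
            return "N.ar"
        if 3 in orders:
            return "N.1"
        if 2 in orders:
            return "N.2"
        # single-bonded N: amide next to C=O, planar next to sulfonyl/aromatic
        for b in nbr_bonds:
            other = by_index[b.j if b.i == atom.index else b.i]
            if other.element == "C" and any(
                nb.order == 2
                and by_index[nb.j if nb.i == other.index else nb.i].element == "O"
                for nb in _incident(other, mol)
            ):
                return "N.am"
            if other.element == "S" and _n_oxo(other, mol, by_index) >= 2:
                return "N.pl3"
            if other.aromatic and atom.heavy_degree >= 2:
                return "N.pl3"
        return "N.3"
    if el == "O":
        if 2 in orders:
            return "O.2"
        return "O.3"
    if el == "S":
        n_oxo = _n_oxo(atom, mol, by_index)
        if n_oxo >= 2:
            return "S.o2"
        if n_oxo == 1:
            return "S.o"
        if 2 in orders or atom.aromatic:
            return "S.2"
        return "S.3"
    if el == "P":
        return "P.3"
    if el in ("F", "Cl", "Br", "I", "H"):
        return el
    raise UnsupportedElementError(el)


def _incident(atom: Atom, mol: Molecule) -> list:
    return [b for b in mol.bonds if atom.index in (b.i, b.j)]


def _n_oxo(atom: Atom, mol: Molecule, by_index: dict) -> int:
    n = 0
    for b in _incident(atom, mol):
        other = by_index[b.j if b.i == atom.index else b.i]
        if other.element == "O" and b.order == 2:
            n += 1
    return n


def perceive_and_type(mol: Molecule) -> Molecule:
    """Assign ring flags, aromaticity, Sybyl types, Bondi radii and
    donor/acceptor flags in place; returns the molecule.

    Donor: N or O carrying at least one hydrogen, explicit or inferred
    from default valence.  Acceptor: any O; N with an available lone pair
    (sp3/sp2/sp nitrogen, or 2-coordinate aromatic N as in pyridine) —
    amide and planar trisubstituted nitrogens are excluded.
    """
    by_index = {a.index: a.index for a in mol.atoms}
    if sorted(by_index) != list(range(len(mol.atoms))):
        raise ValueError("atom indices must be 0..n-1")
    by_index = {a.index: a for a in mol.atoms}

    for a in mol.atoms:
        if a.element not in BONDI_RADII:
            raise UnsupportedElementError(a.element)
        a.vdw_radius = BONDI_RADII[a.element]
        a.heavy_degree = 0
    for b in mol.bonds:
        by_index[b.i].heavy_degree += 1
        by_index[b.j].heavy_degree += 1

    _ring_flags(mol)
    _perceive_aromatic_rings(mol)
    aromatic_atoms = set()
    for b in mol.bonds:
        if b.order == AROMATIC:
            aromatic_atoms.update(b.key())
    for a in mol.atoms:
        a.aromatic = a.index in aromatic_atoms
    _ring_flags(mol)  # ring flags unaffected by order rewrite; cheap re-run

    for a in mol.atoms:
        nbr_bonds = _incident(a, mol)
        a.sybyl_type = _sybyl_type(a, nbr_bonds, mol, by_index)
        default = DEFAULT_VALENCE.get(a.element)
        if a.element == "S":
            default = {"S.o2": 6, "S.o": 4, "S.2": 2, "S.3": 2}[a.sybyl_type]
        used = _bond_order_sum(a, nbr_bonds)
        if default is None:
            a.implicit_h = 0
        else:
            a.implicit_h = max(0, int(round(default - used)) - a.explicit_h)
    for a in mol.atoms:
        if a.element in ("N", "O"):
            a.is_donor = a.n_hydrogens >= 1
            if a.element == "O":
                a.is_acceptor = True
            else:
                a.is_acceptor = a.sybyl_type in ("N.3", "N.2", "N.1") or (
                    a.sybyl_type == "N.ar" and a.heavy_degree == 2
                )
        else:
            a.is_donor = a.is_acceptor = False
    return mol


# ---------------------------------------------------------------------------
# PDB reading


def _perceive_bonds_by_distance(atoms: list) -> list:
    """Bond iff d <= 1.25 x (covalent radius sum); used when CONECT absent."""
    bonds = []
    pos = np.array([a.position for a in atoms])
    rad = np.array([COVALENT_RADII[a.element] for a in atoms])
    for i in range(len(atoms)):
        d = np.linalg.norm(pos[i + 1:] - pos[i], axis=1)
        limit = _BOND_TOL * (rad[i] + rad[i + 1:])
        for off in np.nonzero(d <= limit)[0]:
            bonds.append(Bond(i, int(i + 1 + off), 1))
    return bonds


def _scan_pdb_text(path) -> dict:
    """Validate coordinate records and collect CONECT serial pairs.

    gemmi handles the structural model; this pass exists to (a) report the
    line number of an unparsable ATOM/HETATM record and (b) pick up CONECT
    bonds, which gemmi does not expose.
    """
    conect = set()
    n_coord = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                    int(line[6:11])
                except (ValueError, IndexError):
                    raise PdbFormatError(lineno, f"bad {rec} record") from None
                n_coord += 1
            elif rec == "CONECT":
                try:
                    serials = [int(line[k:k + 5]) for k in range(6, 27, 5)
                               if line[k:k + 5].strip()]
                except ValueError:
                    raise PdbFormatError(lineno, "bad CONECT record") from None
                for other in serials[1:]:
                    conect.add((min(serials[0], other), max(serials[0], other)))
    if n_coord == 0:
        raise PdbFormatError(0, "no ATOM/HETATM records found")
    return {"conect": conect}


def read_pdb_complex(path, exclusions=DEFAULT_EXCLUSIONS) -> ProteinComplex:
    """Read a holo complex: ATOM records become protein atoms, each HETATM
    residue group (minus the exclusion set) becomes one ligand Molecule.

    Ligand bonds come from CONECT records when present, otherwise from the
    covalent-radius distance heuristic.  Explicit hydrogens are folded into
    their nearest heavy atom's hydrogen count and dropped.
    """
    extra = _scan_pdb_text(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    model = st[0]

    protein_atoms, lig_groups = [], []
    index = 0
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            if het and res.name in exclusions:
                continue
            group = []
            for at in res:
                el = at.element.name
                atom = Atom(
                    index=0,
                    element=el if len(el) == 1 else el.capitalize(),
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    name=at.name,
                    residue=(chain.name, res.seqid.num,
                             res.seqid.icode.strip(), res.name),
                )
                atom.serial = at.serial
                group.append(atom)
            if het:
                lig_groups.append((chain.name, res, group))
            else:
                for atom in group:
                    if atom.element == "H":
                        continue
                    atom.index = index
                    index += 1
                    protein_atoms.append(atom)

    ligands = []
    for chain_name, res, group in lig_groups:
        heavy = [a for a in group if a.element != "H"]
        hydrogens = [a for a in group if a.element == "H"]
        if not heavy:
            continue
        serial_map = {}
        for k, a in enumerate(heavy):
            serial_map[a.serial] = k
            a.index = k
        # fold explicit hydrogens into their closest heavy atom
        for h in hydrogens:
            d = [np.linalg.norm(h.position - a.position) for a in heavy]
            heavy[int(np.argmin(d))].explicit_h += 1
        conect_bonds = [
            Bond(serial_map[i], serial_map[j], 1)
            for i, j in extra["conect"]
            if i in serial_map and j in serial_map
        ]
        bonds = conect_bonds or _perceive_bonds_by_distance(heavy)
        lig = Molecule(
            atoms=heavy, bonds=bonds, name=res.name,
            source=(str(path), chain_name, res.name, res.seqid.num),
        )
        ligands.append(perceive_and_type(lig))

    if not ligands:
        raise EmptyLigandError(
            f"{path}: no ligand left after excluding {sorted(exclusions)[:5]}..."
        )
    return ProteinComplex(
        protein_atoms=protein_atoms, ligands=ligands,
        name=st.name or str(path), source=str(path),
    )


def extract_binding_site(complex_: ProteinComplex, ligand: Molecule,
                         cutoff: float = 5.0) -> BindingSite:
    """Residues with >= 1 heavy atom within ``cutoff`` Å (closed interval)
    of any ligand heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_pos = ligand.positions()
    kept = []
    for res in complex_.residues():
        pos = np.array([a.position for a in res.atoms])
        d = np.linalg.norm(pos[:, None, :] - lig_pos[None, :, :], axis=2)
        if d.min() <= cutoff:
            kept.append(res)
    if not kept:
        raise EmptySiteError(
            f"no residue within {cutoff} Å of ligand {ligand.name}")
    return BindingSite(residues=kept, ligand=ligand, cutoff=cutoff)


# ---------------------------------------------------------------------------
# RDKit bridge: MOL/SDF and SMILES

_RDKIT_ORDERS = {
    1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE, AROMATIC: Chem.BondType.AROMATIC,
}
_FROM_RDKIT_ORDERS = {
    Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3, Chem.BondType.AROMATIC: AROMATIC,
}


def to_rdkit(mol: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        rw.AddAtom(ra)
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, _RDKIT_ORDERS[b.order])
        if b.order == AROMATIC:
            rw.GetAtomWithIdx(b.i).SetIsAromatic(True)
            rw.GetAtomWithIdx(b.j).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
    m = rw.GetMol()
    conf = Chem.Conformer(m.GetNumAtoms())
    for a in mol.atoms:
        conf.SetAtomPosition(a.index, tuple(float(x) for x in a.position))
    m.AddConformer(conf)
    try:
        Chem.SanitizeMol(m)
    except Exception:
        # tolerate odd valences from perception-only bond graphs
        m.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(
            m,
            Chem.SanitizeFlags.SANITIZE_FINDRADICALS
            | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
            | Chem.SanitizeFlags.SANITIZE_SYMMRINGS,
            catchErrors=True,
        )
    return m


def from_rdkit(m: Chem.Mol, name: str = "", source=None) -> Molecule:
    m = Chem.Mol(m)
    conf = m.GetConformer() if m.GetNumConformers() else None
    atoms, bonds = [], []
    keep = [a.GetIdx() for a in m.GetAtoms() if a.GetSymbol() != "H"]
    remap = {old: new for new, old in enumerate(keep)}
    for old in keep:
        ra = m.GetAtomWithIdx(old)
        pos = (np.array(list(conf.GetAtomPosition(old)))
               if conf is not None else np.zeros(3))
        atoms.append(Atom(
            index=remap[old], element=ra.GetSymbol(), position=pos,
            explicit_h=sum(1 for nb in ra.GetNeighbors()
                           if nb.GetSymbol() == "H") + ra.GetNumExplicitHs(),
        ))
    for rb in m.GetBonds():
        i, j = rb.GetBeginAtomIdx(), rb.GetEndAtomIdx()
        if i in remap and j in remap:
            bonds.append(Bond(remap[i], remap[j],
                              _FROM_RDKIT_ORDERS[rb.GetBondType()]))
    return perceive_and_type(Molecule(atoms=atoms, bonds=bonds,
                                      name=name, source=source))


def from_smiles(smiles: str, name: str = "", embed3d: bool = True,
                seed: int = 7) -> Molecule:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    if embed3d:
        mh = Chem.AddHs(m)
        params = AllChem.ETKDGv3()
        params.randomSeed = seed
        if AllChem.EmbedMolecule(mh, params) == 0:
            m = Chem.RemoveHs(mh)
    return from_rdkit(m, name=name or smiles)


def to_smiles(mol: Molecule) -> str:
    """Canonical SMILES — invariant under atom reordering of the input."""
    return Chem.MolToSmiles(to_rdkit(mol))


def read_mol(path, name: str = "") -> Molecule:
    m = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=True)
    if m is None:
        m = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
        if m is None:
            raise ValueError(f"unparsable MOL file: {path}")
        m.UpdatePropertyCache(strict=False)
    return from_rdkit(m, name=name or str(path), source=(str(path), None, None, None))


def write_mol(mol: Molecule, path) -> None:
    block = Chem.MolToMolBlock(to_rdkit(mol), kekulize=True)
    with open(path, "w") as fh:
        fh.write(block)


def to_molblock(mol: Molecule) -> str:
    return Chem.MolToMolBlock(to_rdkit(mol), kekulize=True)
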