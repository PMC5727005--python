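"""Deterministic synthetic complexes with planted bioisostere pairs.

Everything downstream of the aligner is testable without any structure
download: this module builds idealized small-molecule templates, places a
six-residue pocket (one labelled functional group per residue, all five
physico-chemical classes represented) around a ligand, and emits pairs of
congruent complexes in which a designated fragment pair is guaranteed to
overlap within a chosen bound after correct superposition.  All outputs
are pure functions of their seeds.

The geometry is intentionally idealized (flat rings, round-number bond
lengths, pockets without backbones); it exercises the pipeline's
contracts, not protein realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .chemio import (
    AROMATIC,
    Atom,
    Bond,
    Molecule,
    ProteinComplex,
    perceive_and_type,
    write_mol,
)
from .sitealign import Transform


# ---------------------------------------------------------------------------
# ligand templates


def _ring(n, radius, elements, orders, z=0.0, start_angle=0.0):
    atoms, bonds = [], []
    for k in range(n):
        a = start_angle + 2 * np.pi * k / n
        atoms.append((elements[k],
                      np.array([radius * np.cos(a), radius * np.sin(a), z])))
    for k in range(n):
        bonds.append((k, (k + 1) % n, orders[k]))
    return atoms, bonds


def _chair(elements, bond=1.54):
    """Six-membered chair: alternating z puckering."""
    d = 0.25
    radius = np.sqrt(bond ** 2 - (2 * d) ** 2)
    atoms = []
    for k in range(6):
        a = 2 * np.pi * k / 6
        atoms.append((elements[k],
                      np.array([radius * np.cos(a), radius * np.sin(a),
                                d if k % 2 else -d])))
    bonds = [(k, (k + 1) % 6, 1) for k in range(6)]
    return atoms, bonds


def _assemble(parts) -> Molecule:
    atoms, bonds = parts
    mol = Molecule(
        atoms=[Atom(index=i, element=el, position=pos)
               for i, (el, pos) in enumerate(atoms)],
        bonds=[Bond(i, j, order) for i, j, order in bonds],
    )
    return perceive_and_type(mol)


def _benzene():
    return _ring(6, 1.39, ["C"] * 6, [AROMATIC] * 6)


def _pyridine():
    return _ring(6, 1.39, ["N"] + ["C"] * 5, [AROMATIC] * 6)


def _thiophene():
    return _ring(5, 1.21, ["S", "C", "C", "C", "C"], [AROMATIC] * 5)


def _cyclohexane():
    return _chair(["C"] * 6)


def _morpholine():
    # O at position 0, N para at position 3
    return _chair(["O", "C", "C", "N", "C", "C"])


def _toluene():
    atoms, bonds = _benzene()
    atoms.append(("C", np.array([2.89, 0.0, 0.0])))
    bonds.append((0, 6, 1))
    return atoms, bonds


def _biphenyl():
    atoms, bonds = _benzene()
    ring_b, bonds_b = _ring(6, 1.39, ["C"] * 6, [AROMATIC] * 6,
                            start_angle=np.pi)
    offset = len(atoms)
    for el, pos in ring_b:
        atoms.append((el, pos + np.array([4.26, 0.0, 0.0])))
    bonds.extend((i + offset, j + offset, o) for i, j, o in bonds_b)
    bonds.append((0, offset, 1))  # 1.39 -> 2.87: 1.48 A inter-ring bond
    return atoms, bonds


def _ethylbenzene():
    atoms, bonds = _benzene()
    # CH2 placed exactly where biphenyl's second-ring carbon sits, so the
    # benzene fragments of the two templates have congruent join geometry
    atoms.append(("C", np.array([2.87, 0.0, 0.0])))
    atoms.append(("C", np.array([3.64, 1.334, 0.0])))
    bonds.append((0, 6, 1))
    bonds.append((6, 7, 1))
    return atoms, bonds


def _sulfonamide_linker():
    # CH3-SO2-NH-CH3
    atoms = [
        ("C", np.array([0.0, 0.0, 0.0])),
        ("S", np.array([1.78, 0.0, 0.0])),
        ("O", np.array([1.78, 1.20, 0.80])),
        ("O", np.array([1.78, -1.20, 0.80])),
        ("N", np.array([3.03, 0.0, -1.00])),
        ("C", np.array([4.50, 0.0, -1.00])),
    ]
    bonds = [(0, 1, 1), (1, 2, 2), (1, 3, 2), (1, 4, 1), (4, 5, 1)]
    return atoms, bonds


def _murf_mock():
    """Topological stand-in for a three-ring, two-linker inhibitor:
    benzene-CH2-benzene-CH2-benzene; fragments into 5 pieces."""
    atoms, bonds = [], []
    centers = [0.0, 5.78, 11.56]
    link_x = [2.89, 8.67]
    for c in centers:
        ring, ring_bonds = _benzene()
        offset = len(atoms)
        for el, pos in ring:
            atoms.append((el, pos + np.array([c, 0.0, 0.0])))
        bonds.extend((i + offset, j + offset, o) for i, j, o in ring_bonds)
    for k, lx in enumerate(link_x):
        atoms.append(("C", np.array([lx, 0.0, 0.0])))
        li = len(atoms) - 1
        bonds.append((0 + 6 * k, li, 1))       # vertex of ring k at angle 0
        bonds.append((li, 6 * (k + 1) + 3, 1))  # vertex of ring k+1 at 180 deg
    return atoms, bonds


def _ethane():
    return ([("C", np.zeros(3)), ("C", np.array([1.54, 0.0, 0.0]))],
            [(0, 1, 1)])


def _methanol():
    return ([("C", np.zeros(3)), ("O", np.array([1.43, 0.0, 0.0]))],
            [(0, 1, 1)])


def _ethanol():
    return ([("C", np.zeros(3)), ("C", np.array([1.54, 0.0, 0.0])),
             ("O", np.array([2.03, 1.35, 0.0]))],
            [(0, 1, 1), (1, 2, 1)])


TEMPLATES = {
    "benzene": _benzene, "pyridine": _pyridine, "thiophene": _thiophene,
    "cyclohexane": _cyclohexane, "morpholine": _morpholine,
    "toluene": _toluene, "biphenyl": _biphenyl,
    "ethylbenzene": _ethylbenzene, "sulfonamide": _sulfonamide_linker,
    "murf_mock": _murf_mock, "ethane": _ethane, "methanol": _methanol,
    "ethanol": _ethanol,
}


def make_ligand(template: str, transform: Transform | None = None,
                seed: int = 0) -> Molecule:
    """Build a typed template molecule; identical output for identical
    arguments (the geometry is closed-form; ``seed`` is accepted for API
    symmetry with the stochastic fixture generators)."""
    try:
        builder = TEMPLATES[template]
    except KeyError:
        raise ValueError(f"unknown template {template!r}; known: "
                         f"{sorted(TEMPLATES)}") from None
    mol = _assemble(builder())
    mol.name = template
    if transform is not None:
        pts = transform.apply(mol.positions())
        for a, p in zip(mol.atoms, pts):
            a.position = p
    return mol


# ---------------------------------------------------------------------------
# pockets


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _frame(direction):
    """Deterministic orthonormal (u, v) spanning the plane normal-ish to
    the residue direction."""
    d = _unit(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = _unit(np.cross(d, ref))
    v = _unit(np.cross(d, u))
    return u, v


def _residue_atoms(resname: str, center: np.ndarray, u: np.ndarray,
                   v: np.ndarray) -> list:
    """Side-chain atoms such that the residue's site point sits at center."""
    def hexagon(names):
        return [(n, center + 1.39 * (np.cos(2 * np.pi * k / 6) * u
                                     + np.sin(2 * np.pi * k / 6) * v))
                for k, n in enumerate(names)]

    if resname in ("PHE", "TYR"):
        out = hexagon(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"])
        out.append(("CB", center + 2.6 * u + 0.8 * v))
        if resname == "TYR":
            out.append(("OH", center - 2.75 * u))
        return out
    if resname == "SER":
        return [("OG", center.copy()), ("CB", center + 1.41 * u)]
    if resname == "LEU":
        return [("CG", center + 0.0 * u),
                ("CB", center + 1.53 * u),
                ("CD1", center + 1.53 * (-0.5 * u + 0.866 * v)),
                ("CD2", center + 1.53 * (-0.5 * u - 0.866 * v))]
    if resname == "LYS":
        return [("NZ", center.copy()), ("CE", center + 1.47 * u)]
    if resname == "ASP":
        return [("OD1", center + 1.1 * v), ("OD2", center - 1.1 * v),
                ("CG", center + 1.0 * u)]
    raise ValueError(f"no fixture template for residue {resname!r}")


#: irregular pocket layout: (resname, direction, radius from pocket center)
POCKET_LAYOUT = (
    # directions keep clear of +x, where elongated ligands extend
    ("PHE", (0.2, 1.0, 0.6), 4.6),
    ("TYR", (-0.9, 0.5, 0.3), 4.2),
    ("SER", (0.1, 1.0, -0.3), 4.0),
    ("LEU", (0.2, -1.0, 0.4), 4.8),
    ("LYS", (0.3, 0.2, 1.0), 4.4),
    ("ASP", (-0.2, -0.4, -1.0), 4.3),
)


def make_pocket(center=np.zeros(3), chain: str = "A",
                layout=POCKET_LAYOUT) -> list:
    """Protein atoms of a six-residue pocket whose site points surround
    ``center`` at 4-5 Å in five distinct physico-chemical labels."""
    atoms = []
    index = 0
    for resnum, (resname, direction, radius) in enumerate(layout, start=1):
        d = _unit(direction)
        u, v = _frame(d)
        res_center = np.asarray(center) + radius * d
        for name, pos in _residue_atoms(resname, res_center, u, v):
            element = name[0] if name[0] != "H" else "H"
            atoms.append(Atom(index=index, element=element, position=pos,
                              name=name,
                              residue=(chain, resnum, "", resname)))
            index += 1
    return atoms


def random_transform(seed: int) -> Transform:
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    return Transform(rot, rng.uniform(-10.0, 10.0, 3))


# ---------------------------------------------------------------------------
# complex pairs with planted ground truth


@dataclass
class ComplexPair:
    complex_a: ProteinComplex
    complex_b: ProteinComplex
    transform: Transform          # maps complex B coordinates into A's frame
    planted_overlap: float
    families: tuple
    expected: dict


def make_complex_pair(pocket_seed: int, lig_a: str = "biphenyl",
                      lig_b: str = "ethylbenzene",
                      planted_overlap: float = 0.0,
                      families: tuple = ("fam.benzene", "fam.benzene"),
                      ) -> ComplexPair:
    """Two congruent-pocket complexes; ligand B is placed so its first
    benzene-like fragment coincides with ligand A's (displaced by
    ``planted_overlap`` Å), then the whole of complex B is carried into
    its own frame by the inverse of a seeded random rigid motion.  The
    emitted ground truth is the transform the aligner should recover and
    the displacement bound for the planted fragment pair.
    """
    if planted_overlap < 0:
        raise ValueError("planted_overlap must be >= 0")
    t_ba = random_transform(pocket_seed)          # B -> A
    t_ab = t_ba.inverse()

    pocket = make_pocket()
    mol_a = make_ligand(lig_a)
    mol_b_in_a = make_ligand(lig_b)
    shift = np.array([planted_overlap, 0.0, 0.0])
    for atom in mol_b_in_a.atoms:
        atom.position = atom.position + shift

    name_a = f"FIXA{pocket_seed:04d}"
    name_b = f"FIXB{pocket_seed:04d}"
    cx_a = ProteinComplex(protein_atoms=pocket, ligands=[mol_a],
                          name=name_a, source="fixture")
    pocket_b = [a.copy() for a in pocket]
    for a in pocket_b:
        a.position = t_ab.apply(a.position[None])[0]
    mol_b = mol_b_in_a.copy()
    pts = t_ab.apply(mol_b.positions())
    for a, p in zip(mol_b.atoms, pts):
        a.position = p
    mol_b.source = ("fixture", "A", mol_b.name, 900)
    mol_a.source = ("fixture", "A", mol_a.name, 900)
    cx_b = ProteinComplex(protein_atoms=pocket_b, ligands=[mol_b],
                          name=name_b, source="fixture")
    return ComplexPair(
        complex_a=cx_a, complex_b=cx_b, transform=t_ba,
        planted_overlap=planted_overlap, families=families,
        expected={
            "transform": t_ba.to_flat(),
            "pair": (lig_a, lig_b),
            "planted_overlap": planted_overlap,
            "site_points": len(POCKET_LAYOUT),
        },
    )


# ---------------------------------------------------------------------------
# PDB emission (fixture writer; the reader is the gemmi-backed one)


def _format_atom_line(record: str, serial: int, name: str, resname: str,
                      chain: str, resnum: int, pos, element: str) -> str:
    pad_name = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"{record:<6s}{serial:>5d} {pad_name} {resname:<3s} {chain}"
            f"{resnum:>4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


def write_complex_pdb(cx: ProteinComplex, path) -> None:
    lines = []
    serial = 1
    for a in cx.protein_atoms:
        chain, resnum, _icode, resname = a.residue
        lines.append(_format_atom_line("ATOM", serial, a.name, resname,
                                       chain, resnum, a.position, a.element))
        serial += 1
    conect = []
    for k, lig in enumerate(cx.ligands):
        serial_of = {}
        for a in lig.atoms:
            serial_of[a.index] = serial
            lines.append(_format_atom_line(
                "HETATM", serial, (a.name or f"{a.element}{a.index + 1}")[:4],
                (lig.name[:3].upper() or "LIG"), "L", 900 + k, a.position,
                a.element))
            serial += 1
        for b in lig.bonds:
            conect.append(f"CONECT{serial_of[b.i]:>5d}{serial_of[b.j]:>5d}")
    lines.extend(conect)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_set(out_dir, seed: int = 7,
                      planted_overlap: float = 0.0) -> dict:
    """Emit a ready-to-mine fixture set: two PDB complexes, the ligand SDF
    files, a families TSV and the ground-truth JSON.  Returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair = make_complex_pair(seed, planted_overlap=planted_overlap)
    paths = {
        "pdb_a": out / f"{pair.complex_a.name}.pdb",
        "pdb_b": out / f"{pair.complex_b.name}.pdb",
        "lig_a": out / "ligand_a.mol",
        "lig_b": out / "ligand_b.mol",
        "families": out / "families.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_complex_pdb(pair.complex_a, paths["pdb_a"])
    write_complex_pdb(pair.complex_b, paths["pdb_b"])
    write_mol(pair.complex_a.ligands[0], paths["lig_a"])
    write_mol(pair.complex_b.ligands[0], paths["lig_b"])
    paths["families"].write_text(
        f"{pair.complex_a.name}\t{pair.families[0]}\n"
        f"{pair.complex_b.name}\t{pair.families[1]}\n")
    paths["ground_truth"].write_text(json.dumps(pair.expected, indent=2))
    return {k: str(v) for k, v in paths.items()}
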