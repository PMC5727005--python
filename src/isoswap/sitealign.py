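"""Binding-site superposition by labelled maximum-clique matching.

A binding site is reduced to one physico-chemical point per residue
(aromatic ring centroid, H-bonding side-chain terminus, hydrophobic
side-chain centroid...).  Two sites are matched by building the product
graph of same-label point pairs, connecting pairs whose within-site
distances agree within ``eps``, and extracting a maximum clique — a
distance-consistent common arrangement of functional groups.  The clique
correspondence is superposed by the Kabsch algorithm, alignment scores are
normalised to Z-scores within the batch, and the resulting rigid transform
carries the co-crystallized ligand of one complex into the other's frame.

This is a desk-scale aligner with the same contract as a full local
structural alignment over the PDB: two sites in, (transform, score,
Z-filter) out.  Externally computed transforms can be substituted via
:func:`load_transforms`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .chemio import BindingSite, Molecule
from .errors import DegenerateGeometryError

logger = logging.getLogger(__name__)

LABELS = ("hydrophobic", "aromatic", "donor", "acceptor", "donor_acceptor")

#: residue name -> (atom names for the representative point, label).
#: Missing atoms are tolerated (centroid of whatever is present).
RESIDUE_FEATURES = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), "aromatic"),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), "aromatic"),
    "TRP": (("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"), "aromatic"),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"), "aromatic"),
    "SER": (("OG",), "donor_acceptor"),
    "THR": (("OG1",), "donor_acceptor"),
    "CYS": (("SG",), "donor"),
    "LYS": (("NZ",), "donor"),
    "ARG": (("NH1", "NH2", "CZ"), "donor"),
    "ASP": (("OD1", "OD2"), "acceptor"),
    "GLU": (("OE1", "OE2"), "acceptor"),
    "ASN": (("OD1", "ND2"), "donor_acceptor"),
    "GLN": (("OE1", "NE2"), "donor_acceptor"),
    "LEU": (("CB", "CG", "CD1", "CD2"), "hydrophobic"),
    "ILE": (("CB", "CG1", "CG2", "CD1"), "hydrophobic"),
    "VAL": (("CB", "CG1", "CG2"), "hydrophobic"),
    "MET": (("CB", "CG", "SD", "CE"), "hydrophobic"),
    "ALA": (("CB",), "hydrophobic"),
    "PRO": (("CB", "CG", "CD"), "hydrophobic"),
    "GLY": (("CA",), "hydrophobic"),
}


@dataclass
class SitePoint:
    position: np.ndarray
    label: str
    residue_id: tuple

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown site-point label {self.label!r}")
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Transform:
    """Rigid transform x -> R @ x + t with a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)

    def compose(self, other: "Transform") -> "Transform":
        """Composition: apply ``other`` first, then ``self``."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def to_flat(self) -> list:
        return [float(x) for x in
                np.concatenate([self.rotation.ravel(), self.translation])]

    @classmethod
    def from_flat(cls, values) -> "Transform":
        v = np.asarray(list(values), dtype=float)
        if v.size != 12:
            raise ValueError("expected 12 numbers (row-major R then t)")
        return cls(v[:9].reshape(3, 3), v[9:])


@dataclass
class SiteAlignment:
    correspondence: list            # (index in A, index in B) pairs
    transform: Transform            # maps B coordinates into A's frame
    score: int                      # clique size
    rmsd: float
    zscore: float | None = None


def describe_site(site: BindingSite) -> list:
    """One labelled point per recognised residue; unknown residues are
    skipped with a logged warning."""
    points = []
    for res in site.residues:
        feat = RESIDUE_FEATURES.get(res.name)
        if feat is None:
            logger.warning("unknown residue %s %s; skipped", res.name, res.id)
            continue
        names, label = feat
        pos = [res.atom(n).position for n in names if res.atom(n) is not None]
        if not pos:
            logger.warning("residue %s %s lacks feature atoms; skipped",
                           res.name, res.id)
            continue
        points.append(SitePoint(np.mean(pos, axis=0), label, res.id))
    return points


def kabsch(P: np.ndarray, Q: np.ndarray) -> Transform:
    """Least-squares proper rigid transform mapping Q onto P.

    Requires >= 3 non-collinear paired points; mirror solutions are
    rejected by the determinant sign correction.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape or len(P) < 3:
        raise DegenerateGeometryError("need >= 3 paired points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    if (np.linalg.svd(Pc, compute_uv=False)[1] < 1e-8
            or np.linalg.svd(Qc, compute_uv=False)[1] < 1e-8):
        raise DegenerateGeometryError("points are collinear or coincident")
    H = Qc.T @ Pc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return Transform(R, cp - R @ cq)


def rmsd_after(transform: Transform, P: np.ndarray, Q: np.ndarray) -> float:
    diff = transform.apply(Q) - np.asarray(P, dtype=float)
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


def product_graph(A: list, B: list, eps: float) -> nx.Graph:
    """Nodes = same-label (i, j) point pairs; edge between (p, q) and
    (p', q') iff |d(p, p') - d(q, q')| <= eps."""
    g = nx.Graph()
    nodes = [(i, j) for i, a in enumerate(A) for j, b in enumerate(B)
             if a.label == b.label]
    g.add_nodes_from(nodes)
    pa = np.array([p.position for p in A]).reshape(-1, 3)
    pb = np.array([p.position for p in B]).reshape(-1, 3)
    for (i1, j1), (i2, j2) in itertools.combinations(nodes, 2):
        if i1 == i2 or j1 == j2:
            continue
        da = np.linalg.norm(pa[i1] - pa[i2])
        db = np.linalg.norm(pb[j1] - pb[j2])
        if abs(da - db) <= eps:
            g.add_edge((i1, j1), (i2, j2))
    return g


def maximum_clique(g: nx.Graph) -> list:
    """Exact maximum clique via maximal-clique enumeration (Bron–Kerbosch);
    ties broken by the lexicographically smallest sorted node set."""
    if g.number_of_nodes() == 0:
        return []
    best = None
    for clique in nx.find_cliques(g):
        cand = sorted(clique)
        if best is None or len(cand) > len(best) or (
                len(cand) == len(best) and cand < best):
            best = cand
    return best or []


def align_sites(A: list, B: list, eps: float = 2.0,
                min_score: int = 4) -> SiteAlignment | None:
    """Match two described sites; returns None when no distance-consistent
    correspondence of at least ``min_score`` points exists."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    g = product_graph(A, B, eps)
    clique = maximum_clique(g)
    if len(clique) < max(min_score, 3):
        return None
    P = np.array([A[i].position for i, _ in clique])
    Q = np.array([B[j].position for _, j in clique])
    try:
        t = kabsch(P, Q)
    except DegenerateGeometryError:
        return None
    return SiteAlignment(correspondence=clique, transform=t,
                         score=len(clique), rmsd=rmsd_after(t, P, Q))


def zscores(scores) -> np.ndarray:
    """Standard scores over the batch, population standard deviation.
    A zero-spread batch yields all-zero Z-scores (logged)."""
    s = np.asarray(list(scores), dtype=float)
    if s.size < 2:
        raise ValueError("Z-scores need a batch of >= 2 scores")
    sd = s.std()
    if sd == 0:
        logger.warning("all alignment scores equal; Z-scores undefined, set to 0")
        return np.zeros_like(s)
    return (s - s.mean()) / sd


def zscore_filter(scores, threshold: float = 2.0) -> list:
    """Indices of scores whose Z-score is >= threshold."""
    z = zscores(scores)
    return [int(i) for i in np.nonzero(z >= threshold)[0]]


def transpose_ligand(mol: Molecule, t: Transform) -> Molecule:
    """Map ligand coordinates x -> R x + t; topology untouched."""
    out = mol.copy()
    new = t.apply(out.positions())
    for a, p in zip(out.atoms, new):
        a.position = p
    return out


def load_transforms(path) -> list:
    """Read externally computed rigid transforms, one per line as 12
    whitespace-separated numbers (row-major rotation, then translation)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(Transform.from_flat(float(x) for x in line.split()))
    return out


def save_transforms(transforms, path) -> None:
    with open(path, "w") as fh:
        for t in transforms:
            fh.write(" ".join(f"{x:.10f}" for x in t.to_flat()) + "\n")
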