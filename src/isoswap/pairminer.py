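"""Mining bioisosteric fragment pairs from aligned complexes.

After two binding sites are superposed and the second ligand is carried
into the first one's frame, both ligands are fragmented and every cross
pair of fragments is scored by the Hausdorff distance (HD) between their
van der Waals surfaces:

    HD(A, B) = max{ oHD(A, B), oHD(B, A) }

where oHD(A, B) is the largest distance from a point of surface A to its
nearest point on surface B.  Small HD means the two fragments occupy
nearly the same region of the pocket — the operational definition of a
bioisosteric or scaffold replacement here.  Three variants are recorded
per pair: *Overall* (all fragment atoms), *Core* (join atoms excluded) and
*H-bonding* (donor/acceptor atoms only, absent when either fragment has
none).  Surfaces are deterministic Fibonacci-lattice samplings of the
atomic vdW spheres with buried points culled.

Pairs with Overall HD within the cutoff (default 1.50 Å) are stored, in
both orientations, in a single-file SQLite database indexed by canonical
core key and descriptor counts.
"""

from __future__ import annotations

import itertools
import json
import logging
import sqlite3
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chemio import Atom, Bond, extract_binding_site
from .errors import (
    EmptySiteError,
    EmptySubsetError,
    SchemaVersionError,
    UndefinedInputError,
)
from .fragmenter import Fragment, core_key, describe_fragment, fragment_molecule
from .sitealign import align_sites, describe_site, transpose_ligand, zscore_filter

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
SUBSETS = ("all", "core", "hbond")
_BURIAL_TOL = 1e-6


@dataclass
class SurfacePointSet:
    points: np.ndarray
    subset: str
    density: int


@dataclass
class PairRecord:
    query_fragment: Fragment
    partner_fragment: Fragment
    hd_overall: float
    hd_core: float
    hd_hbond: float | None
    join_correspondences: list        # (query join parent idx, partner join parent idx)
    source: tuple                     # (complex A, complex B, ligand A, ligand B)
    family_relation: str              # intra | inter | unknown

    def __post_init__(self):
        if self.family_relation not in ("intra", "inter", "unknown"):
            raise ValueError(f"bad family relation {self.family_relation!r}")


# ---------------------------------------------------------------------------
# surfaces and Hausdorff distances


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, near-uniform points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _subset_atoms(frag: Fragment, subset: str) -> list:
    if subset == "all":
        return frag.atoms
    if subset == "core":
        return frag.core_atoms
    if subset == "hbond":
        return [a for a in frag.atoms if a.is_donor or a.is_acceptor]
    raise ValueError(f"unknown subset {subset!r}")


def surface_points(frag: Fragment, subset: str = "all",
                   density: int = 64) -> SurfacePointSet:
    """Sample the union vdW surface of the chosen atom subset.

    Each atom sphere carries ``density`` lattice points; points strictly
    inside any other subset atom's sphere (beyond a small tolerance) are
    removed, leaving the solvent-facing union surface.
    """
    if density < 8:
        raise ValueError("density must be >= 8 points per atom")
    atoms = _subset_atoms(frag, subset)
    if not atoms:
        raise EmptySubsetError(f"fragment has no {subset!r} atoms")
    centers = np.array([a.position for a in atoms]).reshape(-1, 3)
    radii = np.array([a.vdw_radius for a in atoms])
    unit = fibonacci_sphere(density)
    kept = []
    for i in range(len(atoms)):
        pts = centers[i] + radii[i] * unit
        buried = np.zeros(len(pts), dtype=bool)
        for j in range(len(atoms)):
            if j == i:
                continue
            d = np.linalg.norm(pts - centers[j], axis=1)
            buried |= d < radii[j] - _BURIAL_TOL
        kept.append(pts[~buried])
    points = (np.concatenate(kept) if kept else np.empty((0, 3)))
    if len(points) == 0:
        # fully mutually buried subsets cannot occur with equal radii, but
        # guard the contract anyway
        raise EmptySubsetError(f"all {subset!r} surface points buried")
    return SurfacePointSet(points=points, subset=subset, density=density)


def one_sided_hd(A: np.ndarray, B: np.ndarray) -> float:
    """max over a in A of the distance to the nearest b in B."""
    A = np.asarray(A, dtype=float).reshape(-1, 3)
    B = np.asarray(B, dtype=float).reshape(-1, 3)
    if len(A) == 0 or len(B) == 0:
        raise UndefinedInputError("Hausdorff distance of an empty point set")
    d, _ = cKDTree(B).query(A, k=1)
    return float(np.max(d))


def hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric Hausdorff distance: max of the two one-sided values."""
    return max(one_sided_hd(A, B), one_sided_hd(B, A))


def fragment_hd(fa: Fragment, fb: Fragment, subset: str = "all",
                density: int = 64) -> float | None:
    """HD between two fragments' vdW surfaces; None when the subset is
    empty on either side (e.g. H-bonding HD of an apolar fragment)."""
    try:
        sa = surface_points(fa, subset, density)
        sb = surface_points(fb, subset, density)
    except EmptySubsetError:
        return None
    return hausdorff(sa.points, sb.points)


def match_join_atoms(q: Fragment, p: Fragment, tol: float = 1.5) -> list:
    """Greedy nearest-pair matching of join atoms in a common frame; each
    join atom is used at most once, pairs taken in ascending distance."""
    pairs = []
    for qa in q.join_atoms:
        for pa in p.join_atoms:
            d = float(np.linalg.norm(qa.position - pa.position))
            if d <= tol:
                pairs.append((d, qa.index, pa.index))
    pairs.sort()
    used_q, used_p, out = set(), set(), []
    for d, qi, pi in pairs:
        if qi in used_q or pi in used_p:
            continue
        used_q.add(qi)
        used_p.add(pi)
        out.append((qi, pi))
    return out


# ---------------------------------------------------------------------------
# mining


def family_relation(fam_a: str | None, fam_b: str | None) -> str:
    if fam_a is None or fam_b is None:
        return "unknown"
    return "intra" if fam_a == fam_b else "inter"


def load_scop_tsv(path) -> dict:
    """TSV of (pdb_id, chain, family) or (pdb_id, family) rows."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 3:
                out[(parts[0], parts[1])] = parts[2]
            elif len(parts) == 2:
                out[parts[0]] = parts[1]
    return out


def _family_of(scop: dict | None, complex_name: str, ligand) -> str | None:
    if not scop:
        return None
    chain = ligand.source[1] if ligand.source else None
    return scop.get((complex_name, chain)) or scop.get(complex_name)


def _mine_one_alignment(unit_a, unit_b, transform, *, hd_cutoff, density,
                        join_tol, scop) -> list:
    cx_a, lig_a = unit_a
    cx_b, lig_b = unit_b
    lig_b_t = transpose_ligand(lig_b, transform)
    frags_a = fragment_molecule(lig_a)
    frags_b = fragment_molecule(lig_b_t)
    fam_a = _family_of(scop, cx_a.name, lig_a)
    fam_b = _family_of(scop, cx_b.name, lig_b)
    relation = family_relation(fam_a, fam_b)
    records = []
    for fa, fb in itertools.product(frags_a, frags_b):
        hd_all = fragment_hd(fa, fb, "all", density)
        if hd_all is None or hd_all > hd_cutoff:
            continue
        hd_core = fragment_hd(fa, fb, "core", density)
        hd_hb = fragment_hd(fa, fb, "hbond", density)
        corr = match_join_atoms(fa, fb, join_tol)
        src = (cx_a.name, cx_b.name, lig_a.name, lig_b.name)
        records.append(PairRecord(fa, fb, hd_all, hd_core, hd_hb,
                                  corr, src, relation))
        records.append(PairRecord(
            fb, fa, hd_all, hd_core, hd_hb,
            [(p, q) for q, p in corr],
            (cx_b.name, cx_a.name, lig_b.name, lig_a.name), relation))
    return records


def mine_pairs(complexes, *, eps: float = 2.0, zthr: float | None = 2.0,
               hd_cutoff: float = 1.50, density: int = 64,
               site_cutoff: float = 5.0, min_score: int = 4,
               join_tol: float = 1.5, scop: dict | None = None,
               transforms: dict | None = None) -> list:
    """Mine bioisosteric fragment pairs across a batch of complexes.

    Every cross-complex binding-site pair is aligned; alignments passing
    the Z-score filter (``zthr`` standard deviations above the batch mean;
    ``None`` disables the filter, which is the only sensible setting for a
    batch with a single alignment) contribute fragment pairs with Overall
    HD <= ``hd_cutoff``.  ``transforms`` may supply externally computed
    rigid transforms keyed by (complex A name, complex B name); such
    alignments bypass both the surrogate aligner and the Z-filter.
    """
    if len(complexes) < 2:
        raise ValueError("mining needs at least 2 complexes")
    units = []
    for cx in complexes:
        for lig in cx.ligands:
            try:
                site = extract_binding_site(cx, lig, site_cutoff)
            except EmptySiteError:
                logger.info("ligand %s in %s has no pocket; skipped",
                            lig.name, cx.name)
                continue
            units.append((cx, lig, describe_site(site)))

    scored, external = [], []
    for (cx_a, lig_a, pts_a), (cx_b, lig_b, pts_b) in \
            itertools.combinations(units, 2):
        if cx_a is cx_b:
            continue
        key = (cx_a.name, cx_b.name)
        rkey = (cx_b.name, cx_a.name)
        if transforms and (key in transforms or rkey in transforms):
            t = transforms.get(key) or transforms[rkey].inverse()
            external.append(((cx_a, lig_a), (cx_b, lig_b), t))
            continue
        al = align_sites(pts_a, pts_b, eps=eps, min_score=min_score)
        if al is not None:
            scored.append(((cx_a, lig_a), (cx_b, lig_b), al))

    if zthr is not None and len(scored) >= 2:
        keep = set(zscore_filter([al.score for _, _, al in scored], zthr))
        scored = [x for i, x in enumerate(scored) if i in keep]
    elif zthr is not None and len(scored) == 1:
        logger.warning("single alignment in batch; Z-filter not applicable, "
                       "alignment kept")

    records = []
    for unit_a, unit_b, al in scored:
        records.extend(_mine_one_alignment(
            unit_a, unit_b, al.transform, hd_cutoff=hd_cutoff,
            density=density, join_tol=join_tol, scop=scop))
    for unit_a, unit_b, t in external:
        records.extend(_mine_one_alignment(
            unit_a, unit_b, t, hd_cutoff=hd_cutoff,
            density=density, join_tol=join_tol, scop=scop))
    return records


# ---------------------------------------------------------------------------
# persistence

_ATOM_FIELDS = ("index", "element", "sybyl_type", "vdw_radius", "is_donor",
                "is_acceptor", "heavy_degree", "aromatic", "in_ring",
                "explicit_h", "implicit_h", "name")


def _atom_to_json(a: Atom) -> dict:
    d = {f: getattr(a, f) for f in _ATOM_FIELDS}
    d["position"] = [float(x) for x in a.position]
    return d


def _atom_from_json(d: dict) -> Atom:
    return Atom(position=np.array(d["position"]),
                **{f: d[f] for f in _ATOM_FIELDS})


def fragment_to_json(frag: Fragment) -> dict:
    return {
        "core_atoms": [_atom_to_json(a) for a in frag.core_atoms],
        "join_atoms": [_atom_to_json(a) for a in frag.join_atoms],
        "bonds": [[b.i, b.j, b.order, b.in_ring] for b in frag.bonds],
        "parent_name": frag.parent_name,
        "parent_source": list(frag.parent_source) if frag.parent_source else None,
        "broken_bonds": [list(x) for x in frag.broken_bonds],
    }


def fragment_from_json(d: dict) -> Fragment:
    return Fragment(
        core_atoms=[_atom_from_json(x) for x in d["core_atoms"]],
        join_atoms=[_atom_from_json(x) for x in d["join_atoms"]],
        bonds=[Bond(i, j, order, ring) for i, j, order, ring in d["bonds"]],
        parent_name=d["parent_name"],
        parent_source=tuple(d["parent_source"]) if d["parent_source"] else None,
        broken_bonds=[tuple(x) for x in d["broken_bonds"]],
    )


_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE fragments (
    id INTEGER PRIMARY KEY,
    core_key TEXT NOT NULL,
    n_heavy INTEGER, n_donor INTEGER, n_acceptor INTEGER,
    n_ring_atoms INTEGER, n_core INTEGER, n_join INTEGER,
    frag_json TEXT NOT NULL
);
CREATE TABLE pairs (
    id INTEGER PRIMARY KEY,
    query_id INTEGER NOT NULL REFERENCES fragments(id),
    partner_id INTEGER NOT NULL REFERENCES fragments(id),
    hd_overall REAL NOT NULL,
    hd_core REAL,
    hd_hbond REAL,
    family_relation TEXT NOT NULL,
    join_json TEXT NOT NULL,
    source_a TEXT, source_b TEXT, ligand_a TEXT, ligand_b TEXT
);
CREATE INDEX idx_fragments_core ON fragments(core_key);
CREATE INDEX idx_fragments_counts ON fragments(n_heavy, n_ring_atoms, n_join);
CREATE INDEX idx_pairs_hd ON pairs(hd_overall);
"""


class PairDatabase:
    """Handle over the single-file SQLite pair database."""

    def __init__(self, conn: sqlite3.Connection):
        self.conn = conn

    # -- construction

    @classmethod
    def create(cls, path) -> "PairDatabase":
        conn = sqlite3.connect(str(path))
        conn.executescript(_SCHEMA)
        conn.execute("INSERT INTO meta VALUES ('schema_version', ?)",
                     (SCHEMA_VERSION,))
        conn.commit()
        return cls(conn)

    @classmethod
    def open(cls, path) -> "PairDatabase":
        conn = sqlite3.connect(str(path))
        try:
            row = conn.execute(
                "SELECT value FROM meta WHERE key='schema_version'").fetchone()
        except sqlite3.Error as exc:
            raise SchemaVersionError(f"{path}: not a pair database") from exc
        if row is None or row[0] != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"{path}: schema version {row[0] if row else 'missing'!r}, "
                f"expected {SCHEMA_VERSION!r}")
        return cls(conn)

    def _insert_fragment(self, frag: Fragment) -> int:
        d = describe_fragment(frag)
        cur = self.conn.execute(
            "INSERT INTO fragments (core_key, n_heavy, n_donor, n_acceptor, "
            "n_ring_atoms, n_core, n_join, frag_json) VALUES (?,?,?,?,?,?,?,?)",
            (core_key(frag), d.n_heavy, d.n_donor, d.n_acceptor,
             d.n_ring_atoms, d.n_core, d.n_join,
             json.dumps(fragment_to_json(frag))))
        return cur.lastrowid

    def add_records(self, records) -> None:
        for r in records:
            qid = self._insert_fragment(r.query_fragment)
            pid = self._insert_fragment(r.partner_fragment)
            self.conn.execute(
                "INSERT INTO pairs (query_id, partner_id, hd_overall, hd_core,"
                " hd_hbond, family_relation, join_json, source_a, source_b,"
                " ligand_a, ligand_b) VALUES (?,?,?,?,?,?,?,?,?,?,?)",
                (qid, pid, r.hd_overall, r.hd_core, r.hd_hbond,
                 r.family_relation, json.dumps(r.join_correspondences),
                 r.source[0], r.source[1], r.source[2], r.source[3]))
        self.conn.commit()

    # -- retrieval

    def _row_to_record(self, row) -> PairRecord:
        (qjson, pjson, hd_o, hd_c, hd_h, rel, jjson, sa, sb, la, lb) = row
        return PairRecord(
            query_fragment=fragment_from_json(json.loads(qjson)),
            partner_fragment=fragment_from_json(json.loads(pjson)),
            hd_overall=hd_o, hd_core=hd_c, hd_hbond=hd_h,
            join_correspondences=[tuple(x) for x in json.loads(jjson)],
            source=(sa, sb, la, lb), family_relation=rel)

    _RECORD_SQL = (
        "SELECT fq.frag_json, fp.frag_json, p.hd_overall, p.hd_core, "
        "p.hd_hbond, p.family_relation, p.join_json, p.source_a, p.source_b, "
        "p.ligand_a, p.ligand_b FROM pairs p "
        "JOIN fragments fq ON fq.id = p.query_id "
        "JOIN fragments fp ON fp.id = p.partner_id ")

    def records(self) -> list:
        rows = self.conn.execute(self._RECORD_SQL + "ORDER BY p.id").fetchall()
        return [self._row_to_record(r) for r in rows]

    def records_by_core_key(self, key: str) -> list:
        rows = self.conn.execute(
            self._RECORD_SQL + "WHERE fq.core_key = ? ORDER BY p.id",
            (key,)).fetchall()
        return [self._row_to_record(r) for r in rows]

    def query_fragments(self) -> list:
        """Distinct query-side fragments, with their core keys."""
        rows = self.conn.execute(
            "SELECT DISTINCT f.core_key, f.frag_json FROM fragments f "
            "JOIN pairs p ON p.query_id = f.id ORDER BY f.id").fetchall()
        return [(key, fragment_from_json(json.loads(js))) for key, js in rows]

    def close(self) -> None:
        self.conn.close()

    def export_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records():
                fh.write(json.dumps({
                    "query_fragment": fragment_to_json(r.query_fragment),
                    "partner_fragment": fragment_to_json(r.partner_fragment),
                    "hd_overall": r.hd_overall, "hd_core": r.hd_core,
                    "hd_hbond": r.hd_hbond,
                    "join_correspondences": [list(x) for x in
                                             r.join_correspondences],
                    "source": list(r.source),
                    "family_relation": r.family_relation,
                }) + "\n")


def save_db(records, path) -> PairDatabase:
    db = PairDatabase.create(path)
    db.add_records(records)
    return db


def load_db(path) -> PairDatabase:
    return PairDatabase.open(path)
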