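# Methods

## The mining model

`isoswap` operationalises a structure-based definition of bioisosterism:
two ligand fragments are replaceable when, in two independently solved
holo complexes whose binding sites share a similar spatial arrangement of
physico-chemical groups, the fragments occupy nearly the same region of
the superposed pockets. The pipeline is:

1. **Binding-site description.** A site is the set of residues with any
   heavy atom within `site_cutoff` (default 5.0 Å, closed interval) of a
   ligand heavy atom. Each recognised residue contributes one labelled
   point — aromatic ring centroid (Phe/Tyr/Trp/His), H-bond donor and/or
   acceptor terminus (Ser, Thr, Lys, Arg, Asp, Glu, Asn, Gln, Cys), or
   hydrophobic side-chain centroid (Leu, Ile, Val, Met, Ala, Pro, Gly).
   Unknown residues are skipped with a warning.
2. **Superposition.** Two sites are matched on the product graph of
   same-label point pairs, with an edge whenever the two within-site
   distances agree within `eps` (default 2.0 Å). A maximum clique —
   found exactly by Bron–Kerbosch enumeration, ties broken by the
   lexicographically smallest node set — is the alignment; its size is
   the score, and the Kabsch algorithm (SVD with determinant-sign
   correction, so mirror solutions are impossible) gives the rigid
   transform. Alignments scoring fewer than `min_score` (default 4)
   matched points return no result.
3. **Z-filter.** Scores are standardised within the batch of all
   attempted alignments (population SD) and alignments with Z ≥ 2 are
   kept. A batch with equal scores has undefined Z; it is defined as 0
   and nothing passes the default threshold. With a single alignment in
   the batch the filter is not applicable; callers pass `zthr=None` to
   disable it explicitly (the planted-pair analyses do this). The
   reference method standardises against an all-against-all background
   over the whole PDB; the batch background is the desk-scale analogue.
4. **Transposition and fragmentation.** The second ligand is carried into
   the first frame by the alignment transform. Both ligands are cut at
   every rotatable bond — single, acyclic, non-aromatic, both endpoints
   with ≥ 2 heavy neighbours (an optional flag exempts amide C–N bonds).
   Each connected component is a fragment; for every broken bond each
   side retains a copy of the atom across the cut (*join atom*) with its
   original coordinates and Sybyl type. Fragment count is therefore
   breaks + 1, cores partition the parent, and re-joining at the recorded
   bonds reconstructs the parent graph.
5. **Hausdorff scoring.** Each fragment's van der Waals surface is a
   deterministic Fibonacci-lattice sampling, `density` points per atom
   sphere (default 64), with points buried inside another subset atom's
   sphere culled (tolerance 1e-6 Å, so exactly coincident spheres retain
   their surface). HD(A,B) = max{oHD(A,B), oHD(B,A)}, with oHD the
   max-of-nearest-neighbour distance, computed with a k-d tree. Three
   variants are stored: Overall (all atoms), Core (join atoms excluded),
   H-bonding (donor ∪ acceptor atoms; absent when either side has none).
   Pairs with Overall HD ≤ `hd_cutoff` (default 1.50 Å) are recorded in
   both orientations, with greedily matched join-atom correspondences
   (ascending distance, each join used once, tolerance 1.5 Å) and the
   SCOP family relation (intra when both families are known and equal,
   inter when known and different, unknown otherwise).

## Querying

Three input modes: fragment a whole molecule and pick a piece; search the
database by core substructure (labelled subgraph monomorphism, VF2); or
filter by descriptor bounds (heavy atoms, donors, acceptors, ring atoms,
core/join counts — closed intervals). Replacement search then applies:

- *Interchangeable join types* (Rule 1): join atoms match when element
  and geometry class agree (sp3 = {X.3, S.o, S.o2}; trigonal-planar =
  {X.2, X.ar, N.pl3, N.am, C.cat}; linear = {X.1}), instead of exact
  Sybyl equality. The class table is a declared convention anchored on
  the N.2 ↔ N.pl3 exchange.
- *Common-core query* (Rules 3+4): join atoms are stripped from the
  query; any record whose query-side core is isomorphic matches; results
  are reduced to their core and the selected join atom is re-created on
  the bioisostere at the nearest core position (through a deterministic
  core isomorphism — smallest mapping under sorted-pair order). Only the
  Core HD is a meaningful sort key in this mode and it is forced.
- Presets mirror the loose/rigorous option table: loose = both families +
  common core (join types moot); rigorous = intra-family + exact join
  types + specific structure. Unspecified families count as inter-family.
- Rule 2 (join-to-core promotion) is deliberately not implemented; join
  atoms outside the selected reconnection pair are ignored.

Rows are sorted by the active HD (absent H-bonding HDs sort last), ties
broken by source complex ids then partner core key, and paginated at 10
rows by default; descending order is the exact reverse of ascending.

## Reconnection

The incoming fragment is placed by mapping its selected join atom onto
the molecule's attachment atom and rotating the join→anchor direction
onto the original attachment→core direction with the minimal rotation
(180° case: deterministic perpendicular axis). Placement geometry is a
declared convention — the replacement rule itself only constrains
bonding. The primary bond forms at the selected pair; every other severed
attachment is reconnected by taking candidate (incoming atom, molecule
atom) pairs in ascending distance and bonding the first pair where both
partners have free heavy valence. Valence counts bonds to heavy atoms
only (C 4, N 3, O 2, halogens 1, P 4; S by subtype: S.3/S.2 → 2, S.o →
3, S.o2 → 4); hydrogens never count. Formed bonds are single, since only
rotatable single bonds are ever broken. Failure to reconnect any severed
attachment, or a disconnected product, raises instead of returning a
partial molecule.

## Chemical perception

Heavy atoms only: explicit hydrogens in input files are folded into a
per-atom hydrogen count; all geometry (surfaces, HDs) is hydrogen-free,
since deposited ligands usually lack them. Bonds come from CONECT records
when present, else from the 1.25 × covalent-radius-sum heuristic. Bond
graphs without order information get a geometric aromaticity rule: 5/6
rings of C/N/O/S, planar within 0.1 Å RMS, carbons with ≤ 3 neighbours.
Sybyl typing is a compact rule table (aromatic, multiplicity of bonds,
amide/sulfonamide/aniline environments for N, oxo counts for S). Donors
are N/O with ≥ 1 explicit-or-inferred hydrogen; acceptors are any O, and
N with an available lone pair (sp3/sp2/sp, or 2-coordinate aromatic).
Van der Waals radii are Bondi (1964); unsupported elements are rejected
rather than defaulted, for reproducible surfaces.

## Synthetic fixtures

`fixtures` builds idealized ligand templates (flat 1.39 Å aromatic rings,
chair saturated rings, round-number bond lengths) and six-residue pockets
covering all five point labels in an irregular layout (directions kept
clear of +x, where elongated ligands extend). `make_complex_pair` plants
a benzene/benzene fragment pair displaced by `planted_overlap` and moves
the second complex by a seeded random rigid motion; the ground truth
(transform, expected pair, displacement) is emitted alongside. All
fixture output is a pure function of its seeds.

What passing fixture tests shows: the aligner recovers exact congruences,
the HD machinery is oracle-exact, planted overlaps at ≤ 0.5 Å are always
mined at the 1.50 Å cutoff and 6 Å displacements never are, and the query
and reconnection rules behave per contract. What it does not show:
robustness to conformational noise, partial pockets, backbone-mediated
contacts, crystallographic disorder, or realistic chemotype diversity —
real structures are messier on every axis.

## Problem sizes and numerics

The default test and acceptance runs use 50 two-complex minings at
surface density 32, 1,000 (test) / 300 (script) random point-set pairs of
up to 200 points against the exhaustive all-pairs oracle, 500/200 planted
Kabsch recoveries, and 60 exhaustive clique cross-checks on graphs of ≤
12 nodes — sizes chosen so the whole battery completes in seconds while
still exercising every code path. Degenerate inputs fail loudly:
collinear/coincident point sets in Kabsch, empty point sets in HD, empty
surface subsets, sd-zero score batches (logged, nothing kept).

One spec-level correction is recorded in the repository history: the
superposition residual that is monotone under removing a matched pair is
the optimal *sum* of squared residuals, not the RMSD (a mean can grow
when a well-fitting pair is dropped); the test asserts the sum version.

## Known limitations

- The site aligner is a desk-scale surrogate with the same contract as a
  full local-alignment engine (two sites in; transform, score, Z-filter
  out). It matches one coarse point per residue and is not meant to rank
  subtle pocket similarity; externally computed transforms can be
  imported (12 numbers per line) to bypass it entirely.
- The packaged inhibitor connection table is a synthetic reconstruction
  from the textual description of the worked example (three named rings
  joined through a sulfonamide); the deposited 2D depiction was not
  available, so atom-level details beyond the ring systems and linker are
  a modelling choice.
- Aromaticity and Sybyl typing are heuristic; exotic chemotypes
  (polyhalogenated heteroaromatics, charged species, organometallics)
  are out of scope, and unsupported elements raise.
- H-bonding HD uses donor ∪ acceptor atoms; the quantity is named but not
  defined in the source method, so this subset is a declared convention.
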