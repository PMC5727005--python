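# isoswap

Structure-based mining and querying of **bioisosteric fragment
replacements** — substructure swaps that preserve a ligand's interactions
with its target. Medicinal chemists use such replacements during lead
optimization to fix permeability, toxicity, selectivity or patent
problems without losing binding; *scaffold hopping* is the same idea
applied to a molecule's core.

Instead of collecting replacements from the literature, `isoswap` derives
them from structures: when two holo protein–ligand complexes have binding
sites with a similar three-dimensional arrangement of physico-chemical
groups, their co-crystallized ligands can be superposed through the
site alignment, and ligand fragments that then occupy the same region of
space are candidate replacements. Spatial overlap between fragments A and
B is scored by the Hausdorff distance between their van der Waals
surfaces:

    HD(A, B) = max{ oHD(A, B), oHD(B, A) }

where `oHD(A, B)` is the largest distance from a point of surface A to
its nearest point on surface B. Small HD ⇒ near-coincident occupancy.
Pairs with Overall HD ≤ 1.50 Å (the default cutoff) are stored in a
queryable SQLite database together with Core and H-bonding HD variants,
join-atom correspondences and the SCOP family relation of the two
proteins.

The pipeline (each stage is an importable module):

| stage | module | what it does |
|---|---|---|
| read/perceive | `isoswap.chemio` | PDB/MOL/SMILES I/O, Sybyl types, Bondi radii, donor/acceptor flags, binding-site extraction |
| align | `isoswap.sitealign` | labelled site points, product-graph maximum clique, Kabsch transform, Z-score filter |
| fragment | `isoswap.fragmenter` | rotatable-bond cutting into core + join atoms, core-graph identity, descriptors |
| mine | `isoswap.pairminer` | surface sampling, three HDs, join matching, pair database |
| query | `isoswap.queryengine` | three query modes, loose/rigorous presets, join-type interchange, common-core expansion, sorting/pagination |
| reconnect | `isoswap.reconnector` | valence-aware fragment replacement and SMILES/MOL export |
| fixtures | `isoswap.fixtures` | seeded synthetic complexes with planted ground truth |

## Worked example

Fragmenting a sulfonamide-type inhibitor of the bacterial ligase MurF
(three rings — morpholine, dichlorobenzene, benzothiophene — joined
through a sulfonamide):

```text
$ isoswap fragment --mol src/isoswap/data/murf_inhibitor.mol
5 fragment(s)
  [0] core=O=S=O heavy=5 core_atoms=3 join_atoms=2 ring_atoms=1 donors=1 acceptors=2
  [1] core=N heavy=3 core_atoms=1 join_atoms=2 ring_atoms=1 donors=1 acceptors=0
  [2] core=Clc1ccccc1Cl heavy=10 core_atoms=8 join_atoms=2 ring_atoms=7 donors=1 acceptors=0
  [3] core=C1COCCN1 heavy=7 core_atoms=6 join_atoms=1 ring_atoms=7 donors=0 acceptors=1
  [4] core=c1ccc2sccc2c1 heavy=10 core_atoms=9 join_atoms=1 ring_atoms=9 donors=0 acceptors=0
```

Five fragments: the three rings plus the two halves of the sulfonamide
linker. `core=` is the canonical SMILES of the fragment minus its join
atoms; counts include the join atoms (`heavy = core_atoms +
join_atoms`), which is why e.g. the morpholine fragment shows 7 ring
atoms — its join atom is an aromatic ring carbon of the neighbouring
fragment.

Mining and querying a synthetic complex pair with a planted
benzene/benzene overlap:

```text
$ isoswap fixtures --out demo --seed 7
$ isoswap mine demo/pairs.db --no-zfilter --scop demo/families.tsv \
      demo/FIXA0007.pdb demo/FIXB0007.pdb
2 pair record(s) written to demo/pairs.db
$ isoswap query --db demo/pairs.db --smiles "c1ccc(-c2ccccc2)cc1" --preset loose
page 1/1  (2 row(s))
  c1ccccc1     overall=0.001 core=0.001 hbond=- family=intra from=FIXA0007+FIXB0007
  c1ccccc1     overall=0.001 core=0.001 hbond=- family=intra from=FIXB0007+FIXA0007
```

The planted benzene is recovered with Overall HD ≈ 0 (the 0.001 Å is
PDB coordinate rounding), labelled intra-family per the emitted
`families.tsv`, with no H-bonding HD because benzene has no donors or
acceptors. `--no-zfilter` disables the alignment Z-score filter, which
needs a batch of alignments to normalise against; with many input
complexes the default Z ≥ 2 criterion applies. A chosen replacement can
then be wired back into the query molecule with `isoswap replace`, which
forms the selected bond and reconnects any remaining severed attachments
to the closest atoms that still have free heavy valence.

## Pair database schema

Single SQLite file, `schema_version` 1 in the `meta` table:

- `fragments(id, core_key, n_heavy, n_donor, n_acceptor, n_ring_atoms,
  n_core, n_join, frag_json)` — one row per stored fragment side;
  `core_key` is the canonical core SMILES, `frag_json` the full
  atom/bond record including join atoms and 3D coordinates.
- `pairs(id, query_id, partner_id, hd_overall, hd_core, hd_hbond,
  family_relation, join_json, source_a, source_b, ligand_a, ligand_b)` —
  one row per mined orientation; `hd_hbond` is NULL when either fragment
  lacks H-bonding atoms.

Indexes cover `core_key`, the descriptor counts and `hd_overall`.
`PairDatabase.export_jsonl` writes the same records as JSON lines.

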