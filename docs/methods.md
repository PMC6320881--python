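# Methods

## Data model

A glycan is a rooted directed tree. The root is the reducing-end residue;
every edge carries a glycosidic linkage payload (donor position on the
child, a non-empty set of acceptor positions on the parent). Nodes are
monosaccharides, substituents, or repeat units. Substituents are always
leaves; repeat units are host-tree leaves that contain a complete internal
glycan plus the linkage that chains consecutive copies.

Node ids are monotonically increasing integers that are never reused after
deletion, so external references (tests, CLI reports, SVG `data-node`
attributes) stay stable across edits. Editing operations (`add_*`,
`remove_subtree`, `update_node`, `copy_subtree`/`paste_subtree`) enforce
the tree invariants eagerly: one parent per node, positions within the
carbon range, no two children on the same fully stated acceptor position.
`copy_subtree` returns a free-standing deep copy; `paste_subtree` re-inserts
it with fresh ids, which makes copy–paste of whole antennae (the common way
to build symmetric di-antennary structures) cheap and safe.

### Fuzziness

Real-world glycan data is often underdetermined, so fuzziness is explicit
rather than an error state:

* a single `UNKNOWN` sentinel for positions and repeat counts, distinct
  from the *alternatives* encoding (an acceptor set of size > 1, e.g. {3,4});
  the two never mix within one linkage, which keeps `is_fully_defined()`
  a simple decidable predicate;
* `undetermined` members of the anomericity, ring-form and absolute-
  configuration vocabularies.

`is_fully_defined()` is the gate for chemical export: it walks the whole
tree (including repeat interiors) and is invariant under serialization
round-trips.

### Controlled vocabularies

Monosaccharide and substituent types are loaded from versioned TSV tables
shipped with the package. Each monosaccharide row carries: superclass and
carbon count, GlycoCT stem (with configuration prefixes, e.g. `lgro-dman`),
SNFG shape + colour (the (shape, colour) pair is unique across the table),
anomeric carbon (1 for aldoses, 2 for ketoses/ulosonates), chain
modifications in GlycoCT notation (`6:d`, `1:a|2:keto|3:d`, …), amine
positions, and a Fischer-projection configuration string. Formula templates
are derived at load time from the superclass composition CnH2nOn adjusted
per modification (deoxy −O; acid +O−H2; amine +NH−O), e.g. Kdn
C9H16O9 and Neu C9H17NO8.

Amine-carrying residues (GlcN, GalN, ManN, Neu) are first-class types: the
spec-level decomposition "GlcNAc = GlcN + n-acetyl@2" is the stored form,
and the renderer fuses such patterns into single SNFG symbols. The palette
count of 12 and its membership (Glc, Gal, Man, GlcNAc, GalNAc, GlcA, IdoA,
Fuc, Xyl, Neu5Ac, Neu5Gc, Kdn) reflect the canonical mammalian set; the
vocabulary itself is larger (heptoses, Kdo, pentoses, L-sugars) so
bacterial structures like heptose-containing cores are expressible.

## GlycoCT condensed I/O

Only the condensed dialect is implemented (RES, LIN, REP). UND sections
are rejected with an explicit unsupported-feature error: this model
expresses fuzziness inline (`x` anomer/ring markers, `-1` positions,
`3|4` alternatives), so underdetermined-subtree blocks have no natural
image and silently guessing would corrupt round-trips.

Link-type letters follow the condensed grammar as seen in real database
exports: glycosidic bonds are `<acceptor>o(<acc>+<don>)<donor>d`;
hydroxyl-replacing substituents (n-acetyl, n-glycolyl, amino) use `d`/`n`;
hydrogen-of-hydroxyl-replacing substituents (sulfate, phosphate, methyl,
acetyl, pyruvate) use `h`/`n`. On write, an amine type decomposes into its
basetype plus an `amino` substituent entry — unless an N-acyl child already
sits on the amine position, in which case that child subsumes the amine
(exactly how GlcNAc appears in the wild: `b-dglc-HEX-1:5` + `n-acetyl` via
`d(2+1)n`). The parser re-fuses both patterns deterministically, so
write∘parse is the identity on canonical text.

Canonical output order: residues are numbered depth-first from the root;
siblings sort by smallest stated acceptor position (UNKNOWN last), then by
an id-free recursive subtree signature. This gives deterministic,
permutation-invariant output without implementing the full published
GlycoCT canonicalization. Lines are LF; CRLF input is accepted.

Repeats: `REP<n>:<acceptor-idx>o(<acc>+<don>)<root-idx>d=<min>-<max>` with
−1 for unknown bounds. The model stores which internal residue accepts the
next copy (`acceptor_node_id`, defaulting to the canonical last leaf),
because the internal linkage alone underdetermines multi-residue units.

## Layout

The grid layout assigns every monosaccharide/repeat node an integer cell;
substituents are fused into their parent's symbol. The root sits at (0,0)
and children are always one column to the left (columns encode distance
from the reducing end, the standard SNFG orientation with the reducing end
rightmost). The preferred row offset comes from the acceptor position —
6→+1, 3→−1, 2/4/others/UNKNOWN→0 — so linkage geometry is readable from
bond angles; for alternative acceptor sets the smallest stated position
drives geometry and the renderer prints the full "3/4" label. The exact
angle table is this package's choice, anchored to the common convention of
drawing the 6-arm above and the 3-arm below.

Since several branches can prefer one cell, an occupied set is consulted
and collisions resolve to the nearest free row in the same column, probing
+1, −1, +2, −2, … — deterministic and compact. Children are processed in
the same id-free canonical order as the writer, so relabelling node ids
cannot change the occupied-cell multiset.

## Rendering

SVG 1.1 assembled with the standard library XML tree; output is
byte-deterministic for identical inputs. Symbols use the 10-colour SNFG
palette (hex table shipped as data); divided shapes (crossed square,
divided diamond/triangle) are drawn as a white base, a coloured half and
an outline. Anomericity is encoded in edge strokes: β solid, α dashed
(pattern "6,4"), undetermined dotted ("2,3") — dashed and dotted are
visually distinct at the default 60 px cell size, and the open form (rare
on an edge) renders solid. Linkage labels ("1→4", "2→3/6", "?" for
UNKNOWN) sit at edge midpoints and can be disabled. Repeat units are drawn
as the unit root's symbol between brackets with a "min–max" annotation.
The y axis is flipped (SVG y grows downward) so row +1 — the 6-arm —
appears above its parent.

## Validity rules

Five advisory rules (`validate()` returns violations as data): R1 duplicate
stated-acceptor occupancy, R2 position beyond the carbon count, R3 donor
position differing from the donor type's anomeric carbon, R4 open-chain
residue with α/β anomericity, R5 substituent on the ring-closure carbon or
a glycosidically used carbon. Quick mode additionally blocks: conflicts
raise instead of reporting, which suits its non-expert audience; normal
mode stays advisory so experts can hold intermediate states.

## Chemical export

Export is restricted to fully defined structures; fuzzy input raises
`UnderdeterminedStructureError`. A repeat with min ≠ max passes
`is_fully_defined()` (its counts are stated) but still raises on export,
because a 2–5 repeat denotes a family of molecules, not one; with
min == max the chain is expanded explicitly.

Residue expansion is generic over the vocabulary: carbons C1..Cn, a
hydroxyl (or amine, carboxyl, deoxy-hydrogen) per position, and a
hemiacetal ring closure whose oxygen is the ring-end hydroxyl oxygen.
Tetrahedral parity comes from the Fischer projection: each stereocentre is
modelled with chain neighbours vertical (pointing away from the viewer)
and the heteroatom horizontal on the stated side; the signed volume of the
neighbour slots gives the parity, and a single calibrated constant maps
parity to SMILES `@`/`@@`. L-configured residues mirror every centre.
The anomeric side follows the classical rule: α places the exocyclic
anomeric oxygen on the same Fischer side as the hydroxyl of the
configurational (highest-numbered chiral) carbon, β opposite. Open-chain
residues get a plain carbonyl and no anomeric stereo. The construction
reproduces the standard InChIKeys of α/β-D-glucopyranose, β-D-
galactopyranose, aldehydo-D-glucose and the Neu5Ac skeleton, which the
test suite asserts via RDKit.

Glycosidic condensation removes the donor's anomeric hydroxyl and bonds
the donor anomeric carbon to the acceptor's position oxygen — the
glycosidic oxygen is acceptor-derived (the formula is invariant under the
opposite convention; one is fixed for determinism). Substituents either
convert the position oxygen to nitrogen and acylate it (amino, N-acyl) or
esterify/etherify the oxygen (sulfate, phosphate, methyl, acetyl,
pyruvate). Pyruvate is modelled as a single-position pyruvyl ester rather
than the two-position ketal bridge — a deliberate simplification; bridging
acetals are out of scope. Charged groups are emitted protonated (neutral)
for determinism; pH handling is out of scope.

The molecular formula is computed twice by independent routes — arithmetic
(Σ residue templates + Σ substituent deltas − edges × H2O, with the delta
adjusted when an N-acyl lands on an amine position) and atomistic (counting
atoms of the expansion) — and the SMILES writer (DFS from the reducing-end
anomeric carbon, ring-closure digits reused after release, permutation-
parity stereo emission) is checked against RDKit parsing in tests. The
package never calls RDKit itself.

## Random-glycan generator

`generate_random_glycan(seed, n_nodes, fuzz_prob)` is first-class test
infrastructure: it draws residues from the palette plus Rha/Ara/LDmanHep/
Kdo, attaches them only at chemically free positions (never the anomeric,
ring-closure, deoxy, acid or amine carbons), always sets the donor to the
anomeric carbon, and occasionally adds O-substituents (12%), repeat units
(8%) or furanose rings (10%, only where the closure carbon bears a
hydroxyl). With `fuzz_prob = 0` every output validates cleanly and is
fully defined (hence chemically exportable); `fuzz_prob` is the
per-attribute probability of injecting undetermined anomers/rings/
configurations, UNKNOWN or alternative positions and unknown repeat counts,
and at 1.0 the output is never fully defined. Generated repeats always
have min == max or unknown bounds, so full definedness coincides with
exportability on generated corpora. The generator emulates structural
diversity (branching, fuzziness, rare residues), not the statistics of any
natural glycome — passing corpus tests demonstrates implementation
soundness, not biological coverage.

Default corpus conditions used by the test suite and the acceptance
script: 500 glycans, 1–40 nodes, fuzz ∈ {0, 0.3}, fully seeded. These run
in a few seconds; sizes were chosen as the package's own standard corpus,
large enough to exercise every residue type, ring form, substituent and
repeat path.

## Known limitations

* GlycoCT UND/ALT sections and other encodings (WURCS, LINUCS, IUPAC
  condensed) are not supported.
* InChI/InChIKey generation is delegated to external tools operating on
  the emitted SMILES.
* An N-acyl substituent placed at a fusable amine position of a *plain*
  hexose (e.g. n-acetyl@2 on Glc rather than GlcN) re-parses as the
  aminated type; the two states are chemically identical but not
  structurally distinguished after a round-trip.
* SMILES output is valid and stereo-complete but not canonical;
  canonicalization is left to consumers.
* Cyclic (non-tree) glycans and undo/redo are out of scope.
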