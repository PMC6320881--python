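# glycoforge

Glycans — the branched carbohydrates decorating proteins and lipids — are
awkward to describe: chemists need atom-level formats (SMILES), databases
need sequence encodings (GlycoCT), and people need pictures (SNFG symbols).
`glycoforge` is a headless Python library plus CLI that keeps one tree-shaped
structure at the centre and converts faithfully between all three views.
It is aimed at glycoinformatics developers who need a scriptable structure
builder, and at glycobiologists who want correct SNFG depictions and
machine-readable exports without drawing by hand.

## What it does

* **Tree data model.** A glycan is a rooted tree: the reducing-end residue is
  the root, each edge is a glycosidic linkage *donor→acceptor* (e.g. β1→4),
  and nodes are monosaccharides, substituents (NAc, sulfate, phosphate, …)
  or repeat units. All node fields come from controlled vocabularies (SNFG
  shape/colour, superclass, anomeric carbon, GlycoCT chain modifications);
  arbitrary tokens are rejected. Fuzziness is first-class: undetermined
  anomericity/ring/configuration, UNKNOWN positions and alternative acceptor
  sets ({3,4}) are representable and tracked by `is_fully_defined()`.
* **GlycoCT condensed I/O.** A parser/writer for RES/LIN/REP sections with a
  canonical, deterministic output order: `parse(write(G)) ≅ G` and
  `write(parse(write(G))) == write(G)` byte-for-byte.
* **Layout + SVG.** A grid layout places the root at (0,0) and grows leftward;
  the acceptor position sets the bond angle (6→up, 4→level, 3→down) and an
  occupied-cell grid with a deterministic probe removes overlays. The SVG
  renderer draws SNFG symbols (fusing GlcN + NAc into the GlcNAc blue square,
  etc.) and encodes anomericity in the stroke: **β solid, α dashed,
  undetermined dotted**.
* **Quick and normal building modes.** Quick mode needs exactly two chemistry
  parameters per residue (anomericity + acceptor position) from a 12-residue
  mammalian palette; the donor carbon is inferred (aldoses → C1,
  ketoses/ulosonates → C2). Normal mode exposes the full six-parameter API.
  Chemical-validity rules (R1–R5: duplicate occupancy, range, wrong donor
  carbon, open-chain anomer, substituent/ring clashes) are blocking in quick
  mode and advisory (`validate()`) otherwise. N-/O-glycan core templates and
  common epitopes ship as GlycoCT files.
* **Chemical export.** Fully defined structures expand to an atom graph:
  residues are instantiated from Fischer-projection stereo tables, each
  glycosidic bond condenses out one water, and the result is emitted as
  SMILES with tetrahedral stereo plus a Hill-order molecular formula.
  Export of fuzzy structures raises a dedicated error by design.

## Worked example

Lactose, built in quick mode from a glucose reducing end:

```python
import glycoforge as gf

g = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
gf.quick_add(g, g.root_id, "Gal", gf.Anomer.BETA, 4)   # donor C1 inferred

print(gf.write_glycoct(g))
print(gf.molecular_formula(g))
```

prints

```
RES
1b:b-dglc-HEX-1:5
2b:b-dgal-HEX-1:5
LIN
1:1o(4+1)2d

C12H22O11
```

The GlycoCT says: residue 1 is β-D-glucopyranose (ring 1:5), residue 2
β-D-galactopyranose, and linkage 1 joins position 4 of residue 1 (through
its oxygen, `o`) to carbon 1 of residue 2 (which loses its anomeric
hydroxyl, `d`) — i.e. Gal-(β1→4)-Glc. The formula C12H22O11 is two hexoses
minus one water of condensation. `gf.to_smiles(g)` yields a stereo-complete
SMILES for the same molecule, and `gf.render_svg(g)` draws a yellow circle
(Gal) connected level-and-solid (β1→4) to a blue circle (Glc).

The same conversions are available from the shell:

```bash
glycoforge convert --from template --name N-core --to formula -
# C34H58N2O26
glycoforge random --seed 7 --size 12 | glycoforge convert --to svg - -o out.svg
```

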