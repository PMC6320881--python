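"""Grid layout: assign every visible node an integer cell.

The reducing end sits at (0, 0) and the structure grows leftward (column =
-distance from the root), matching the standard SNFG orientation.  The
preferred row of a child encodes its acceptor position on the parent —
6 branches rise one row, 3 branches drop one row, everything else stays
level — so linkage geometry is readable from bond angles.  Because several
branches can prefer the same cell, a grid of occupied cells is kept and a
deterministic probe (+1, -1, +2, -2, ... rows in the same column) resolves
collisions, so two nodes never overlay.

Substituents do not receive cells: they are fused into (or decorated onto)
their parent's symbol by the renderer.  A repeat unit occupies a single
cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import StructureError
from .model import Glycan, node_signature
from .vocab import UNKNOWN

#: Preferred row offset by acceptor position (applied before collision
#: resolution); positions without an entry, and UNKNOWN, stay level.
ANGLE_MAP = {2: 0, 3: -1, 4: 0, 6: +1}


@dataclass
class GridLayout:
    cells: dict = field(default_factory=dict)     # node_id -> (col, row)
    occupied: set = field(default_factory=set)

    def place(self, node_id, cell):
        if cell in self.occupied:
            raise StructureError(f"cell {cell} already occupied")
        self.cells[node_id] = cell
        self.occupied.add(cell)


def resolve_collision(occupied, desired):
    """Nearest free cell in the desired column, probing rows +1, -1, +2, -2…"""
    if desired not in occupied:
        return desired
    col, row = desired
    for step in range(1, 2 * len(occupied) + 2):
        for offset in (step, -step):
            cell = (col, row + offset)
            if cell not in occupied:
                return cell
    raise AssertionError("unreachable: grid is unbounded")


def _preferred_offset(link):
    stated = sorted(p for p in link.acceptor_positions if p is not UNKNOWN)
    if not stated:
        return 0
    return ANGLE_MAP.get(stated[0], 0)


def layout_glycan(g: Glycan) -> GridLayout:
    """Deterministic, injective node -> cell assignment for a non-empty glycan."""
    if g.root_id is None:
        raise StructureError("cannot lay out an empty glycan")
    layout = GridLayout()
    layout.place(g.root_id, (0, 0))

    def visit(nid):
        col, row = layout.cells[nid]
        kids = g.monosaccharide_children(nid)
        # id-free deterministic order: by acceptor position then structure
        kids.sort(key=lambda c: (g.linkage_of(c).sort_key(),
                                 node_signature(g, c)))
        for child in kids:
            desired = (col - 1, row + _preferred_offset(g.linkage_of(child)))
            layout.place(child, resolve_collision(layout.occupied, desired))
            visit(child)

    visit(g.root_id)
    return layout
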