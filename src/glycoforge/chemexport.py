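"""Expansion of fully defined glycans to atoms: SMILES and molecular formula.

Each residue is instantiated from its superclass / chain-modification /
Fischer-configuration data: carbons C1..Cn, hydroxyls (or amines, carboxyls,
deoxy hydrogens) per position, and a hemiacetal ring closure between the
anomeric carbon and the ring-end hydroxyl oxygen.  Tetrahedral parities are
derived from the Fischer projection: every stereocentre is modelled with its
chain neighbours vertical (previous carbon up, next down) and its
heteroatom on the side the projection states; the anomeric side follows the
rule that alpha places the exocyclic anomeric oxygen on the same side as
the hydroxyl of the configurational (highest-numbered chiral) carbon, beta
on the opposite side.  L-residues mirror every centre.

A glycosidic bond is formed by condensation: the donor's anomeric hydroxyl
is dropped and its anomeric carbon binds the acceptor's position oxygen
(the glycosidic oxygen is acceptor-derived; one water per edge).
Substituents either replace the whole hydroxyl (amino, N-acyl: the oxygen
becomes nitrogen) or only its hydrogen (O-esters and ethers).

Everything here is gated on :func:`Glycan.is_fully_defined`; additionally a
repeat unit must have ``min_count == max_count`` to denote a single molecule.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

from .errors import StructureError, UnderdeterminedStructureError
from .model import Glycan, Monosaccharide, RepeatUnit, Substituent
from .vocab import UNKNOWN, WATER, Anomer, Config, hill_formula

_VALENCE = {"C": 4, "N": 3, "O": 2, "P": 5}

# deep linear chains (large expanded repeats) exceed the default limit
sys.setrecursionlimit(max(sys.getrecursionlimit(), 20000))

# slot coordinates of a Fischer-projection centre (vertical bonds away from
# the viewer, horizontal bonds toward it); the reference parity of a centre
# is the sign of the signed volume of its neighbours in stored order.
_UP, _DOWN = (0.0, 1.0, -1.0), (0.0, -1.0, -1.0)
_RIGHT, _LEFT = (1.0, 0.0, 1.0), (-1.0, 0.0, 1.0)


def _volume_sign(v1, v2, v3, v4):
    a = [v2[i] - v1[i] for i in range(3)]
    b = [v3[i] - v1[i] for i in range(3)]
    c = [v4[i] - v1[i] for i in range(3)]
    det = (a[0] * (b[1] * c[2] - b[2] * c[1])
           - a[1] * (b[0] * c[2] - b[2] * c[0])
           + a[2] * (b[0] * c[1] - b[1] * c[0]))
    return 1 if det > 0 else -1

#: parity of ref order (up, down, side-X, other) with X on the right
_PARITY_RIGHT = _volume_sign(_UP, _DOWN, _RIGHT, _LEFT)

#: sign that maps to the '@' chirality token (calibrated against
#: D-glyceraldehyde / beta-D-glucopyranose literature SMILES)
_AT_SIGN = -1

_H = "H"  # implicit-hydrogen token inside stereo reference lists


class _Atom:
    __slots__ = ("idx", "element", "bonds", "hcount", "stereo", "node_id")

    def __init__(self, idx, element, node_id):
        self.idx = idx
        self.element = element
        self.bonds = []           # [(other atom idx, order), ...]
        self.hcount = 0
        self.stereo = None        # (ref list of 4 tokens, parity +1/-1)
        self.node_id = node_id


class _Mol:
    def __init__(self):
        self.atoms = []

    def add_atom(self, element, node_id=None) -> int:
        atom = _Atom(len(self.atoms), element, node_id)
        self.atoms.append(atom)
        return atom.idx

    def add_bond(self, i, j, order=1):
        self.atoms[i].bonds.append((j, order))
        self.atoms[j].bonds.append((i, order))

    def finalize_hydrogens(self):
        for atom in self.atoms:
            total = sum(order for _, order in atom.bonds)
            if atom.element == "S":
                target = 6 if total > 2 else 2
            else:
                target = _VALENCE[atom.element]
            atom.hcount = max(target - total, 0)
            if atom.stereo is not None and _H in atom.stereo[0]:
                assert atom.hcount == 1, "stereocentre lost its hydrogen"


def _set_parity(mol, idx, up, down, x, other, side):
    """Record tetrahedral parity for a Fischer centre (side = 'R' or 'L')."""
    parity = _PARITY_RIGHT if side == "R" else -_PARITY_RIGHT
    mol.atoms[idx].stereo = ([up, down, x, other], parity)


def _flip(side):
    return "L" if side == "R" else "R"


@dataclass
class MolecularGraph:
    """Atoms/bonds expansion of a glycan, hydrogens materialized."""

    atoms: list                    # (element, charge, stereo token or None)
    bonds: list                    # (atom_i, atom_j, order)
    provenance: dict               # heavy-atom index -> originating node id

    @property
    def formula(self) -> dict:
        counts = {}
        for element, _, _ in self.atoms:
            counts[element] = counts.get(element, 0) + 1
        return counts


class _ResidueAtoms:
    __slots__ = ("carbons", "attachment", "anomeric_carbon")

    def __init__(self):
        self.carbons = {}          # position -> atom idx
        self.attachment = {}       # position -> heteroatom idx (O or N)
        self.anomeric_carbon = None


def _require_defined(g: Glycan):
    if g.root_id is None:
        raise UnderdeterminedStructureError("empty glycan has no structure")
    if not g.is_fully_defined():
        raise UnderdeterminedStructureError(
            "structure has undetermined linkages or residues; chemical "
            "export requires a fully defined glycan")


def _expand_repeats(g: Glycan) -> Glycan:
    """Replace every repeat unit by an explicit chain of its copies."""

    def copy_into(dst, dst_parent, src, src_id, payload):
        node = src.nodes[src_id]
        if isinstance(node, RepeatUnit):
            if (node.min_count is UNKNOWN or node.max_count is UNKNOWN
                    or node.min_count != node.max_count):
                raise UnderdeterminedStructureError(
                    f"repeat unit with count range "
                    f"{node.min_count}-{node.max_count} does not denote a "
                    "single molecule")
            inner = _expand_repeats(node.internal_glycan)
            attach_parent, attach_payload = dst_parent, payload
            for _ in range(node.min_count):
                id_map = {}
                for sid in inner.walk():
                    snode = inner.nodes[sid]
                    if sid == inner.root_id:
                        if attach_parent is None:
                            id_map[sid] = dst.set_root(snode)
                        else:
                            id_map[sid] = dst.add_monosaccharide(
                                attach_parent, snode, attach_payload)
                    else:
                        pid, spayload = inner._parent[sid]
                        if isinstance(snode, Substituent):
                            id_map[sid] = dst.add_substituent(
                                id_map[pid], snode, spayload)
                        else:
                            id_map[sid] = dst.add_monosaccharide(
                                id_map[pid], snode, spayload)
                attach_parent = id_map[node.acceptor_node_id]
                attach_payload = node.internal_linkage
            return
        if isinstance(node, Substituent):
            new_id = dst.add_substituent(dst_parent, node, payload)
        elif dst_parent is None:
            new_id = dst.set_root(node)
        else:
            new_id = dst.add_monosaccharide(dst_parent, node, payload)
        for cid in src.children_of(src_id):
            copy_into(dst, new_id, src, cid, src._parent[cid][1])

    out = Glycan()
    copy_into(out, None, g, g.root_id, None)
    return out


def _build_residue(mol: _Mol, node: Monosaccharide, glyco_oxygen=None):
    """Instantiate one residue; ``glyco_oxygen`` is the acceptor oxygen this
    residue's anomeric carbon condenses onto (None at the reducing end)."""
    mt = node.mtype
    n = mt.carbon_count
    a = mt.anomeric_carbon
    res = _ResidueAtoms()
    fischer = dict(mt.fischer)
    if node.absolute_config is Config.L:
        fischer = {p: _flip(s) for p, s in fischer.items()}
    ring = node.ring
    closure = mt.ring_closure(ring)
    deoxy, acid = mt.deoxy_positions, mt.acid_positions
    amines = mt.amine_positions

    for i in range(1, n + 1):
        res.carbons[i] = mol.add_atom("C", node.node_id)
    for i in range(1, n):
        mol.add_bond(res.carbons[i], res.carbons[i + 1])
    res.anomeric_carbon = res.carbons[a]

    ring_oxygen = None
    for i in range(1, n + 1):
        c = res.carbons[i]
        if i == a:
            continue  # handled last, once the ring oxygen exists
        if i in acid:
            o_dbl = mol.add_atom("O", node.node_id)
            o_oh = mol.add_atom("O", node.node_id)
            mol.add_bond(c, o_dbl, 2)
            mol.add_bond(c, o_oh, 1)
            res.attachment[i] = o_oh
            continue
        if i in deoxy:
            continue
        element = "N" if i in amines else "O"
        het = mol.add_atom(element, node.node_id)
        mol.add_bond(c, het)
        res.attachment[i] = het
        if i == closure:
            ring_oxygen = het
            del res.attachment[i]
        if i in fischer:
            _set_parity(mol, c, res.carbons[i - 1], res.carbons[i + 1],
                        het, _H, fischer[i])

    c_anomeric = res.carbons[a]
    if closure is None:
        # open chain: plain carbonyl at the anomeric carbon
        o_dbl = mol.add_atom("O", node.node_id)
        mol.add_bond(c_anomeric, o_dbl, 2)
    else:
        mol.add_bond(c_anomeric, ring_oxygen)
        if glyco_oxygen is None:
            o_exo = mol.add_atom("O", node.node_id)
            mol.add_bond(c_anomeric, o_exo)
            res.attachment[a] = o_exo
        else:
            o_exo = glyco_oxygen
            mol.add_bond(c_anomeric, o_exo)
        ref_pos = max(fischer)
        side = fischer[ref_pos]
        if node.anomericity is Anomer.BETA:
            side = _flip(side)
        if a == 1:
            _set_parity(mol, c_anomeric, ring_oxygen, res.carbons[2],
                        o_exo, _H, side)
        else:
            _set_parity(mol, c_anomeric, res.carbons[a - 1],
                        res.carbons[a + 1], o_exo, ring_oxygen, side)
    return res


_SUB_GROUPS = {
    # name -> (converts O to N, [atoms spec]) where atoms are appended onto
    # the attachment heteroatom; spec entries: (element, bond order to prev
    # index into the growing list, parent offset)
    "amino": (True, ()),
    "n-acetyl": (True, (("C", 0, 1), ("O", 1, 2), ("C", 1, 1))),
    "n-glycolyl": (True, (("C", 0, 1), ("O", 1, 2), ("C", 1, 1), ("O", 3, 1))),
    "acetyl": (False, (("C", 0, 1), ("O", 1, 2), ("C", 1, 1))),
    "methyl": (False, (("C", 0, 1),)),
    "sulfate": (False, (("S", 0, 1), ("O", 1, 2), ("O", 1, 2), ("O", 1, 1))),
    "phosphate": (False, (("P", 0, 1), ("O", 1, 2), ("O", 1, 1), ("O", 1, 1))),
    "pyruvate": (False, (("C", 0, 1), ("O", 1, 2), ("C", 1, 1), ("O", 3, 2),
                         ("C", 3, 1))),
}


def _apply_substituent(mol, res, stype, position, node_id):
    het = res.attachment.get(position)
    if het is None:
        raise StructureError(
            f"position {position} has no free hydroxyl/amine for {stype.name}")
    to_n, spec = _SUB_GROUPS[stype.name]
    if to_n and mol.atoms[het].element == "O":
        mol.atoms[het].element = "N"
    chain = [het]
    for element, anchor, order in spec:
        idx = mol.add_atom(element, node_id)
        mol.add_bond(chain[anchor], idx, order)
        chain.append(idx)
    del res.attachment[position]


def to_molecular_graph(g: Glycan) -> MolecularGraph:
    """Full atomistic expansion (hydrogens explicit) of a fully defined glycan."""
    mol, _ = _expand_to_mol(g)
    atoms, bonds, provenance = [], [], {}
    for atom in mol.atoms:
        stereo = None
        if atom.stereo is not None:
            stereo = "@" if atom.stereo[1] == _AT_SIGN else "@@"
        atoms.append((atom.element, 0, stereo))
        provenance[atom.idx] = atom.node_id
        for j, order in atom.bonds:
            if j > atom.idx:
                bonds.append((atom.idx, j, order))
    for atom in mol.atoms:
        for _ in range(atom.hcount):
            h = len(atoms)
            atoms.append(("H", 0, None))
            bonds.append((atom.idx, h, 1))
            provenance[h] = atom.node_id
    return MolecularGraph(atoms=atoms, bonds=bonds, provenance=provenance)


def _expand_to_mol(g: Glycan):
    _require_defined(g)
    flat = _expand_repeats(g)
    mol = _Mol()
    residues = {}

    def visit(nid, parent_res):
        node = flat.nodes[nid]
        if isinstance(node, Substituent):
            pos = flat.linkage_of(nid)
            _apply_substituent(mol, parent_res,
                               node.stype, pos, nid)
            return
        link = flat.linkage_of(nid)
        glyco_oxygen = None
        if link is not None:
            (pos,) = link.acceptor_positions
            glyco_oxygen = parent_res.attachment.get(pos)
            if glyco_oxygen is None:
                raise StructureError(
                    f"acceptor position {pos} has no free hydroxyl")
            del parent_res.attachment[pos]
        res = _build_residue(mol, node, glyco_oxygen)
        residues[nid] = res
        # substituents first so amines/esters are settled before children bind
        for cid in flat.substituent_children(nid):
            visit(cid, res)
        for cid in flat.monosaccharide_children(nid):
            visit(cid, res)

    visit(flat.root_id, None)
    mol.finalize_hydrogens()
    start = residues[flat.root_id].anomeric_carbon
    return mol, start


def to_smiles(g: Glycan) -> str:
    """Deterministic SMILES (DFS from the reducing-end anomeric carbon)."""
    mol, start = _expand_to_mol(g)
    return _write_smiles(mol, start)


def molecular_formula(g: Glycan) -> str:
    """Hill-order formula from residue templates + substituent deltas - water.

    Computed arithmetically, without the atomistic expansion, so the two
    routes cross-check each other.
    """
    _require_defined(g)
    flat = _expand_repeats(g)
    counts = {}
    n_edges = 0
    for nid in flat.walk():
        node = flat.nodes[nid]
        if isinstance(node, Monosaccharide):
            for el, k in node.mtype.formula_template.items():
                counts[el] = counts.get(el, 0) + k
            if flat.linkage_of(nid) is not None:
                n_edges += 1
        else:
            pos = flat.linkage_of(nid)
            parent = flat.nodes[flat.parent_of(nid)]
            aminated = (pos in parent.mtype.amine_positions
                        and node.stype.name in ("n-acetyl", "n-glycolyl"))
            for el, k in node.stype.delta_on(aminated).items():
                counts[el] = counts.get(el, 0) + k
    for el, k in WATER.items():
        counts[el] = counts.get(el, 0) - k * n_edges
    return hill_formula({el: k for el, k in counts.items() if k})


# ---------------------------------------------------------------------------
# SMILES writer

def _permutation_sign(ref, actual):
    perm = [ref.index(x) for x in actual]
    sign = 1
    seen = [False] * len(perm)
    for i in range(len(perm)):
        if seen[i]:
            continue
        j, length = i, 0
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            length += 1
        if length % 2 == 0:
            sign = -sign
    return sign


def _write_smiles(mol: _Mol, start: int) -> str:
    atoms = mol.atoms
    parent = {start: None}
    children = {a.idx: [] for a in atoms}
    order = []                    # emission (pre-)order
    ring_neighbors = {a.idx: [] for a in atoms}
    visited = set()

    def dfs(idx):
        visited.add(idx)
        order.append(idx)
        for j, _ in atoms[idx].bonds:
            if j == parent[idx]:
                continue
            if j in visited:
                if idx not in ring_neighbors[j]:
                    ring_neighbors[idx].append(j)
                    ring_neighbors[j].append(idx)
                continue
            parent[j] = idx
            children[idx].append(j)
            dfs(j)

    dfs(start)

    # allocate ring-closure digits in emission order, reusing freed digits
    token_digits = {a.idx: [] for a in atoms}   # atom -> [(digit, partner)]
    open_digits = {}
    free = list(range(99, 0, -1))
    for idx in order:
        for j in ring_neighbors[idx]:
            key = frozenset((idx, j))
            if key in open_digits:
                d = open_digits.pop(key)
                token_digits[idx].append((d, j))
                free.append(d)
                free.sort(reverse=True)
            else:
                d = free.pop()
                open_digits[key] = d
                token_digits[idx].append((d, j))

    bond_order = {}
    for atom in atoms:
        for j, o in atom.bonds:
            bond_order[frozenset((atom.idx, j))] = o

    out = []

    def bond_token(i, j):
        return "=" if bond_order[frozenset((i, j))] == 2 else ""

    def atom_token(idx):
        atom = atoms[idx]
        if atom.stereo is None:
            return atom.element
        ref, parity = atom.stereo
        actual = []
        if parent[idx] is not None:
            actual.append(parent[idx])
        if _H in ref:
            actual.append(_H)
        actual.extend(partner for _, partner in token_digits[idx])
        actual.extend(children[idx])
        sign = parity * _permutation_sign(ref, actual)
        mark = "@" if sign == _AT_SIGN else "@@"
        h = "H" if atom.hcount == 1 else ""
        return f"[{atom.element}{mark}{h}]"

    def emit(idx):
        out.append(atom_token(idx))
        for d, partner in token_digits[idx]:
            out.append(bond_token(idx, partner) + (str(d) if d < 10 else f"%{d}"))
        kids = children[idx]
        for k, j in enumerate(kids):
            if k < len(kids) - 1:
                out.append("(" + bond_token(idx, j))
                emit(j)
                out.append(")")
            else:
                out.append(bond_token(idx, j))
                emit(j)

    emit(start)
    return "".join(out)
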