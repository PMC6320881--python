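"""Glycan tree data structure and structural editing operations.

A glycan is a rooted directed tree.  Nodes are monosaccharides, substituents
or repeat units; edges carry a :class:`GlycosidicLinkage` payload (donor and
acceptor carbon positions, either of which may be fuzzy).  The root is the
reducing-end residue.  Node ids are monotonically increasing integers that
are never reused after deletion, so references stay stable across edits.

Fuzziness lives in both nodes (undetermined anomericity / ring form /
absolute configuration) and edges (UNKNOWN positions, alternative acceptor
position sets); :func:`Glycan.is_fully_defined` decides whether a structure
is exportable to chemical formats.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterator, Optional, Union

from .errors import AttachmentConflict, StructureError
from .vocab import (
    UNKNOWN, Anomer, Config, MonosaccharideType, RingForm, SubstituentType,
    monosaccharide_type, substituent_type,
)

Position = Union[int, type(UNKNOWN)]


def _check_position(pos, carbon_count, what):
    if pos is UNKNOWN:
        return
    if not isinstance(pos, int) or not 1 <= pos <= 9:
        raise StructureError(f"{what} position {pos!r} out of range 1..9")
    if pos > carbon_count:
        raise StructureError(
            f"{what} position {pos} exceeds carbon count {carbon_count}")


@dataclass(frozen=True)
class GlycosidicLinkage:
    """Edge payload: donor carbon on the child, acceptor carbon(s) on the parent.

    ``acceptor_positions`` with more than one member encodes alternative
    attachment points (e.g. 3 or 4); UNKNOWN never mixes with stated
    alternatives in the same set.
    """

    donor_position: Position
    acceptor_positions: frozenset

    def __post_init__(self):
        aps = frozenset(self.acceptor_positions)
        object.__setattr__(self, "acceptor_positions", aps)
        if not aps:
            raise StructureError("acceptor position set must be non-empty")
        if UNKNOWN in aps and len(aps) > 1:
            raise StructureError(
                "UNKNOWN cannot co-occur with stated alternative positions")

    @property
    def is_fully_defined(self) -> bool:
        return (self.donor_position is not UNKNOWN
                and len(self.acceptor_positions) == 1
                and UNKNOWN not in self.acceptor_positions)

    @property
    def stated_acceptor(self) -> Optional[int]:
        """The single fully stated acceptor position, if there is one."""
        if len(self.acceptor_positions) == 1:
            (p,) = self.acceptor_positions
            if p is not UNKNOWN:
                return p
        return None

    def sort_key(self):
        stated = sorted(p for p in self.acceptor_positions if p is not UNKNOWN)
        return (0, tuple(stated)) if stated else (1, ())


def linkage(donor, acceptors) -> GlycosidicLinkage:
    """Convenience constructor; ``acceptors`` may be a single position."""
    if isinstance(acceptors, (int, type(UNKNOWN))):
        acceptors = (acceptors,)
    return GlycosidicLinkage(donor, frozenset(acceptors))


@dataclass
class Monosaccharide:
    node_id: Optional[int]
    mtype: MonosaccharideType
    anomericity: Anomer
    ring: RingForm
    absolute_config: Config

    def __post_init__(self):
        if not isinstance(self.mtype, MonosaccharideType):
            self.mtype = monosaccharide_type(self.mtype)
        self.anomericity = Anomer(self.anomericity)
        self.ring = RingForm(self.ring)
        self.absolute_config = Config(self.absolute_config)
        if self.ring is RingForm.OPEN and self.anomericity is not Anomer.OPEN:
            raise StructureError(
                "open-chain residue must have open anomericity")


@dataclass
class Substituent:
    node_id: Optional[int]
    stype: SubstituentType

    def __post_init__(self):
        if not isinstance(self.stype, SubstituentType):
            self.stype = substituent_type(self.stype)


@dataclass
class RepeatUnit:
    """A repeated subtree, inserted into the host glycan as a single node.

    ``internal_linkage`` joins copy *i* (at ``acceptor_node_id``, by default
    the canonical last leaf of the unit) to copy *i+1*'s root.  Counts are
    strictly positive; UNKNOWN on either bound marks an undetermined repeat.
    """

    node_id: Optional[int]
    internal_glycan: "Glycan"
    min_count: Position
    max_count: Position
    internal_linkage: GlycosidicLinkage
    acceptor_node_id: Optional[int] = None

    def __post_init__(self):
        if self.internal_glycan.root_id is None:
            raise StructureError("repeat unit must contain a non-empty glycan")
        for bound, name in ((self.min_count, "min"), (self.max_count, "max")):
            if bound is not UNKNOWN and (not isinstance(bound, int) or bound < 1):
                raise StructureError(f"repeat {name}_count must be positive")
        if (self.min_count is not UNKNOWN and self.max_count is not UNKNOWN
                and self.min_count > self.max_count):
            raise StructureError("repeat min_count exceeds max_count")
        if self.acceptor_node_id is None:
            self.acceptor_node_id = self.internal_glycan.last_leaf()
        elif self.acceptor_node_id not in self.internal_glycan.nodes:
            raise StructureError("acceptor_node_id not in internal glycan")


Node = Union[Monosaccharide, Substituent, RepeatUnit]


def monosaccharide(name, anomericity=Anomer.UNDETERMINED,
                   ring=RingForm.PYRANOSE, absolute_config=None) -> Monosaccharide:
    """Build a free (unattached) residue from vocabulary tokens."""
    mtype = monosaccharide_type(name) if isinstance(name, str) else name
    if absolute_config is None:
        absolute_config = mtype.default_absolute_config
    return Monosaccharide(None, mtype, anomericity, ring, absolute_config)


def substituent(name) -> Substituent:
    return Substituent(None, name if isinstance(name, SubstituentType)
                       else substituent_type(name))


class Glycan:
    """Rooted tree of residue / substituent / repeat nodes."""

    def __init__(self):
        self.nodes: dict = {}
        self._parent: dict = {}          # child_id -> (parent_id, linkage-ish)
        self._children: dict = {}        # parent_id -> [child_id, ...]
        self.root_id: Optional[int] = None
        self._ids = itertools.count(1)

    # -- introspection -------------------------------------------------

    def __len__(self):
        return len(self.nodes)

    @property
    def edges(self):
        """Iterate (parent_id, child_id, payload) over all edges."""
        return [(p, c, l) for c, (p, l) in self._parent.items()]

    def node(self, node_id) -> Node:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise StructureError(f"no node with id {node_id}") from None

    def parent_of(self, node_id):
        entry = self._parent.get(node_id)
        return entry[0] if entry else None

    def linkage_of(self, node_id):
        """Edge payload between node and its parent (linkage or position)."""
        entry = self._parent.get(node_id)
        return entry[1] if entry else None

    def children_of(self, node_id):
        return list(self._children.get(node_id, ()))

    def monosaccharide_children(self, node_id):
        return [c for c in self.children_of(node_id)
                if isinstance(self.nodes[c], (Monosaccharide, RepeatUnit))]

    def substituent_children(self, node_id):
        return [c for c in self.children_of(node_id)
                if isinstance(self.nodes[c], Substituent)]

    def walk(self, start=None) -> Iterator[int]:
        """Pre-order DFS over node ids (children in insertion order)."""
        if start is None:
            start = self.root_id
        if start is None:
            return
        stack = [start]
        while stack:
            nid = stack.pop()
            yield nid
            stack.extend(reversed(self.children_of(nid)))

    def subtree_ids(self, node_id):
        return list(self.walk(node_id))

    def last_leaf(self, start=None):
        """Deepest last node in pre-order; used as default repeat exit point."""
        last = None
        for nid in self.walk(start):
            last = nid
        return last

    # -- occupancy -----------------------------------------------------

    def occupied_acceptors(self, parent_id):
        """Fully stated acceptor positions taken by glycosidic children."""
        taken = set()
        for c in self.monosaccharide_children(parent_id):
            pos = self._parent[c][1].stated_acceptor
            if pos is not None:
                taken.add(pos)
        return taken

    def substituent_positions(self, parent_id):
        taken = set()
        for c in self.substituent_children(parent_id):
            pos = self._parent[c][1]
            if pos is not UNKNOWN:
                taken.add(pos)
        return taken

    # -- editing -------------------------------------------------------

    def _fresh_id(self):
        return next(self._ids)

    def _insert(self, node: Node) -> int:
        nid = self._fresh_id()
        node = replace(node, node_id=nid)
        self.nodes[nid] = node
        self._children.setdefault(nid, [])
        return nid

    def add_monosaccharide(self, parent_id, residue: Monosaccharide,
                           link: GlycosidicLinkage) -> int:
        parent = self.node(parent_id)
        if not isinstance(parent, Monosaccharide):
            raise StructureError(
                "only a monosaccharide can accept a glycosidic child")
        for pos in link.acceptor_positions:
            _check_position(pos, parent.mtype.carbon_count, "acceptor")
        _check_position(link.donor_position, residue.mtype.carbon_count, "donor")
        stated = link.stated_acceptor
        if stated is not None and stated in self.occupied_acceptors(parent_id):
            raise AttachmentConflict(
                f"acceptor position {stated} of node {parent_id} is occupied")
        nid = self._insert(residue)
        self._parent[nid] = (parent_id, link)
        self._children[parent_id].append(nid)
        return nid

    def add_substituent(self, parent_id, sub: Substituent, position) -> int:
        parent = self.node(parent_id)
        if not isinstance(parent, Monosaccharide):
            raise StructureError("substituents attach to monosaccharides only")
        _check_position(position, parent.mtype.carbon_count, "substituent")
        if position is not UNKNOWN and position in self.substituent_positions(parent_id):
            raise AttachmentConflict(
                f"substituent position {position} of node {parent_id} is occupied")
        nid = self._insert(sub)
        self._parent[nid] = (parent_id, position)
        self._children[parent_id].append(nid)
        return nid

    def add_repeat_unit(self, parent_id, unit: RepeatUnit,
                        link: GlycosidicLinkage) -> int:
        parent = self.node(parent_id)
        if not isinstance(parent, Monosaccharide):
            raise StructureError("repeat units attach to monosaccharides")
        for pos in link.acceptor_positions:
            _check_position(pos, parent.mtype.carbon_count, "acceptor")
        stated = link.stated_acceptor
        if stated is not None and stated in self.occupied_acceptors(parent_id):
            raise AttachmentConflict(
                f"acceptor position {stated} of node {parent_id} is occupied")
        nid = self._insert(unit)
        self._parent[nid] = (parent_id, link)
        self._children[parent_id].append(nid)
        return nid

    def set_root(self, node: Node) -> int:
        if self.root_id is not None:
            raise StructureError("glycan already has a root")
        if isinstance(node, Substituent):
            raise StructureError("root must be a monosaccharide or repeat unit")
        nid = self._insert(node)
        self.root_id = nid
        return nid

    def remove_subtree(self, node_id) -> "Glycan":
        self.node(node_id)
        doomed = self.subtree_ids(node_id)
        parent = self.parent_of(node_id)
        for nid in doomed:
            del self.nodes[nid]
            self._children.pop(nid, None)
            self._parent.pop(nid, None)
        if parent is not None:
            self._children[parent].remove(node_id)
        if node_id == self.root_id:
            self.root_id = None
        return self

    def update_node(self, node_id, **new_fields) -> "Glycan":
        node = self.node(node_id)
        updated = replace(node, **new_fields)
        if isinstance(updated, Monosaccharide):
            limit = updated.mtype.carbon_count
            for c in self.children_of(node_id):
                payload = self._parent[c][1]
                positions = (payload.acceptor_positions
                             if isinstance(payload, GlycosidicLinkage)
                             else (payload,))
                for pos in positions:
                    if pos is not UNKNOWN and pos > limit:
                        raise StructureError(
                            f"existing linkage at position {pos} exceeds new "
                            f"carbon count {limit}")
            own = self.linkage_of(node_id)
            if isinstance(own, GlycosidicLinkage):
                dp = own.donor_position
                if dp is not UNKNOWN and dp > limit:
                    raise StructureError(
                        f"donor position {dp} exceeds new carbon count {limit}")
        self.nodes[node_id] = updated
        return self

    # -- copy / paste --------------------------------------------------

    def copy_subtree(self, node_id) -> "Glycan":
        """Deep copy of the subtree as a free-standing fragment."""
        self.node(node_id)
        fragment = Glycan()
        mapping = {}
        for nid in self.subtree_ids(node_id):
            node = self.nodes[nid]
            if isinstance(node, RepeatUnit):
                node = replace(node, internal_glycan=node.internal_glycan.copy())
            if nid == node_id:
                if isinstance(node, Substituent):
                    raise StructureError("cannot copy a bare substituent subtree")
                mapping[nid] = fragment.set_root(node)
                continue
            pid, payload = self._parent[nid]
            new_parent = mapping[pid]
            if isinstance(node, Substituent):
                mapping[nid] = fragment.add_substituent(new_parent, node, payload)
            elif isinstance(node, RepeatUnit):
                mapping[nid] = fragment.add_repeat_unit(new_parent, node, payload)
            else:
                mapping[nid] = fragment.add_monosaccharide(new_parent, node, payload)
        return fragment

    def paste_subtree(self, parent_id, fragment: "Glycan",
                      link: GlycosidicLinkage) -> list:
        """Attach a deep copy of ``fragment`` under ``parent_id``.

        Returns the fresh ids in fragment pre-order; the fragment is untouched.
        """
        if fragment.root_id is None:
            raise StructureError("cannot paste an empty fragment")
        mapping = {}
        new_ids = []
        for nid in fragment.subtree_ids(fragment.root_id):
            node = fragment.nodes[nid]
            if isinstance(node, RepeatUnit):
                node = replace(node, internal_glycan=node.internal_glycan.copy())
            if nid == fragment.root_id:
                if isinstance(node, RepeatUnit):
                    new = self.add_repeat_unit(parent_id, node, link)
                else:
                    new = self.add_monosaccharide(parent_id, node, link)
            else:
                pid, payload = fragment._parent[nid]
                target = mapping[pid]
                if isinstance(node, Substituent):
                    new = self.add_substituent(target, node, payload)
                elif isinstance(node, RepeatUnit):
                    new = self.add_repeat_unit(target, node, payload)
                else:
                    new = self.add_monosaccharide(target, node, payload)
            mapping[nid] = new
            new_ids.append(new)
        return new_ids

    def copy(self) -> "Glycan":
        if self.root_id is None:
            return Glycan()
        return self.copy_subtree(self.root_id)

    # -- fuzziness -----------------------------------------------------

    def is_fully_defined(self) -> bool:
        """True iff nothing anywhere is undetermined (vacuously true if empty)."""
        for nid in self.walk():
            node = self.nodes[nid]
            if isinstance(node, Monosaccharide):
                if (node.anomericity is Anomer.UNDETERMINED
                        or node.ring is RingForm.UNDETERMINED
                        or node.absolute_config is Config.UNDETERMINED):
                    return False
            elif isinstance(node, RepeatUnit):
                if node.min_count is UNKNOWN or node.max_count is UNKNOWN:
                    return False
                if not node.internal_linkage.is_fully_defined:
                    return False
                if not node.internal_glycan.is_fully_defined():
                    return False
            payload = self.linkage_of(nid)
            if payload is None:
                continue
            if isinstance(payload, GlycosidicLinkage):
                if not payload.is_fully_defined:
                    return False
            elif payload is UNKNOWN:
                return False
        return True


def create_glycan(root_residue) -> Glycan:
    """New single-node glycan; the residue becomes the reducing end."""
    if isinstance(root_residue, str):
        root_residue = monosaccharide(root_residue)
    g = Glycan()
    g.set_root(root_residue)
    return g


# -- structural signatures / isomorphism -------------------------------

def _payload_key(payload):
    if isinstance(payload, GlycosidicLinkage):
        donor = -1 if payload.donor_position is UNKNOWN else payload.donor_position
        acc = tuple(sorted(-1 if p is UNKNOWN else p
                           for p in payload.acceptor_positions))
        return ("L", donor, acc)
    return ("S", -1 if payload is UNKNOWN else payload)


def node_signature(g: Glycan, node_id) -> tuple:
    """Canonical, id-free signature of a subtree (used for sorting and tests)."""
    node = g.nodes[node_id]
    if isinstance(node, Monosaccharide):
        head = ("m", node.mtype.name, node.anomericity.value, node.ring.value,
                node.absolute_config.value)
    elif isinstance(node, Substituent):
        head = ("s", node.stype.name)
    else:
        head = ("r", -1 if node.min_count is UNKNOWN else node.min_count,
                -1 if node.max_count is UNKNOWN else node.max_count,
                _payload_key(node.internal_linkage),
                node_signature(node.internal_glycan, node.internal_glycan.root_id))
    kids = sorted((_payload_key(g.linkage_of(c)), node_signature(g, c))
                  for c in g.children_of(node_id))
    return (head, tuple(kids))


def isomorphic(a: Glycan, b: Glycan) -> bool:
    """Field-by-field equality up to node-id renaming (and sibling order)."""
    if (a.root_id is None) != (b.root_id is None):
        return False
    if a.root_id is None:
        return True
    return node_signature(a, a.root_id) == node_signature(b, b.root_id)
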