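"""Quick-mode and normal-mode construction APIs.

Quick mode mirrors the two-parameter workflow: the user picks one of the 12
palette residues (the monosaccharides most common in mammalian glycans) and
supplies only the linkage anomericity and the acceptor position; the donor
position is inferred from the residue class (aldoses donate C1, ketoses and
ulosonates C2) and stereochemistry defaults to the dominant mammalian form
(D, pyranose; L for fucose and iduronic acid).  Quick mode is blocking:
chemically forbidden input raises.  Normal mode is the full model API
(:meth:`Glycan.add_monosaccharide` and friends, six chemistry parameters
per residue) with :func:`validate` available as an advisory check.

A template catalog (N-/O-glycan cores and common epitopes, stored as
GlycoCT files and parsed on load) and a seeded random-glycan generator for
test corpora round out the module.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources

from .errors import AttachmentConflict, CatalogError, VocabularyError
from .glycoct import parse_glycoct
from .model import (
    Glycan, GlycosidicLinkage, Monosaccharide, RepeatUnit, create_glycan,
    linkage, monosaccharide, substituent,
)
from .vocab import (
    UNKNOWN, Anomer, Config, MonosaccharideType, RingForm, monosaccharide_type,
)


@dataclass(frozen=True)
class PaletteEntry:
    display_name: str
    base: str                       # vocabulary monosaccharide type name
    substituents: tuple             # ((substituent name, position), ...)
    ring: RingForm = RingForm.PYRANOSE
    absolute_config: Config = None  # None -> the base type's default

    def expand(self, anomericity=Anomer.UNDETERMINED) -> Glycan:
        """One-residue glycan (plus implied substituents) for this entry."""
        g = create_glycan(self.residue(anomericity))
        for name, pos in self.substituents:
            g.add_substituent(g.root_id, substituent(name), pos)
        return g

    def residue(self, anomericity) -> Monosaccharide:
        return monosaccharide(self.base, anomericity, self.ring,
                              self.absolute_config)


_PALETTE = (
    PaletteEntry("Glc", "Glc", ()),
    PaletteEntry("Gal", "Gal", ()),
    PaletteEntry("Man", "Man", ()),
    PaletteEntry("GlcNAc", "GlcN", (("n-acetyl", 2),)),
    PaletteEntry("GalNAc", "GalN", (("n-acetyl", 2),)),
    PaletteEntry("GlcA", "GlcA", ()),
    PaletteEntry("IdoA", "IdoA", ()),
    PaletteEntry("Fuc", "Fuc", ()),
    PaletteEntry("Xyl", "Xyl", ()),
    PaletteEntry("Neu5Ac", "Neu", (("n-acetyl", 5),)),
    PaletteEntry("Neu5Gc", "Neu", (("n-glycolyl", 5),)),
    PaletteEntry("Kdn", "Kdn", ()),
)


def quick_palette() -> list:
    """The 12-entry quick-mode residue palette, in fixed display order."""
    return list(_PALETTE)


def palette_entry(name: str) -> PaletteEntry:
    for entry in _PALETTE:
        if entry.display_name == name:
            return entry
    raise VocabularyError(f"{name!r} is not in the quick-mode palette")


def infer_donor_position(residue) -> int:
    """Donor carbon from residue class: aldoses 1, ketoses/ulosonates 2."""
    if isinstance(residue, PaletteEntry):
        mtype = monosaccharide_type(residue.base)
    elif isinstance(residue, Monosaccharide):
        mtype = residue.mtype
    elif isinstance(residue, MonosaccharideType):
        mtype = residue
    else:
        mtype = monosaccharide_type(residue)
    return mtype.anomeric_carbon


def quick_add(g: Glycan, parent_id, entry, anomericity, acceptor_position) -> int:
    """Attach a palette residue with only (anomericity, acceptor) given.

    Donor position, absolute configuration, ring form and implied
    substituents all come from the palette entry.  Quick mode is blocking:
    conflicts and forbidden positions raise instead of producing a
    violation report.
    """
    if isinstance(entry, str):
        entry = palette_entry(entry)
    anomericity = Anomer(anomericity)
    if acceptor_position is not UNKNOWN:
        parent = g.node(parent_id)
        if acceptor_position in g.substituent_positions(parent_id):
            raise AttachmentConflict(
                f"position {acceptor_position} of node {parent_id} carries a "
                "substituent")
        closure = parent.mtype.ring_closure(parent.ring)
        if acceptor_position in (parent.mtype.anomeric_carbon, closure):
            raise AttachmentConflict(
                f"position {acceptor_position} of node {parent_id} is part of "
                "the ring")
    residue = entry.residue(anomericity)
    link = linkage(infer_donor_position(entry), acceptor_position)
    nid = g.add_monosaccharide(parent_id, residue, link)
    for name, pos in entry.substituents:
        g.add_substituent(nid, substituent(name), pos)
    return nid


# ---------------------------------------------------------------------------
# chemical-validity rules

RULES = {
    "R1": "two residues attached at the same stated acceptor position",
    "R2": "linkage or substituent position exceeds the residue's carbon count",
    "R3": "donor position differs from the anomeric carbon of the donor type",
    "R4": "open-chain residue carries alpha/beta anomericity",
    "R5": "substituent on the ring-closure or a glycosidically used carbon",
}


@dataclass(frozen=True)
class Violation:
    rule_id: str
    message: str
    node_ids: tuple

    def __post_init__(self):
        assert self.rule_id in RULES


def validate(g: Glycan) -> list:
    """Advisory chemical-validity check; empty list means no rule fires."""
    out = []

    def check(glycan):
        for nid in glycan.walk():
            node = glycan.nodes[nid]
            if isinstance(node, RepeatUnit):
                _check_edge(glycan, None, nid,
                            node.internal_linkage, out, internal=node)
                check(node.internal_glycan)
                continue
            if not isinstance(node, Monosaccharide):
                continue
            mt = node.mtype
            if (node.ring is RingForm.OPEN
                    and node.anomericity in (Anomer.ALPHA, Anomer.BETA)):
                out.append(Violation("R4", f"open-chain {mt.name} with "
                                     f"{node.anomericity.value} anomer", (nid,)))
            seen = {}
            for cid in glycan.monosaccharide_children(nid):
                link = glycan.linkage_of(cid)
                _check_edge(glycan, nid, cid, link, out)
                pos = link.stated_acceptor
                if pos is not None:
                    if pos in seen:
                        out.append(Violation(
                            "R1", f"position {pos} of {mt.name} node {nid} "
                            "used twice", (nid, seen[pos], cid)))
                    seen[pos] = cid
            closure = mt.ring_closure(node.ring)
            glyco_used = set(seen)
            own = glycan.linkage_of(nid)
            for cid in glycan.substituent_children(nid):
                pos = glycan.linkage_of(cid)
                if pos is UNKNOWN:
                    continue
                if pos > mt.carbon_count:
                    out.append(Violation(
                        "R2", f"substituent position {pos} exceeds "
                        f"{mt.name}'s {mt.carbon_count} carbons", (nid, cid)))
                elif pos == closure or pos in glyco_used:
                    out.append(Violation(
                        "R5", f"substituent at position {pos} of node {nid} "
                        "clashes with the ring or a glycosidic bond",
                        (nid, cid)))

    def _check_edge(glycan, pid, cid, link, out, internal=None):
        child = glycan.nodes[cid]
        donor_type = (internal.internal_glycan.nodes[
            internal.internal_glycan.root_id].mtype if internal is not None
            else child.mtype if isinstance(child, Monosaccharide) else None)
        dp = link.donor_position
        if donor_type is not None and dp is not UNKNOWN:
            if dp > donor_type.carbon_count:
                out.append(Violation(
                    "R2", f"donor position {dp} exceeds {donor_type.name}'s "
                    f"{donor_type.carbon_count} carbons", (cid,)))
            elif dp != donor_type.anomeric_carbon:
                out.append(Violation(
                    "R3", f"donor position {dp} is not the anomeric carbon "
                    f"({donor_type.anomeric_carbon}) of {donor_type.name}",
                    (cid,)))
        if pid is not None:
            parent_count = glycan.nodes[pid].mtype.carbon_count
            for pos in link.acceptor_positions:
                if pos is not UNKNOWN and pos > parent_count:
                    out.append(Violation(
                        "R2", f"acceptor position {pos} exceeds parent's "
                        f"{parent_count} carbons", (pid, cid)))

    check(g)
    return out


# ---------------------------------------------------------------------------
# template catalog

_TEMPLATES = {
    "N-core": "n_core.glycoct",
    "N-core-fucosylated": "n_core_fucosylated.glycoct",
    "O-core-1": "o_core_1.glycoct",
    "O-core-2": "o_core_2.glycoct",
    "O-core-3": "o_core_3.glycoct",
    "O-core-4": "o_core_4.glycoct",
    "O-core-5": "o_core_5.glycoct",
    "O-core-6": "o_core_6.glycoct",
    "O-core-7": "o_core_7.glycoct",
    "O-core-8": "o_core_8.glycoct",
    "LacNAc": "lacnac.glycoct",
    "Lewis-a": "lewis_a.glycoct",
    "Lewis-x": "lewis_x.glycoct",
    "sialyl-Lewis-x": "sialyl_lewis_x.glycoct",
    "blood-A": "blood_a.glycoct",
    "blood-B": "blood_b.glycoct",
    "blood-H": "blood_h.glycoct",
}

TEMPLATE_CATEGORIES = {
    name: ("N-core" if name.startswith("N-core") else
           "O-core" if name.startswith("O-core") else "epitope")
    for name in _TEMPLATES
}


def list_templates() -> list:
    return list(_TEMPLATES)


def load_template(name: str) -> Glycan:
    """A fresh, mutation-safe copy of a catalog structure."""
    try:
        fname = _TEMPLATES[name]
    except KeyError:
        raise CatalogError(f"unknown template {name!r}; see list_templates()")
    text = (resources.files(__package__) / "data" / "templates" / fname).read_text()
    return parse_glycoct(text)


# ---------------------------------------------------------------------------
# random corpus generator

#: residue pool for random structures: the palette plus a few non-mammalian
#: residues so heptoses/pentoses and L-sugars are exercised too.
_RANDOM_POOL = tuple(
    [(e.base, e.substituents) for e in _PALETTE]
    + [("Rha", ()), ("Ara", ()), ("LDmanHep", ()), ("Kdo", ()), ("Man", ())]
)
_RANDOM_SUBS = ("methyl", "acetyl", "sulfate", "phosphate")


def _free_positions(mtype: MonosaccharideType, ring: RingForm, taken=()):
    closure = mtype.ring_closure(ring)
    blocked = {mtype.anomeric_carbon, closure} | set(taken)
    blocked |= mtype.deoxy_positions | mtype.acid_positions
    blocked |= set(mtype.amine_positions)
    return sorted(set(range(1, mtype.carbon_count + 1)) - blocked)


def generate_random_glycan(seed, n_nodes, fuzz_prob=0.0) -> Glycan:
    """Deterministic random glycan; rule-conformant when ``fuzz_prob`` is 0.

    ``fuzz_prob`` is the per-attribute probability of injecting fuzziness
    (undetermined anomer/ring/configuration, UNKNOWN or alternative
    positions, unknown repeat counts).  With ``fuzz_prob = 1`` the result is
    never fully defined; with 0 it always is, and validates cleanly.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not 0 <= fuzz_prob <= 1:
        raise ValueError("fuzz_prob must be in [0, 1]")
    rng = random.Random(seed)

    def fuzz():
        return rng.random() < fuzz_prob

    def pick_entry(budget):
        options = [e for e in _RANDOM_POOL if 1 + len(e[1]) <= budget]
        return options[rng.randrange(len(options))]

    def make_residue(base, root=False):
        mtype = monosaccharide_type(base)
        anomer = (Anomer.UNDETERMINED if fuzz()
                  else rng.choice((Anomer.ALPHA, Anomer.BETA)))
        ring = RingForm.PYRANOSE

        def closable(form):
            closure = mtype.ring_closure(form)
            blocked = (mtype.deoxy_positions | mtype.acid_positions
                       | mtype.amine_positions)
            return (closure is not None and closure <= mtype.carbon_count
                    and closure not in blocked)

        if closable(RingForm.FURANOSE) and rng.random() < 0.1:
            ring = RingForm.FURANOSE
        if fuzz():
            ring = RingForm.UNDETERMINED
        config = mtype.default_absolute_config
        if not mtype.compound_stem and fuzz():
            config = Config.UNDETERMINED
        return Monosaccharide(None, mtype, anomer, ring, config)

    total = 0
    base, subs = pick_entry(max(n_nodes, 1))
    g = create_glycan(make_residue(base, root=True))
    total += 1
    free = {}          # node_id -> available positions
    root_node = g.nodes[g.root_id]
    ring0 = root_node.ring if root_node.ring is not RingForm.UNDETERMINED \
        else RingForm.PYRANOSE
    free[g.root_id] = _free_positions(root_node.mtype, ring0)
    for name, pos in subs:
        if total >= n_nodes:
            break
        g.add_substituent(g.root_id, substituent(name), pos)
        total += 1

    def take_position(nid):
        pos = free[nid].pop(rng.randrange(len(free[nid])))
        return pos

    def fuzzy_acceptor(nid, pos):
        if fuzz():
            roll = rng.random()
            if roll < 0.5 or not free[nid]:
                return frozenset([UNKNOWN])
            alt = take_position(nid)
            return frozenset([pos, alt])
        return frozenset([pos])

    while total < n_nodes:
        open_nodes = sorted(nid for nid, positions in free.items() if positions)
        if not open_nodes:
            break
        nid = open_nodes[rng.randrange(len(open_nodes))]
        pos = take_position(nid)
        budget = n_nodes - total
        roll = rng.random()
        if roll < 0.12:
            sub_pos = pos if not fuzz() else UNKNOWN
            g.add_substituent(nid, substituent(rng.choice(_RANDOM_SUBS)), sub_pos)
            total += 1
            continue
        if roll < 0.20 and budget >= 2:
            unit_base, _ = ("Glc", ()) if rng.random() < 0.5 else ("Gal", ())
            inner = create_glycan(make_residue(unit_base))
            inner_node = inner.nodes[inner.root_id]
            inner_ring = (inner_node.ring
                          if inner_node.ring is not RingForm.UNDETERMINED
                          else RingForm.PYRANOSE)
            inner_free = _free_positions(inner_node.mtype, inner_ring)
            internal_acc = inner_free[rng.randrange(len(inner_free))]
            donor = inner_node.mtype.anomeric_carbon
            if fuzz():
                count = (UNKNOWN, UNKNOWN)
            else:
                k = rng.randrange(2, 6)
                count = (k, k)
            unit = RepeatUnit(None, inner, count[0], count[1],
                              linkage(donor, internal_acc))
            g.add_repeat_unit(nid, unit, GlycosidicLinkage(
                UNKNOWN if fuzz() else donor, fuzzy_acceptor(nid, pos)))
            total += 1 + len(inner)
            continue
        base, subs = pick_entry(budget)
        residue = make_residue(base)
        donor = UNKNOWN if fuzz() else residue.mtype.anomeric_carbon
        child = g.add_monosaccharide(
            nid, residue, GlycosidicLinkage(donor, fuzzy_acceptor(nid, pos)))
        total += 1
        child_ring = residue.ring if residue.ring is not RingForm.UNDETERMINED \
            else RingForm.PYRANOSE
        taken = [p for _, p in subs]
        free[child] = _free_positions(residue.mtype, child_ring, taken)
        for name, sub_pos in subs:
            if total >= n_nodes:
                break
            g.add_substituent(child, substituent(name), sub_pos)
            total += 1
    return g
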