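"""GlycoCT condensed reader and writer.

Dialect notes
-------------
Only the condensed flavour is supported: ``RES`` (``b`` basetype, ``s``
substituent and ``r`` repeat entries), ``LIN`` and ``REP`` sections.  ``UND``
sections are rejected with an explicit error: this library expresses
fuzziness inline (``x`` anomers / ring descriptors, ``-1`` positions,
``3|4`` alternative position sets) rather than through underdetermined
subtrees.

Link-type letters follow the condensed grammar: a glycosidic bond is written
``<acceptor>o(<acc>+<don>)<donor>d`` (the parent provides the oxygen, the
child loses its anomeric hydroxyl); substituents replacing a hydroxyl
(n-acetyl, n-glycolyl, amino) use ``d``/``n`` and substituents replacing
only the hydroxyl hydrogen (sulfate, phosphate, methyl, acetyl, pyruvate)
use ``h``/``n``.

Amine-carrying residue types are decomposed on write (GlcN becomes the
``dglc-HEX`` basetype plus an ``amino`` substituent; its N-acetyl child, if
present, subsumes the amine) and re-fused on parse, so writing is a fixpoint.

The writer emits a canonical form: residues are numbered depth-first from
the reducing end with siblings ordered by smallest stated acceptor position
(UNKNOWN last), then by an id-free subtree signature; lines end with LF.
"""

from __future__ import annotations

import os
import re

from .errors import (
    AttachmentConflict, GlycoCTParseError, StructureError,
    UnsupportedFeatureError,
)
from .model import (
    Glycan, GlycosidicLinkage, Monosaccharide, RepeatUnit, Substituent,
    node_signature, substituent,
)
from .vocab import (
    AMINE_FUSIONS, MONOSACCHARIDES, SUBSTITUENTS, UNKNOWN, Anomer, Config,
    RingForm,
)

_ANOMER_TO_CHAR = {Anomer.ALPHA: "a", Anomer.BETA: "b",
                   Anomer.OPEN: "o", Anomer.UNDETERMINED: "x"}
_CHAR_TO_ANOMER = {v: k for k, v in _ANOMER_TO_CHAR.items()}

# descriptor lookup index over amine-free types:
# (config-free stems, superclass, mods) -> [MonosaccharideType, ...]
_DESCRIPTOR_INDEX = {}
for _mt in MONOSACCHARIDES.values():
    if _mt.amine_positions:
        continue
    _key = (tuple(stem for _, stem in _mt.stem_segments), _mt.superclass,
            _mt.chain_modifications)
    _DESCRIPTOR_INDEX.setdefault(_key, []).append(_mt)

_N_LINKED = ("n-acetyl", "n-glycolyl", "amino")


def _positions_str(positions) -> str:
    stated = sorted(p for p in positions if p is not UNKNOWN)
    return "|".join(str(p) for p in stated) if stated else "-1"


def _count_str(count) -> str:
    return "-1" if count is UNKNOWN else str(count)


def _sub_link_types(stype):
    return ("d", "n") if stype.attachment_mode == "replaces-hydroxyl" else ("h", "n")


class _Writer:
    def __init__(self, g: Glycan):
        self.g = g
        self.res_lines = []           # (block, text) in numbering order
        self.lin_lines = []
        self.blocks = []              # rep blocks: (num, header, res, lin)
        self._res_counter = 0
        self._lin_counter = 0
        self._rep_queue = []

    def _res(self, lines, kind, descriptor) -> int:
        self._res_counter += 1
        lines.append(f"{self._res_counter}{kind}:{descriptor}")
        return self._res_counter

    def _lin(self, lines, pidx, ptype, ppos, cpos, cidx, ctype):
        self._lin_counter += 1
        lines.append(f"{self._lin_counter}:{pidx}{ptype}({ppos}+{cpos}){cidx}{ctype}")

    def run(self) -> str:
        if self.g.root_id is None:
            raise StructureError("cannot serialize an empty glycan")
        main_res, main_lin = [], []
        self._emit_node(self.g, self.g.root_id, None, None, main_res, main_lin)
        out = ["RES"] + main_res
        if main_lin:
            out += ["LIN"] + main_lin
        qi = 0
        rep_sections = []
        while qi < len(self._rep_queue):
            num, unit = self._rep_queue[qi]
            qi += 1
            res, lin, idx_map = [], [], {}
            ig = unit.internal_glycan
            self._emit_node(ig, ig.root_id, None, None, res, lin, idx_map)
            il = unit.internal_linkage
            header = (f"REP{num}:{idx_map[unit.acceptor_node_id]}o("
                      f"{_positions_str(il.acceptor_positions)}+"
                      f"{_positions_str([il.donor_position])})"
                      f"{idx_map[ig.root_id]}d="
                      f"{_count_str(unit.min_count)}-{_count_str(unit.max_count)}")
            section = [header, "RES"] + res
            if lin:
                section += ["LIN"] + lin
            rep_sections.append(section)
        if rep_sections:
            out.append("REP")
            for section in rep_sections:
                out += section
        return "\n".join(out) + "\n"

    def _emit_node(self, g, nid, parent_idx, payload, res, lin, idx_map=None):
        node = g.nodes[nid]
        if isinstance(node, RepeatUnit):
            num = len(self._rep_queue) + 1
            self._rep_queue.append((num, node))
            idx = self._res(res, "r", f"r{num}")
            if idx_map is not None:
                idx_map[nid] = idx
            if parent_idx is not None:
                self._lin(lin, parent_idx, "o",
                          _positions_str(payload.acceptor_positions),
                          _positions_str([payload.donor_position]), idx, "n")
            return
        if isinstance(node, Substituent):
            idx = self._res(res, "s", node.stype.name)
            if idx_map is not None:
                idx_map[nid] = idx
            ptype, ctype = _sub_link_types(node.stype)
            self._lin(lin, parent_idx, ptype, _positions_str([payload]),
                      "1", idx, ctype)
            return
        idx = self._res(res, "b", self._descriptor(node))
        if idx_map is not None:
            idx_map[nid] = idx
        if parent_idx is not None:
            self._lin(lin, parent_idx, "o",
                      _positions_str(payload.acceptor_positions),
                      _positions_str([payload.donor_position]), idx, "d")
        for child_nid, child_payload, synthetic in _ordered_children(g, nid):
            if synthetic:  # implicit amine written as an amino substituent
                sidx = self._res(res, "s", "amino")
                self._lin(lin, idx, "d", str(child_payload), "1", sidx, "n")
            else:
                self._emit_node(g, child_nid, idx, child_payload, res, lin, idx_map)

    def _descriptor(self, node: Monosaccharide) -> str:
        mt = node.mtype
        segments = mt.stem_segments
        config = node.absolute_config
        if config is Config.UNDETERMINED:
            last_char = "x"
        else:
            last_char = config.value.lower()
        stem = "-".join(
            (last_char if i == len(segments) - 1 else c) + s
            for i, (c, s) in enumerate(segments))
        closure = mt.ring_closure(node.ring)
        if node.ring is RingForm.OPEN:
            ring = "0:0"
        elif node.ring is RingForm.UNDETERMINED:
            ring = "x:x"
        else:
            ring = f"{mt.anomeric_carbon}:{closure}"
        mods = "".join(f"|{p}:{tok}" for p, tok in
                       sorted(mt.chain_modifications))
        return f"{_ANOMER_TO_CHAR[node.anomericity]}-{stem}-{mt.superclass}-{ring}{mods}"


def _ordered_children(g: Glycan, nid):
    """Canonical child order: (child_id, payload, synthetic_amino) triples.

    Ordered by stated position (UNKNOWN last), substituents before glycosidic
    children at the same position, ties broken by subtree signature.
    """
    node = g.nodes[nid]
    entries = []
    amine_left = set(node.mtype.amine_positions)
    for c in g.substituent_children(nid):
        pos = g.linkage_of(c)
        sub = g.nodes[c]
        if pos in amine_left and sub.stype.name in _N_LINKED:
            amine_left.discard(pos)
        key = ((0, (pos,)) if pos is not UNKNOWN else (1, ()),
               0, node_signature(g, c))
        entries.append((key, (c, pos, False)))
    for p in amine_left:
        entries.append((((0, (p,)), 0, (("s", "amino"), ())), (None, p, True)))
    for c in g.monosaccharide_children(nid):
        link = g.linkage_of(c)
        entries.append(((link.sort_key(), 1, node_signature(g, c)),
                        (c, link, False)))
    entries.sort(key=lambda e: e[0])
    return [payload for _, payload in entries]


def write_glycoct(g: Glycan, path=None) -> str:
    """Serialize a glycan to canonical GlycoCT condensed text."""
    text = _Writer(g).run()
    if path is not None:
        with open(path, "w", newline="\n") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# parsing

_RES_RE = re.compile(r"^(\d+)([bsr]):(.+)$")
_BASE_RE = re.compile(
    r"^([abox])-((?:[dlx][a-z]{3}-)*[dlx][a-z]{3})"
    r"-(TRI|TET|PEN|HEX|HEP|OCT|NON)-(\d|x):(\d|x)((?:\|\d:[a-z]+)*)$")
_LIN_RE = re.compile(
    r"^(\d+):(\d+)([odhnx])\((-1|\d(?:\|\d)*)\+(-1|\d)\)(\d+)([odhnx])$")
_REP_RE = re.compile(
    r"^REP(\d+):(\d+)([odhnx])\((-1|\d(?:\|\d)*)\+(-1|\d)\)(\d+)([odhnx])"
    r"=(-?\d+)-(-?\d+)$")


def _parse_positions(tok):
    if tok == "-1":
        return frozenset([UNKNOWN])
    return frozenset(int(p) for p in tok.split("|"))


def _parse_single_position(tok):
    return UNKNOWN if tok == "-1" else int(tok)


class _ResEntry:
    __slots__ = ("index", "kind", "descriptor", "line", "block")

    def __init__(self, index, kind, descriptor, line, block):
        self.index, self.kind, self.descriptor = index, kind, descriptor
        self.line, self.block = line, block


class _LinEntry:
    __slots__ = ("index", "parent", "ptype", "ppos", "cpos", "child",
                 "ctype", "line", "block")

    def __init__(self, index, parent, ptype, ppos, cpos, child, ctype,
                 line, block):
        self.index, self.parent, self.ptype = index, parent, ptype
        self.ppos, self.cpos, self.child, self.ctype = ppos, cpos, child, ctype
        self.line, self.block = line, block


class _RepBlock:
    __slots__ = ("number", "acceptor", "ppos", "cpos", "root", "mini",
                 "maxi", "line")

    def __init__(self, number, acceptor, ppos, cpos, root, mini, maxi, line):
        self.number, self.acceptor = number, acceptor
        self.ppos, self.cpos, self.root = ppos, cpos, root
        self.mini, self.maxi, self.line = mini, maxi, line


def _tokenize(text):
    """Split into RES / LIN / REP entries tagged with their block."""
    lines = [(i + 1, ln.rstrip("\r")) for i, ln in enumerate(text.split("\n"))]
    lines = [(no, ln.strip()) for no, ln in lines if ln.strip()]
    if not lines:
        raise GlycoCTParseError("empty document")
    res_entries, lin_entries, rep_blocks = [], [], {}
    block = "main"
    section = None
    first = True
    for no, ln in lines:
        if ln == "UND":
            raise UnsupportedFeatureError(
                "UND sections are not supported by this dialect", line=no)
        if ln in ("RES", "LIN"):
            if first and ln != "RES":
                raise GlycoCTParseError("document must start with RES", line=no)
            section = ln
            first = False
            continue
        if ln == "REP":
            section = "REP"
            continue
        if first:
            raise GlycoCTParseError("document must start with RES", line=no)
        m = _REP_RE.match(ln)
        if m:
            if section not in ("REP", "RES", "LIN"):
                raise GlycoCTParseError("unexpected REP header", line=no)
            num = int(m.group(1))
            if num in rep_blocks:
                raise GlycoCTParseError(f"duplicate REP{num} header", line=no)
            mini = int(m.group(8))
            maxi = int(m.group(9))
            if mini == 0 or maxi == 0 or mini < -1 or maxi < -1:
                raise GlycoCTParseError(
                    "repeat counts must be positive or -1", line=no)
            rep_blocks[num] = _RepBlock(
                num, int(m.group(2)), _parse_positions(m.group(4)),
                _parse_single_position(m.group(5)), int(m.group(6)),
                UNKNOWN if mini == -1 else mini,
                UNKNOWN if maxi == -1 else maxi, no)
            block = f"rep{num}"
            section = None
            continue
        if section == "RES" or (section is None and _RES_RE.match(ln)):
            m = _RES_RE.match(ln)
            if not m:
                raise GlycoCTParseError(f"malformed RES entry {ln!r}", line=no)
            res_entries.append(_ResEntry(int(m.group(1)), m.group(2),
                                         m.group(3), no, block))
            section = "RES"
            continue
        if section == "LIN":
            m = _LIN_RE.match(ln)
            if not m:
                raise GlycoCTParseError(f"malformed LIN entry {ln!r}", line=no)
            lin_entries.append(_LinEntry(
                int(m.group(1)), int(m.group(2)), m.group(3),
                _parse_positions(m.group(4)),
                _parse_single_position(m.group(5)),
                int(m.group(6)), m.group(7), no, block))
            continue
        raise GlycoCTParseError(f"unexpected line {ln!r}", line=no)
    return res_entries, lin_entries, rep_blocks


def _resolve_basetype(descriptor, line):
    m = _BASE_RE.match(descriptor)
    if not m:
        raise GlycoCTParseError(f"malformed basetype {descriptor!r}", line=line)
    anomer = _CHAR_TO_ANOMER[m.group(1)]
    segments = [(seg[0], seg[1:]) for seg in m.group(2).split("-")]
    superclass = m.group(3)
    mods = frozenset((int(p), tok) for p, tok in
                     (item.split(":") for item in m.group(6).split("|")[1:]))
    key = (tuple(stem for _, stem in segments), superclass, mods)
    candidates = [mt for mt in _DESCRIPTOR_INDEX.get(key, ())
                  if all(cc == "x" or cc == mc
                         for (cc, _), (mc, _) in zip(segments, mt.stem_segments))]
    if not candidates:
        raise GlycoCTParseError(
            f"unknown residue descriptor {descriptor!r}", line=line)
    if len(candidates) > 1:
        raise GlycoCTParseError(
            f"ambiguous residue descriptor {descriptor!r}", line=line)
    mt = candidates[0]
    last_cc = segments[-1][0]
    if last_cc == "x":
        config = Config.UNDETERMINED
    else:
        config = Config.D if last_cc == "d" else Config.L
    ring_start, ring_end = m.group(4), m.group(5)
    if (ring_start, ring_end) == ("0", "0"):
        ring = RingForm.OPEN
        if anomer not in (Anomer.OPEN, Anomer.UNDETERMINED):
            raise GlycoCTParseError(
                "open-chain residue must carry anomer 'o'", line=line)
        anomer = Anomer.OPEN
    elif "x" in (ring_start, ring_end):
        ring = RingForm.UNDETERMINED
    else:
        start, end = int(ring_start), int(ring_end)
        if start != mt.anomeric_carbon:
            raise GlycoCTParseError(
                f"ring start {start} does not match anomeric carbon of "
                f"{mt.name}", line=line)
        span = end - start
        if span == 4:
            ring = RingForm.PYRANOSE
        elif span == 3:
            ring = RingForm.FURANOSE
        else:
            raise GlycoCTParseError(
                f"unsupported ring closure {start}:{end}", line=line)
    return Monosaccharide(None, mt, anomer, ring, config)


def parse_glycoct(source) -> Glycan:
    """Parse GlycoCT condensed text (or a file path) into a Glycan."""
    if isinstance(source, os.PathLike):
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        stripped = source.lstrip()
        if stripped.startswith("RES") or "\n" in source:
            text = source
        elif os.path.exists(source):
            with open(source) as fh:
                text = fh.read()
        else:
            text = source
    else:
        raise TypeError("source must be text or a path")
    res_entries, lin_entries, rep_blocks = _tokenize(text)

    expected = 1
    index = {}
    for entry in res_entries:
        if entry.index != expected:
            raise GlycoCTParseError(
                f"residue indices must be contiguous from 1; got {entry.index}",
                line=entry.line)
        index[entry.index] = entry
        expected += 1
        # eager syntax checks so malformed entries carry their line number
        if entry.kind == "b":
            _resolve_basetype(entry.descriptor, entry.line)
        elif entry.kind == "s":
            if entry.descriptor not in SUBSTITUENTS:
                raise GlycoCTParseError(
                    f"unknown substituent {entry.descriptor!r}",
                    line=entry.line)
        elif not re.match(r"^r\d+$", entry.descriptor):
            raise GlycoCTParseError(
                f"malformed repeat reference {entry.descriptor!r}",
                line=entry.line)
    for i, entry in enumerate(lin_entries, start=1):
        if entry.index != i:
            raise GlycoCTParseError(
                f"linkage indices must be contiguous from 1; got {entry.index}",
                line=entry.line)
        for ref in (entry.parent, entry.child):
            if ref not in index:
                raise GlycoCTParseError(
                    f"linkage references unknown residue {ref}", line=entry.line)
            if index[ref].block != entry.block:
                raise GlycoCTParseError(
                    f"linkage crosses block boundary at residue {ref}",
                    line=entry.line)

    children = {}                     # parent index -> [lin entry, ...]
    has_parent = set()
    for entry in lin_entries:
        children.setdefault(entry.parent, []).append(entry)
        if entry.child in has_parent:
            raise GlycoCTParseError(
                f"residue {entry.child} has two parents", line=entry.line)
        has_parent.add(entry.child)

    def block_root(block):
        roots = [e for e in res_entries
                 if e.block == block and e.index not in has_parent]
        if len(roots) != 1:
            raise GlycoCTParseError(
                f"expected exactly one root residue in {block} section; "
                f"found {len(roots)}")
        return roots[0]

    built_reps = {}

    def build_block(block) -> Glycan:
        g = Glycan()
        id_map = {}
        root = block_root(block)

        def attach(entry, parent_model_id, lin):
            node_kind = entry.kind
            try:
                if node_kind == "b":
                    residue = _resolve_basetype(entry.descriptor, entry.line)
                    if lin is None:
                        nid = g.set_root(residue)
                    else:
                        link = GlycosidicLinkage(lin.cpos, lin.ppos)
                        nid = g.add_monosaccharide(parent_model_id, residue, link)
                elif node_kind == "s":
                    if entry.descriptor not in SUBSTITUENTS:
                        raise GlycoCTParseError(
                            f"unknown substituent {entry.descriptor!r}",
                            line=entry.line)
                    if lin is None:
                        raise GlycoCTParseError(
                            "substituent cannot be the root", line=entry.line)
                    stated = sorted(p for p in lin.ppos if p is not UNKNOWN)
                    if len(stated) > 1:
                        raise GlycoCTParseError(
                            "substituent with alternative positions is not "
                            "supported", line=lin.line)
                    pos = stated[0] if stated else UNKNOWN
                    nid = g.add_substituent(
                        parent_model_id, substituent(entry.descriptor), pos)
                else:
                    m = re.match(r"^r(\d+)$", entry.descriptor)
                    if not m or int(m.group(1)) not in rep_blocks:
                        raise GlycoCTParseError(
                            f"unresolved repeat reference {entry.descriptor!r}",
                            line=entry.line)
                    unit = build_repeat(int(m.group(1)))
                    if lin is None:
                        nid = g.set_root(unit)
                    else:
                        link = GlycosidicLinkage(lin.cpos, lin.ppos)
                        nid = g.add_repeat_unit(parent_model_id, unit, link)
            except (AttachmentConflict, StructureError) as exc:
                raise GlycoCTParseError(str(exc),
                                        line=lin.line if lin else entry.line)
            id_map[entry.index] = nid
            for sub_lin in children.get(entry.index, ()):
                attach(index[sub_lin.child], nid, sub_lin)

        attach(root, None, None)
        _fuse_amines(g)
        return g, id_map

    def build_repeat(num) -> RepeatUnit:
        if num in built_reps:
            raise GlycoCTParseError(f"repeat r{num} referenced twice")
        built_reps[num] = True
        blk = rep_blocks[num]
        g, id_map = build_block(f"rep{num}")
        for ref in (blk.acceptor, blk.root):
            if ref not in id_map:
                raise GlycoCTParseError(
                    f"REP{num} references residue {ref} outside its block",
                    line=blk.line)
        if id_map[blk.root] != g.root_id:
            raise GlycoCTParseError(
                f"REP{num} internal donor is not the unit root", line=blk.line)
        return RepeatUnit(
            None, g, blk.mini, blk.maxi,
            GlycosidicLinkage(blk.cpos, blk.ppos),
            acceptor_node_id=id_map[blk.acceptor])

    glycan, _ = build_block("main")
    for num in rep_blocks:
        if num not in built_reps:
            raise GlycoCTParseError(f"repeat block REP{num} is never used",
                                    line=rep_blocks[num].line)
    return glycan


def _fuse_amines(g: Glycan):
    """Re-fuse amino / N-acyl substituents into amine-carrying residue types."""
    for nid in list(g.walk()):
        node = g.nodes.get(nid)
        if not isinstance(node, Monosaccharide):
            continue
        for cid in g.substituent_children(nid):
            sub = g.nodes[cid]
            pos = g.linkage_of(cid)
            if pos is UNKNOWN or sub.stype.name not in _N_LINKED:
                continue
            fused = AMINE_FUSIONS.get((node.mtype.name, pos))
            if fused is None:
                continue
            g.update_node(nid, mtype=MONOSACCHARIDES[fused])
            if sub.stype.name == "amino":
                g.remove_subtree(cid)
            break


def normalize(text) -> str:
    """Canonical (parse -> write) fixpoint representative of a document."""
    return write_glycoct(parse_glycoct(text))
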