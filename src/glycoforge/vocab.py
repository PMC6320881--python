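"""Controlled vocabularies: monosaccharide types, substituent types, SNFG palette.

The tables are shipped as plain-text TSV files under ``glycoforge/data`` and
loaded once at import.  Every node field in a glycan must come from these
dictionaries; arbitrary tokens are rejected at construction time.

A monosaccharide type maps sugar chemistry (superclass, chain modifications,
anomeric carbon, Fischer configuration) to its SNFG symbol (shape + colour).
Amine-carrying types (GlcN, GalN, ManN, Neu) record the amine position so the
GlycoCT adapter can decompose them into basetype + amino/N-acyl substituent
and re-fuse them on parse.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .errors import VocabularyError


class UnknownPosition:
    """Singleton sentinel for an unknown linkage position or repeat count."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UNKNOWN"

    def __reduce__(self):
        return (UnknownPosition, ())


#: The single UNKNOWN sentinel; distinct from any integer and from the
#: "alternative positions" encoding (a set of size > 1).
UNKNOWN = UnknownPosition()


class Anomer(enum.Enum):
    ALPHA = "alpha"
    BETA = "beta"
    OPEN = "open"
    UNDETERMINED = "undetermined"


class RingForm(enum.Enum):
    PYRANOSE = "pyranose"
    FURANOSE = "furanose"
    OPEN = "open"
    UNDETERMINED = "undetermined"


class Config(enum.Enum):
    D = "D"
    L = "L"
    UNDETERMINED = "undetermined"


SUPERCLASS_CARBONS = {
    "TRI": 3, "TET": 4, "PEN": 5, "HEX": 6, "HEP": 7, "OCT": 8, "NON": 9,
}

SNFG_SHAPES = frozenset({
    "circle", "square", "crossed-square", "divided-diamond", "triangle",
    "divided-triangle", "rectangle", "star", "diamond", "hexagon",
    "pentagon", "flat-rectangle",
})

WATER = {"H": 2, "O": 1}


def _merge(total: dict, delta: Mapping[str, int], times: int = 1) -> dict:
    for el, n in delta.items():
        total[el] = total.get(el, 0) + n * times
        if total[el] == 0:
            del total[el]
    return total


def hill_formula(counts: Mapping[str, int]) -> str:
    """Element counts -> Hill-order formula string (C, H, then alphabetic)."""
    order = []
    if "C" in counts:
        order.append("C")
        if "H" in counts:
            order.append("H")
        order.extend(sorted(k for k in counts if k not in ("C", "H")))
    else:
        order = sorted(counts)
    return "".join(f"{el}{counts[el] if counts[el] != 1 else ''}" for el in order
                   if counts[el])


@dataclass(frozen=True)
class MonosaccharideType:
    name: str
    superclass: str
    carbon_count: int
    stem: str                       # GlycoCT stem with config prefixes, e.g. "lgro-dman"
    snfg_shape: str
    snfg_color: str
    default_absolute_config: Config
    anomeric_carbon: int
    chain_modifications: frozenset  # of (position, token in {d, a, keto, en})
    amine_positions: frozenset      # positions where an NH2 replaces the OH
    fischer: Mapping[int, str]      # stereocentre -> 'R'/'L' for the default-D form
    formula_template: Mapping[str, str] = field(default=None)

    def __post_init__(self):
        if self.anomeric_carbon not in (1, 2):
            raise VocabularyError(f"{self.name}: anomeric carbon must be 1 or 2")
        if SUPERCLASS_CARBONS.get(self.superclass) != self.carbon_count:
            raise VocabularyError(
                f"{self.name}: superclass {self.superclass} inconsistent with "
                f"{self.carbon_count} carbons")
        if self.snfg_shape not in SNFG_SHAPES:
            raise VocabularyError(f"{self.name}: unknown SNFG shape {self.snfg_shape}")
        # free reducing monosaccharide formula: CnH2nOn adjusted by mods/amines
        counts = {"C": self.carbon_count, "H": 2 * self.carbon_count,
                  "O": self.carbon_count}
        for pos, tok in self.chain_modifications:
            if tok == "d":
                _merge(counts, {"O": -1})
            elif tok == "a":
                _merge(counts, {"O": 1, "H": -2})
            elif tok == "en":
                _merge(counts, {"H": -2, "O": -1})
            elif tok != "keto":
                raise VocabularyError(f"{self.name}: unknown chain modifier {tok}")
        for _ in self.amine_positions:
            _merge(counts, {"N": 1, "H": 1, "O": -1})
        object.__setattr__(self, "formula_template", dict(counts))

    @property
    def deoxy_positions(self):
        return frozenset(p for p, tok in self.chain_modifications if tok == "d")

    @property
    def acid_positions(self):
        return frozenset(p for p, tok in self.chain_modifications if tok == "a")

    @property
    def stem_segments(self):
        """[(config_char, stem), ...] e.g. [('l', 'gro'), ('d', 'man')]."""
        return [(seg[0], seg[1:]) for seg in self.stem.split("-")]

    @property
    def compound_stem(self) -> bool:
        return len(self.stem_segments) > 1

    def ring_closure(self, ring: RingForm):
        """Ring-end carbon for a given ring form, or None for open chains."""
        if ring is RingForm.PYRANOSE:
            return self.anomeric_carbon + 4
        if ring is RingForm.FURANOSE:
            return self.anomeric_carbon + 3
        return None


@dataclass(frozen=True)
class SubstituentType:
    name: str
    label: str
    attachment_mode: str            # replaces-hydroxyl | replaces-hydroxyl-H
    formula_delta: Mapping[str, int]

    def __post_init__(self):
        if not self.label:
            raise VocabularyError(f"{self.name}: empty label")
        if self.attachment_mode not in (
                "replaces-hydroxyl", "replaces-hydroxyl-H", "replaces-hydrogen"):
            raise VocabularyError(f"{self.name}: bad attachment mode")

    def delta_on(self, aminated: bool) -> dict:
        """Net formula change when attached at a plain (OH) or aminated position.

        On an amine the group bonds to the existing nitrogen (replacing an N-H)
        so the substituent's own N and one H are not added and the parent keeps
        its oxygenless position: delta' = delta - N - H + O.
        """
        d = dict(self.formula_delta)
        if aminated:
            _merge(d, {"N": -1, "H": -1, "O": 1})
        return d


def _data_lines(fname):
    text = (resources.files(__package__) / "data" / fname).read_text()
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield line.split("\t")


def _parse_mods(tok):
    if tok == "-":
        return frozenset()
    return frozenset((int(p), m) for p, m in
                     (item.split(":") for item in tok.split("|")))


def _load_monosaccharides():
    table = {}
    pairs = set()
    for row in _data_lines("monosaccharides.tsv"):
        (name, superclass, carbons, stem, shape, color, config, anomeric,
         mods, amines, fischer) = row
        mt = MonosaccharideType(
            name=name, superclass=superclass, carbon_count=int(carbons),
            stem=stem, snfg_shape=shape, snfg_color=color,
            default_absolute_config=Config(config),
            anomeric_carbon=int(anomeric),
            chain_modifications=_parse_mods(mods),
            amine_positions=frozenset() if amines == "-" else
            frozenset(int(p) for p in amines.split(",")),
            fischer={int(p): o for p, o in
                     (item.split(":") for item in fischer.split(","))},
        )
        if (shape, color) in pairs:
            raise VocabularyError(f"duplicate SNFG symbol {(shape, color)}")
        pairs.add((shape, color))
        table[name] = mt
    return table


def _load_substituents():
    table = {}
    for name, label, mode, delta in _data_lines("substituents.tsv"):
        table[name] = SubstituentType(
            name=name, label=label, attachment_mode=mode,
            formula_delta={el: int(n) for el, n in
                           (item.split(":") for item in delta.split(","))})
    return table


def _load_colors():
    return {name: hexval for name, hexval in _data_lines("snfg_colors.tsv")}


MONOSACCHARIDES: Mapping[str, MonosaccharideType] = _load_monosaccharides()
SUBSTITUENTS: Mapping[str, SubstituentType] = _load_substituents()
SNFG_COLORS: Mapping[str, str] = _load_colors()

# (base type name, amine position) -> aminated type name, for GlycoCT re-fusion
AMINE_FUSIONS = {}
for _mt in MONOSACCHARIDES.values():
    if _mt.amine_positions:
        for _base in MONOSACCHARIDES.values():
            if (_base.amine_positions or _base.stem != _mt.stem
                    or _base.superclass != _mt.superclass
                    or _base.chain_modifications != _mt.chain_modifications):
                continue
            for _p in _mt.amine_positions:
                AMINE_FUSIONS[(_base.name, _p)] = _mt.name


def monosaccharide_type(name: str) -> MonosaccharideType:
    try:
        return MONOSACCHARIDES[name]
    except KeyError:
        raise VocabularyError(f"unknown monosaccharide type: {name!r}") from None


def substituent_type(name: str) -> SubstituentType:
    try:
        return SUBSTITUENTS[name]
    except KeyError:
        raise VocabularyError(f"unknown substituent type: {name!r}") from None
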