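"""GlycoCT condensed parsing, writing and canonicalization."""

import itertools

import pytest

import glycoforge as gf
from glycoforge.glycoct import normalize, parse_glycoct, write_glycoct
from glycoforge.model import RepeatUnit, linkage

LACTOSE_DOC = "RES\n1b:b-dglc-HEX-1:5\n2b:b-dgal-HEX-1:5\nLIN\n1:1o(4+1)2d"


class TestParse:
    def test_disaccharide_document(self):
        g = parse_glycoct(LACTOSE_DOC)
        assert len(g) == 2
        root = g.nodes[g.root_id]
        (leaf_id,) = g.monosaccharide_children(g.root_id)
        leaf = g.nodes[leaf_id]
        assert root.mtype.name == "Glc" and leaf.mtype.name == "Gal"
        for node in (root, leaf):
            assert node.anomericity is gf.Anomer.BETA
            assert node.ring is gf.RingForm.PYRANOSE
            assert node.absolute_config is gf.Config.D
        link = g.linkage_of(leaf_id)
        assert link.donor_position == 1 and link.stated_acceptor == 4

    def test_single_residue(self):
        g = parse_glycoct("RES\n1b:a-dgal-HEX-1:5")
        node = g.nodes[g.root_id]
        assert (node.mtype.name, node.anomericity) == ("Gal", gf.Anomer.ALPHA)

    def test_x_anomer_is_undetermined(self):
        g = parse_glycoct("RES\n1b:x-dglc-HEX-1:5")
        assert g.nodes[g.root_id].anomericity is gf.Anomer.UNDETERMINED
        assert not g.is_fully_defined()

    def test_substituent_refusion(self):
        text = ("RES\n1b:b-dglc-HEX-1:5\n2s:n-acetyl\nLIN\n1:1d(2+1)2n")
        g = parse_glycoct(text)
        assert g.nodes[g.root_id].mtype.name == "GlcN"
        assert len(g.substituent_children(g.root_id)) == 1

    def test_amino_fuses_silently(self):
        g = parse_glycoct("RES\n1b:b-dglc-HEX-1:5\n2s:amino\nLIN\n1:1d(2+1)2n")
        assert g.nodes[g.root_id].mtype.name == "GlcN"
        assert len(g) == 1

    def test_file_path_input(self, tmp_path, lactose):
        p = tmp_path / "lactose.glycoct"
        write_glycoct(lactose, p)
        assert gf.isomorphic(parse_glycoct(p), lactose)


class TestRejection:
    @pytest.mark.parametrize("mutant", [
        "RES\n1bb-dglc-HEX-1:5",                    # deleted colon
        "RES\n0b:b-dglc-HEX-1:5",                   # index 0
        "RES\n1b:b-dglc-HEXX-1:5",                  # unknown superclass
        "RES\n1b:b-dglc-HEX-1:5\n3b:b-dgal-HEX-1:5",  # gap in indices
        "RES\n1b:b-dqqq-HEX-1:5",                   # unknown stem
        "RES\n1b:b-dglc-HEX-1:5\nLIN\n1:1o(4+1)9d",   # dangling index
        "RES\n1s:n-acetyl",                         # substituent root
        "RES\n1b:b-dglc-HEX-1:5\n2b:b-dgal-HEX-1:5",  # two roots
        "LIN\n1:1o(4+1)2d",                         # missing RES
        "",                                         # empty
    ])
    def test_grammar_violations_raise(self, mutant):
        with pytest.raises(gf.GlycoCTParseError):
            parse_glycoct(mutant)

    def test_und_section_is_an_explicit_unsupported_feature(self):
        text = LACTOSE_DOC + "\nUND\nUND1:100.0:100.0"
        with pytest.raises(gf.UnsupportedFeatureError):
            parse_glycoct(text)

    def test_errors_carry_line_numbers(self):
        with pytest.raises(gf.GlycoCTParseError) as err:
            parse_glycoct("RES\n1b:b-dglc-HEX-1:5\n2b:oops")
        assert err.value.line == 3


class TestWrite:
    def test_writer_needs_nonempty_glycan(self):
        with pytest.raises(gf.StructureError):
            write_glycoct(gf.Glycan())

    def test_lactose_normal_form(self, lactose):
        assert normalize(LACTOSE_DOC) == write_glycoct(lactose)

    def test_glcnac_writes_base_plus_substituent(self, glcnac):
        text = write_glycoct(glcnac)
        lines = text.strip().split("\n")
        assert lines.count("RES") == 1
        assert sum(1 for l in lines if ":" in l and "b:" in l) == 1
        assert "2s:n-acetyl" in lines
        assert "1:1d(2+1)2n" in lines

    def test_bare_hexosamine_writes_amino(self):
        g = gf.create_glycan(gf.monosaccharide("GlcN", gf.Anomer.BETA))
        assert "2s:amino" in write_glycoct(g)

    def test_alternative_positions_use_pipe(self, lactose):
        lactose.add_monosaccharide(
            lactose.root_id, gf.monosaccharide("Fuc", gf.Anomer.ALPHA),
            linkage(1, frozenset({3, 6})))
        assert "(3|6+1)" in write_glycoct(lactose)

    def test_unknown_positions_written_as_minus_one(self, lactose):
        lactose.add_monosaccharide(
            lactose.root_id, gf.monosaccharide("Fuc", gf.Anomer.ALPHA),
            linkage(gf.UNKNOWN, gf.UNKNOWN))
        assert "(-1+-1)" in write_glycoct(lactose)


class TestNormalize:
    def test_idempotent(self):
        assert normalize(normalize(LACTOSE_DOC)) == normalize(LACTOSE_DOC)

    def test_crlf_and_lf_agree(self):
        assert normalize(LACTOSE_DOC.replace("\n", "\r\n")) == \
            normalize(LACTOSE_DOC)

    def test_sibling_order_is_canonical(self):
        """All LIN permutations of a branched document share one normal form."""
        doc = ("RES\n1b:b-dglc-HEX-1:5\n2b:a-dman-HEX-1:5\n"
               "3b:b-dgal-HEX-1:5\n4b:a-lgal-HEX-1:5|6:d\nLIN\n"
               "{0}\n{1}\n{2}")
        body = ["1o(3+1)2d", "1o(4+1)3d", "1o(6+1)4d"]
        forms = set()
        for perm in itertools.permutations(body):
            lines = [f"{i + 1}:{entry}" for i, entry in enumerate(perm)]
            forms.add(normalize(doc.format(*lines)))
        assert len(forms) == 1


class TestRoundTrip:
    def test_repeat_units_preserve_counts(self):
        inner = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
        unit = RepeatUnit(None, inner, 2, 5, linkage(1, 4))
        g = gf.create_glycan(gf.monosaccharide("Gal", gf.Anomer.BETA))
        g.add_repeat_unit(g.root_id, unit, linkage(1, 3))
        g2 = parse_glycoct(write_glycoct(g))
        (rep,) = [n for n in g2.nodes.values() if isinstance(n, RepeatUnit)]
        assert (rep.min_count, rep.max_count) == (2, 5)
        assert gf.isomorphic(g, g2)

    def test_fuzziness_survives_roundtrip(self):
        for seed in range(25):
            g = gf.generate_random_glycan(seed, 12, fuzz_prob=0.5)
            g2 = parse_glycoct(write_glycoct(g))
            assert g.is_fully_defined() == g2.is_fully_defined()

    def test_write_is_a_fixpoint(self, small_corpus):
        for g in small_corpus:
            text = write_glycoct(g)
            assert write_glycoct(parse_glycoct(text)) == text
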