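"""Glycan tree construction, editing and fuzziness semantics."""

import pytest

import glycoforge as gf
from glycoforge.model import (
    GlycosidicLinkage, RepeatUnit, linkage, node_signature,
)


class TestCreate:
    def test_single_residue_glycan(self):
        g = gf.create_glycan(gf.monosaccharide("GlcN", gf.Anomer.BETA))
        assert len(g) == 1 and not g.edges
        assert g.nodes[g.root_id].anomericity is gf.Anomer.BETA

    def test_open_ring_forces_open_anomer(self):
        with pytest.raises(gf.StructureError):
            gf.monosaccharide("Glc", gf.Anomer.ALPHA, gf.RingForm.OPEN)

    def test_unknown_type_token_rejected(self):
        with pytest.raises(gf.VocabularyError):
            gf.create_glycan("NotASugar")
        with pytest.raises(gf.VocabularyError):
            gf.substituent("glitter")

    def test_heptose_root_from_vocabulary(self):
        g = gf.create_glycan(gf.monosaccharide("LDmanHep", gf.Anomer.ALPHA))
        mt = g.nodes[g.root_id].mtype
        assert (mt.snfg_shape, mt.snfg_color) == ("hexagon", "green")


class TestAttach:
    def test_attach_monosaccharide(self, lactose):
        assert len(lactose) == 2 and len(lactose.edges) == 1

    def test_occupied_position_conflicts(self, lactose):
        with pytest.raises(gf.AttachmentConflict):
            lactose.add_monosaccharide(
                lactose.root_id, gf.monosaccharide("Man", gf.Anomer.ALPHA),
                linkage(1, 4))

    def test_fuzzy_alternative_acceptor_accepted(self, lactose):
        lactose.add_monosaccharide(
            lactose.root_id, gf.monosaccharide("Fuc", gf.Anomer.ALPHA),
            linkage(1, frozenset({3, 6})))
        assert not lactose.is_fully_defined()

    def test_substituent_is_a_leaf(self, glcnac):
        sub_id = glcnac.substituent_children(glcnac.root_id)[0]
        with pytest.raises(gf.StructureError):
            glcnac.add_monosaccharide(
                sub_id, gf.monosaccharide("Gal", gf.Anomer.BETA), linkage(1, 4))

    def test_substituent_position_range(self, lactose):
        with pytest.raises(gf.StructureError):
            lactose.add_substituent(lactose.root_id,
                                    gf.substituent("sulfate"), 11)

    def test_substituent_at_unknown_position(self, lactose):
        lactose.add_substituent(lactose.root_id, gf.substituent("n-acetyl"),
                                gf.UNKNOWN)
        assert not lactose.is_fully_defined()

    def test_linkage_invariants(self):
        with pytest.raises(gf.StructureError):
            GlycosidicLinkage(1, frozenset())
        with pytest.raises(gf.StructureError):
            GlycosidicLinkage(1, frozenset({gf.UNKNOWN, 3}))


class TestRemove:
    def _chain(self):
        g = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
        a = g.add_monosaccharide(g.root_id,
                                 gf.monosaccharide("Gal", gf.Anomer.BETA),
                                 linkage(1, 4))
        b = g.add_monosaccharide(a, gf.monosaccharide("Fuc", gf.Anomer.ALPHA),
                                 linkage(1, 2))
        return g, a, b

    def test_remove_leaf(self):
        g, a, b = self._chain()
        g.remove_subtree(b)
        assert len(g) == 2

    def test_remove_middle_prunes_descendants(self):
        g, a, b = self._chain()
        g.remove_subtree(a)
        assert len(g) == 1 and b not in g.nodes

    def test_remove_root_empties_glycan(self):
        g, _, _ = self._chain()
        g.remove_subtree(g.root_id)
        assert len(g) == 0 and g.root_id is None
        assert g.is_fully_defined()  # vacuously

    def test_ids_never_reused(self):
        g, a, b = self._chain()
        g.remove_subtree(a)
        c = g.add_monosaccharide(g.root_id,
                                 gf.monosaccharide("Man", gf.Anomer.ALPHA),
                                 linkage(1, 3))
        assert c not in (a, b)


class TestUpdate:
    def test_anomericity_update_keeps_topology(self, lactose):
        leaf = lactose.monosaccharide_children(lactose.root_id)[0]
        lactose.update_node(leaf, anomericity=gf.Anomer.ALPHA)
        assert len(lactose) == 2
        assert lactose.nodes[leaf].anomericity is gf.Anomer.ALPHA

    def test_shrinking_carbon_count_checks_linkages(self, lactose):
        glc6 = lactose.root_id
        lactose.add_monosaccharide(glc6,
                                   gf.monosaccharide("Man", gf.Anomer.ALPHA),
                                   linkage(1, 6))
        with pytest.raises(gf.StructureError):
            lactose.update_node(glc6, mtype=gf.MONOSACCHARIDES["Xyl"])

    def test_ring_update_changes_serialization(self, lactose):
        leaf = lactose.monosaccharide_children(lactose.root_id)[0]
        before = gf.write_glycoct(lactose)
        lactose.update_node(leaf, ring=gf.RingForm.FURANOSE)
        after = gf.write_glycoct(lactose)
        assert "1:4" in after and after != before


class TestCopyPaste:
    def _antenna(self):
        """4-residue antenna: Neu5Ac-Gal-GlcNAc stub on a Man."""
        g = gf.create_glycan(gf.monosaccharide("Man", gf.Anomer.ALPHA))
        gn = g.add_monosaccharide(g.root_id,
                                  gf.monosaccharide("GlcN", gf.Anomer.BETA),
                                  linkage(1, 2))
        g.add_substituent(gn, gf.substituent("n-acetyl"), 2)
        g.add_monosaccharide(gn, gf.monosaccharide("Gal", gf.Anomer.BETA),
                             linkage(1, 4))
        return g

    def test_copy_paste_duplicates_antenna(self, branched_mannose):
        arm = branched_mannose.monosaccharide_children(
            branched_mannose.root_id)[0]
        frag = self._antenna()
        n = len(branched_mannose)
        branched_mannose.paste_subtree(arm, frag, linkage(1, 2))
        assert len(branched_mannose) == n + len(frag)

    def test_paste_on_occupied_position_conflicts(self, branched_mannose):
        frag = self._antenna()
        with pytest.raises(gf.AttachmentConflict):
            branched_mannose.paste_subtree(branched_mannose.root_id, frag,
                                           linkage(1, 3))

    def test_copy_is_deep(self, branched_mannose):
        arm = branched_mannose.monosaccharide_children(
            branched_mannose.root_id)[0]
        frag = branched_mannose.copy_subtree(arm)
        sig_before = node_signature(branched_mannose, arm)
        frag.update_node(frag.root_id, anomericity=gf.Anomer.BETA)
        frag.add_substituent(frag.root_id, gf.substituent("sulfate"), 4)
        assert node_signature(branched_mannose, arm) == sig_before

    def test_delete_paste_roundtrip_is_isomorphic(self, branched_mannose):
        reference = branched_mannose.copy()
        arm = sorted(branched_mannose.monosaccharide_children(
            branched_mannose.root_id))[0]
        link = branched_mannose.linkage_of(arm)
        frag = branched_mannose.copy_subtree(arm)
        branched_mannose.remove_subtree(arm)
        branched_mannose.paste_subtree(branched_mannose.root_id, frag, link)
        assert gf.isomorphic(branched_mannose, reference)


class TestRepeatUnits:
    def _unit(self, lo, hi):
        inner = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
        return RepeatUnit(None, inner, lo, hi, linkage(1, 4))

    def test_repeat_is_single_host_node(self, lactose):
        n = len(lactose)
        lactose.add_repeat_unit(lactose.root_id, self._unit(2, 5),
                                linkage(1, 3))
        assert len(lactose) == n + 1

    def test_count_bounds_validated(self):
        with pytest.raises(gf.StructureError):
            self._unit(5, 2)
        with pytest.raises(gf.StructureError):
            self._unit(0, 2)

    def test_unknown_counts_allowed_but_fuzzy(self, lactose):
        lactose.add_repeat_unit(lactose.root_id,
                                self._unit(gf.UNKNOWN, gf.UNKNOWN),
                                linkage(1, 3))
        assert not lactose.is_fully_defined()


class TestFullyDefined:
    def test_lactose_is_fully_defined(self, lactose):
        assert lactose.is_fully_defined()

    def test_alternative_positions_are_fuzzy(self, lactose):
        lactose.add_monosaccharide(
            lactose.root_id, gf.monosaccharide("Fuc", gf.Anomer.ALPHA),
            linkage(1, frozenset({3, 6})))
        assert not lactose.is_fully_defined()

    @pytest.mark.parametrize("field,value", [
        ("anomericity", gf.Anomer.UNDETERMINED),
        ("ring", gf.RingForm.UNDETERMINED),
        ("absolute_config", gf.Config.UNDETERMINED),
    ])
    def test_undetermined_node_fields_are_fuzzy(self, lactose, field, value):
        lactose.update_node(lactose.root_id, **{field: value})
        assert not lactose.is_fully_defined()


def test_editing_leaves_sibling_subtrees_untouched(branched_mannose):
    arms = branched_mannose.monosaccharide_children(branched_mannose.root_id)
    sig = node_signature(branched_mannose, arms[1])
    branched_mannose.add_monosaccharide(
        arms[0], gf.monosaccharide("Gal", gf.Anomer.BETA), linkage(1, 2))
    branched_mannose.update_node(arms[0], anomericity=gf.Anomer.BETA)
    assert node_signature(branched_mannose, arms[1]) == sig
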