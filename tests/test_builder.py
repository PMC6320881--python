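"""Quick mode, validity rules, template catalog, random generator."""

import inspect

import pytest

import glycoforge as gf
from glycoforge.builder import (
    generate_random_glycan, infer_donor_position, list_templates,
    load_template, quick_add, quick_palette, validate,
)
from glycoforge.model import linkage


class TestPalette:
    def test_twelve_entries(self):
        assert len(quick_palette()) == 12

    def test_entries_unique_and_ordered(self):
        names = [e.display_name for e in quick_palette()]
        assert len(set(names)) == 12
        assert names == [e.display_name for e in quick_palette()]

    def test_every_entry_expands_validly(self):
        for entry in quick_palette():
            g = entry.expand(gf.Anomer.BETA)
            assert validate(g) == []
            assert g.is_fully_defined()


class TestQuickAdd:
    def test_lactose_from_two_parameters(self):
        g = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
        leaf = quick_add(g, g.root_id, "Gal", gf.Anomer.BETA, 4)
        assert g.linkage_of(leaf).donor_position == 1   # aldose rule
        assert g.is_fully_defined() and validate(g) == []

    def test_sialic_acid_donates_c2(self):
        g = gf.create_glycan(gf.monosaccharide("Gal", gf.Anomer.BETA))
        leaf = quick_add(g, g.root_id, "Neu5Ac", gf.Anomer.ALPHA, 3)
        assert g.linkage_of(leaf).donor_position == 2   # ketose/ulosonate rule
        assert g.nodes[leaf].mtype.name == "Neu"
        assert len(g.substituent_children(leaf)) == 1

    def test_fucose_defaults_to_l_configuration(self):
        g = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
        leaf = quick_add(g, g.root_id, "Fuc", gf.Anomer.ALPHA, 3)
        assert g.nodes[leaf].absolute_config is gf.Config.L

    def test_occupied_position_blocks(self):
        g = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
        quick_add(g, g.root_id, "Gal", gf.Anomer.BETA, 4)
        with pytest.raises(gf.AttachmentConflict):
            quick_add(g, g.root_id, "Man", gf.Anomer.ALPHA, 4)

    def test_ring_carbons_block(self):
        g = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
        with pytest.raises(gf.AttachmentConflict):
            quick_add(g, g.root_id, "Gal", gf.Anomer.BETA, 5)

    def test_quick_mode_needs_exactly_two_chemistry_parameters(self):
        params = inspect.signature(quick_add).parameters
        chemistry = [p for p in params if p not in ("g", "parent_id", "entry")]
        assert chemistry == ["anomericity", "acceptor_position"]
        # normal mode takes a six-field residue + linkage description
        residue_fields = ("mtype", "anomericity", "ring", "absolute_config")
        link_fields = ("donor_position", "acceptor_positions")
        from glycoforge.model import GlycosidicLinkage, Monosaccharide
        assert all(f in Monosaccharide.__dataclass_fields__
                   for f in residue_fields)
        assert all(f in GlycosidicLinkage.__dataclass_fields__
                   for f in link_fields)


class TestInferDonor:
    @pytest.mark.parametrize("name,expected", [
        ("Glc", 1), ("Gal", 1), ("Fuc", 1), ("LDmanHep", 1),
        ("Neu", 2), ("Kdn", 2), ("Kdo", 2), ("Fru", 2),
    ])
    def test_aldose_vs_ketose(self, name, expected):
        assert infer_donor_position(name) == expected

    def test_consistent_with_vocabulary(self):
        for mtype in gf.MONOSACCHARIDES.values():
            assert infer_donor_position(mtype) == mtype.anomeric_carbon


class TestValidate:
    def test_lactose_clean(self, lactose):
        assert validate(lactose) == []

    def test_non_anomeric_donor_fires_r3(self):
        g = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
        g.add_monosaccharide(g.root_id,
                             gf.monosaccharide("Gal", gf.Anomer.BETA),
                             linkage(3, 4))
        assert [v.rule_id for v in validate(g)] == ["R3"]

    def test_substituent_glycoside_clash_fires_r5(self):
        g = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
        g.add_monosaccharide(g.root_id,
                             gf.monosaccharide("Gal", gf.Anomer.BETA),
                             linkage(1, 6))
        g.add_substituent(g.root_id, gf.substituent("sulfate"), 6)
        assert "R5" in [v.rule_id for v in validate(g)]

    def test_open_chain_anomer_fires_r4(self, lactose):
        lactose.update_node(lactose.root_id, ring=gf.RingForm.OPEN,
                            anomericity=gf.Anomer.OPEN)
        # force the inconsistent state through update rather than construction
        lactose.nodes[lactose.root_id].anomericity = gf.Anomer.ALPHA
        assert "R4" in [v.rule_id for v in validate(lactose)]

    def test_violations_are_data_not_exceptions(self):
        g = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
        g.add_monosaccharide(g.root_id,
                             gf.monosaccharide("Gal", gf.Anomer.BETA),
                             linkage(3, 4))
        (v,) = validate(g)
        assert v.rule_id == "R3" and v.node_ids and v.message


class TestTemplates:
    def test_catalog_contains_core_fucosylated_n_core(self):
        assert "N-core-fucosylated" in list_templates()

    def test_n_core_is_man3glcnac2(self):
        g = load_template("N-core")
        residues = [n for n in g.nodes.values()
                    if isinstance(n, gf.Monosaccharide)]
        assert len(residues) == 5
        names = sorted(n.mtype.name for n in residues)
        assert names == ["GlcN", "GlcN", "Man", "Man", "Man"]
        assert g.nodes[g.root_id].mtype.name == "GlcN"

    def test_o_core_1_is_gal_b3_galnac(self):
        g = load_template("O-core-1")
        root = g.nodes[g.root_id]
        assert root.mtype.name == "GalN"
        (leaf,) = g.monosaccharide_children(g.root_id)
        assert g.nodes[leaf].mtype.name == "Gal"
        assert g.linkage_of(leaf).stated_acceptor == 3

    def test_unknown_name_raises(self):
        with pytest.raises(gf.CatalogError):
            load_template("Z-core")

    def test_loaded_templates_are_mutation_safe(self):
        a = load_template("N-core")
        a.remove_subtree(a.root_id)
        b = load_template("N-core")
        assert len(b) == 7

    def test_all_templates_sound(self):
        for name in list_templates():
            g = load_template(name)
            assert g.is_fully_defined(), name
            assert validate(g) == [], name
            text = gf.write_glycoct(g)
            assert gf.write_glycoct(gf.parse_glycoct(text)) == text, name
            layout = gf.layout_glycan(g)
            cells = list(layout.cells.values())
            assert len(cells) == len(set(cells)), name


class TestRandomGenerator:
    def test_fuzz_zero_is_fully_defined_and_valid(self):
        g = generate_random_glycan(1, 10, 0.0)
        assert len(g) == 10
        assert g.is_fully_defined()
        assert validate(g) == []

    def test_deterministic_per_seed(self):
        a = gf.write_glycoct(generate_random_glycan(42, 15, 0.3))
        b = gf.write_glycoct(generate_random_glycan(42, 15, 0.3))
        assert a == b

    def test_full_fuzz_is_never_fully_defined(self):
        for seed in range(10):
            assert not generate_random_glycan(seed, 10, 1.0).is_fully_defined()

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            generate_random_glycan(1, 0)
        with pytest.raises(ValueError):
            generate_random_glycan(1, 5, 1.5)
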