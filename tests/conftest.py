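import pytest

import glycoforge as gf
from glycoforge.model import linkage


@pytest.fixture
def lactose():
    """Gal-(b1->4)-Glc, fully defined."""
    g = gf.create_glycan(gf.monosaccharide("Glc", gf.Anomer.BETA))
    g.add_monosaccharide(g.root_id,
                         gf.monosaccharide("Gal", gf.Anomer.BETA),
                         linkage(1, 4))
    return g


@pytest.fixture
def glcnac():
    """Single GlcNAc: GlcN residue + n-acetyl at C2."""
    g = gf.create_glycan(gf.monosaccharide("GlcN", gf.Anomer.BETA))
    g.add_substituent(g.root_id, gf.substituent("n-acetyl"), 2)
    return g


@pytest.fixture
def branched_mannose():
    """Man core carrying a 3-arm and a 6-arm (the N-glycan branch motif)."""
    g = gf.create_glycan(gf.monosaccharide("Man", gf.Anomer.BETA))
    g.add_monosaccharide(g.root_id, gf.monosaccharide("Man", gf.Anomer.ALPHA),
                         linkage(1, 3))
    g.add_monosaccharide(g.root_id, gf.monosaccharide("Man", gf.Anomer.ALPHA),
                         linkage(1, 6))
    return g


def corpus(n=500, max_nodes=40, fuzzes=(0.0, 0.3), base_seed=20_000):
    """Seeded random corpus shared by property and acceptance tests."""
    per_fuzz = n // len(fuzzes)
    for k, fuzz in enumerate(fuzzes):
        for i in range(per_fuzz):
            seed = base_seed + 1000 * k + i
            size = 1 + (i * 7) % max_nodes
            yield gf.generate_random_glycan(seed, size, fuzz)


@pytest.fixture(scope="session")
def small_corpus():
    return list(corpus(n=60, base_seed=777))
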