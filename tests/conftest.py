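import pytest
from hypothesis import settings

from metatrx import TaxonomyTree, generate_community, generate_taxonomy

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_tree() -> TaxonomyTree:
    """Hand-built two-phylum tree with named ranks for LCA tests.

    root(1) - Bacteria(2)
      Phylum_A(3) - Class_A(4) - Order_A(5) - Fam_A(6)
          Genus_A1(7) - sp_A1a(8), sp_A1b(9)
          Genus_A2(10) - sp_A2a(11)
      Phylum_B(12) - Class_B(13) - Order_B(14) - Fam_B(15)
          Genus_B1(16) - sp_B1a(17)
    """
    t = TaxonomyTree()
    t.add_node(1, 1, "no rank", "root")
    t.add_node(2, 1, "domain", "Bacteria")
    t.add_node(3, 2, "phylum", "Phylum_A")
    t.add_node(4, 3, "class", "Class_A")
    t.add_node(5, 4, "order", "Order_A")
    t.add_node(6, 5, "family", "Fam_A")
    t.add_node(7, 6, "genus", "Genus_A1")
    t.add_node(8, 7, "species", "sp_A1a")
    t.add_node(9, 7, "species", "sp_A1b")
    t.add_node(10, 6, "genus", "Genus_A2")
    t.add_node(11, 10, "species", "sp_A2a")
    t.add_node(12, 2, "phylum", "Phylum_B")
    t.add_node(13, 12, "class", "Class_B")
    t.add_node(14, 13, "order", "Order_B")
    t.add_node(15, 14, "family", "Fam_B")
    t.add_node(16, 15, "genus", "Genus_B1")
    t.add_node(17, 16, "species", "sp_B1a")
    t.validate()
    return t


@pytest.fixture(scope="session")
def demo_community():
    """A small 4-taxon community reused across module tests."""
    tree = generate_taxonomy(4, 2, seed=11)
    truth = generate_community(tree, 4, dominance=0.4, expression_sigma=0.8, seed=11)
    return tree, truth
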