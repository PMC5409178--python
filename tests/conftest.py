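import numpy as np
import pytest

from dupfit import phylo, presets, simulate


@pytest.fixture(scope="session")
def two_leaf_model():
    return phylo.PhyloModel(phylo.read_tree("(a:0.5,b:0.5);", from_string=True))


@pytest.fixture(scope="session")
def three_leaf_model():
    return phylo.PhyloModel(
        phylo.read_tree("((a:0.3,b:0.4):0.2,c:0.5);", from_string=True)
    )


#: 8-taxon tree with a flagged post-duplication clade, used by LRT tests
DUP_TREE = (
    "((pre1:0.3,pre2:0.3):0.2,((a1:0.2,a2:0.2):0.2,"
    "((b1:0.15,b2:0.15):0.1,(b3:0.15,b4:0.15):0.1)DUP:0.2):0.2);"
)

#: 4-taxon tree of root-to-tip depth ~1 subst/site, for decode recovery
DEPTH1_TREE = "((a:0.5,b:0.5):0.5,(c:0.5,d:0.5):0.5);"


@pytest.fixture(scope="session")
def dup_model():
    return phylo.PhyloModel(phylo.read_tree(DUP_TREE, from_string=True))


@pytest.fixture(scope="session")
def screen_fixture():
    """One simulated three-class screen plus its generative truth."""
    genos = presets.reconstructed_genotypes()
    design = simulate.ScreenDesign.all_by_all([g.label for g in genos])
    counts = simulate.simulate_screen(
        design,
        presets.class_assignment(genos),
        simulate.SimCompetitionConfig(
            bio_sd=simulate.calibrated_bio_sd(), seed=20260
        ),
    )
    truth = {g.label: presets.true_fitness_class(g) for g in genos}
    return genos, counts, truth
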