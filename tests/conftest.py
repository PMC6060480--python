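import numpy as np
import pytest

from massmap.data import AbundanceMatrix, PhyloTree, TaxonomyMap, TraitData, parse_lineage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_taxonomy():
    lin = {
        "t1": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Lachnospiraceae; g__Blautia; s__producta",
        "t2": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Lachnospiraceae; g__Dorea; s__formicigenerans",
        "t3": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Ruminococcaceae; g__Oscillospira; s__",
        "t4": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Prevotellaceae; g__Prevotella; s__stercorea",
        "t5": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__; g__; s__",
    }
    return TaxonomyMap({t: parse_lineage(s) for t, s in lin.items()})


@pytest.fixture
def toy_abundance():
    values = np.array(
        [
            [5, 3, 1, 1, 0],
            [2, 2, 4, 1, 1],
            [0, 1, 3, 5, 1],
            [1, 0, 2, 6, 1],
        ],
        dtype=float,
    )
    values = values / values.sum(axis=1, keepdims=True)
    return AbundanceMatrix(
        sample_ids=[f"s{i}" for i in range(1, 5)],
        taxon_ids=["t1", "t2", "t3", "t4", "t5"],
        values=values,
    )


@pytest.fixture
def toy_tree():
    return PhyloTree.from_newick(
        "(((t1:0.1,t2:0.2):0.3,t3:0.5):0.2,(t4:0.4,t5:0.3):0.6);"
    )


@pytest.fixture
def continuous_trait(rng):
    n = 30
    X = rng.normal(size=(n, 2))
    y = 0.5 + X @ np.array([1.0, -0.5]) + rng.normal(size=n)
    return TraitData(y=y, X=X, trait_type="continuous")


@pytest.fixture
def binary_trait(rng):
    n = 40
    y = np.zeros(n)
    y[: n // 2] = 1
    rng.shuffle(y)
    return TraitData(y=y, X=rng.normal(size=(n, 1)), trait_type="binary")
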