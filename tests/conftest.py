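import numpy as np
import pandas as pd
import pytest

from evoexpr.io_formats import parse_species_tree
from evoexpr.synthetic import SynthConfig, synth_study
from evoexpr.types import Domain, GeneRecord


@pytest.fixture(scope="session")
def toy_tree():
    return parse_species_tree("((A,B)AB,(C,D)CD)Root;")


@pytest.fixture
def kzfp_record():
    """KRAB at [1,70], two fingers [101,128] and [129,156], length 200."""
    return GeneRecord(
        gene_id="gK",
        species="sp01",
        protein_id="pK",
        protein_length=200,
        domains=[
            Domain("KRAB", 1, 70, is_krab=True),
            Domain("zf-C2H2", 101, 128, is_c2h2=True),
            Domain("zf-C2H2", 129, 156, is_c2h2=True),
        ],
    )


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down synthetic study shared by the slower integration tests."""
    cfg = SynthConfig(seed=11, n_genes=800, module_sizes=(160, 160, 160))
    tree, records, tracks, ages, datasets, truth = synth_study(cfg)
    return {
        "cfg": cfg,
        "tree": tree,
        "records": records,
        "tracks": tracks,
        "ages": ages,
        "datasets": datasets,
        "truth": truth,
    }


def random_named_tree(rng: np.random.Generator, n_leaves: int):
    """Random rooted tree over sp1..spN with named internal nodes."""
    counter = [0]

    def build(leaves):
        if len(leaves) == 1:
            return leaves[0]
        k = int(rng.integers(1, len(leaves)))
        counter[0] += 1
        my_id = counter[0]
        return f"({build(leaves[:k])},{build(leaves[k:])})N{my_id}"

    leaves = [f"sp{i}" for i in range(1, n_leaves + 1)]
    rng.shuffle(leaves)
    return parse_species_tree(build(leaves) + ";")


def oracle_mrca(tree, species):
    """Independent MRCA: deepest node common to every root path."""
    paths = [tree.root_path(s) for s in species]
    common = set(paths[0]).intersection(*[set(p) for p in paths[1:]])
    return max(common, key=lambda name: tree.rank_index[name])
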