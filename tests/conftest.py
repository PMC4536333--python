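import numpy as np
import pytest
from hypothesis import settings

from balaena.trees import PhyloTree

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def six_taxon_tree():
    tree = PhyloTree.from_newick(
        "((A:0.2,B:0.2):0.1,(C:0.15,(D:0.1,(E:0.05,F:0.05):0.05):0.05):0.1);"
    )
    return tree


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A small synthetic study bundle shared by pipeline-level tests."""
    from balaena.simulate import write_bundle

    out = tmp_path_factory.mktemp("bundle")
    write_bundle(out, seed=5, n_codons=120, n_background_families=3)
    return out
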