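from __future__ import annotations

import dendropy
import numpy as np
import pytest

from sagpop.trees import IndexedTree, index_tree


def tree_from_newick(nwk: str) -> IndexedTree:
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    tree.is_rooted = True
    return index_tree(tree)


@pytest.fixture
def quartet() -> IndexedTree:
    """((A,B),(C,D)) with unit branch lengths."""
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130)
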