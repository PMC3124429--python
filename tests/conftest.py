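import numpy as np
import pytest

from phylofold.family_io import Alignment, SequenceRecord
from phylofold.substmodel import jtt_model
from phylofold.synthetic_data import default_species_tree
from phylofold.treeutils import PhyloTree


@pytest.fixture(scope="session")
def model():
    return jtt_model()


@pytest.fixture(scope="session")
def species8():
    return default_species_tree()


@pytest.fixture
def quartet_tree():
    """Rooted 4-tip tree with fixed branch lengths used by the ASR oracles."""
    return PhyloTree.from_newick(
        "((A:0.1,B:0.2):0.1,(C:0.3,D:0.4):0.1);", rooted=True
    )


@pytest.fixture
def toy_alignment():
    return Alignment(
        [
            SequenceRecord(id="s1_HUMAN", residues="WWLAK", species="HUMAN"),
            SequenceRecord(id="s2_MOUSE", residues="WWLAK", species="MOUSE"),
            SequenceRecord(id="s3_CHICK", residues="WLIAK", species="CHICK"),
            SequenceRecord(id="s4_RAJEG", residues="WL-AK", species="RAJEG"),
        ]
    )


def path_distance_matrix(tree: PhyloTree):
    """Leaf-to-leaf path lengths (the additivity oracle for NJ)."""
    leaves = tree.root.leaves()
    labels = [l.label for l in leaves]

    def ancestors(n):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa = ancestors(leaves[i])
            pb = ancestors(leaves[j])
            common = next(x for x in pa if x in pb)
            dist = 0.0
            for node in pa:
                if node is common:
                    break
                dist += node.length or 0.0
            for node in pb:
                if node is common:
                    break
                dist += node.length or 0.0
            d[i, j] = d[j, i] = dist
    return labels, d
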