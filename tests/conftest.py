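import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from stregnet.io import CountMatrix, GeneAnnotation


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """2 spots x 3 genes with two nonzero entries."""
    counts = np.array([[5, 0, 0], [0, 0, 2]])
    return CountMatrix(sp.csr_matrix(counts), ["b1", "b2"], ["g1", "g2", "g3"])


@pytest.fixture
def simple_annotation() -> GeneAnnotation:
    table = pd.DataFrame(
        {
            "symbol": ["ANR", "GGT2", "TCP4", "MYB1"],
            "is_tf": [False, False, True, True],
            "tf_family": ["", "", "TCP", "MYB"],
            "pathway_tags": [{"catechin_synthesis"}, {"theanine_hydrolysis"}, set(), set()],
            "term_ids": [{"T1"}, {"T1", "T2"}, {"T2"}, set()],
        },
        index=pd.Index(["gA", "gB", "tfA", "tfB"], name="gene_id"),
    )
    return GeneAnnotation(table)


@pytest.fixture(scope="session")
def demo_results():
    """One full pipeline run on the default synthetic screen, shared
    across tests that only need to inspect its outputs."""
    from stregnet.pipeline import demo

    return demo(seed=1)
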