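import numpy as np
import pytest
import scipy.sparse as sp

from nichecompare import (
    CellAnnotation,
    CountMatrix,
    SyntheticConfig,
    generate_dataset,
    normalize,
    filter_genes,
)
import pandas as pd


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down two-niche design used across module tests."""
    return SyntheticConfig(seed=11, n_genes=600, cells_per_group=40)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    mat, ann, truth = small_dataset
    norm = normalize(filter_genes(mat))
    return norm, ann.reindex(norm.cells), truth


@pytest.fixture()
def toy_matrix():
    """3 genes x 4 cells with simple hand-checkable counts."""
    counts = np.array(
        [
            [3, 0, 1, 2],
            [1, 2, 0, 0],
            [0, 2, 3, 2],
        ]
    )
    return CountMatrix(
        genes=["gA", "gB", "gC"],
        cells=["c1", "c2", "c3", "c4"],
        counts=sp.csr_matrix(counts),
    )


@pytest.fixture()
def toy_annotation():
    t = pd.DataFrame(
        {
            "niche": ["V-SVZ", "V-SVZ", "SGZ", "SGZ"],
            "age_label": ["E14.5", "P0", "P20", "P60"],
            "age_days": [-5, 0, 20, 60],
            "group": ["emb", "emb", "adult", "adult"],
            "batch": ["b1", "b1", "b2", "b2"],
        },
        index=pd.Index(["c1", "c2", "c3", "c4"], name="cell"),
    )
    return CellAnnotation(t)
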