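import numpy as np
import pandas as pd
import pytest

from stressmeta.diffexpr import DEResult
from stressmeta.simulate import ExpressionDataset, SimConfig


@pytest.fixture
def single_counts_config():
    """One counts dataset, one stressed timepoint, 5 replicates."""
    def make(seed=0, **kw):
        defaults = dict(
            n_datasets=1, species_tags=("dmel",), platforms=("counts",),
            timepoints=((6.0,),), n_replicates=5, shared_truth_groups=(),
            seed=seed,
        )
        defaults.update(kw)
        return SimConfig(**defaults)
    return make


@pytest.fixture
def tiny_counts_dataset():
    """Hand-built 4-gene, 2x2-sample counts dataset."""
    samples = pd.DataFrame(
        {
            "genotype": ["control"] * 4,
            "condition": ["baseline", "baseline", "stressed", "stressed"],
            "timepoint": [0.0, 0.0, 6.0, 6.0],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    matrix = pd.DataFrame(
        [[10, 10, 10, 10], [20, 20, 20, 20], [5, 6, 40, 44], [100, 90, 95, 105]],
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
        columns=samples.index,
    )
    return ExpressionDataset(name="tiny", matrix=matrix, samples=samples,
                             platform="counts", species="dmel")


def make_de_result(log2fc, p=None, p_adj=None, mode="count_test",
                   contrast="c", meta=None):
    """Build a DEResult from plain vectors for classification tests."""
    genes = [f"g{i}" for i in range(len(log2fc))]
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.zeros_like(log2fc) if p is None else np.asarray(p, dtype=float)
    if p_adj is None:
        p_adj = p
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adj": np.asarray(p_adj, dtype=float)},
        index=pd.Index(genes, name="gene_id"),
    )
    return DEResult(contrast=contrast, mode=mode, table=table, meta=meta or {})
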