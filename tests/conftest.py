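import numpy as np
import pandas as pd
import pytest

from metatree import EffectSizeSet, SubgroupPartition


@pytest.fixture
def toy4():
    """Four studies, equal variances, one perfectly separating binary."""
    return EffectSizeSet(
        d=[0.1, 0.2, 0.6, 0.7], var=[0.04] * 4,
        X=pd.DataFrame({"x1": [0, 0, 1, 1], "x2": [1, 0, 1, 0]}),
        types={"x1": "binary", "x2": "binary"},
    )


@pytest.fixture
def pair():
    """Two studies d = 0, 1 with variance 0.04 (DL tau2 = 0.46)."""
    return EffectSizeSet(
        d=[0.0, 1.0], var=[0.04, 0.04],
        X=pd.DataFrame({"x1": [0, 1]}), types={"x1": "binary"},
    )


def random_dataset(seed, K=12, M=3, mtype="continuous"):
    """Small random dataset for oracle comparisons."""
    from metatree import SimDesign, gen_dataset
    design = SimDesign(K=K, nbar=40, tau2=0.025, deltaI=0.5, M=M,
                       mtype=mtype, correlated=False, model="B")
    data, truth = gen_dataset(design, seed)
    return data, truth


def one_group(data):
    return SubgroupPartition(
        assignment=np.zeros(data.K, dtype=np.int64), J=1)
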