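import numpy as np
import pytest

import psrsm
from psrsm.partition import PartitionScheme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_bin():
    """A small, strongly separable single-bin dataset (train, holdout)."""
    cfg = psrsm.SyntheticConfig(
        n_proteins=50,
        length_ranges=((40, 80),),
        length_weights=(1.0,),
        class_means=psrsm.separated_class_means(3.0),
        seed=99,
    )
    records = psrsm.generate_dataset(cfg)
    return records[:40], records[40:]


@pytest.fixture(scope="session")
def two_bin_model():
    """A trained 2-bin model plus its held-out proteins."""
    cfg = psrsm.SyntheticConfig(
        n_proteins=80,
        length_ranges=((30, 100), (101, 200)),
        length_weights=(1.0, 1.0),
        class_means=psrsm.separated_class_means(3.0),
        seed=7,
    )
    records = psrsm.generate_dataset(cfg)
    train, test = records[:64], records[64:]
    model = psrsm.train_psrsm(train, scheme=PartitionScheme((100.0,)),
                              t=4, r=80, residue_cap=600, seed=3)
    return model, train, test
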