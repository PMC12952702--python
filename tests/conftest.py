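import numpy as np
import pytest

from idrscope import SimConfig, call_regions, simulate_dataset, type_regions
from idrscope.regions import disorder_mask


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (seed 0), shared across tests."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def called_regions(default_dataset):
    """Regions called at the default threshold on the default dataset."""
    ds = default_dataset
    return {rec.id: call_regions(ds.disorder_profiles[rec.id],
                                 threshold=0.5, min_len=1, max_gap=0,
                                 sequence_length=len(rec))
            for rec in ds.records}


@pytest.fixture(scope="session")
def typed_regions(default_dataset, called_regions):
    ds = default_dataset
    return {rec.id: type_regions(rec, called_regions[rec.id],
                                 ss=ds.ss_profiles[rec.id])
            for rec in ds.records}


def truth_mask(ds, pid, length):
    return disorder_mask(
        [r for r in ds.truth.regions if r.protein_id == pid], length)
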