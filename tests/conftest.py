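import pytest

import cuecomp as cc


@pytest.fixture(scope="session")
def designs():
    return {eid: cc.load_design(eid) for eid in cc.EXPERIMENT_IDS}


@pytest.fixture(scope="session")
def default_params():
    return cc.agency_params(), cc.passive_params()


@pytest.fixture(scope="session")
def exp1_dataset():
    """One synthetic exp1 dataset at default (biased vs unbiased) params."""
    return cc.generate_dataset(
        cc.load_design("exp1_blocking"),
        cc.agency_params(),
        cc.passive_params(),
        n_pairs=8,
        seed=11,
    )
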