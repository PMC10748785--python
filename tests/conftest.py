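import pytest

from vcbench.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """A compact but fully featured synthetic study (all error classes)."""
    return SimConfig(seed=11, region_length=6000, n_snv=12, n_ins=6, n_del=6,
                     depth_mean=60.0, depth_dispersion=5.0)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_cfg):
    out = tmp_path_factory.mktemp("smalldata")
    return generate_dataset(small_cfg, out)


@pytest.fixture(scope="session")
def identity_cfg():
    """No injected errors: query and truth describe the same callset."""
    return SimConfig(seed=5, region_length=6000, n_snv=12, n_ins=6, n_del=6,
                     depth_mean=60.0, depth_dispersion=5.0,
                     fp_rate=0.0, bfn_rate=0.0, seqfn_rate=0.0,
                     symbolic_rate=0.0)


@pytest.fixture(scope="session")
def identity_dataset(tmp_path_factory, identity_cfg):
    out = tmp_path_factory.mktemp("identdata")
    return generate_dataset(identity_cfg, out)
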