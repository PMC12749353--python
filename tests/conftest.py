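import numpy as np
import pytest

from qsvar.pipeline import RunConfig
from qsvar.synthetic_data import SimConfig, gen_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small two-arm synthetic study bundle shared across pipeline tests."""
    out = tmp_path_factory.mktemp("bundle")
    config = SimConfig(seed=11, n_orthogroups=8, n_tips_max=24)
    manifest = gen_study(config, out)
    return out, config, manifest


@pytest.fixture
def run_config(small_bundle, tmp_path):
    bundle_dir, _, _ = small_bundle
    return RunConfig(input_dir=str(bundle_dir), output_dir=str(tmp_path / "out"))
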