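import numpy as np
import pytest

from hmblocks.pipeline import RunConfig, RunContext, stage_features, stage_regions
from hmblocks.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One seed-fixed bundle under the default study conditions."""
    return simulate_bundle(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_ctx(default_bundle, tmp_path_factory):
    """Run context with regions and features computed once for the session."""
    out = tmp_path_factory.mktemp("ctx")
    cfg = RunConfig(outdir=out, sim=SimConfig(seed=1), seed=1)
    ctx = RunContext(cfg)
    ctx._bundle = default_bundle
    stage_regions(ctx)
    stage_features(ctx)
    return ctx


@pytest.fixture(scope="session")
def chromatin_bundle():
    """Larger-block conditions used for the Hi-C / TAD analyses."""
    return simulate_bundle(SimConfig.chromatin(seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
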