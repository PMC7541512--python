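import numpy as np
import pytest

from rangecast import (
    EnvStack,
    GridSpec,
    LandscapeConfig,
    Layer,
    demo_config,
    make_landscape,
    run_pipeline,
)


@pytest.fixture
def spec10():
    return GridSpec(10, 10, x_origin=0.0, y_origin=0.0, cellsize=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_layer(spec10, rng):
    return Layer(spec10, "noise", rng.normal(size=spec10.shape))


@pytest.fixture
def landscape():
    """Small synthetic landscape reused across tests."""
    cfg = LandscapeConfig(spec=GridSpec(40, 40, cellsize=1000.0), seed=7)
    return make_landscape(cfg)


def make_stack(spec, arrays: dict) -> EnvStack:
    stack = EnvStack(spec)
    for name, vals in arrays.items():
        stack.add(Layer(spec, name, np.asarray(vals, dtype=float)))
    return stack


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One shared execution of the shipped 50x50 two-species demo pipeline."""
    out = tmp_path_factory.mktemp("demo")
    config = demo_config(output_dir=str(out), master_seed=1)
    manifest = run_pipeline(config)
    return config, manifest, out
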