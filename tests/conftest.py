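import numpy as np
import pytest

from predisp import (
    InversionConfig,
    SceneConfig,
    default_generator,
    measure_interp_bound,
    render_sequence,
)
from predisp.bench import BenchConfig, run_benchmark


@pytest.fixture(scope="session")
def scene_cfg():
    """Small noiseless scene used by most unit tests."""
    return SceneConfig(sigma=0.0, n_frames=20, seed=11)


@pytest.fixture(scope="session")
def gen(scene_cfg):
    return default_generator(scene_cfg)


@pytest.fixture(scope="session")
def noiseless_ds(scene_cfg, gen):
    return render_sequence(scene_cfg, gen)


@pytest.fixture(scope="session")
def eps_interp(scene_cfg, gen):
    """Calibrated interpolation-noise bound of the noiseless fixture."""
    return measure_interp_bound(scene_cfg, gen, n_frames=20)


@pytest.fixture(scope="session")
def inv_cfg(eps_interp):
    return InversionConfig(epsilon=2.0 * eps_interp)


@pytest.fixture(scope="session")
def benchmark_run():
    """The full trained benchmark (Stage-2 training + held-out comparison).

    Expensive (several minutes); shared by every test that needs trained
    predictors.
    """
    cfg = BenchConfig(base_seed=0)
    table, results, state, failures = run_benchmark(cfg)
    assert not failures, f"benchmark strategies failed: {failures}"
    return {"config": cfg, "table": table, "results": results, "state": state}
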