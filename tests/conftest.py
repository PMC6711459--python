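import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dcmfmri as d
from dcmfmri.model import ModelSpec, ParameterSet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fig3_spec():
    """Four-region, three-condition blocked factorial architecture."""
    return d.default_spec()


def make_two_region_spec(with_modulation: bool, n_confounds: int = 1) -> ModelSpec:
    b = np.zeros((2, 2, 2), dtype=int)
    if with_modulation:
        b[1] = np.eye(2, dtype=int)
    return ModelSpec(
        region_names=["r1", "r2"],
        condition_names=["drive", "ctx"],
        a_mask=np.ones((2, 2), dtype=int),
        b_masks=b,
        c_mask=np.array([[1, 0], [1, 0]]),
        TR=2.0,
        TE=0.03,
        n_confounds=n_confounds,
    )


def two_region_inputs(n_volumes: int = 100, TR: float = 2.0):
    total = n_volumes * TR
    onsets = tuple(np.arange(10.0, total - 20.0, 16.0))
    timings = [
        d.ConditionTiming("drive", onsets, tuple(0.0 for _ in onsets)),
        d.ConditionTiming("ctx", (40.0, 120.0), (40.0, 40.0)),
    ]
    return d.mean_centre(d.build_input_matrix(timings, total, TR / 16))


@pytest.fixture(scope="session")
def two_region_fit():
    """A small fitted model on data simulated from itself (shared, ~10 s)."""
    spec = make_two_region_spec(False)
    V = 100
    U = two_region_inputs(V)
    truth = ParameterSet.zeros(spec)
    truth.a[0, 1] = -0.2
    truth.a[1, 0] = 0.3
    truth.c[:, 0] = [0.3, 0.25]
    pred = d.integrate_model(truth, spec, U, V)
    rng = np.random.default_rng(0)
    Y = pred.y_hat + rng.standard_normal(pred.y_hat.shape) * 0.05
    data = d.Dataset(U=U, Y=Y, TR=spec.TR, slice_times=spec.slice_times)
    result = d.fit(spec, data)
    return spec, data, truth, result


@pytest.fixture(scope="session")
def recovery_fit():
    """Full-size parameter-recovery fit: 4 regions, V=200, SNR 1 (shared, ~40 s)."""
    cfg = d.SyntheticConfig(seed=42, snr=1.0, n_volumes=200)
    data, truth = d.generate_dataset(cfg)
    result = d.fit(cfg.spec, data)
    return cfg, data, truth, result
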