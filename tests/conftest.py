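import numpy as np
import pytest

from oxicam import SpO2Model, default_table
from oxicam.synth import SceneConfig, simulate


@pytest.fixture(scope="session")
def table():
    return default_table()


def clean_scene(**overrides) -> SceneConfig:
    """A noise-free, nuisance-free scene at constant SpO2 (deep layer only)."""
    base = dict(
        shallow_gain=0.0,
        motion_std=0.0,
        ambient=0.0,
        noise_sd=0.0,
        dip_depth=0.0,
        duration_s=60.0,
    )
    base.update(overrides)
    return SceneConfig(**base)


def fit_values(record, method, **model_kwargs):
    """Unclipped per-window estimates of one method on a record."""
    model_kwargs.setdefault("clip", False)
    res = SpO2Model(record.traces, method=method, **model_kwargs).fit()
    return res.raw_values


def record_rmse(record, method) -> float:
    res = SpO2Model(record.traces, method=method).fit()
    return res.evaluate(record.truth).rmse
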