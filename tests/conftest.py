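import numpy as np
import pytest

from enose_stl.simulate import (
    BASELINE_END_S,
    EXPOSURE_END_S,
    TOTAL_S,
    ResponseCurve,
    SimConfig,
)


def make_curve(signal: np.ndarray, sample_id: str = "analytic", label=1) -> ResponseCurve:
    """Wrap a [T] or [T x S] array on the standard 1 Hz grid as a curve."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = signal[:, None]
    t = np.arange(signal.shape[0], dtype=float)
    return ResponseCurve(sample_id=sample_id, timestamps=t, readings=signal, label=label)


def plateau_curve(baseline: float, height: float) -> ResponseCurve:
    """Baseline everywhere, baseline+height during the exposure phase."""
    t = np.arange(TOTAL_S + 1)
    sig = np.full(t.size, baseline)
    sig[(t >= BASELINE_END_S) & (t <= EXPOSURE_END_S)] = baseline + height
    return make_curve(sig)


@pytest.fixture
def noiseless_sim() -> SimConfig:
    return SimConfig(noise_sd=0.0, seed=0)


@pytest.fixture
def small_sim() -> SimConfig:
    """Reduced pool sizes for fast end-to-end tests."""
    return SimConfig(noise_sd=0.02, n_unlabeled_per_gas=(25, 25, 25, 25), seed=0)
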