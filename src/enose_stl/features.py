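"""Per-sensor feature extraction and dataset normalization.

Five scalar features are computed per sensor from a baseline-subtracted
response curve: steady-state maximum, maximum rising slope (exposure),
maximum falling slope (recovery), trapezoidal integral of the exposure
phase, and the maximum absolute detail coefficient of a discrete wavelet
transform.  An ``n x n`` matrix (n features x n sensors, n in {3,4,5}) is
flattened row-major into a feature vector x in R^(n^2); datasets are
min-max normalized to [0,1], the input range a sigmoid autoencoder expects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pywt

from .simulate import UNLABELED, ResponseCurve

FEATURE_NAMES = ("steady_max", "rise_slope", "fall_slope", "integral", "wavelet")


@dataclass
class FeatureVector:
    """Flattened n x n feature-by-sensor matrix with its label."""

    values: np.ndarray  # length n^2
    n: int
    label: int | str = UNLABELED
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.n * self.n:
            raise ValueError(f"expected {self.n**2} values, got {self.values.size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def matrix(self) -> np.ndarray:
        """Row-major reshape back to the n x n feature-by-sensor matrix."""
        return self.values.reshape(self.n, self.n)


@dataclass(frozen=True)
class FeatureSpec:
    """Which features and sensors fill the n x n matrix, and wavelet settings."""

    feature_order: tuple[str, ...] = FEATURE_NAMES
    sensor_order: tuple[int, ...] = (0, 1, 2, 3, 4)
    wavelet_name: str = "db4"
    wavelet_level: int = 3

    def __post_init__(self) -> None:
        if len(self.feature_order) != len(self.sensor_order):
            raise ValueError("feature_order and sensor_order must have equal length")
        unknown = set(self.feature_order) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        if self.wavelet_level < 1:
            raise ValueError("wavelet_level must be >= 1")

    @property
    def n(self) -> int:
        return len(self.feature_order)

    @classmethod
    def for_dim(cls, n: int, **kwargs) -> "FeatureSpec":
        """Default spec for an n x n matrix: first n features, first n sensors."""
        if not 1 <= n <= len(FEATURE_NAMES):
            raise ValueError(f"n must be in 1..{len(FEATURE_NAMES)}")
        return cls(
            feature_order=FEATURE_NAMES[:n], sensor_order=tuple(range(n)), **kwargs
        )


def _phase_masks(curve: ResponseCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    b, e, total = curve.phase_bounds
    t = curve.timestamps
    return (t < b), (t >= b) & (t <= e), (t > e)


def baseline_level(curve: ResponseCurve, sensor: int) -> float:
    """Clean-air reference: mean of the last 60 s of the baseline phase.

    The early baseline may contain startup transients; the final minute is
    taken as the settled clean-air level.
    """
    b = curve.phase_bounds[0]
    window = (curve.timestamps >= b - 60.0) & (curve.timestamps < b)
    if not window.any():
        raise ValueError("empty baseline window")
    return float(curve.readings[window, sensor].mean())


def steady_state_max(curve: ResponseCurve, sensor: int) -> float:
    """Maximum baseline-subtracted response during the exposure phase."""
    _, exposure, _ = _phase_masks(curve)
    if not exposure.any():
        raise ValueError("empty exposure window")
    base = baseline_level(curve, sensor)
    return float((curve.readings[exposure, sensor] - base).max())


def max_rising_slope(curve: ResponseCurve, sensor: int) -> float:
    """Maximum forward first difference (per second) over the exposure phase."""
    _, exposure, _ = _phase_masks(curve)
    x = curve.readings[exposure, sensor]
    if x.size < 2:
        raise ValueError("exposure window too short for a slope")
    return float(np.diff(x).max())


def max_falling_slope(curve: ResponseCurve, sensor: int) -> float:
    """Largest-magnitude negative forward difference over recovery, as a
    positive number (0 if the recovery never falls).

    The window starts at the exposure-end sample so the initial drop of the
    falling edge is included.
    """
    x = curve.readings[curve.timestamps >= curve.phase_bounds[1], sensor]
    if x.size < 2:
        raise ValueError("recovery window too short for a slope")
    return float(max(0.0, -np.diff(x).min()))


def integral_feature(curve: ResponseCurve, sensor: int) -> float:
    """Trapezoidal integral of the baseline-subtracted exposure phase."""
    _, exposure, _ = _phase_masks(curve)
    if not exposure.any():
        raise ValueError("empty exposure window")
    base = baseline_level(curve, sensor)
    y = curve.readings[exposure, sensor] - base
    return float(np.trapezoid(y, curve.timestamps[exposure]))


def wavelet_feature(
    curve: ResponseCurve, sensor: int, spec: FeatureSpec | None = None
) -> float:
    """Maximum absolute detail coefficient of the DWT of the full
    baseline-subtracted signal at ``spec.wavelet_level``."""
    spec = spec or FeatureSpec()
    base = baseline_level(curve, sensor)
    signal = curve.readings[:, sensor] - base
    wavelet = pywt.Wavelet(spec.wavelet_name)
    max_level = pywt.dwt_max_level(signal.size, wavelet.dec_len)
    if spec.wavelet_level > max_level:
        raise ValueError(
            f"signal of length {signal.size} supports at most level {max_level} "
            f"for {spec.wavelet_name}, requested {spec.wavelet_level}"
        )
    coeffs = pywt.wavedec(signal, wavelet, level=spec.wavelet_level)
    detail = coeffs[1]  # detail coefficients at the requested (coarsest) level
    return float(np.abs(detail).max())


_FEATURE_FUNCS = {
    "steady_max": steady_state_max,
    "rise_slope": max_rising_slope,
    "fall_slope": max_falling_slope,
    "integral": integral_feature,
}


def build_feature_vector(curve: ResponseCurve, spec: FeatureSpec) -> FeatureVector:
    """Assemble M[i][j] = feature_order[i] applied to sensor_order[j] and
    flatten row-major."""
    n = spec.n
    if max(spec.sensor_order) >= curve.n_sensors:
        raise ValueError("sensor_order refers to a sensor the curve lacks")
    M = np.empty((n, n))
    for i, fname in enumerate(spec.feature_order):
        for j, sensor in enumerate(spec.sensor_order):
            if fname == "wavelet":
                M[i, j] = wavelet_feature(curve, sensor, spec)
            else:
                M[i, j] = _FEATURE_FUNCS[fname](curve, sensor)
    return FeatureVector(
        values=M.ravel(), n=n, label=curve.label, sample_id=curve.sample_id
    )


def extract_features(
    curves: Iterable[ResponseCurve], spec: FeatureSpec
) -> list[FeatureVector]:
    return [build_feature_vector(c, spec) for c in curves]


# ---------------------------------------------------------------------------
# normalization


class MinMaxScaler:
    """Per-coordinate affine map to [0,1]; constant coordinates map to 0."""

    def __init__(self) -> None:
        self.mins: np.ndarray | None = None
        self.maxs: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("fit requires a nonempty [n_samples x d] matrix")
        self.mins = X.min(axis=0)
        self.maxs = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mins is None or self.maxs is None:
            raise ValueError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        span = self.maxs - self.mins
        out = np.zeros_like(X)
        nonconstant = span > 0
        out[:, nonconstant] = (X[:, nonconstant] - self.mins[nonconstant]) / span[
            nonconstant
        ]
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"mins": list(self.mins), "maxs": list(self.maxs)}, indent=1
        )

    @classmethod
    def from_json(cls, text: str) -> "MinMaxScaler":
        payload = json.loads(text)
        scaler = cls()
        scaler.mins = np.asarray(payload["mins"], dtype=float)
        scaler.maxs = np.asarray(payload["maxs"], dtype=float)
        return scaler


def stack_values(vectors: Sequence[FeatureVector]) -> np.ndarray:
    """[n_samples x n^2] matrix of feature values."""
    return np.array([v.values for v in vectors])


def _apply(scaler: MinMaxScaler, vectors: Sequence[FeatureVector]) -> list[FeatureVector]:
    if not vectors:
        return []
    scaled = scaler.transform(stack_values(vectors))
    return [
        FeatureVector(values=row, n=v.n, label=v.label, sample_id=v.sample_id)
        for row, v in zip(scaled, vectors)
    ]


def normalize_dataset(
    fit_vectors: Sequence[FeatureVector],
    *other_sets: Sequence[FeatureVector],
) -> tuple[list[FeatureVector], list[list[FeatureVector]], MinMaxScaler]:
    """Min-max normalize to [0,1], bounds fitted on ``fit_vectors``.

    The fit set should be the union of the unlabeled pool and the labeled
    training split; the same affine map is applied to every other set (so
    test data never influences the scaling).
    """
    if not fit_vectors:
        raise ValueError("cannot fit a scaler on an empty set")
    scaler = MinMaxScaler().fit(stack_values(fit_vectors))
    return _apply(scaler, fit_vectors), [_apply(scaler, s) for s in other_sets], scaler


# ---------------------------------------------------------------------------
# feature-table I/O: `sample_id,label,f1..f{n^2}`


def vectors_to_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    if not vectors:
        raise ValueError("no feature vectors to tabulate")
    d = vectors[0].values.size
    rows = []
    for v in vectors:
        row = {"sample_id": v.sample_id, "label": v.label}
        row.update({f"f{i + 1}": x for i, x in enumerate(v.values)})
        rows.append(row)
    frame = pd.DataFrame(rows)
    assert frame.shape[1] == d + 2
    return frame


def save_feature_table(vectors: Sequence[FeatureVector], path: str | Path) -> None:
    vectors_to_frame(vectors).to_csv(path, index=False)


def load_feature_table(path: str | Path) -> list[FeatureVector]:
    frame = pd.read_csv(path)
    fcols = [c for c in frame.columns if c.startswith("f")]
    n = int(round(len(fcols) ** 0.5))
    if n * n != len(fcols):
        raise ValueError(f"feature table has {len(fcols)} columns, not a square")
    out = []
    for row in frame.itertuples(index=False):
        label: int | str = row.label
        if label != UNLABELED:
            label = int(label)
        values = np.array([getattr(row, c) for c in fcols], dtype=float)
        out.append(
            FeatureVector(values=values, n=n, label=label, sample_id=str(row.sample_id))
        )
    return out
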