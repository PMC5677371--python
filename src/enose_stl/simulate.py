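"""Synthetic gas-sensor-array recordings.

Emulates the sampling protocol of a metal-oxide e-nose experiment: each
recording is 1200 s at 1 Hz over three phases — 3 min of clean-air baseline,
5 min of analyte exposure, 15 min of clean-air recovery.  A class (or gas)
archetype is a vector of per-sensor steady-state response amplitudes; the
exposure phase rises toward baseline + amplitude with first-order kinetics
``1 - exp(-t/rise_tau)`` and the recovery phase decays back with
``exp(-t/decay_tau)``.  Gaussian noise is added pointwise.

Two sample pools are generated: labeled "wound infection" recordings
(4 classes x 20 samples = 80) and unlabeled "pollutant gas" recordings
(132 + 203 + 153 + 164 = 652 across benzene, formaldehyde, acetone and
ethyl alcohol), matching the study design this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

UNLABELED = "unlabeled"

BASELINE_END_S = 180.0
EXPOSURE_END_S = 480.0
TOTAL_S = 1200.0

# Per-sensor steady-state amplitude archetypes (arbitrary voltage units).
# The labeled infection classes lie inside the span of the gas archetypes so
# that a basis learned on the unlabeled pool is in-distribution for transfer.
DEFAULT_CLASS_NAMES = ("uninfected", "P_aeruginosa", "E_coli", "S_aureus")
DEFAULT_CLASS_AMPLITUDES = (
    (0.40, 0.50, 0.45, 0.35, 0.30),
    (1.20, 0.80, 1.70, 1.00, 1.50),
    (0.80, 1.60, 0.70, 1.40, 0.90),
    (1.80, 0.90, 1.30, 0.70, 1.10),
)
DEFAULT_GAS_NAMES = ("benzene", "formaldehyde", "acetone", "ethylalcohol")
DEFAULT_GAS_AMPLITUDES = (
    (1.50, 0.60, 1.10, 0.50, 0.80),
    (0.60, 1.30, 0.90, 1.20, 0.50),
    (1.00, 1.00, 1.50, 0.80, 1.20),
    (0.90, 1.40, 0.60, 1.10, 1.60),
)
DEFAULT_UNLABELED_COUNTS = (132, 203, 153, 164)


@dataclass
class ResponseCurve:
    """One sampling experiment: per-sensor time series plus phase bounds."""

    sample_id: str
    timestamps: np.ndarray  # seconds, uniform 1 Hz grid
    readings: np.ndarray  # [T x S] sensor voltages, nonnegative
    phase_bounds: tuple[float, float, float] = (BASELINE_END_S, EXPOSURE_END_S, TOTAL_S)
    label: int | str = UNLABELED  # class index 1..C, or "unlabeled"
    gas_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        b, e, total = self.phase_bounds
        if not (0 < b < e < total):
            raise ValueError(f"phase bounds must increase: {self.phase_bounds}")
        if self.readings.ndim != 2 or self.readings.shape[0] != self.timestamps.size:
            raise ValueError("readings must be [T x S] matching timestamps")
        if self.timestamps.size != int(total) + 1:
            raise ValueError("expected a 1 Hz grid spanning the full record")
        if not np.all(np.isfinite(self.readings)):
            raise ValueError("readings must be finite")

    @property
    def n_sensors(self) -> int:
        return self.readings.shape[1]


@dataclass(frozen=True)
class SimConfig:
    """Study design: archetypes, kinetics, noise, sample counts, seed."""

    n_sensors: int = 5
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    class_amplitudes: tuple[tuple[float, ...], ...] = DEFAULT_CLASS_AMPLITUDES
    gas_names: tuple[str, ...] = DEFAULT_GAS_NAMES
    gas_amplitudes: tuple[tuple[float, ...], ...] = DEFAULT_GAS_AMPLITUDES
    rise_tau: float = 25.0  # s; exposure-phase first-order rise
    decay_tau: float = 90.0  # s; recovery-phase first-order decay
    noise_sd: float = 0.02  # additive Gaussian sigma, voltage units
    baseline_range: tuple[float, float] = (0.4, 0.6)  # per-sensor clean-air level
    n_labeled_per_class: int = 20
    n_unlabeled_per_gas: tuple[int, ...] = DEFAULT_UNLABELED_COUNTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensors < 1:
            raise ValueError("n_sensors must be >= 1")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_labeled_per_class < 0:
            raise ValueError("n_labeled_per_class must be >= 0")
        if len(self.class_names) != len(self.class_amplitudes):
            raise ValueError("class_names and class_amplitudes disagree")
        if len(self.gas_names) != len(self.gas_amplitudes):
            raise ValueError("gas_names and gas_amplitudes disagree")
        if len(self.n_unlabeled_per_gas) != len(self.gas_names):
            raise ValueError("one unlabeled count per gas required")
        for amps in (*self.class_amplitudes, *self.gas_amplitudes):
            if len(amps) != self.n_sensors:
                raise ValueError("every archetype needs one amplitude per sensor")
            if any(a < 0 for a in amps):
                raise ValueError("amplitudes must be nonnegative")
        if any(n < 0 for n in self.n_unlabeled_per_gas):
            raise ValueError("unlabeled counts must be >= 0")
        lo, hi = self.baseline_range
        if not (0 <= lo <= hi):
            raise ValueError("baseline_range must satisfy 0 <= lo <= hi")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def response_template(
    amplitudes: Sequence[float], config: SimConfig, baseline: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free response: (timestamps, readings [T x S]).

    Closed form used both by the simulator and by feature-oracle tests:
    exposure value at time t is ``base + A * (1 - exp(-(t-180)/rise_tau))``,
    recovery decays from the value reached at 480 s with ``decay_tau``.
    """
    t = np.arange(0.0, TOTAL_S + 1.0)
    base = np.asarray(baseline, dtype=float)[None, :]
    amps = np.asarray(amplitudes, dtype=float)[None, :]
    signal = np.broadcast_to(base, (t.size, base.shape[1])).copy()

    exposure = (t >= BASELINE_END_S) & (t <= EXPOSURE_END_S)
    te = t[exposure, None] - BASELINE_END_S
    signal[exposure] = base + amps * (1.0 - np.exp(-te / config.rise_tau))

    peak = amps * (1.0 - np.exp(-(EXPOSURE_END_S - BASELINE_END_S) / config.rise_tau))
    recovery = t > EXPOSURE_END_S
    tr = t[recovery, None] - EXPOSURE_END_S
    signal[recovery] = base + peak * np.exp(-tr / config.decay_tau)
    return t, signal


def simulate_curve(
    archetype: Sequence[float],
    config: SimConfig,
    rng: np.random.Generator,
    baseline: Sequence[float] | None = None,
    sample_id: str = "sample",
    label: int | str = UNLABELED,
    gas_id: str = "",
) -> ResponseCurve:
    """Simulate one sampling experiment for an amplitude archetype.

    Deterministic given the generator state: the noise draw is the only
    stochastic step.  ``baseline`` defaults to the midpoint of the config's
    baseline range (dataset generation draws it once per dataset instead).
    """
    if len(archetype) != config.n_sensors:
        raise ValueError(
            f"archetype length {len(archetype)} != n_sensors {config.n_sensors}"
        )
    if baseline is None:
        lo, hi = config.baseline_range
        baseline = np.full(config.n_sensors, 0.5 * (lo + hi))
    t, signal = response_template(archetype, config, baseline)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    # MOS sensor voltages cannot go below zero
    signal = np.maximum(signal, 0.0)
    return ResponseCurve(
        sample_id=sample_id, timestamps=t, readings=signal, label=label, gas_id=gas_id
    )


def generate_dataset(
    config: SimConfig,
) -> tuple[list[ResponseCurve], list[ResponseCurve]]:
    """Generate the labeled and unlabeled pools as a pure function of config.

    Returns ``(labeled, unlabeled)``.  With defaults: 80 labeled curves
    (4 classes x 20) and 652 unlabeled curves (132 + 203 + 153 + 164).
    The per-sensor clean-air baseline is drawn once per dataset so that
    baseline subtraction downstream is genuinely exercised.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=config.n_sensors)

    labeled: list[ResponseCurve] = []
    for ci, (name, amps) in enumerate(
        zip(config.class_names, config.class_amplitudes), start=1
    ):
        for i in range(config.n_labeled_per_class):
            labeled.append(
                simulate_curve(
                    amps,
                    config,
                    rng,
                    baseline=baseline,
                    sample_id=f"{name}_{i:03d}",
                    label=ci,
                    gas_id=name,
                )
            )

    unlabeled: list[ResponseCurve] = []
    for name, amps, count in zip(
        config.gas_names, config.gas_amplitudes, config.n_unlabeled_per_gas
    ):
        for i in range(count):
            unlabeled.append(
                simulate_curve(
                    amps,
                    config,
                    rng,
                    baseline=baseline,
                    sample_id=f"{name}_{i:03d}",
                    label=UNLABELED,
                    gas_id=name,
                )
            )
    return labeled, unlabeled


# ---------------------------------------------------------------------------
# plain-text I/O: one CSV per curve plus a manifest


def write_dataset(
    out_dir: str | Path, curves: Sequence[ResponseCurve], seed: int
) -> Path:
    """Write per-curve CSVs (`t,s1..sS`) and a manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for curve in curves:
        cols = {"t": curve.timestamps}
        for s in range(curve.n_sensors):
            cols[f"s{s + 1}"] = curve.readings[:, s]
        rel = f"{curve.sample_id}.csv"
        pd.DataFrame(cols).to_csv(out / rel, index=False)
        rows.append(
            {
                "sample_id": curve.sample_id,
                "path": rel,
                "label": curve.label,
                "gas_id": curve.gas_id,
                "seed": seed,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> list[ResponseCurve]:
    """Load curves listed in a manifest CSV written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    curves = []
    for row in table.itertuples(index=False):
        frame = pd.read_csv(manifest_path.parent / row.path)
        label: int | str = row.label
        if label != UNLABELED:
            label = int(label)
        sensor_cols = [c for c in frame.columns if c != "t"]
        curves.append(
            ResponseCurve(
                sample_id=str(row.sample_id),
                timestamps=frame["t"].to_numpy(),
                readings=frame[sensor_cols].to_numpy(),
                label=label,
                gas_id=str(row.gas_id),
            )
        )
    return curves
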