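"""Self-taught re-representation of labeled samples through a learned basis.

Given autoencoder parameters theta learned from the unlabeled pool, each
labeled feature vector x is replaced by its reconstruction

    x_hat = f(W2 f(W1 x + b1) + b2)

i.e. the full forward pass to the output layer.  Labels, ordering and
sample counts are preserved.  Passing the hidden activation f(W1 x + b1)
instead is available as an explicit, non-default option
(``representation="hidden"``), the variant classic self-taught learning
would use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autoencoder import AutoencoderParams, feedforward
from .features import FeatureVector


@dataclass
class ReconstructedSample:
    values: np.ndarray
    label: int | str
    source_id: str = ""
    model_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reconstructed values must be finite")


def reconstruct(
    params: AutoencoderParams,
    x: FeatureVector,
    representation: str = "output",
    model_id: str = "",
) -> ReconstructedSample:
    """Re-represent one (normalized) feature vector through the basis."""
    if x.values.size != params.n_visible:
        raise ValueError(
            f"sample dimension {x.values.size} != model dimension {params.n_visible}"
        )
    if representation not in ("output", "hidden"):
        raise ValueError("representation must be 'output' or 'hidden'")
    fp = feedforward(params, x.values[:, None])
    values = (fp.a3 if representation == "output" else fp.a2)[:, 0]
    return ReconstructedSample(
        values=values, label=x.label, source_id=x.sample_id, model_id=model_id
    )


def reconstruct_dataset(
    params: AutoencoderParams,
    samples: Sequence[FeatureVector],
    representation: str = "output",
    model_id: str = "",
) -> list[ReconstructedSample]:
    """Elementwise reconstruction; order and labels untouched."""
    return [reconstruct(params, x, representation, model_id) for x in samples]


def reconstruction_error(
    params: AutoencoderParams, samples: Sequence[FeatureVector]
) -> float:
    """Mean squared reconstruction error ||x_hat - x||^2 over samples."""
    if not samples:
        raise ValueError("no samples")
    X = np.array([s.values for s in samples]).T
    a3 = feedforward(params, X).a3
    return float(np.mean(np.sum((a3 - X) ** 2, axis=0)))
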