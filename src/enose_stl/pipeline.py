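"""End-to-end self-taught-learning pipeline and experiment grids.

One run executes: simulate (or load) sensor recordings -> extract n x n
features -> stratified 15/5-per-class split -> min-max normalize (bounds
fitted on unlabeled + labeled-train) -> train the sparse autoencoder on
the unlabeled pool -> reconstruct the labeled samples through the learned
basis -> tune and train a classifier on BOTH the raw and the
reconstructed ("self-taught") representations -> report train/test
accuracy for each branch.  The grid runner sweeps matrix dimension,
unlabeled-pool size and hidden-layer width with repeats.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import autoencoder as sae
from . import classifiers as clf
from .features import FeatureSpec, extract_features, normalize_dataset, stack_values
from .qpso import SwarmConfig
from .simulate import SimConfig, generate_dataset
from .transfer import reconstruct_dataset

logger = logging.getLogger("enose_stl")

# Desk-scale swarm for hyperparameter tuning inside pipeline runs; the
# optimizer's own defaults (30 particles / 300 iterations) remain available
# through the `swarm` argument.
PIPELINE_TUNE_PARTICLES = 12
PIPELINE_TUNE_ITERATIONS = 40


def _derive_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def run_pipeline(
    sim_config: SimConfig | None = None,
    n: int = 3,
    classifier: str = "rbf",
    sae_config: sae.TrainConfig | None = None,
    split: clf.SplitSpec | None = None,
    tune: bool = True,
    swarm: SwarmConfig | None = None,
    unlabeled_size: int | None = None,
    representation: str = "output",
    seed: int = 0,
) -> dict:
    """Run the full pipeline once; returns a flat result record.

    All sub-stage seeds are derived from ``seed`` (seeds inside provided
    configs are overridden), so a single integer reproduces the whole run
    bit-for-bit.
    """
    t0 = time.perf_counter()
    sim_seed, split_seed, sae_seed, clf_seed, sub_seed = _derive_seeds(seed, 5)
    sim = replace(sim_config or SimConfig(), seed=sim_seed)
    sae_cfg = replace(sae_config or sae.TrainConfig(), seed=sae_seed)
    split_spec = clf.SplitSpec(
        **{
            "train_per_class": (split or clf.SplitSpec()).train_per_class,
            "test_per_class": (split or clf.SplitSpec()).test_per_class,
            "seed": split_seed,
        }
    )

    labeled_curves, unlabeled_curves = generate_dataset(sim)
    logger.info("simulate: %d labeled, %d unlabeled", len(labeled_curves), len(unlabeled_curves))

    spec = FeatureSpec.for_dim(n)
    labeled = extract_features(labeled_curves, spec)
    unlabeled = extract_features(unlabeled_curves, spec)
    if unlabeled_size is not None:
        if unlabeled_size > len(unlabeled):
            raise ValueError(
                f"unlabeled_size {unlabeled_size} exceeds pool of {len(unlabeled)}"
            )
        pick = np.random.default_rng(sub_seed).choice(
            len(unlabeled), size=unlabeled_size, replace=False
        )
        unlabeled = [unlabeled[i] for i in sorted(pick)]

    train_l, test_l = clf.split_dataset(labeled, split_spec)
    fit_set = list(unlabeled) + list(train_l)
    _, (unlabeled_n, train_n, test_n), scaler = normalize_dataset(
        fit_set, unlabeled, train_l, test_l
    )

    X_u = stack_values(unlabeled_n).T  # [n^2 x k]
    params, trace = sae.train(X_u, sae_cfg)
    logger.info(
        "train-sae: hidden=%d, %d iterations, final J=%.5f",
        sae_cfg.hidden, sae_cfg.iterations, trace[-1] if trace.size else float("nan"),
    )

    train_r = reconstruct_dataset(params, train_n, representation=representation)
    test_r = reconstruct_dataset(params, test_n, representation=representation)

    record = {
        "dim": n,
        "classifier": classifier,
        "hidden": sae_cfg.hidden,
        "unlabeled_size": len(unlabeled),
        "seed": seed,
        "n_labeled": len(labeled),
        "n_train": len(train_l),
        "n_test": len(test_l),
    }
    for branch, (tr, te) in (
        ("raw", (train_n, test_n)),
        ("sae", (train_r, test_r)),
    ):
        model = _fit_branch(classifier, tr, tune, swarm, clf_seed)
        record[f"{branch}_train"] = clf.accuracy(model, tr)
        record[f"{branch}_test"] = clf.accuracy(model, te)
    record["elapsed_s"] = round(time.perf_counter() - t0, 3)
    logger.info(
        "pipeline dim=%d: raw %.1f/%.1f, sae %.1f/%.1f (train/test %%)",
        n, record["raw_train"], record["raw_test"],
        record["sae_train"], record["sae_test"],
    )
    return record


def _fit_branch(classifier, train_set, tune, swarm, seed):
    if tune:
        if swarm is None:
            swarm = SwarmConfig(
                bounds=((0.0, 1.0),),  # placeholder; tune substitutes real bounds
                n_particles=PIPELINE_TUNE_PARTICLES,
                iterations=PIPELINE_TUNE_ITERATIONS,
                seed=seed,
            )
        model, _, _ = clf.tune_with_eqpso(classifier, train_set, swarm=swarm, seed=seed)
        return model
    X, y = clf.stack_xy(train_set)
    if classifier == "rbf":
        # heuristic defaults: moderate basis size, median-distance width
        from scipy.spatial.distance import pdist

        dists = pdist(X)
        sigma = float(np.median(dists[dists > 0])) if np.any(dists > 0) else 1.0
        return clf.train_rbf(
            (X, y), K=min(20, X.shape[0]), sigma=sigma, ridge=1e-4, seed=seed
        )
    return clf.train_plsda((X, y), n_components=min(X.shape[1], 8, X.shape[0] - 1))


@dataclass(frozen=True)
class ExperimentGrid:
    dims: tuple[int, ...] = (3, 4, 5)
    unlabeled_sizes: tuple[int | None, ...] = (None,)  # None -> full pool
    hidden_sizes: tuple[int, ...] = (10,)
    repeats: int = 5
    classifier: str = "rbf"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def run_grid(
    grid: ExperimentGrid,
    sim_config: SimConfig | None = None,
    sae_config: sae.TrainConfig | None = None,
    tune: bool = True,
    swarm: SwarmConfig | None = None,
) -> pd.DataFrame:
    """Sweep the grid; returns long-format rows, one per
    (dim, unlabeled_size, hidden, repeat, input_kind, split).

    Per-cell failures are recorded in the ``error`` column and the grid
    continues.
    """
    rows = []
    for dim in grid.dims:
        for size in grid.unlabeled_sizes:
            for hidden in grid.hidden_sizes:
                for rep in range(grid.repeats):
                    cell_seed = _derive_seeds(
                        grid.base_seed * 100003 + hash((dim, size, hidden, rep)) % 65521, 1
                    )[0]
                    base = {
                        "dim": dim,
                        "unlabeled_size": size if size is not None else -1,
                        "hidden": hidden,
                        "repeat": rep,
                        "seed": cell_seed,
                    }
                    try:
                        cfg = replace(sae_config or sae.TrainConfig(), hidden=hidden)
                        rec = run_pipeline(
                            sim_config=sim_config,
                            n=dim,
                            classifier=grid.classifier,
                            sae_config=cfg,
                            tune=tune,
                            swarm=swarm,
                            unlabeled_size=size,
                            seed=cell_seed,
                        )
                    except Exception as exc:  # record and continue
                        logger.warning("grid cell %s failed: %s", base, exc)
                        for kind in ("raw", "sae"):
                            for split_name in ("train", "test"):
                                rows.append(
                                    base
                                    | {
                                        "input_kind": kind,
                                        "split": split_name,
                                        "accuracy": np.nan,
                                        "error": str(exc),
                                    }
                                )
                        continue
                    for kind in ("raw", "sae"):
                        for split_name in ("train", "test"):
                            rows.append(
                                base
                                | {
                                    "input_kind": kind,
                                    "split": split_name,
                                    "accuracy": rec[f"{kind}_{split_name}"],
                                    "error": "",
                                }
                            )
    return pd.DataFrame(rows)


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean accuracy over repeats."""
    keys = ["dim", "unlabeled_size", "hidden", "input_kind", "split"]
    return (
        results.dropna(subset=["accuracy"])
        .groupby(keys, as_index=False)["accuracy"]
        .mean()
    )


def results_table(records: Sequence[dict]) -> pd.DataFrame:
    """Dimension x {raw, sae} x {train, test} accuracy table."""
    frame = pd.DataFrame(records)
    cols = ["dim", "raw_train", "raw_test", "sae_train", "sae_test"]
    return frame[cols].groupby("dim", as_index=False).mean()
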