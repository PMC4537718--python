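"""Bin-level ROC/AUC evaluation and the factor-sweep harness.

Every method is scored per bin — the HMM strategies by their posterior
probability of the differential state, the raw exact test by 1 - p — and
compared against the simulated ground-truth labels with the area under the
ROC curve (equivalently the normalised Mann-Whitney U statistic, ties
counted one half).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .contingency import test_bins
from .errors import ValidationError
from .simulate import SimConfig, SimulatedDataset, simulate_dataset
from .strategies import StrategyConfig, smooth_results

METHODS = ("raw", "fhb", "fhc", "fastfhc")

SWEEP_FACTORS = ("threshold", "transition", "depth", "unbalanced_depth")


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC of ``scores`` against binary ``labels``; both classes required."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValidationError(
            "AUC needs both classes present; labels must contain 0s and 1s"
        )
    return float(roc_auc_score(labels, scores))


def evaluate_methods(
    dataset: SimulatedDataset,
    strategy_cfg: StrategyConfig | None = None,
    methods: tuple[str, ...] = METHODS,
) -> dict[str, float]:
    """Bin-level AUC of each requested method on one simulated dataset.

    The exact tests are run once and shared by every strategy.
    """
    cfg = strategy_cfg or StrategyConfig()
    labels = dataset.labels
    results = test_bins(dataset.table, dataset.config.sizes, cfg.test_pseudocount)
    aucs: dict[str, float] = {}
    for method in methods:
        if method == "raw":
            scores = 1.0 - results["p_value"].to_numpy()
        elif method in ("fhb", "fhc", "fastfhc"):
            res = smooth_results(results, replace(cfg, strategy=method))
            scores = res.bins["posterior"].to_numpy()
        else:
            raise ValidationError(f"unknown method {method!r}")
        aucs[method] = compute_auc(scores, labels)
    return aucs


def _apply_level(cfg: SimConfig, scfg: StrategyConfig, factor: str, level: float):
    if factor == "threshold":
        return cfg, replace(scfg, fdr_threshold=float(level))
    if factor == "transition":
        d = float(level)
        return (
            replace(cfg, a_sim=((d, 1.0 - d), (1.0 - d, d))),
            scfg,
        )
    if factor == "depth":
        v = float(level)
        return replace(cfg, n0=v, n1=v, m0=v, m1=v), scfg
    if factor == "unbalanced_depth":
        return replace(cfg, m1=float(level)), scfg
    raise ValidationError(f"unknown sweep factor {factor!r}; choose from {SWEEP_FACTORS}")


def sweep(
    factor: str,
    levels: list[float],
    n_datasets: int,
    seed: int,
    base_cfg: SimConfig | None = None,
    strategy_cfg: StrategyConfig | None = None,
    methods: tuple[str, ...] = METHODS,
) -> pd.DataFrame:
    """AUC of every method at every level of one simulation factor.

    ``factor`` is one of ``threshold`` (FDR binarisation cut-off),
    ``transition`` (self-transition probability of the generating chain),
    ``depth`` (all four library sizes) or ``unbalanced_depth`` (treated IP
    depth only). Returns a tidy frame with columns
    (factor, level, dataset, method, auc).
    """
    base_cfg = base_cfg or SimConfig()
    strategy_cfg = strategy_cfg or StrategyConfig()
    rows = []
    # threshold is an analysis knob, so all its levels see the same datasets;
    # generative factors draw fresh data per level
    shared_children = np.random.SeedSequence(seed).spawn(n_datasets)
    for li, level in enumerate(levels):
        cfg, scfg = _apply_level(base_cfg, strategy_cfg, factor, level)
        if factor == "threshold":
            children = shared_children
        else:
            children = np.random.SeedSequence((seed, li)).spawn(n_datasets)
        for di, child in enumerate(children):
            ds = simulate_dataset(cfg, child)
            for method, auc in evaluate_methods(ds, scfg, methods).items():
                rows.append(
                    {
                        "factor": factor,
                        "level": level,
                        "dataset": di,
                        "method": method,
                        "auc": auc,
                    }
                )
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of AUC per (level, method)."""
    return (
        table.groupby(["factor", "level", "method"], sort=False)["auc"]
        .agg(["mean", "std"])
        .reset_index()
    )
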