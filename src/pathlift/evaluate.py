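"""Repeated stratified cross-validation and ablation harnesses.

The protocol is stratified 5-fold cross-validation repeated 5 times (the
repeat index perturbs the shuffling seed deterministically); each run
reports AUC, AUPR, accuracy and F1 on the held-out fold, and the summary is
the arithmetic mean/SD over the 25 runs.  Chi-square feature selection and
class weights are refit inside each training fold by default so no label
information leaks into the evaluation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, average_precision_score, f1_score,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold

from .hierarchy import MaskStack, PathwayHierarchy, build_masks
from .network import TrainConfig, forward, train
from .omics import OmicsMatrix, assemble_input, chi2_select

__all__ = [
    "CVResult",
    "compute_metrics",
    "cross_validate",
    "cross_validate_pipeline",
    "omics_ablation",
    "augmentation_ablation",
]

METRICS = ("auc", "aupr", "accuracy", "f1")


@dataclass
class CVResult:
    """Per-fold metrics plus their mean/SD summary."""

    per_fold: pd.DataFrame      # columns: repeat, fold, auc, aupr, accuracy, f1
    summary: dict[str, dict[str, float]]
    config: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_rows(cls, rows: list[dict], config: dict, seed: int) -> "CVResult":
        df = pd.DataFrame(rows)
        summary = {m: {"mean": float(df[m].mean()), "sd": float(df[m].std(ddof=1))}
                   for m in METRICS}
        return cls(per_fold=df, summary=summary, config=config, seed=seed)

    def to_csv(self, path) -> None:
        tidy = self.per_fold.melt(id_vars=["repeat", "fold"], value_vars=list(METRICS),
                                  var_name="metric", value_name="value")
        tidy.to_csv(path, index=False)


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                    threshold: float = 0.5) -> dict[str, float]:
    """AUC (rank statistic, ties averaged), AUPR (step integration),
    accuracy and F1 at ``threshold``."""
    y_true = np.asarray(y_true).ravel()
    y_prob = np.asarray(y_prob, dtype=float).ravel()
    if y_true.shape != y_prob.shape:
        raise ValueError("length mismatch between labels and scores")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC/AUPR undefined: y_true holds a single class")
    y_pred = (y_prob >= threshold).astype(int)
    return {
        "auc": float(roc_auc_score(y_true, y_prob)),
        "aupr": float(average_precision_score(y_true, y_prob)),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }


def _fold_iter(y: np.ndarray, folds: int, repeats: int, seed: int):
    """Deterministic stratified folds; the repeat index perturbs the shuffle seed."""
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 1000 * rep)
        for fold, (tr, te) in enumerate(skf.split(np.zeros_like(y), y)):
            yield rep, fold, tr, te


def cross_validate(
    X: np.ndarray, y: np.ndarray, masks: MaskStack,
    config: TrainConfig | None = None,
    folds: int = 5, repeats: int = 5, seed: int = 0,
) -> CVResult:
    """Repeated stratified CV of the masked network on a fixed input matrix."""
    y = np.asarray(y).ravel()
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise ValueError(f"need at least {folds} samples of each class")
    config = config or TrainConfig()
    rows = []
    for rep, fold, tr, te in _fold_iter(y, folds, repeats, seed):
        cfg = replace(config, seed=seed + 7919 * rep + 104729 * fold)
        params, _ = train(X[tr], y[tr], masks, cfg)
        prob = forward(X[te], masks, params)
        rows.append({"repeat": rep, "fold": fold, **compute_metrics(y[te], prob)})
    return CVResult.from_rows(rows, {"folds": folds, "repeats": repeats,
                                     **vars(config)}, seed)


def cross_validate_pipeline(
    blocks: Sequence[OmicsMatrix], y: np.ndarray, hier: PathwayHierarchy,
    config: TrainConfig | None = None,
    folds: int = 5, repeats: int = 5, seed: int = 0,
    top_k: int = 3000, select_in_fold: bool = True,
) -> CVResult:
    """CV over raw omics blocks with chi-square selection refit per fold.

    ``select_in_fold=False`` reproduces selection on the full data set before
    CV (leaks label information into the evaluation folds; offered only for
    comparability with selection-before-split protocols).
    """
    y = np.asarray(y).ravel()
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise ValueError(f"need at least {folds} samples of each class")
    config = config or TrainConfig()

    def _prepare(train_idx: np.ndarray):
        sel = []
        for b in blocks:
            bb = OmicsMatrix(b.values.iloc[train_idx], b.feature_gene, b.omics_type)
            chosen = chi2_select(bb, y[train_idx], k=top_k)
            sel.append(OmicsMatrix(b.values[chosen.feature_ids], chosen.feature_gene,
                                   chosen.omics_type))
        feature_table = [row for b in sel for row in b.feature_table()]
        masks = build_masks(hier, feature_table)
        X, sample_ids, masks = assemble_input(list(sel), masks)
        return X, masks

    rows = []
    if not select_in_fold:
        X_all, masks_all = _prepare(np.arange(y.size))
    for rep, fold, tr, te in _fold_iter(y, folds, repeats, seed):
        if select_in_fold:
            X_all, masks_all = _prepare(tr)
        cfg = replace(config, seed=seed + 7919 * rep + 104729 * fold)
        params, _ = train(X_all[tr], y[tr], masks_all, cfg)
        prob = forward(X_all[te], masks_all, params)
        rows.append({"repeat": rep, "fold": fold, **compute_metrics(y[te], prob)})
    return CVResult.from_rows(rows, {"folds": folds, "repeats": repeats,
                                     "top_k": top_k, "select_in_fold": select_in_fold,
                                     **vars(config)}, seed)


def omics_ablation(
    blocks: dict[str, OmicsMatrix], y: np.ndarray, hier: PathwayHierarchy,
    combos: Sequence[Sequence[str]] | None = None,
    config: TrainConfig | None = None,
    folds: int = 5, repeats: int = 5, seed: int = 0, top_k: int = 3000,
) -> pd.DataFrame:
    """Cross-validate each omics combination with identical seeds.

    Default combos: SNV, AMP_CNV, DEL_CNV, SNV+AMP_CNV, SNV+DEL_CNV,
    SNV+AMP_CNV+DEL_CNV.
    """
    if combos is None:
        combos = [["SNV"], ["AMP_CNV"], ["DEL_CNV"],
                  ["SNV", "AMP_CNV"], ["SNV", "DEL_CNV"],
                  ["SNV", "AMP_CNV", "DEL_CNV"]]
    rows = []
    for combo in combos:
        unknown = [c for c in combo if c not in blocks]
        if unknown:
            raise KeyError(f"unknown omics block(s) {unknown}; have {list(blocks)}")
        res = cross_validate_pipeline([blocks[c] for c in combo], y, hier,
                                      config=config, folds=folds, repeats=repeats,
                                      seed=seed, top_k=top_k)
        row = {"combo": "+".join(combo)}
        for m in METRICS:
            row[f"{m}_mean"] = res.summary[m]["mean"]
            row[f"{m}_sd"] = res.summary[m]["sd"]
        rows.append(row)
    return pd.DataFrame(rows)


def augmentation_ablation(
    X: np.ndarray, y: np.ndarray, masks: MaskStack, augmented_masks: MaskStack,
    config: TrainConfig | None = None,
    folds: int = 5, repeats: int = 5, seed: int = 0,
) -> dict:
    """Paired CV with and without latent-link augmentation (shared folds).

    Returns both CVResults and per-metric mean deltas (augmented - original).
    """
    if masks.node_index != augmented_masks.node_index:
        raise ValueError("mask stacks must share node orderings")
    base = cross_validate(X, y, masks, config, folds, repeats, seed)
    aug = cross_validate(X, y, augmented_masks, config, folds, repeats, seed)
    deltas = {m: aug.summary[m]["mean"] - base.summary[m]["mean"] for m in METRICS}
    return {"original": base, "augmented": aug, "delta": deltas}
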