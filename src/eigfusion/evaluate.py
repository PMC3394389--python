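"""Evaluation of gene rankings against a spike-in truth set.

Confusion counting follows the benchmark's asymmetric logic: a false positive
is a *biomarker* test gene (affected in all cancer samples) ranked inside the
top list — the mistake the spectral score is designed to avoid — while a false
negative is a *positive* test gene (affected in under half the cancer samples)
that the method buries. Background genes never enter the counts (they are
reported separately as intrusions). The headline rates are false *discovery*
proportions, FPR = FP/(FP+TP) and FNR = FN/(FN+TN), not classical ROC rates;
ROC/AUC over positives vs (background + biomarker) genes is computed alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .comparators import METHODS, score_matrix
from .config import RunConfig
from .simulate import SimulatedDataset, TruthSet


@dataclass
class ConfusionCounts:
    """Counts over labelled test genes only (ambiguous k excluded)."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    background_intrusions: int = 0  # background genes inside the top list


def confusion(
    ranking: pd.DataFrame,
    truth: TruthSet,
    top_n: int = 10,
    bottom_n: int | None = None,
) -> ConfusionCounts:
    """Count TP/FP/TN/FN from a ranking and a truth set.

    TP: positive test genes ranked within ``top_n``; FP: biomarker test genes
    within ``top_n``; TN: biomarker genes outside it. With ``bottom_n=None``
    (default) FN is every positive outside ``top_n``, so TP+FN partitions the
    positives. With an integer ``bottom_n``, FN counts only positives ranked in
    the bottom ``bottom_n`` of the list — the "ranked at the bottom" rule used
    by the synthetic benchmark, under which a positive left mid-list is neither
    recovered nor actively buried. A truth gene absent from the ranking (e.g.
    dropped for zero MAD) counts as FN if positive, TN if biomarker.
    """
    ranks = dict(zip(ranking["gene"], ranking["rank"]))
    n_ranked = len(ranking)
    counts = ConfusionCounts()
    for entry in truth.entries:
        if entry.label == "ambiguous":
            continue
        rank = ranks.get(entry.gene_id)
        if rank is None:
            warnings.warn(
                f"truth gene {entry.gene_id!r} missing from ranking; "
                f"counted as {'FN' if entry.label == 'positive' else 'TN'}",
                stacklevel=2,
            )
            if entry.label == "positive":
                counts.fn += 1
            else:
                counts.tn += 1
            continue
        if entry.label == "positive":
            if rank <= top_n:
                counts.tp += 1
            elif bottom_n is None or rank > n_ranked - bottom_n:
                counts.fn += 1
        else:  # biomarker
            if rank <= top_n:
                counts.fp += 1
            else:
                counts.tn += 1
    truth_ids = set(truth.gene_ids())
    counts.background_intrusions = int(
        ((ranking["rank"] <= top_n) & ~ranking["gene"].isin(truth_ids)).sum()
    )
    return counts


def f_measure(c: ConfusionCounts) -> float:
    """Harmonic mean of precision TP/(TP+FP) and recall TP/(TP+FN); 0 when both
    are undefined or zero."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def false_positive_rate(c: ConfusionCounts) -> float:
    """False positive discovery proportion FP/(FP+TP); 0 when no calls."""
    return c.fp / (c.fp + c.tp) if (c.fp + c.tp) else 0.0


def false_negative_rate(c: ConfusionCounts) -> float:
    """False negative discovery proportion FN/(FN+TN); 0 when empty."""
    return c.fn / (c.fn + c.tn) if (c.fn + c.tn) else 0.0


def roc_auc(scores: pd.DataFrame, truth: TruthSet) -> float:
    """Area under the ROC curve for separating positive test genes from the
    negatives (background genes plus biomarker test genes; ambiguous test genes
    excluded). Ties count half, i.e. the Mann-Whitney probability that a
    positive outscores a negative."""
    labels_by_gene = {e.gene_id: e.label for e in truth.entries}
    y, s = [], []
    score_by_gene = dict(zip(scores["gene"], scores["score"]))
    fill = min(score_by_gene.values()) - 1.0 if score_by_gene else 0.0
    genes = list(scores["gene"]) + [
        g for g in labels_by_gene if g not in score_by_gene
    ]
    for gene in genes:
        label = labels_by_gene.get(gene)
        if label == "ambiguous":
            continue
        y.append(1 if label == "positive" else 0)
        s.append(score_by_gene.get(gene, fill))
    y_arr = np.asarray(y)
    if y_arr.sum() == 0 or y_arr.sum() == y_arr.size:
        raise ValueError("ROC needs at least one positive and one negative gene")
    return float(roc_auc_score(y_arr, np.asarray(s)))


def benchmark(
    methods: list[str],
    sweep: list[SimulatedDataset],
    config: RunConfig | None = None,
    fn_rule: str = "bottom",
) -> pd.DataFrame:
    """Run every method on every simulated scenario.

    ``fn_rule`` selects the false-negative convention: ``"bottom"`` (default,
    the benchmark's rule — a positive is FN only when ranked in the bottom
    ``top_n`` of the list) or ``"outside_top"`` (a positive is FN whenever it
    misses the top list). Returns one row per (method, cancer_size) with
    confusion counts, FPR, FNR, f-measure and AUC.
    """
    if fn_rule not in ("bottom", "outside_top"):
        raise ValueError("fn_rule must be 'bottom' or 'outside_top'")
    config = config or RunConfig()
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
    bottom_n = config.top_n if fn_rule == "bottom" else None
    rows = []
    for dataset in sweep:
        for method in methods:
            scores = score_matrix(dataset.matrix, dataset.labels, method, config)
            c = confusion(scores, dataset.truth, config.top_n, bottom_n)
            rows.append(
                {
                    "method": method,
                    "cancer_size": dataset.spec.cancer_size,
                    "seed": dataset.spec.seed,
                    "tp": c.tp,
                    "fp": c.fp,
                    "tn": c.tn,
                    "fn": c.fn,
                    "background_intrusions": c.background_intrusions,
                    "fpr": false_positive_rate(c),
                    "fnr": false_negative_rate(c),
                    "f_measure": f_measure(c),
                    "auc": roc_auc(scores, dataset.truth),
                }
            )
    return pd.DataFrame(rows)
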