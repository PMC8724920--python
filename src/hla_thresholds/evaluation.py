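"""Confusion-matrix benchmarking of prediction thresholds.

Positives (eluted ligands or T-cell epitopes) scoring at or below a threshold
are true positives, above it false negatives; background decoys at or below
the threshold are false positives, above it true negatives.  Five rates
follow: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
NPV TN/(TN+FN), accuracy (TP+TN)/total.  A rate with a zero denominator is
reported as undefined (None), never as zero, and is excluded (with a count)
from across-allele means — silent zeros would bias the summaries.

ROC/AUC comparisons between metrics use lower-is-positive orientation;
the AUC equals the Mann-Whitney probability that a random positive outscores
a random negative, with half-credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .calibration import ThresholdSet
from .scores import metric_column

POSITIVE_ROLES = frozenset({"ligand", "epitope"})

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    """The five rates; ``None`` marks an undefined (0/0) ratio."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def classify(
    scored: pd.DataFrame, metric: str, threshold: float
) -> ConfusionCounts:
    """Confusion counts for one allele's scored dataset at a cutoff.

    ``scored`` carries a ``role`` column (ligand/epitope = positive,
    background = negative) and the metric's score column; "predicted
    positive" is score <= threshold.
    """
    if scored.empty:
        raise ValueError("cannot classify an empty dataset")
    col = metric_column(metric)
    is_pos = scored["role"].isin(POSITIVE_ROLES).to_numpy()
    below = (scored[col] <= threshold).to_numpy()
    return ConfusionCounts(
        tp=int((is_pos & below).sum()),
        fn=int((is_pos & ~below).sum()),
        fp=int((~is_pos & below).sum()),
        tn=int((~is_pos & ~below).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> PerformanceMetrics:
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    return PerformanceMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        accuracy=_ratio(c.tp + c.tn, c.total),
    )


def evaluate_per_allele(
    scored: pd.DataFrame, thresholds: ThresholdSet
) -> dict[str, PerformanceMetrics]:
    """Five rates per allele, each allele evaluated at its family threshold."""
    return {
        allele: compute_metrics(
            classify(group, thresholds.metric, thresholds.value_for(allele))
        )
        for allele, group in scored.groupby("allele", sort=True)
    }


def summarize_across_alleles(
    per_allele: dict[str, PerformanceMetrics],
) -> pd.DataFrame:
    """Per-allele rates plus unweighted Mean/SD rows across alleles.

    Undefined per-allele values are excluded from that metric's mean and SD;
    the ``n_defined`` row records how many alleles contributed.  SD is the
    sample standard deviation (ddof=1; 0 for a single allele).
    """
    if not per_allele:
        raise ValueError("need at least one allele to summarize")
    table = pd.DataFrame(
        {a: m.as_dict() for a, m in sorted(per_allele.items())}
    ).T.astype(float)
    table.index.name = "allele"
    mean = table.mean(skipna=True)
    sd = table.std(skipna=True, ddof=1).fillna(0.0)
    n_defined = table.notna().sum()
    summary = pd.DataFrame(
        [mean, sd, n_defined.astype(float)], index=["Mean", "SD", "n_defined"]
    )
    summary.index.name = "allele"
    return pd.concat([table, summary])


def roc_auc(
    positives: np.ndarray | pd.Series,
    negatives: np.ndarray | pd.Series,
    metric: str = "el_rank",
) -> tuple[float, pd.DataFrame]:
    """AUC and ROC points for a lower-is-positive score metric.

    Scores are negated so the standard higher-is-positive ROC machinery
    applies; tied positive/negative pairs receive half credit (Mann-Whitney
    convention).  Returns (auc, points) with points ordered by the threshold
    sweep over observed values.
    """
    metric_column(metric)
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = -np.concatenate([pos, neg])
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    points = pd.DataFrame({"threshold": -thr, "fpr": fpr, "tpr": tpr})
    return float(_sk_auc(fpr, tpr)), points


def compare_metric_aucs(
    scored: pd.DataFrame, metrics: tuple[str, ...] = ("el_rank", "ic50")
) -> pd.DataFrame:
    """Pooled ROC AUC per score metric on a positives-vs-background dataset."""
    is_pos = scored["role"].isin(POSITIVE_ROLES)
    rows = []
    for metric in metrics:
        col = metric_column(metric)
        a, _ = roc_auc(scored.loc[is_pos, col], scored.loc[~is_pos, col], metric)
        rows.append({"metric": metric, "auc": a, "n_pos": int(is_pos.sum()), "n_neg": int((~is_pos).sum())})
    return pd.DataFrame(rows)


def two_allele_demo(
    scored: pd.DataFrame,
    allele_thresholds: dict[str, float],
    common: float,
    metric: str = "el_rank",
) -> pd.DataFrame:
    """Pooled sensitivity/precision for two alleles: own vs common threshold.

    The practical case for allele-specific cutoffs: pool the epitopes and
    decoys of two alleles with very different calibrated thresholds and
    compare (a) each allele classified at its own threshold with (b) both at
    the one common threshold.
    """
    alleles = sorted(scored["allele"].unique())
    if len(alleles) != 2:
        raise ValueError(f"exactly two alleles required, got {alleles}")
    if set(allele_thresholds) != set(alleles):
        raise ValueError("allele_thresholds must cover exactly the two alleles")
    for allele in alleles:
        sub = scored[scored["allele"] == allele]
        if not sub["role"].isin(POSITIVE_ROLES).any():
            raise ValueError(f"allele {allele} has no positive peptides")

    def pooled(thresholds: dict[str, float]) -> dict:
        parts = [
            classify(scored[scored["allele"] == a], metric, thresholds[a])
            for a in alleles
        ]
        c = ConfusionCounts(
            tp=sum(p.tp for p in parts),
            fp=sum(p.fp for p in parts),
            tn=sum(p.tn for p in parts),
            fn=sum(p.fn for p in parts),
        )
        m = compute_metrics(c)
        return {"sensitivity": m.sensitivity, "precision": m.ppv}

    rows = [
        {"strategy": "allele_specific", **pooled(allele_thresholds)},
        {"strategy": "common", **pooled({a: common for a in alleles})},
    ]
    return pd.DataFrame(rows)
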