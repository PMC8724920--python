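"""Threshold calibration at fixed sensitivity, stepwise rescaling, repertoire sizes.

The core operation sets a score cutoff for a lower-is-better prediction
metric so that a target fraction of positive peptides (eluted ligands or
T-cell epitopes) falls at or below it.  With ``n`` positives and target
sensitivity ``s`` the cutoff is the k-th order statistic of the observed
scores, ``k = ceil(s * n)`` — the smallest observed value capturing at least
``s`` of the positives.  "Predicted positive" is ``score <= threshold``
(inclusive), so re-applying a calibrated threshold to its own calibration
data yields sensitivity exactly ``k / n`` when scores are tie-free.

Three threshold families are supported:

* allele-specific — one cutoff per allele, each calibrated on that allele's
  positives;
* common — a single cutoff calibrated on all alleles' positives pooled;
* binder-fraction-derived — per allele, the percentage of background decoys
  predicted to bind at an IC50 cutoff (500 nM classically), reused as an
  EL-rank percentile threshold.

A family calibrated on eluted ligands systematically under-captures T-cell
epitopes; :func:`scale_to_target` therefore inflates a family by a shared
multiplier ``(1 + step)`` per iteration until the unweighted mean per-allele
sensitivity on an epitope set reaches the target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .scores import metric_column

logger = logging.getLogger(__name__)


@dataclass
class ThresholdSet:
    """A named family of cutoffs on one score metric.

    Either ``common`` (one scalar for all alleles), ``per_allele`` (one value
    per analyzed allele), or both may be present.  ``value_for`` resolves
    per-allele first, then common.  ``scale_applied`` records the cumulative
    fold-change of stepwise rescaling (1.0 if unscaled).
    """

    metric: str
    common: float | None = None
    per_allele: dict[str, float] | None = None
    provenance: str = "el_derived"
    scale_applied: float = 1.0

    def __post_init__(self) -> None:
        metric_column(self.metric)  # validates
        values = list(self.per_allele.values()) if self.per_allele else []
        if self.common is not None:
            values.append(self.common)
        if not values:
            raise ValueError("ThresholdSet needs a common and/or per-allele family")
        if any(not (v > 0) for v in values if v != 0.0):
            raise ValueError("thresholds must be strictly positive")

    def value_for(self, allele: str) -> float:
        if self.per_allele is not None:
            if allele not in self.per_allele:
                raise KeyError(f"no threshold for allele {allele}")
            return self.per_allele[allele]
        assert self.common is not None
        return self.common

    def scaled(self, factor: float, provenance: str = "scaled") -> "ThresholdSet":
        return replace(
            self,
            common=None if self.common is None else self.common * factor,
            per_allele=None
            if self.per_allele is None
            else {a: v * factor for a, v in self.per_allele.items()},
            provenance=provenance,
            scale_applied=self.scale_applied * factor,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.common is not None:
            rows.append(("ALL", self.common))
        if self.per_allele is not None:
            rows.extend(sorted(self.per_allele.items()))
        return pd.DataFrame(
            {
                "allele": [a for a, _ in rows],
                "metric": self.metric,
                "threshold": [v for _, v in rows],
                "provenance": self.provenance,
                "scale_applied": self.scale_applied,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ThresholdSet":
        metrics = df["metric"].unique()
        if len(metrics) != 1:
            raise ValueError("threshold table mixes metrics")
        common_rows = df[df["allele"] == "ALL"]
        per = df[df["allele"] != "ALL"]
        return cls(
            metric=metrics[0],
            common=float(common_rows["threshold"].iloc[0]) if len(common_rows) else None,
            per_allele=dict(zip(per["allele"], per["threshold"].astype(float)))
            if len(per)
            else None,
            provenance=str(df["provenance"].iloc[0]),
            scale_applied=float(df["scale_applied"].iloc[0]),
        )


@dataclass
class ScalingConfig:
    step: float = 0.05
    target_mean_sensitivity: float = 0.8
    max_iterations: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.step < 1:
            raise ValueError("step must be in (0, 1)")
        if not 0 < self.target_mean_sensitivity < 1:
            raise ValueError("target_mean_sensitivity must be in (0, 1)")
        if self.max_iterations <= 0:
            raise ValueError("max_iterations must be positive")


@dataclass
class RepertoireEstimate:
    allele: str
    fraction_bound: float
    threshold_used: float
    metric: str


def _order_statistic_cutoff(scores: np.ndarray, target_sensitivity: float) -> float:
    n = scores.size
    if n == 0:
        raise ValueError("cannot calibrate a threshold on an empty score list")
    if not 0 < target_sensitivity <= 1:
        raise ValueError("target_sensitivity must be in (0, 1]")
    # round() guards against ceil() jumping a rank on float artefacts
    # (e.g. 0.8 * 100 binding to 80.00000000000001).
    k = math.ceil(round(target_sensitivity * n, 10))
    return float(np.sort(scores)[k - 1])


def allele_threshold(
    scores: Iterable[float], metric: str, target_sensitivity: float = 0.8
) -> float:
    """Cutoff capturing at least ``target_sensitivity`` of one allele's positives."""
    metric_column(metric)
    return _order_statistic_cutoff(np.asarray(list(scores), dtype=float), target_sensitivity)


def common_threshold(
    scores: Iterable[float], metric: str, target_sensitivity: float = 0.8
) -> float:
    """As :func:`allele_threshold`, on the pooled positives of all alleles."""
    return allele_threshold(scores, metric, target_sensitivity)


def calibrate_thresholds(
    positives: pd.DataFrame, metric: str, target_sensitivity: float = 0.8
) -> ThresholdSet:
    """Common + allele-specific thresholds from a positive score table.

    ``positives`` must carry ``allele`` and the metric's score column
    (e.g. ``el_rank``).
    """
    col = metric_column(metric)
    per = {
        allele: allele_threshold(group[col], metric, target_sensitivity)
        for allele, group in positives.groupby("allele", sort=True)
    }
    common = common_threshold(positives[col], metric, target_sensitivity)
    return ThresholdSet(metric=metric, common=common, per_allele=per, provenance="el_derived")


def binder_fraction_thresholds(
    background: pd.DataFrame, ic50_cutoff: float = 500.0
) -> ThresholdSet:
    """EL-rank thresholds set to each allele's predicted-binder percentage.

    Per allele, the fraction of background decoys with predicted IC50 at or
    below ``ic50_cutoff`` (nM) — the allele's repertoire breadth — times 100
    is reused as an EL-rank percentile cutoff; the common value pools all
    alleles.  A zero fraction is kept (flagged degenerate) so downstream
    scaling can still operate on the family.
    """
    if ic50_cutoff <= 0:
        raise ValueError("ic50_cutoff must be positive")
    if background.empty:
        raise ValueError("background score table is empty")
    per: dict[str, float] = {}
    for allele, group in background.groupby("allele", sort=True):
        if group.empty:
            raise ValueError(f"allele {allele} has no background peptides")
        frac = float((group["ic50_nm"] <= ic50_cutoff).mean())
        if frac == 0.0:
            logger.warning("allele %s: no background binder at %.0f nM; threshold 0", allele, ic50_cutoff)
        per[allele] = 100.0 * frac
    common = 100.0 * float((background["ic50_nm"] <= ic50_cutoff).mean())
    return ThresholdSet(
        metric="el_rank", common=common, per_allele=per, provenance="binder_derived"
    )


def per_allele_sensitivity(
    positives: pd.DataFrame, thresholds: ThresholdSet, factor: float = 1.0
) -> pd.Series:
    """Fraction of each allele's positives at or below its (scaled) threshold."""
    col = metric_column(thresholds.metric)
    out = {
        allele: float((group[col] <= thresholds.value_for(allele) * factor).mean())
        for allele, group in positives.groupby("allele", sort=True)
    }
    return pd.Series(out, name="sensitivity", dtype=float)


def _mean_sensitivity(positives: pd.DataFrame, thresholds: ThresholdSet, factor: float) -> float:
    return float(per_allele_sensitivity(positives, thresholds, factor).mean())


def scale_to_target(
    thresholds: ThresholdSet, eval_positives: pd.DataFrame, cfg: ScalingConfig
) -> ThresholdSet:
    """Inflate a threshold family stepwise until mean sensitivity meets target.

    Every threshold in the family is multiplied by ``(1 + step)`` per
    iteration (one shared multiplier — per-allele values are not re-tuned
    individually), stopping at the first iteration where the unweighted mean
    over alleles of per-allele sensitivity on ``eval_positives`` reaches
    ``target_mean_sensitivity``.  ``scale_applied`` is ``(1 + step)**i``.
    """
    if eval_positives.empty:
        raise ValueError("evaluation epitope set is empty")
    if eval_positives.groupby("allele").size().min() < 1:
        raise ValueError("every allele needs at least one evaluation epitope")
    for i in range(cfg.max_iterations + 1):
        factor = (1.0 + cfg.step) ** i
        mean_sens = _mean_sensitivity(eval_positives, thresholds, factor)
        # Tolerance guards against float summation artifacts when every
        # per-allele sensitivity sits exactly on the target.
        if mean_sens >= cfg.target_mean_sensitivity - 1e-12:
            logger.info(
                "scaling converged after %d iteration(s): fold %.4f, mean sensitivity %.4f",
                i,
                factor,
                mean_sens,
            )
            return thresholds.scaled(factor) if i else replace(thresholds, provenance="scaled")
    raise RuntimeError(
        f"scaling did not reach target {cfg.target_mean_sensitivity} within "
        f"{cfg.max_iterations} iterations (last mean sensitivity {mean_sens:.4f})"
    )


def repertoire_size(
    background: pd.DataFrame, metric: str, threshold: float
) -> list[RepertoireEstimate]:
    """Per-allele fraction of background decoys at or below ``threshold``.

    This is the allele's predicted repertoire size: wide for promiscuous
    alleles, narrow for fastidious ones.
    """
    if background.empty:
        raise ValueError("background score table is empty")
    col = metric_column(metric)
    return [
        RepertoireEstimate(
            allele=allele,
            fraction_bound=float((group[col] <= threshold).mean()),
            threshold_used=float(threshold),
            metric=metric,
        )
        for allele, group in background.groupby("allele", sort=True)
    ]


def repertoire_table(
    background: pd.DataFrame, thresholds: ThresholdSet
) -> pd.DataFrame:
    """Repertoire sizes per allele, each evaluated at its own family threshold."""
    col = metric_column(thresholds.metric)
    rows = []
    for allele, group in background.groupby("allele", sort=True):
        t = thresholds.value_for(allele)
        rows.append(
            {
                "allele": allele,
                "metric": thresholds.metric,
                "threshold": t,
                "fraction_bound": float((group[col] <= t).mean()),
            }
        )
    return pd.DataFrame(rows)
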