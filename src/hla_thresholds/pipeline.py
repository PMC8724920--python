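"""End-to-end orchestration: calibrate -> scale -> evaluate -> report.

Stages read and write TSV tables in a run directory so each stage is
independently testable and a run is fully determined by (config, seed).
The stage layout mirrors the analysis narrative:

1. ``run_el_calibration`` — common + allele-specific thresholds (EL rank and
   IC50) at the target sensitivity from the ligand dataset, benchmarked on
   ligands vs background;
2. ``run_epitope_scaling`` — those EL-rank thresholds evaluated unscaled on
   epitopes (exposing the ligand/epitope sensitivity gap), then stepwise
   rescaled to the target mean epitope sensitivity; binder-fraction-derived
   thresholds rescaled likewise; optional validation-set evaluation without
   re-scaling;
3. ``run_report`` — one human-readable summary (thresholds, repertoire
   sizes, ROC/AUC, common-vs-allele-specific Mean/SD tables, two-allele
   demonstration).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calibration, evaluation
from .calibration import ScalingConfig, ThresholdSet
from .curation import CurationConfig
from .background import BackgroundConfig
from .synthetic import SyntheticDataset, read_fixture

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    data_dir: str = "data"
    out_dir: str = "results"
    target_sensitivity: float = 0.8
    ic50_cutoff_nm: float = 500.0
    metrics: tuple[str, ...] = ("el_rank", "ic50")
    el_scaling: ScalingConfig = field(default_factory=lambda: ScalingConfig(step=0.05))
    binder_scaling: ScalingConfig = field(default_factory=lambda: ScalingConfig(step=0.1))
    curation: CurationConfig = field(default_factory=CurationConfig)
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("el_scaling", ScalingConfig),
            ("binder_scaling", ScalingConfig),
            ("curation", CurationConfig),
            ("background", BackgroundConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "metrics" in kwargs:
            kwargs["metrics"] = tuple(kwargs["metrics"])
        return cls(**kwargs)


def _dataset_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode()
    ).hexdigest()[:12]


def _performance_frame(
    scored: pd.DataFrame, thresholds: ThresholdSet, family: str, test_dataset: str
) -> pd.DataFrame:
    per = evaluation.evaluate_per_allele(scored, thresholds)
    summary = evaluation.summarize_across_alleles(per).reset_index()
    summary.insert(0, "threshold_family", family)
    summary.insert(1, "metric", thresholds.metric)
    summary.insert(2, "test_dataset", test_dataset)
    return summary


def _family_sets(ts: ThresholdSet) -> dict[str, ThresholdSet]:
    """Split a calibrated set into its common-only and allele-only families."""
    out = {}
    if ts.common is not None:
        out["common"] = ThresholdSet(
            metric=ts.metric,
            common=ts.common,
            provenance=ts.provenance,
            scale_applied=ts.scale_applied,
        )
    if ts.per_allele is not None:
        out["allele_specific"] = ThresholdSet(
            metric=ts.metric,
            per_allele=dict(ts.per_allele),
            provenance=ts.provenance,
            scale_applied=ts.scale_applied,
        )
    return out


def _combine(scored_pos: pd.DataFrame, background: pd.DataFrame) -> pd.DataFrame:
    return pd.concat([scored_pos, background], ignore_index=True)


def run_el_calibration(dataset: SyntheticDataset | None, cfg: RunConfig) -> dict:
    """Stage 1: ligand-derived thresholds and ligand-task performance tables."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        dataset = read_fixture(cfg.data_dir)
    alleles = sorted(dataset.ligands["allele"].unique())
    missing = set(alleles) - set(dataset.background["allele"].unique())
    if missing:
        raise ValueError(f"alleles missing background scores: {sorted(missing)}")
    logger.info(
        "calibrating on %d alleles (ligands hash %s)",
        len(alleles),
        _dataset_hash(dataset.ligands),
    )

    threshold_frames, perf_frames = [], []
    thresholds: dict[str, ThresholdSet] = {}
    for metric in cfg.metrics:
        ts = calibration.calibrate_thresholds(
            dataset.ligands, metric, cfg.target_sensitivity
        )
        thresholds[metric] = ts
        threshold_frames.append(ts.to_frame())
        combined = _combine(dataset.ligands, dataset.background)
        for family, fam_ts in _family_sets(ts).items():
            perf_frames.append(
                _performance_frame(combined, fam_ts, family, "ligands")
            )

    thresholds_df = pd.concat(threshold_frames, ignore_index=True)
    performance_df = pd.concat(perf_frames, ignore_index=True)
    thresholds_df.to_csv(out_dir / "el_thresholds.tsv", sep="\t", index=False)
    performance_df.to_csv(out_dir / "el_performance.tsv", sep="\t", index=False)
    return {
        "thresholds": thresholds,
        "thresholds_table": thresholds_df,
        "performance": performance_df,
    }


def run_epitope_scaling(
    dataset: SyntheticDataset | None,
    cfg: RunConfig,
    el_thresholds: ThresholdSet | None = None,
) -> dict:
    """Stage 2: epitope-task evaluation of EL-derived thresholds, then rescaling."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        dataset = read_fixture(cfg.data_dir)
    if el_thresholds is None:
        el_thresholds = calibration.calibrate_thresholds(
            dataset.ligands, "el_rank", cfg.target_sensitivity
        )
    epi_alleles = sorted(dataset.epitopes["allele"].unique())
    background = dataset.background[
        dataset.background["allele"].isin(epi_alleles)
    ]
    combined = _combine(dataset.epitopes, background)

    threshold_frames, perf_frames = [], []
    scaled_sets: dict[str, ThresholdSet] = {}

    families = _family_sets(el_thresholds)
    for family, fam_ts in families.items():
        # Unscaled: the ligand-calibrated thresholds under-capture epitopes.
        perf_frames.append(
            _performance_frame(combined, fam_ts, f"{family}_unscaled", "epitopes")
        )
        scaled = calibration.scale_to_target(fam_ts, dataset.epitopes, cfg.el_scaling)
        scaled_sets[f"el_{family}"] = scaled
        threshold_frames.append(
            scaled.to_frame().assign(family=family, source="el_derived")
        )
        perf_frames.append(
            _performance_frame(combined, scaled, f"{family}_scaled", "epitopes")
        )

    # Binder-fraction-derived EL-rank thresholds, rescaled with the coarser step.
    binder_ts = calibration.binder_fraction_thresholds(background, cfg.ic50_cutoff_nm)
    for family, fam_ts in _family_sets(binder_ts).items():
        if min(fam_ts.per_allele.values() if fam_ts.per_allele else [fam_ts.common]) <= 0:
            logger.warning("degenerate zero binder-fraction threshold in %s family", family)
        scaled = calibration.scale_to_target(
            fam_ts, dataset.epitopes, cfg.binder_scaling
        )
        scaled_sets[f"binder_{family}"] = scaled
        threshold_frames.append(
            scaled.to_frame().assign(family=family, source="binder_derived")
        )
        perf_frames.append(
            _performance_frame(
                combined, scaled, f"binder_{family}_scaled", "epitopes"
            )
        )

    # Independent validation epitopes: evaluate scaled families as-is.
    validation = dataset.epitopes_validation
    if validation is not None and len(validation):
        val_alleles = sorted(validation["allele"].unique())
        val_combined = _combine(
            validation,
            dataset.background[dataset.background["allele"].isin(val_alleles)],
        )
        for name, ts in scaled_sets.items():
            fam_ts = ts
            if ts.per_allele is not None:
                fam_ts = dataclasses.replace(
                    ts,
                    per_allele={
                        a: v for a, v in ts.per_allele.items() if a in val_alleles
                    },
                )
            perf_frames.append(
                _performance_frame(val_combined, fam_ts, f"{name}_scaled", "epitopes_validation")
            )

    thresholds_df = pd.concat(threshold_frames, ignore_index=True)
    performance_df = pd.concat(perf_frames, ignore_index=True)
    thresholds_df.to_csv(out_dir / "epitope_thresholds.tsv", sep="\t", index=False)
    performance_df.to_csv(out_dir / "epitope_performance.tsv", sep="\t", index=False)
    return {
        "scaled": scaled_sets,
        "thresholds_table": thresholds_df,
        "performance": performance_df,
    }


def _fmt_table(df: pd.DataFrame) -> str:
    return df.to_string(index=False, float_format=lambda x: f"{x:.4f}")


def run_report(dataset: SyntheticDataset | None, cfg: RunConfig) -> str:
    """Stage 3: one deterministic plain-text report over all prior outputs."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        dataset = read_fixture(cfg.data_dir)

    stage1 = run_el_calibration(dataset, cfg)
    stage2 = run_epitope_scaling(
        dataset, cfg, el_thresholds=stage1["thresholds"].get("el_rank")
    )

    sections = []
    sections.append(
        "## Threshold families (ligand-derived, target sensitivity "
        f"{cfg.target_sensitivity:.0%})\n" + _fmt_table(stage1["thresholds_table"])
    )

    el_ts = stage1["thresholds"].get("el_rank")
    if el_ts is not None and el_ts.per_allele:
        rep = calibration.repertoire_table(dataset.background, el_ts)
        sections.append(
            "## Repertoire sizes (fraction of background at the allele-specific "
            "EL-rank threshold)\n" + _fmt_table(rep)
        )

    try:
        combined = _combine(dataset.ligands, dataset.background)
        aucs = evaluation.compare_metric_aucs(combined, tuple(cfg.metrics))
        sections.append(
            "## ROC AUC, ligands vs background (pooled over alleles)\n"
            + _fmt_table(aucs)
        )
    except ValueError as exc:
        sections.append(f"## ROC AUC\nsection skipped: {exc}")

    mean_sd = stage2["performance"]
    mean_sd = mean_sd[mean_sd["allele"].isin(["Mean", "SD"])]
    sections.append(
        "## Common vs allele-specific performance on epitopes (Mean/SD across alleles)\n"
        + _fmt_table(mean_sd)
    )

    demo = _two_allele_section(dataset, el_ts)
    sections.append(demo)

    report = "\n\n".join(sections) + "\n"
    (out_dir / "report.txt").write_text(report)
    return report


def _two_allele_section(dataset: SyntheticDataset, el_ts: ThresholdSet | None) -> str:
    header = "## Two-allele demonstration (widest vs narrowest calibrated threshold)"
    if el_ts is None or not el_ts.per_allele:
        return f"{header}\nsection skipped: no allele-specific EL-rank thresholds"
    epi_alleles = set(dataset.epitopes["allele"].unique())
    per = {a: v for a, v in el_ts.per_allele.items() if a in epi_alleles}
    if len(per) < 2:
        return f"{header}\nsection skipped: fewer than two alleles with epitopes"
    ranked = sorted(per, key=per.get)
    pair = [ranked[0], ranked[-1]]
    scored = pd.concat(
        [
            dataset.epitopes[dataset.epitopes["allele"].isin(pair)],
            dataset.background[dataset.background["allele"].isin(pair)],
        ],
        ignore_index=True,
    )
    table = evaluation.two_allele_demo(
        scored, {a: per[a] for a in pair}, el_ts.common, metric="el_rank"
    )
    return (
        f"{header}\nalleles: {pair[0]} (threshold {per[pair[0]]:.3f}) and "
        f"{pair[1]} (threshold {per[pair[1]]:.3f}); common {el_ts.common:.3f}\n"
        + _fmt_table(table)
    )
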