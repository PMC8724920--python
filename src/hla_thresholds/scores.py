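"""Prediction-score containers and I/O.

Every peptide-allele pair carries four NetMHCpan-4.0-style outputs:

* ``ic50_nm`` — predicted binding affinity as an IC50 in nM (lower = stronger);
* ``ba_rank`` — binding-affinity percentile rank in [0, 100] (lower = better);
* ``el_score`` — eluted-ligand likelihood in [0, 1] (higher = better);
* ``el_rank`` — eluted-ligand percentile rank in [0, 100] (lower = better).

Percentile ranks are carried on the 0-100 scale throughout; all thresholding
uses lower-is-positive metrics (``ic50``, ``el_rank``, ``ba_rank``), so a
peptide is called positive when its score is at or below the threshold.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: Metrics eligible for thresholding; all oriented lower-is-positive.
THRESHOLD_METRICS = ("ic50", "el_rank", "ba_rank")

#: Mapping from metric name to score-table column.
METRIC_COLUMNS = {"ic50": "ic50_nm", "el_rank": "el_rank", "ba_rank": "ba_rank"}

SCORE_COLUMNS = ["sequence", "allele", "ic50_nm", "ba_rank", "el_score", "el_rank", "role"]


@dataclass(frozen=True)
class ScoredPeptide:
    sequence: str
    allele: str
    ic50: float
    ba_rank: float
    el_score: float
    el_rank: float
    role: str = "background"


def metric_column(metric: str) -> str:
    if metric not in METRIC_COLUMNS:
        raise ValueError(
            f"unknown or non-thresholdable metric {metric!r}; "
            f"expected one of {THRESHOLD_METRICS}"
        )
    return METRIC_COLUMNS[metric]


def _validate_ranges(df: pd.DataFrame) -> pd.Series:
    ok = (
        (df["ic50_nm"] > 0)
        & df["ba_rank"].between(0, 100)
        & df["el_rank"].between(0, 100)
        & df["el_score"].between(0, 1)
    )
    return ok


def read_score_table(path, format: str = "artifact-tsv") -> pd.DataFrame:
    """Read a score table in either supported dialect.

    ``artifact-tsv`` is this package's own single-header TSV with columns
    ``sequence, allele, ic50_nm, ba_rank, el_score, el_rank, role``.
    ``netmhcpan-xls`` is the NetMHCpan 4.0 tab-delimited "xls" export whose
    first line carries the allele name and whose second line holds the column
    headers (Peptide, EL score/rank, BA IC50/rank).

    Rows violating the range invariants (non-positive IC50, ranks outside
    [0, 100], EL score outside [0, 1]) are rejected and counted in the log.
    """
    if format == "artifact-tsv":
        df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "allele": str})
        missing = [c for c in SCORE_COLUMNS if c not in df.columns and c != "role"]
        if missing:
            raise ValueError(f"artifact-tsv missing column(s) {missing}")
        if "role" not in df.columns:
            df["role"] = "background"
    elif format == "netmhcpan-xls":
        df = _read_netmhcpan_xls(path)
    else:
        raise ValueError(f"unknown score-table format {format!r}")

    ok = _validate_ranges(df)
    if not ok.all():
        logger.warning(
            "rejecting %d score row(s) violating range invariants", int((~ok).sum())
        )
        df = df[ok]
    return df[SCORE_COLUMNS].reset_index(drop=True)


def _read_netmhcpan_xls(path) -> pd.DataFrame:
    """NetMHCpan 4.0 tab 'xls' export: allele line, then a header line."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = text.splitlines()
    if len(lines) < 2:
        raise ValueError("netmhcpan-xls file too short to contain its two-line header")
    allele_line = lines[0].split("\t")
    allele = next((tok.strip() for tok in allele_line if tok.strip()), "")
    body = pd.read_csv(io.StringIO("\n".join(lines[1:])), sep="\t")
    body.columns = [str(c).strip() for c in body.columns]

    def pick(*names):
        for n in names:
            if n in body.columns:
                return n
        raise ValueError(f"netmhcpan-xls header lacks any of {names}")

    out = pd.DataFrame(
        {
            "sequence": body[pick("Peptide", "peptide")].astype(str),
            "allele": allele,
            "ic50_nm": body[pick("ic50", "Aff(nM)", "aff")].astype(float),
            "ba_rank": body[pick("BA_Rank", "Rank_BA", "ba_rank")].astype(float),
            "el_score": body[pick("EL_Score", "Score_EL", "Ave", "el_score")].astype(float),
            "el_rank": body[pick("EL_Rank", "Rank_EL", "Rank", "el_rank")].astype(float),
        }
    )
    out["role"] = "background"
    return out


def write_score_table(df: pd.DataFrame, path) -> None:
    """Write the artifact-tsv dialect (round-trips with read_score_table)."""
    df.to_csv(path, sep="\t", index=False, columns=SCORE_COLUMNS)


def join_scores(peptides: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Annotate a peptide table with its four scores, exactly on (sequence, allele).

    Score rows duplicated with identical values are collapsed silently;
    duplicates with conflicting values raise, as they signal an upstream
    prediction mismatch.  A peptide without a score row raises, listing up to
    ten missing pairs.
    """
    key = ["sequence", "allele"]
    score_cols = ["ic50_nm", "ba_rank", "el_score", "el_rank"]
    scores = scores.drop_duplicates(subset=key + score_cols)
    dup = scores.duplicated(subset=key, keep=False)
    if dup.any():
        pairs = scores.loc[dup, key].drop_duplicates().head(10).itertuples(index=False)
        raise ValueError(
            "conflicting duplicate score rows for pairs: "
            + ", ".join(f"{s}/{a}" for s, a in pairs)
        )
    merged = peptides.merge(scores[key + score_cols], on=key, how="left")
    missing = merged["el_rank"].isna()
    if missing.any():
        pairs = merged.loc[missing, key].head(10).itertuples(index=False)
        raise KeyError(
            f"{int(missing.sum())} peptide(s) lack score rows, e.g.: "
            + ", ".join(f"{s}/{a}" for s, a in pairs)
        )
    return merged
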