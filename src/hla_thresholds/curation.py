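"""Curation of eluted-ligand and T-cell-epitope records from IEDB-style exports.

The curation rules implemented here mirror standard immunopeptidomics
practice for building benchmark datasets of HLA class I 9-mer peptides:

* keep only peptides of the configured length (9 by default) made of the 20
  canonical amino acids;
* require a defined four-digit HLA restriction (allele group + specific
  protein, e.g. ``HLA-A*02:01``; serotype-level names like ``HLA-A2`` are
  dropped);
* collapse duplicate (sequence, allele) observations — for epitopes, keeping
  the most positive assay outcome;
* drop alleles that do not reach a minimum number of retained records;
* optionally subsample a fixed number of peptides per allele, reproducibly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Assay outcomes ordered from least to most positive.  Tetramer staining is
#: the most stringent evidence of MHC restriction; graded functional readouts
#: rank below it.  ``none`` is reserved for background decoys.
OUTCOME_LEVELS: dict[str, int] = {
    "none": 0,
    "positive-low": 1,
    "positive": 2,
    "positive-intermediate": 3,
    "positive-high": 4,
    "tetramer": 5,
}

ROLES = ("ligand", "epitope", "background")

# Four-digit (protein-level) HLA class I allele, e.g. HLA-A*02:01.
_ALLELE_RE = re.compile(r"^HLA-[A-Z]+\d*\*\d{2,3}:\d{2,3}$")


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide-allele observation with its provenance."""

    sequence: str
    allele: str
    role: str
    outcome: str = "none"
    source_protein_id: str = ""
    pubmed_id: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "background" and self.outcome != "none":
            raise ValueError("background records must have outcome 'none'")


@dataclass
class CurationConfig:
    peptide_length: int = 9
    min_ligands_per_allele: int = 100
    ligands_sampled_per_allele: int = 100
    min_assays_per_allele_epitope: int = 20
    epitopes_sampled_per_allele: int = 50
    excluded_pubmed_ids: frozenset[str] = frozenset({"28188227", "29393594"})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.peptide_length,
            self.min_ligands_per_allele,
            self.ligands_sampled_per_allele,
            self.min_assays_per_allele_epitope,
            self.epitopes_sampled_per_allele,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all curation counts must be strictly positive")
        if self.ligands_sampled_per_allele > self.min_ligands_per_allele:
            raise ValueError(
                "ligands_sampled_per_allele must not exceed min_ligands_per_allele"
            )
        self.excluded_pubmed_ids = frozenset(str(p) for p in self.excluded_pubmed_ids)


@dataclass
class ColumnMap:
    """Maps logical fields to column names of an assay export.

    ``header_rows=2`` handles IEDB full exports whose CSV carries a two-row
    header; the two rows are flattened to ``"top - bottom"`` names, and the
    mapping refers to the flattened names.
    """

    sequence: str = "Description"
    allele: str = "Allele Name"
    outcome: str = "Qualitative Measure"
    source_protein: str = "Parent Protein IRI"
    pubmed: str = "PubMed ID"
    header_rows: int = 1

    def mapped_columns(self) -> dict[str, str]:
        return {
            "sequence": self.sequence,
            "allele": self.allele,
            "outcome": self.outcome,
            "source_protein": self.source_protein,
            "pubmed": self.pubmed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnMap":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown column-map keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ParseResult:
    records: list[PeptideRecord]
    n_rows: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def is_valid_allele(name: str) -> bool:
    """True for a four-digit (protein-level) HLA allele name."""
    return bool(_ALLELE_RE.match(name))


def is_valid_sequence(seq: str) -> bool:
    return bool(seq) and set(seq) <= CANONICAL_AA


def normalize_outcome(label: str) -> str | None:
    """Map an assay-outcome label to the canonical hierarchy, or None."""
    norm = str(label).strip().lower().replace(" ", "-")
    return norm if norm in OUTCOME_LEVELS else None


def _flatten_two_row_header(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [
        str(b).strip() if str(a).startswith("Unnamed") else f"{a} - {b}".strip()
        for a, b in df.columns
    ]
    return df


def parse_assay_export(
    path, dialect: ColumnMap | dict | None = None, role: str = "ligand"
) -> ParseResult:
    """Parse an IEDB-style CSV export into peptide records.

    Rows without a parseable sequence (canonical amino acids only) or without
    a syntactically valid allele name are dropped and counted in the returned
    :class:`ParseResult`.  Outcome labels outside the known hierarchy are
    carried as-is here and rejected later by :func:`filter_epitopes`.
    """
    if dialect is None:
        dialect = ColumnMap()
    elif isinstance(dialect, dict):
        dialect = ColumnMap.from_dict(dialect)

    try:
        if dialect.header_rows == 2:
            df = pd.read_csv(path, header=[0, 1], dtype=str, keep_default_na=False)
            df = _flatten_two_row_header(df)
        else:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read assay export {path}: {exc}") from exc

    missing = [c for c in dialect.mapped_columns().values() if c not in df.columns]
    if missing:
        raise KeyError(
            f"mapped column(s) {missing} absent from export; found {list(df.columns)}"
        )

    cols = dialect.mapped_columns()
    records: list[PeptideRecord] = []
    dropped = {"bad_sequence": 0, "bad_allele": 0}
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        seq = str(row_d[cols["sequence"]]).strip().upper()
        allele = str(row_d[cols["allele"]]).strip()
        if not is_valid_sequence(seq):
            dropped["bad_sequence"] += 1
            continue
        if not allele or not is_valid_allele(allele):
            dropped["bad_allele"] += 1
            continue
        outcome = normalize_outcome(row_d[cols["outcome"]]) or str(
            row_d[cols["outcome"]]
        ).strip().lower()
        if role == "ligand":
            outcome = outcome if outcome in OUTCOME_LEVELS else "positive"
        records.append(
            PeptideRecord(
                sequence=seq,
                allele=allele,
                role=role,
                outcome=outcome if role != "background" else "none",
                source_protein_id=str(row_d[cols["source_protein"]]).strip(),
                pubmed_id=str(row_d[cols["pubmed"]]).strip(),
            )
        )
    result = ParseResult(records=records, n_rows=len(df), dropped=dropped)
    logger.info(
        "parsed %d/%d rows from %s (dropped: %s)",
        len(records),
        result.n_rows,
        path,
        dropped,
    )
    return result


def records_to_frame(records: list[PeptideRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence": r.sequence,
                "allele": r.allele,
                "role": r.role,
                "outcome": r.outcome,
                "source_protein_id": r.source_protein_id,
                "pubmed_id": r.pubmed_id,
            }
            for r in records
        ],
        columns=[
            "sequence",
            "allele",
            "role",
            "outcome",
            "source_protein_id",
            "pubmed_id",
        ],
    )


def filter_ligands(
    records: list[PeptideRecord] | pd.DataFrame, cfg: CurationConfig
) -> pd.DataFrame:
    """Apply the eluted-ligand retention rules.

    Excludes blacklisted PubMed IDs, keeps only peptides of the configured
    length, retains one instance per (sequence, allele) pair (first in input
    order), and drops alleles with fewer than ``min_ligands_per_allele``
    unique ligands.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        logger.warning("filter_ligands received an empty input")
        return df.copy()
    df = df[~df["pubmed_id"].astype(str).isin(cfg.excluded_pubmed_ids)]
    df = df[df["sequence"].str.len() == cfg.peptide_length]
    df = df[df["allele"].map(is_valid_allele)]
    df = df.drop_duplicates(subset=["sequence", "allele"], keep="first")
    counts = df.groupby("allele")["sequence"].size()
    keep = counts[counts >= cfg.min_ligands_per_allele].index
    dropped_alleles = sorted(set(counts.index) - set(keep))
    if dropped_alleles:
        logger.info(
            "dropping %d allele(s) below %d unique ligands: %s",
            len(dropped_alleles),
            cfg.min_ligands_per_allele,
            dropped_alleles,
        )
    return df[df["allele"].isin(keep)].reset_index(drop=True)


def filter_epitopes(
    records: list[PeptideRecord] | pd.DataFrame, cfg: CurationConfig
) -> pd.DataFrame:
    """Apply the T-cell-epitope retention rules.

    Keeps 9-mers with a defined four-digit restriction; for duplicate
    (sequence, allele) pairs retains the most positive outcome (first record
    wins ties, in input order); an epitope found in several source proteins is
    one instance.  Alleles with fewer than ``min_assays_per_allele_epitope``
    retained records are removed.  Records with outcome labels outside the
    hierarchy are rejected with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        logger.warning("filter_epitopes received an empty input")
        return df.copy()
    unknown = ~df["outcome"].isin(OUTCOME_LEVELS)
    if unknown.any():
        labels = sorted(df.loc[unknown, "outcome"].unique())
        logger.warning(
            "rejecting %d record(s) with unknown outcome label(s): %s",
            int(unknown.sum()),
            labels,
        )
        df = df[~unknown]
    df = df[df["sequence"].str.len() == cfg.peptide_length]
    df = df[df["allele"].map(is_valid_allele)]
    # Most-positive-outcome dedup, stable: a stable sort on descending level
    # keeps input order within each level, so `first` breaks ties by position.
    levels = df["outcome"].map(OUTCOME_LEVELS)
    order = np.argsort(-levels.to_numpy(), kind="stable")
    df = df.iloc[order].drop_duplicates(subset=["sequence", "allele"], keep="first")
    counts = df.groupby("allele")["sequence"].size()
    keep = counts[counts >= cfg.min_assays_per_allele_epitope].index
    return df[df["allele"].isin(keep)].sort_index().reset_index(drop=True)


def sample_per_allele(table: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Draw exactly ``n`` peptides per allele, uniformly without replacement.

    A single RNG seeded from ``seed`` is consumed in sorted-allele order, so
    the selection is reproducible regardless of input row order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for allele in sorted(table["allele"].unique()):
        sub = table[table["allele"] == allele].sort_values("sequence")
        if len(sub) < n:
            raise ValueError(
                f"allele {allele} has only {len(sub)} peptides; {n} requested"
            )
        idx = rng.choice(len(sub), size=n, replace=False)
        out.append(sub.iloc[np.sort(idx)])
    return pd.concat(out, ignore_index=True)


def sample_disjoint(
    table: pd.DataFrame, exclude: pd.DataFrame, n: int, seed: int
) -> pd.DataFrame:
    """Sample ``n`` peptides per allele from rows disjoint from ``exclude``.

    Used to build an independent validation set that shares no (sequence,
    allele) pair with a previously drawn sample.  Alleles without ``n``
    remaining peptides are omitted (with a log notice) rather than failing,
    since typically only a subset of alleles has enough spare records.
    """
    key = ["sequence", "allele"]
    merged = table.merge(exclude[key].drop_duplicates(), on=key, how="left", indicator=True)
    remaining = table[(merged["_merge"] == "left_only").to_numpy()]
    counts = remaining.groupby("allele")["sequence"].size()
    eligible = counts[counts >= n].index
    skipped = sorted(set(remaining["allele"].unique()) - set(eligible))
    if skipped:
        logger.info(
            "validation sampling skipped %d allele(s) with <%d spare peptides",
            len(skipped),
            n,
        )
    if len(eligible) == 0:
        return remaining.iloc[0:0].copy()
    return sample_per_allele(remaining[remaining["allele"].isin(eligible)], n, seed)


def write_peptide_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("sequence", "allele", "role", "outcome") if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_peptide_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sequence": str, "allele": str})
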