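"""Decoy (background) peptide construction from source proteins.

Background 9-mers are drawn uniformly from the set of all distinct k-mer
windows of the positive peptides' source proteins, excluding any sequence
already present in a positive dataset; the one shared decoy list is then
assigned to every analyzed allele, so each allele is benchmarked against an
identical negative set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .curation import CANONICAL_AA, PeptideRecord

logger = logging.getLogger(__name__)


@dataclass
class BackgroundConfig:
    k: int = 9
    n_background: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.n_background <= 0:
            raise ValueError("k and n_background must be positive")


def extract_kmers(proteins, k: int) -> set[str]:
    """All distinct length-``k`` windows over the given proteins.

    ``proteins`` may be a FASTA path or an iterable of (id, sequence) pairs /
    Bio.SeqRecord objects.  Windows containing non-canonical residues
    (B, J, O, U, X, Z, ...) are discarded; sequences shorter than ``k`` are
    skipped with a warning.
    """
    if isinstance(proteins, (str, bytes)) or hasattr(proteins, "__fspath__"):
        proteins = SeqIO.parse(proteins, "fasta")
    kmers: set[str] = set()
    n_short = 0
    for rec in proteins:
        if hasattr(rec, "seq"):
            seq = str(rec.seq).upper()
        else:
            _, seq = rec
            seq = str(seq).upper()
        if len(seq) < k:
            n_short += 1
            continue
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) <= CANONICAL_AA:
                kmers.add(window)
    if n_short:
        logger.warning("skipped %d protein(s) shorter than k=%d", n_short, k)
    return kmers


def sample_background(
    kmers: set[str], cfg: BackgroundConfig, exclude: Iterable[str] = ()
) -> list[PeptideRecord]:
    """Uniform sample of ``n_background`` decoys from ``kmers`` minus ``exclude``.

    Exclusion is applied against the union of positive sequences over all
    alleles before sampling, so a peptide observed as a ligand or epitope
    anywhere is kept only in the positive datasets.  Deterministic under
    ``cfg.rng_seed``.
    """
    eligible = sorted(kmers - set(exclude))
    if len(eligible) < cfg.n_background:
        raise ValueError(
            f"only {len(eligible)} eligible k-mers after exclusion; "
            f"{cfg.n_background} requested (shortfall {cfg.n_background - len(eligible)})"
        )
    rng = np.random.default_rng(cfg.rng_seed)
    idx = rng.choice(len(eligible), size=cfg.n_background, replace=False)
    return [
        PeptideRecord(sequence=eligible[i], allele="", role="background")
        for i in np.sort(idx)
    ]


def assign_to_alleles(
    background: list[PeptideRecord] | pd.DataFrame, alleles: list[str]
) -> pd.DataFrame:
    """Cross-product of the shared decoy list with every analyzed allele."""
    if isinstance(background, pd.DataFrame):
        sequences = background["sequence"].tolist()
    else:
        sequences = [r.sequence for r in background]
    if not sequences:
        raise ValueError("background peptide list is empty")
    if not alleles:
        raise ValueError("allele list is empty")
    return pd.DataFrame(
        {
            "sequence": np.repeat(sequences, len(alleles)),
            "allele": np.tile(alleles, len(sequences)),
            "role": "background",
            "outcome": "none",
        }
    )
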