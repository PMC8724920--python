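"""Curation rules: parsing dialects, retention filters, reproducible sampling."""

import numpy as np
import pandas as pd
import pytest

from hla_thresholds import curation
from hla_thresholds.curation import (
    ColumnMap,
    CurationConfig,
    PeptideRecord,
    filter_epitopes,
    filter_ligands,
    parse_assay_export,
    records_to_frame,
    sample_disjoint,
    sample_per_allele,
)

from conftest import random_unique_9mers


def _export_csv(tmp_path, rows, columns=None, name="export.csv"):
    columns = columns or ColumnMap()
    df = pd.DataFrame(
        rows,
        columns=[
            columns.sequence,
            columns.allele,
            columns.outcome,
            columns.source_protein,
            columns.pubmed,
        ],
    )
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


ROWS = [
    ("AAAAAAAAK", "HLA-A*02:01", "Positive", "P1", "1"),
    ("CCCCCCCCK", "HLA-A*02:01", "Positive-High", "P1", "2"),
    ("DDDDDDDDK", "HLA-B*07:02", "Positive-Low", "P2", "3"),
    ("EEEEEEEEK", "HLA-B*07:02", "tetramer", "P2", "4"),
    ("FFFFFFFFK", "HLA-C*05:01", "Positive", "P3", "5"),
]


class TestParseAssayExport:
    def test_identity_parse(self, tmp_path):
        result = parse_assay_export(_export_csv(tmp_path, ROWS))
        assert len(result.records) == 5
        assert result.n_dropped == 0
        assert result.records[0] == PeptideRecord(
            "AAAAAAAAK", "HLA-A*02:01", "ligand", "positive", "P1", "1"
        )

    def test_row_with_empty_allele_dropped_and_counted(self, tmp_path):
        rows = ROWS + [("GGGGGGGGK", "", "Positive", "P4", "6")]
        result = parse_assay_export(_export_csv(tmp_path, rows))
        assert len(result.records) == 5
        assert result.dropped["bad_allele"] == 1

    def test_unparseable_sequence_dropped(self, tmp_path):
        rows = ROWS + [("AAAX1AAAK", "HLA-A*02:01", "Positive", "P4", "6")]
        result = parse_assay_export(_export_csv(tmp_path, rows))
        assert result.dropped["bad_sequence"] == 1

    def test_remapped_dialect_yields_identical_records(self, tmp_path):
        alt = ColumnMap(
            sequence="pep", allele="hla", outcome="qual", source_protein="src", pubmed="pmid"
        )
        default = parse_assay_export(_export_csv(tmp_path, ROWS)).records
        remapped = parse_assay_export(
            _export_csv(tmp_path, ROWS, columns=alt, name="alt.csv"), dialect=alt
        ).records
        assert default == remapped

    def test_two_row_header_flatten(self, tmp_path):
        path = tmp_path / "two_row.csv"
        path.write_text(
            "Epitope,Epitope,Assay,Epitope,Reference\n"
            "Description,Allele Name,Qualitative Measure,Parent Protein IRI,PubMed ID\n"
            "AAAAAAAAK,HLA-A*02:01,Positive,P1,1\n"
        )
        dialect = ColumnMap(
            sequence="Epitope - Description",
            allele="Epitope - Allele Name",
            outcome="Assay - Qualitative Measure",
            source_protein="Epitope - Parent Protein IRI",
            pubmed="Reference - PubMed ID",
            header_rows=2,
        )
        result = parse_assay_export(path, dialect=dialect)
        assert [r.sequence for r in result.records] == ["AAAAAAAAK"]

    def test_missing_mapped_column_is_configuration_error(self, tmp_path):
        with pytest.raises(KeyError, match="Qualitative Measure"):
            parse_assay_export(
                _export_csv(tmp_path, ROWS),
                dialect=ColumnMap(outcome="Qualitative Measure 2"),
            )

    def test_unreadable_file_is_io_error(self, tmp_path):
        with pytest.raises(OSError):
            parse_assay_export(tmp_path / "nope.csv")


def _ligand_frame(rng, per_allele_counts, pubmed="9"):
    rows = []
    for allele, n in per_allele_counts.items():
        for seq in random_unique_9mers(rng, n):
            rows.append(
                PeptideRecord(seq, allele, "ligand", "positive", "P", pubmed)
            )
    return records_to_frame(rows)


class TestFilterLigands:
    def test_minimum_ligands_per_allele_boundary(self):
        rng = np.random.default_rng(0)
        df = pd.concat(
            [
                _ligand_frame(rng, {"HLA-A*01:01": 120}),
                _ligand_frame(rng, {"HLA-A*02:01": 100}),
                _ligand_frame(rng, {"HLA-A*03:01": 99}),
            ]
        )
        out = filter_ligands(df, CurationConfig())
        assert sorted(out["allele"].unique()) == ["HLA-A*01:01", "HLA-A*02:01"]

    def test_excluded_pubmed_ids_removed(self):
        rng = np.random.default_rng(1)
        keep = _ligand_frame(rng, {"HLA-A*01:01": 100}, pubmed="123")
        drop = _ligand_frame(rng, {"HLA-A*01:01": 100}, pubmed="28188227")
        drop2 = _ligand_frame(rng, {"HLA-A*02:01": 100}, pubmed="29393594")
        out = filter_ligands(pd.concat([keep, drop, drop2]), CurationConfig())
        assert set(out["pubmed_id"]) == {"123"}

    def test_non_9mers_removed(self):
        rng = np.random.default_rng(2)
        df = _ligand_frame(rng, {"HLA-A*01:01": 100})
        extra = records_to_frame(
            [
                PeptideRecord("AAAAAAAA", "HLA-A*01:01", "ligand"),
                PeptideRecord("AAAAAAAAAA", "HLA-A*01:01", "ligand"),
            ]
        )
        out = filter_ligands(
            pd.concat([df, extra]),
            CurationConfig(min_ligands_per_allele=1, ligands_sampled_per_allele=1),
        )
        assert (out["sequence"].str.len() == 9).all()

    def test_duplicates_collapsed_and_idempotent(self):
        rng = np.random.default_rng(3)
        df = _ligand_frame(rng, {"HLA-A*01:01": 100})
        doubled = pd.concat([df, df])
        cfg = CurationConfig()
        out = filter_ligands(doubled, cfg)
        assert not out.duplicated(subset=["sequence", "allele"]).any()
        assert len(out) == 100
        pd.testing.assert_frame_equal(filter_ligands(out, cfg), out)

    def test_empty_input_gives_empty_output(self):
        out = filter_ligands(records_to_frame([]), CurationConfig())
        assert out.empty


class TestSamplePerAllele:
    def test_exhaustive_when_n_equals_count(self):
        rng = np.random.default_rng(4)
        df = _ligand_frame(rng, {"HLA-A*01:01": 10})
        out = sample_per_allele(df, 10, seed=0)
        assert sorted(out["sequence"]) == sorted(df["sequence"])

    def test_same_seed_identical_outputs(self):
        rng = np.random.default_rng(5)
        df = _ligand_frame(rng, {"HLA-A*01:01": 50, "HLA-B*07:02": 50})
        a = sample_per_allele(df, 20, seed=42)
        b = sample_per_allele(df, 20, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = sample_per_allele(df, 20, seed=43)
        assert not a["sequence"].equals(c["sequence"])

    def test_input_row_order_does_not_change_selection(self):
        rng = np.random.default_rng(6)
        df = _ligand_frame(rng, {"HLA-A*01:01": 50, "HLA-B*07:02": 50})
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        a = sample_per_allele(df, 20, seed=7)
        b = sample_per_allele(shuffled, 20, seed=7)
        assert set(map(tuple, a[["sequence", "allele"]].values)) == set(
            map(tuple, b[["sequence", "allele"]].values)
        )

    def test_subset_of_exact_size_per_allele(self):
        rng = np.random.default_rng(7)
        df = _ligand_frame(rng, {"HLA-A*01:01": 30, "HLA-B*07:02": 40})
        out = sample_per_allele(df, 25, seed=0)
        assert out.groupby("allele").size().eq(25).all()
        merged = out.merge(df, on=list(out.columns), how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_short_allele_raises_naming_it(self):
        rng = np.random.default_rng(8)
        df = _ligand_frame(rng, {"HLA-A*01:01": 9})
        with pytest.raises(ValueError, match="HLA-A\\*01:01"):
            sample_per_allele(df, 10, seed=0)


def _epitope_records(n, allele="HLA-A*02:01", outcome="positive", rng_seed=9):
    rng = np.random.default_rng(rng_seed)
    return [
        PeptideRecord(seq, allele, "epitope", outcome)
        for seq in random_unique_9mers(rng, n)
    ]


class TestFilterEpitopes:
    cfg = CurationConfig()

    def test_most_positive_outcome_kept_on_duplicate(self):
        recs = _epitope_records(20) + [
            PeptideRecord("KKKKKKKKK", "HLA-A*02:01", "epitope", "positive-low"),
            PeptideRecord("KKKKKKKKK", "HLA-A*02:01", "epitope", "positive-high"),
        ]
        out = filter_epitopes(recs, self.cfg)
        kept = out[out["sequence"] == "KKKKKKKKK"]
        assert len(kept) == 1
        assert kept["outcome"].iloc[0] == "positive-high"

    def test_positivity_hierarchy_is_strict_total_order(self):
        order = ["positive-low", "positive", "positive-intermediate", "positive-high", "tetramer"]
        for lower, higher in zip(order, order[1:]):
            recs = _epitope_records(20) + [
                PeptideRecord("KKKKKKKKK", "HLA-A*02:01", "epitope", lower),
                PeptideRecord("KKKKKKKKK", "HLA-A*02:01", "epitope", higher),
            ]
            out = filter_epitopes(recs, self.cfg)
            assert out[out["sequence"] == "KKKKKKKKK"]["outcome"].iloc[0] == higher

    def test_tied_outcomes_keep_first_in_input_order(self):
        recs = _epitope_records(20) + [
            PeptideRecord("KKKKKKKKK", "HLA-A*02:01", "epitope", "positive", "protA"),
            PeptideRecord("KKKKKKKKK", "HLA-A*02:01", "epitope", "positive", "protB"),
        ]
        out = filter_epitopes(recs, self.cfg)
        kept = out[out["sequence"] == "KKKKKKKKK"]
        assert kept["source_protein_id"].tolist() == ["protA"]

    def test_allele_minimum_assay_boundary(self):
        recs = _epitope_records(20, "HLA-A*02:01") + _epitope_records(
            19, "HLA-B*07:02", rng_seed=10
        )
        out = filter_epitopes(recs, self.cfg)
        assert sorted(out["allele"].unique()) == ["HLA-A*02:01"]

    def test_multi_protein_epitope_single_instance(self):
        recs = _epitope_records(20) + [
            PeptideRecord("KKKKKKKKK", "HLA-A*02:01", "epitope", "positive", "protA"),
            PeptideRecord("KKKKKKKKK", "HLA-A*02:01", "epitope", "positive", "protB"),
        ]
        out = filter_epitopes(recs, self.cfg)
        assert (out["sequence"] == "KKKKKKKKK").sum() == 1

    def test_unknown_outcome_rejected_with_warning(self, caplog):
        recs = _epitope_records(20) + [
            PeptideRecord("KKKKKKKKK", "HLA-A*02:01", "epitope", "weird-label")
        ]
        with caplog.at_level("WARNING"):
            out = filter_epitopes(recs, self.cfg)
        assert "weird-label" in caplog.text
        assert "KKKKKKKKK" not in set(out["sequence"])

    def test_serotype_restriction_dropped(self):
        recs = _epitope_records(20)
        df = records_to_frame(recs)
        df.loc[0, "allele"] = "HLA-A2"
        out = filter_epitopes(df, CurationConfig(min_assays_per_allele_epitope=1))
        assert "HLA-A2" not in set(out["allele"])

    def test_idempotent(self):
        out = filter_epitopes(_epitope_records(25), self.cfg)
        pd.testing.assert_frame_equal(filter_epitopes(out, self.cfg), out)


class TestSampleDisjoint:
    def test_validation_sample_shares_no_pair_with_primary(self):
        recs = _epitope_records(60)
        table = records_to_frame(recs)
        primary = sample_per_allele(table, 30, seed=0)
        validation = sample_disjoint(table, primary, 20, seed=1)
        overlap = validation.merge(primary, on=["sequence", "allele"], how="inner")
        assert overlap.empty
        assert len(validation) == 20

    def test_alleles_without_enough_spare_records_are_omitted(self):
        table = records_to_frame(
            _epitope_records(40, "HLA-A*02:01")
            + _epitope_records(25, "HLA-B*07:02", rng_seed=12)
        )
        primary = sample_per_allele(table, 20, seed=0)
        validation = sample_disjoint(table, primary, 10, seed=1)
        assert sorted(validation["allele"].unique()) == ["HLA-A*02:01"]


class TestConfigValidation:
    def test_sample_larger_than_minimum_rejected(self):
        with pytest.raises(ValueError):
            CurationConfig(min_ligands_per_allele=50, ligands_sampled_per_allele=60)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            CurationConfig(min_assays_per_allele_epitope=0)

    def test_background_role_requires_none_outcome(self):
        with pytest.raises(ValueError):
            PeptideRecord("AAAAAAAAK", "HLA-A*02:01", "background", "positive")
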