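import numpy as np
import pytest

from mirtarnet import (
    DataKind,
    EntityKind,
    ExpressionDataset,
    load_case_study_tables,
    read_expression_dataset,
    read_sequence_target_db,
)
from mirtarnet.data_io import (
    DesignError,
    FormatError,
    match_tcga_barcodes,
    write_expression_dataset,
)

from conftest import make_dataset


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadExpressionDataset:
    def test_multisample_identity_parse(self, tmp_path):
        p = write_tsv(
            tmp_path / "m.tsv",
            "id\ts1\ts2\ts3\ts4\na\t1\t2\t3\t4\nb\t5\t6\t7\t8\nc\t9\t10\t11\t12\n",
        )
        ds = read_expression_dataset(p, "multisample", "mRNA")
        assert ds.entity_ids == ["a", "b", "c"]
        assert ds.sample_ids == ["s1", "s2", "s3", "s4"]
        assert np.array_equal(ds.values, np.arange(1, 13).reshape(3, 4))

    def test_stats_only_populates_stats_without_values(self, tmp_path):
        p = write_tsv(tmp_path / "s.tsv", "id\tp-value\tfold-change\ng1\t0.01\t-2.0\ng2\t0.5\t1.3\n")
        ds = read_expression_dataset(p, "stats_only", "mRNA")
        assert ds.values is None
        assert ds.stats is not None
        assert ds.stats.p_of("g1") == 0.01
        assert ds.stats.fc_of("g1") == -2.0

    def test_duplicate_entity_id_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "d.tsv", "id\ts1\ts2\na\t1\t2\na\t3\t4\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_expression_dataset(p, "multisample", "mRNA")

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = write_tsv(tmp_path / "n.tsv", "id\ts1\ts2\na\t1\tok\n")
        with pytest.raises(FormatError, match="'a'.*'s2'"):
            read_expression_dataset(p, "multisample", "mRNA")

    def test_paired_design_requires_equal_groups(self):
        with pytest.raises(DesignError, match="equal group sizes"):
            ExpressionDataset(
                entity_kind=EntityKind.MIRNA,
                data_kind=DataKind.PAIRED2,
                entity_ids=["a"],
                sample_ids=["s1", "s2", "s3"],
                values=np.ones((1, 3)),
                group_of_sample={"s1": "G1", "s2": "G1", "s3": "G2"},
                pair_of_sample={"s1": "s3"},
            )

    def test_non_finite_cells_rejected(self):
        with pytest.raises(FormatError, match="non-finite"):
            make_dataset([[1.0, np.nan]])

    def test_round_trip_canonical_dialect(self, tmp_path):
        ds = make_dataset(np.linspace(0.1, 1.2, 12).reshape(3, 4))
        out = tmp_path / "rt.tsv"
        write_expression_dataset(ds, out)
        back = read_expression_dataset(out, "multisample", "mRNA")
        assert back.entity_ids == ds.entity_ids
        assert back.sample_ids == ds.sample_ids
        assert np.array_equal(back.values, ds.values)


class TestSequenceTargetDB:
    def test_targetscan_records_have_no_score(self, tmp_path):
        p = write_tsv(
            tmp_path / "t.tsv",
            "mirna_id\tgene_symbol\tspecies\nmir-1\tGENE1\thuman\nmir-2\tGENE2\tmouse\n",
        )
        db = read_sequence_target_db(p, "targetscan")
        assert len(db) == 2
        assert all(r.score is None for r in db.records)

    def test_microrna_org_carries_mirsvr_score(self, tmp_path):
        p = write_tsv(
            tmp_path / "m.tsv",
            "mirna_id\tgene_symbol\tspecies\tmirsvr_score\nmir-1\tGENE1\thuman\t-1.2\n",
        )
        db = read_sequence_target_db(p, "microrna_org")
        assert db.records[0].score == -1.2

    def test_exact_duplicate_rows_deduplicated(self, tmp_path):
        p = write_tsv(
            tmp_path / "d.tsv",
            "mirna_id\tgene_symbol\tspecies\nmir-1\tGENE1\thuman\nmir-1\tGENE1\thuman\n",
        )
        assert len(read_sequence_target_db(p, "targetscan")) == 1

    def test_unknown_species_kept_with_warning(self, tmp_path, caplog):
        p = write_tsv(
            tmp_path / "u.tsv", "mirna_id\tgene_symbol\tspecies\nmir-1\tGENE1\tzebrafish\n"
        )
        with caplog.at_level("WARNING"):
            db = read_sequence_target_db(p, "targetscan")
        assert len(db) == 1
        assert "zebrafish" in caplog.text

    def test_missing_column_is_format_error(self, tmp_path):
        p = write_tsv(tmp_path / "b.tsv", "mirna_id\tgene_symbol\nmir-1\tGENE1\n")
        with pytest.raises(FormatError, match="species"):
            read_sequence_target_db(p, "targetscan")


class TestTcgaMatching:
    def test_barcode_prefix_alignment(self):
        mi = make_dataset(
            np.arange(6).reshape(2, 3), data_kind=DataKind.TCGA, entity_prefix="m"
        )
        mi.sample_ids = ["TCGA-AA-0001-01A-x", "TCGA-AA-0002-01B-y", "TCGA-AA-0003-01A-z"]
        mr = make_dataset(
            np.arange(4).reshape(2, 2), data_kind=DataKind.TCGA, entity_prefix="g"
        )
        mr.sample_ids = ["TCGA-AA-0002-01B-q", "TCGA-AA-0001-01A-r"]
        a, b = match_tcga_barcodes(mi, mr, prefix_length=15)
        assert a.sample_ids == b.sample_ids
        assert len(a.sample_ids) == 2
        # value columns follow the matched barcodes
        assert np.array_equal(b.values[:, a.sample_ids.index("TCGA-AA-0001-01")], [1, 3])


class TestCaseStudyFixture:
    def test_published_pair_and_entity_counts(self):
        non, ast = load_case_study_tables()
        assert (len(non), len(non.mirna_ids()), len(non.mrna_ids())) == (45, 15, 33)
        assert (len(ast), len(ast.mirna_ids()), len(ast.mrna_ids())) == (61, 33, 27)

    def test_first_nonasthmatic_row_flags(self):
        non, _ = load_case_study_tables()
        row = non.frame.iloc[0]
        assert (row["mirna_id"], row["mrna_id"]) == ("hp_hsa-mir-3118-5_x_st", "ACVR2B")
        assert [bool(row[a]) for a in non.algorithms] == [True, True, False, True, False]

    def test_acvr2b_is_shared_across_conditions(self):
        non, ast = load_case_study_tables()
        assert "ACVR2B" in (non.mrna_ids() & ast.mrna_ids())
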