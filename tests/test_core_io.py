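import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigscreen import core_io
from sigscreen.core_io import (
    Bioset,
    BiosetMetadata,
    BiosetRecord,
    ExpressionMatrix,
    FactorClass,
    GeneSignature,
    ParseError,
    SigscreenError,
    read_bioset,
    read_signature,
    write_bioset,
    write_signature,
)


# ---------------------------------------------------------------------- types


class TestTypes:
    def test_record_rejects_zero_fc(self):
        with pytest.raises(SigscreenError):
            BiosetRecord(gene="a", fold_change=0.0, adj_p=0.5)

    def test_record_rejects_bad_adj_p(self):
        with pytest.raises(SigscreenError):
            BiosetRecord(gene="a", fold_change=1.5, adj_p=1.5)

    def test_bioset_rejects_duplicate_gene(self):
        with pytest.raises(SigscreenError, match="dup"):
            Bioset(records=[
                BiosetRecord("a", 1.5, 0.01), BiosetRecord("a", -2.0, 0.01),
            ])

    def test_bioset_universe_at_least_records(self):
        with pytest.raises(SigscreenError):
            Bioset(records=[BiosetRecord("a", 1.5, 0.01)], universe_size=0)

    def test_signature_disjoint_halves(self):
        with pytest.raises(SigscreenError, match="both"):
            GeneSignature(up=[("a", 2.0)], down=[("a", -2.0)])

    def test_signature_sign_consistency(self):
        with pytest.raises(SigscreenError):
            GeneSignature(up=[("a", -2.0)], down=[])

    def test_matrix_duplicate_samples(self):
        with pytest.raises(SigscreenError, match="duplicate sample"):
            ExpressionMatrix(
                genes=["g1"], samples=["s", "s"],
                values=np.ones((1, 2)), groups={"s": "a"},
            )

    def test_matrix_missing_group(self):
        with pytest.raises(SigscreenError, match="without a group"):
            ExpressionMatrix(
                genes=["g1"], samples=["s1", "s2"],
                values=np.ones((1, 2)), groups={"s1": "a"},
            )

    def test_matrix_all_nan_row(self):
        with pytest.raises(SigscreenError, match="finite"):
            ExpressionMatrix(
                genes=["g1"], samples=["s1"],
                values=np.full((1, 1), np.nan), groups={"s1": "a"},
            )

    def test_log2_signed_conversion(self):
        assert core_io.log2_to_signed(1.0) == 2.0
        assert core_io.log2_to_signed(-1.0) == -2.0
        assert core_io.log2_to_signed(0.0) == 1.0
        assert core_io.signed_to_log2(-2.0) == -1.0


# -------------------------------------------------------------- bioset files


class TestBiosetIO:
    def test_tsv3col_preserves_order(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text(
            "# universe=100\n"
            "gene\tfold_change\tadj_p\n"
            "A\t1.5\t0.001\nB\t-2\t0.002\nC\t3.25\t0.003\n"
        )
        bs = read_bioset(p)
        assert bs.genes() == ["A", "B", "C"]
        assert bs.universe_size == 100
        assert [r.fold_change for r in bs.records] == [1.5, -2.0, 3.25]

    def test_rnk_duplicate_gene_names_it(self, tmp_path):
        p = tmp_path / "b.rnk"
        p.write_text("A\t1.5\nB\t2.0\nA\t-1.5\n")
        with pytest.raises(ParseError, match="'A'"):
            read_bioset(p, dialect="rnk")

    def test_bad_adj_p_reports_line_number(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("gene\tfold_change\tadj_p\nA\t1.5\t0.5\nB\t2\t1.5\n")
        with pytest.raises(ParseError, match=":3"):
            read_bioset(p)

    def test_unparseable_number_reports_line_number(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("gene\tfold_change\tadj_p\nA\txx\t0.5\n")
        with pytest.raises(ParseError, match=":2"):
            read_bioset(p)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("A\t1.5\t0.5\n")
        with pytest.raises(ParseError, match="header"):
            read_bioset(p)

    def test_round_trip_100_records(self, tmp_path, rng):
        records = [
            BiosetRecord(
                gene=f"g{i}",
                fold_change=float(rng.choice([-1, 1]) * (1 + rng.random() * 5)),
                adj_p=float(rng.random() * 0.01),
            )
            for i in range(100)
        ]
        md = BiosetMetadata(
            study_id="S1", contrast_name="c1",
            factor_class=FactorClass.diet, factor_name="fasting",
        )
        bs = Bioset(records=records, metadata=md, universe_size=12345)
        p = tmp_path / "b.tsv"
        write_bioset(bs, p)
        back = read_bioset(p)
        assert back.metadata == bs.metadata
        assert back.universe_size == bs.universe_size
        assert back.records == bs.records  # exact float round-trip

    def test_rnk_round_trip(self, tmp_path):
        bs = Bioset(
            records=[BiosetRecord("a", 1.23456789), BiosetRecord("b", -4.5)],
            universe_size=10,
        )
        p = tmp_path / "b.rnk"
        write_bioset(bs, p, dialect="rnk")
        back = read_bioset(p, dialect="rnk")
        assert back.genes() == ["a", "b"]
        assert [r.fold_change for r in back.records] == [1.23456789, -4.5]
        assert all(math.isnan(r.adj_p) for r in back.records)

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(min_value=1.0, max_value=1e6, exclude_min=True),
                st.booleans(),
                st.floats(min_value=0.0, max_value=1.0),
            ),
            min_size=0,
            max_size=30,
        )
    )
    def test_round_trip_property(self, tmp_path_factory, data):
        records = [
            BiosetRecord(f"g{i}", -mag if neg else mag, p)
            for i, (mag, neg, p) in enumerate(data)
        ]
        bs = Bioset(records=records, universe_size=1000)
        p = tmp_path_factory.mktemp("rt") / "b.tsv"
        write_bioset(bs, p)
        back = read_bioset(p)
        assert back.records == bs.records
        assert len(back) == len(bs)  # nothing silently dropped


# ----------------------------------------------------------- signature files


class TestSignatureIO:
    def _write_gmt(self, path, up, down, name="SIG"):
        path.write_text(
            f"{name}_UP\tdesc\t" + "\t".join(up) + "\n"
            + f"{name}_DOWN\tdesc\t" + "\t".join(down) + "\n"
        )

    def test_gmt_with_fc_table(self, tmp_path):
        gmt = tmp_path / "s.gmt"
        self._write_gmt(gmt, ["a", "b"], ["c"])
        fc = tmp_path / "fc.tsv"
        fc.write_text("gene\tavg_fold_change\na\t2.0\nb\t1.6\nc\t-1.8\n")
        sig = read_signature(gmt, fc)
        assert sig.up == [("a", 2.0), ("b", 1.6)]
        assert sig.down == [("c", -1.8)]
        assert sig.name == "SIG"

    def test_gene_in_both_sets_rejected(self, tmp_path):
        gmt = tmp_path / "s.gmt"
        self._write_gmt(gmt, ["a", "b"], ["a"])
        with pytest.raises(ParseError, match="both"):
            read_signature(gmt)

    def test_fc_sign_conflict_rejected(self, tmp_path):
        gmt = tmp_path / "s.gmt"
        self._write_gmt(gmt, ["a"], ["c"])
        fc = tmp_path / "fc.tsv"
        fc.write_text("gene\tavg_fold_change\na\t2.0\nc\t1.8\n")
        with pytest.raises(ParseError, match="DOWN"):
            read_signature(gmt, fc)

    def test_missing_fc_table_defaults_with_warning(self, tmp_path, caplog):
        gmt = tmp_path / "s.gmt"
        self._write_gmt(gmt, ["a"], ["c"])
        with caplog.at_level("WARNING"):
            sig = read_signature(gmt)
        assert sig.up == [("a", 1.5)] and sig.down == [("c", -1.5)]
        assert "defaulting" in caplog.text

    def test_wrong_set_count_rejected(self, tmp_path):
        gmt = tmp_path / "s.gmt"
        gmt.write_text("ONLY_UP\tdesc\ta\tb\n")
        with pytest.raises(ParseError, match="exactly two"):
            read_signature(gmt)

    def test_round_trip_empty_down(self, tmp_path):
        sig = GeneSignature(up=[("a", 2.0), ("b", 1.5)], down=[], name="S")
        gmt, fc = tmp_path / "s.gmt", tmp_path / "fc.tsv"
        write_signature(sig, gmt, fc)
        back = read_signature(gmt, fc)
        assert back == sig

    def test_round_trip_precision(self, tmp_path):
        sig = GeneSignature(
            up=[("a", 1.234567891234)], down=[("c", -9.87654321)], name="S"
        )
        gmt, fc = tmp_path / "s.gmt", tmp_path / "fc.tsv"
        write_signature(sig, gmt, fc)
        back = read_signature(gmt, fc)
        assert back.up[0][1] == pytest.approx(1.234567891234, rel=1e-12)
        assert back.down[0][1] == pytest.approx(-9.87654321, rel=1e-12)


# -------------------------------------------------------------- matrix files


class TestMatrixIO:
    @pytest.fixture
    def matrix(self, rng):
        genes = [f"g{i}" for i in range(5)]
        samples = [f"s{i}" for i in range(4)]
        groups = {"s0": "ctl", "s1": "ctl", "s2": "trt", "s3": "trt"}
        return ExpressionMatrix(
            genes=genes, samples=samples,
            values=rng.normal(8, 1, (5, 4)), groups=groups,
        )

    def test_gct_round_trip(self, tmp_path, matrix):
        p = tmp_path / "m.gct"
        core_io.write_gct(matrix, p)
        back = core_io.read_gct(p, matrix.groups)
        assert back.genes == matrix.genes
        assert back.samples == matrix.samples
        np.testing.assert_array_equal(back.values, matrix.values)

    def test_tsv_round_trip(self, tmp_path, matrix):
        p = tmp_path / "m.tsv"
        core_io.write_matrix_tsv(matrix, p)
        back = core_io.read_matrix_tsv(p, matrix.groups)
        assert back.genes == matrix.genes
        np.testing.assert_allclose(back.values, matrix.values, rtol=1e-15)

    def test_gct_bad_version_rejected(self, tmp_path):
        p = tmp_path / "m.gct"
        p.write_text("#1.3\n1\t1\nNAME\tDescription\ts1\ng\tna\t1.0\n")
        with pytest.raises(ParseError, match="1.2"):
            core_io.read_gct(p)

    def test_groups_round_trip(self, tmp_path, matrix):
        p = tmp_path / "groups.tsv"
        core_io.write_groups(matrix.groups, p)
        assert core_io.read_groups(p) == matrix.groups

    def test_stats_table_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"fold_change": [1.5, -2.0], "adj_p": [0.001, 0.5]},
            index=pd.Index(["a", "b"], name="gene"),
        )
        p = tmp_path / "stats.tsv"
        core_io.write_stats_table(df, p)
        back = core_io.read_stats_table(p)
        pd.testing.assert_frame_equal(back, df)
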