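import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oimet.signature import (
    Thresholds,
    build_model_signature,
    build_signature_pipeline,
    call_isoform_switch,
    call_regulation,
    call_table,
    intersect_signatures,
    read_diffexpr_table,
    select_de_features,
    SignatureSet,
)
from oimet.synthdata import ExpressionConfig, gen_expression


def make_records(rows):
    return pd.DataFrame(
        rows,
        columns=["feature_id", "level", "gene_symbol", "model", "treatment",
                 "fold_change", "fdr", "status"],
    )


class TestSelection:
    @pytest.mark.parametrize(
        "fc,fdr,status,selected",
        [
            (2.5, 0.01, "OK", True),
            (1.9, 0.01, "OK", False),   # inside the exclusion band
            (0.50, 0.05, "OK", True),   # ties are inclusive on both bounds
            (2.0, 0.05, "OK", True),
            (2.5, 0.051, "OK", False),
            (2.5, 0.01, "NOTEST", False),
            (0.51, 0.01, "OK", False),
        ],
    )
    def test_threshold_clauses(self, fc, fdr, status, selected):
        df = make_records([("f1", "gene", "G1", "BC", "OVOL1", fc, fdr, status)])
        got = select_de_features(df, Thresholds())
        assert (got == {"f1"}) is selected

    def test_empty_table_gives_empty_set(self):
        assert select_de_features(make_records([]), Thresholds()) == set()

    def test_malformed_record_names_offender(self):
        df = make_records([("bad1", "gene", "G1", "BC", "OVOL1", -2.0, 0.01, "OK")])
        with pytest.raises(ValueError, match="bad1"):
            select_de_features(df, Thresholds())
        df = make_records([("bad2", "gene", "G1", "BC", "OVOL1", 2.0, 1.5, "OK")])
        with pytest.raises(ValueError, match="bad2"):
            select_de_features(df, Thresholds())

    def test_planted_features_recovered_exactly(self):
        cfg = ExpressionConfig(n_genes=200, de_fraction={"BC": 0.05, "PC": 0.05},
                               shared_fraction=0.5)
        tables, truth = gen_expression(cfg, 11)
        df = tables["BC"]
        sub = df[df["level"] == "gene"]
        selected_genes = {
            sub.loc[sub["feature_id"] == f, "gene_symbol"].iloc[0]
            for f in select_de_features(sub, Thresholds())
        }
        assert selected_genes == truth.de_genes["BC"]

    @given(
        fdr_tight=st.floats(0.001, 0.05),
        fc_high2=st.floats(2.0, 6.0),
        data=st.lists(
            st.tuples(st.floats(0, 10), st.floats(0, 1)), min_size=1, max_size=60
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_selection_monotone_in_thresholds(self, fdr_tight, fc_high2, data):
        """Tightening FDR or widening the fold exclusion band never adds features."""
        df = make_records(
            [(f"f{i}", "gene", f"G{i}", "BC", "OVOL1", fc, fdr, "OK")
             for i, (fc, fdr) in enumerate(data)]
        )
        base = select_de_features(df, Thresholds())
        tighter = select_de_features(df, Thresholds(fdr_max=fdr_tight))
        wider = select_de_features(
            df, Thresholds(fc_high=fc_high2, fc_low=2.0 / fc_high2 / 4)
        )
        assert tighter <= base
        assert wider <= base or fc_high2 == 2.0


class TestSignatures:
    def test_union_across_treatments(self):
        sets = {"OVOL1": {"a", "b"}, "OVOL2": {"b", "c"}, "OVOL1and2": {"c", "d"}}
        gmap = {f: f.upper() for f in "abcd"}
        sig = build_model_signature(sets, gmap, model="BC")
        assert sig.genes == {"A", "B", "C", "D"}

    def test_unmapped_feature_raises(self):
        with pytest.raises(ValueError, match="zz"):
            build_model_signature({"OVOL1": {"zz"}}, {}, model="BC")

    def test_intersection_and_concordance(self):
        a = SignatureSet("BC", {"A", "B", "C"}, Thresholds())
        b = SignatureSet("PC", {"B", "C", "D"}, Thresholds())
        folds = {"B": (2.0, 3.0), "C": (0.4, 2.0)}
        inter = intersect_signatures(a, b, folds)
        assert inter.genes == {"B", "C"}
        assert inter.concordance_fraction == 0.5
        assert inter.genes <= a.genes and inter.genes <= b.genes

    def test_missing_fold_pairs_drop_from_denominator(self):
        a = SignatureSet("BC", {"A", "B"}, Thresholds())
        b = SignatureSet("PC", {"A", "B"}, Thresholds())
        inter = intersect_signatures(a, b, {"A": (2.0, 2.0)})
        assert inter.concordance_fraction == 1.0
        assert inter.n_missing_folds == 1

    def test_pipeline_recovers_planted_structure(self):
        cfg = ExpressionConfig(n_genes=400, de_fraction={"BC": 0.25, "PC": 0.25},
                               shared_fraction=0.3, concordance=0.7)
        tables, truth = gen_expression(cfg, 2)
        sigs, inter = build_signature_pipeline(tables)
        assert sigs["BC"].genes == truth.de_genes["BC"]
        assert sigs["PC"].genes == truth.de_genes["PC"]
        assert inter.genes == truth.shared_genes
        assert inter.genes <= sigs["BC"].genes
        n = len(truth.shared_genes)
        assert inter.concordance_fraction == pytest.approx(
            len(truth.concordant_genes) / n
        )


class TestRegulationCalls:
    @pytest.mark.parametrize(
        "folds,expected",
        [
            ((1.5, 2.2, 2.1), "Up"),
            ((0.7, 0.7, 0.6), "Down"),
            ((1.4, 1.4, 1.4), "none"),
            ((0.0, 0.4, 6.3), "UpDown"),
            ((0.68, 1.49, 1.0), "none"),  # just inside both thresholds
            ((0.67, 1.5, 1.0), "UpDown"),  # ties fire both rules
        ],
    )
    def test_gene_level_calls(self, folds, expected):
        assert call_regulation(folds) == expected

    def test_negative_fold_rejected(self):
        with pytest.raises(ValueError):
            call_regulation([-1.0])
        with pytest.raises(ValueError):
            call_regulation([])

    @pytest.mark.parametrize(
        "isoforms,expected",
        [
            # one isoform far up, the other down in the same treatments
            ({"a": (10.0, 10.0, 10.0), "b": (0.7, 0.5, 0.4)}, "Switch"),
            # both isoforms trend up: no switch
            ({"a": (1.1, 1.4, 1.9), "b": (0.8, 1.7, 2.2)}, "none"),
            ({"a": (0.2, 5.0, 1.0)}, "none"),  # single isoform
            # up and down exist but never in the same treatment
            ({"a": (2.0, 1.0, 1.0), "b": (1.0, 0.5, 1.0)}, "none"),
        ],
    )
    def test_switch_calls(self, isoforms, expected):
        assert call_isoform_switch(isoforms) == expected

    def test_switch_implies_pooled_updown(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            iso = {
                f"i{k}": tuple(rng.uniform(0, 5, size=3)) for k in range(rng.integers(2, 4))
            }
            if call_isoform_switch(iso) == "Switch":
                pooled = [f for v in iso.values() for f in v]
                assert call_regulation(pooled) == "UpDown"

    def test_planted_switches_recovered(self):
        cfg = ExpressionConfig(n_genes=300, de_fraction={"BC": 0.2, "PC": 0.2},
                               shared_fraction=0.5, switch_fraction=0.3)
        tables, truth = gen_expression(cfg, 4)
        for model in ("BC", "PC"):
            calls = call_table(tables[model])
            got = set(calls[calls["call"] == "Switch"]["gene"])
            assert got == truth.switch_genes[model]


class TestIO:
    def test_tsv_round_trip_and_log2_conversion(self, tmp_path):
        df = make_records(
            [("f1", "gene", "G1", "BC", "OVOL1", 2.5, 0.01, "OK"),
             ("f2", "gene", "G2", "BC", "OVOL1", 0.3, 0.20, "OK")]
        )
        p = tmp_path / "de.tsv"
        df.to_csv(p, sep="\t", index=False)
        back = read_diffexpr_table(p)
        pd.testing.assert_frame_equal(back, df)

        log_df = df.drop(columns=["fold_change"]).assign(log2fc=[1.0, -12.0])
        p2 = tmp_path / "log.tsv"
        log_df.to_csv(p2, sep="\t", index=False)
        back2 = read_diffexpr_table(p2)
        assert back2.loc[0, "fold_change"] == pytest.approx(2.0)
        assert back2.loc[1, "fold_change"] == pytest.approx(2.0 ** -12)  # tiny, kept

    def test_column_mapping_dialect(self, tmp_path):
        raw = pd.DataFrame(
            {"test_id": ["x"], "lvl": ["gene"], "gene": ["G"], "m": ["BC"],
             "sample_2": ["OVOL1"], "fc": [3.0], "q_value": [0.01], "stat": ["OK"]}
        )
        p = tmp_path / "cuff.tsv"
        raw.to_csv(p, sep="\t", index=False)
        back = read_diffexpr_table(
            p,
            column_map={"test_id": "feature_id", "lvl": "level", "gene": "gene_symbol",
                        "m": "model", "sample_2": "treatment", "fc": "fold_change",
                        "q_value": "fdr", "stat": "status"},
        )
        assert back.loc[0, "feature_id"] == "x"
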