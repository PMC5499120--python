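import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from polyasym.analysis_pipeline import (AnalysisConfig, Bundle,
                                        bundle_from_synthetic,
                                        read_expression_table,
                                        run_distance_profile,
                                        run_expression_strata, run_geneset,
                                        run_position_classes,
                                        run_species_summary,
                                        run_strength_profile, run_all,
                                        trimmed_introns)
from polyasym.synthetic_data import SyntheticConfig, generate_genome

from conftest import small_analysis_config


class TestGating:
    def test_below_min_n_rows_carry_no_dsa(self, null_bundle):
        cfg = small_analysis_config(min_sample_n=10**6)
        df = run_species_summary(null_bundle, cfg)
        flagged = df[df["flags"] == "below-min-n"]
        assert len(flagged) > 0
        assert flagged["dsa"].isna().all()

    def test_empty_genome_reports_empty(self):
        gb = generate_genome(SyntheticConfig(n_genes=0, chrom_length=500), seed=0)
        cfg = small_analysis_config()
        bundle = bundle_from_synthetic(gb, cfg)
        df = run_species_summary(bundle, cfg)
        assert len(df) == 0


class TestConsistency:
    def test_position_classes_partition_all_introns(self, null_bundle, small_cfg):
        introns = trimmed_introns(null_bundle, small_cfg)
        classes = [f.position_class for f in introns]
        df = run_position_classes(null_bundle, small_cfg)
        per_class = df.set_index("sample_id")["n_seqs"]
        total = sum(int(per_class[c]) for c in ("first", "internal", "last")
                    if c in per_class.index)
        assert total == len(introns)
        assert set(classes) <= {"first", "internal", "last"}

    def test_geneset_of_all_genes_matches_species_summary(self, null_bundle,
                                                          small_cfg):
        all_ids = [m.gene_id for m in null_bundle.models]
        gs = run_geneset(null_bundle, all_ids, small_cfg)
        sp = run_species_summary(null_bundle, small_cfg)
        a = gs[(gs["sample_id"] == "introns") & (gs["motif"] == "AATAAA")].iloc[0]
        b = sp[(sp["sample_id"] == "introns_all") & (sp["motif"] == "AATAAA")].iloc[0]
        assert a["F"] == b["F"] and a["R"] == b["R"]
        assert a["dsa"] == pytest.approx(b["dsa"])

    def test_end_to_end_determinism(self, tmp_path, null_bundle, small_cfg):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        run_all(null_bundle, small_cfg, str(d1))
        run_all(null_bundle, small_cfg, str(d2))
        for name in ("species_summary.tsv", "distance_profile.tsv",
                     "strength_profile.tsv", "position_classes.tsv"):
            assert (d1 / name).read_text() == (d2 / name).read_text()


class TestDistanceProfile:
    def test_bin_zero_adjacent_to_donor(self, null_bundle):
        cfg = small_analysis_config(distance_bins=2, distance_width=100,
                                    min_sample_n=5)
        df = run_distance_profile(null_bundle, cfg)
        assert list(df["sample_id"])[:2] == ["bin0_0-100nt", "bin1_100-200nt"]

    def test_all_short_introns_flagged(self):
        gb = generate_genome(SyntheticConfig(
            n_genes=60, intron_length_law=("constant", 80),
            exons_per_gene_law=("constant", 3), seed=33), seed=33)
        cfg = small_analysis_config()
        bundle = bundle_from_synthetic(gb, cfg)
        df = run_distance_profile(bundle, cfg)  # 500-nt bins cannot fit
        assert (df["flags"] == "below-min-n").all()


class TestStrengthProfile:
    def test_quartile_rows_present(self, null_bundle):
        cfg = small_analysis_config(strength_bins=1, min_sample_n=5)
        df = run_strength_profile(null_bundle, cfg)
        ids = set(df["sample_id"])
        assert {"5ss_low_bin0", "5ss_high_bin0", "3ss_low_bin0",
                "3ss_high_bin0"} <= ids


class TestExpressionStrata:
    def test_quartile_error_on_tiny_table(self, null_bundle, small_cfg):
        df = run_expression_strata(null_bundle, {"g00000": 5.0}, small_cfg)
        assert (df["flags"] == "quartile-error").any()

    def test_missing_genes_excluded(self, null_bundle, small_cfg, caplog):
        expr = {m.gene_id: float(i + 1)
                for i, m in enumerate(null_bundle.models[:40])}
        with caplog.at_level("INFO", logger="polyasym"):
            df = run_expression_strata(null_bundle, expr, small_cfg)
        assert any("missing from the expression table" in r.message
                   for r in caplog.records)
        assert (df["analysis"] == "expression_strata").all()

    def test_expression_coupled_depletion_recovered(self):
        """Higher expression strata show more negative DSA when the generator
        couples depletion to expression rank."""
        gb = generate_genome(SyntheticConfig(
            n_genes=400, exons_per_gene_law=("constant", 4),
            depletion_base_q=0.3, expression_depletion_coupling=1.5,
            seed=44), seed=44)
        cfg = small_analysis_config(min_sample_n=50)
        bundle = bundle_from_synthetic(gb, cfg)
        expr = read_expression_table(gb.expression_text)
        df = run_expression_strata(bundle, expr, cfg)
        aat = df[df["motif"] == "AATAAA"].set_index("sample_id")["dsa"]
        assert aat["q4"] < aat["q1"] - 0.1

    def test_rank_sum_row_emitted(self, null_bundle, small_cfg, null_genome):
        expr = read_expression_table(null_genome.expression_text)
        df = run_expression_strata(null_bundle, expr, small_cfg)
        assert "5ss_strength_q1_vs_q4" in set(df["sample_id"])


class TestGeneset:
    def test_empty_list_rejected(self, null_bundle, small_cfg):
        with pytest.raises(ValueError):
            run_geneset(null_bundle, [], small_cfg)

    def test_undepleted_subset_not_significant(self, depleted_bundle):
        """Contrast p-values are computed for the subset's own introns."""
        cfg = small_analysis_config(min_sample_n=50)
        ids = [m.gene_id for m in depleted_bundle.models[:100]]
        df = run_geneset(depleted_bundle, ids, cfg)
        contrast = df[df["sample_id"] == "AATAAA_vs_TAAAAA"]
        assert len(contrast) == 1
        assert 0 < contrast["p_value"].iloc[0] <= 1


class TestPositionClasses:
    def test_two_intron_genes_have_empty_internal(self):
        gb = generate_genome(SyntheticConfig(
            n_genes=80, exons_per_gene_law=("constant", 3), seed=55), seed=55)
        cfg = small_analysis_config(min_sample_n=10)
        bundle = bundle_from_synthetic(gb, cfg)
        df = run_position_classes(bundle, cfg).set_index("sample_id")
        assert df.loc["internal", "n_seqs"] == 0
        assert df.loc["internal", "flags"] == "empty-class"

    def test_uniform_depletion_gives_null_contrast(self, depleted_bundle):
        cfg = small_analysis_config(min_sample_n=50)
        df = run_position_classes(depleted_bundle, cfg)
        p = df.set_index("sample_id").loc["first_vs_last", "p_value"]
        assert p > 0.01

    def test_first_intron_extra_depletion_detected(self, null_bundle, small_cfg):
        """Planting extra depletion only in first introns separates the classes."""
        from polyasym.dsa_core import compare_groups
        from polyasym.synthetic_data import plant_depletion
        rng = np.random.default_rng(6)
        introns = trimmed_introns(null_bundle, small_cfg)
        first = [plant_depletion(f.seq, "AATAAA", lambda d, s: 0.7, rng)[0]
                 for f in introns if f.position_class == "first"]
        last = [f.seq for f in introns if f.position_class == "last"]
        r = compare_groups(first, last, "AATAAA", n_boot=999, seed=8)
        assert r.p_value <= 0.01


class TestExpressionTableParsing:
    def test_header_tolerated(self):
        t = "gene_id\tvalue\ng1\t2.5\ng2\t7\n"
        assert read_expression_table(t) == {"g1": 2.5, "g2": 7.0}


class TestReportExtras:
    def test_feature_export_tsv(self, null_bundle, small_cfg):
        from polyasym.feature_extraction import export_features_tsv
        introns = trimmed_introns(null_bundle, small_cfg)
        text = export_features_tsv(introns)
        lines = text.strip().splitlines()
        assert lines[0].startswith("gene_id\tkind")
        assert len(lines) == len(introns) + 1
        assert "\tintron\t" in lines[1]

    def test_p_adjustment_flag_defaults_off_and_monotone(self, depleted_bundle):
        raw = small_analysis_config(min_sample_n=50)
        adj = small_analysis_config(min_sample_n=50, adjust_p=True)
        df_raw = run_position_classes(depleted_bundle, raw).set_index("sample_id")
        df_adj = run_position_classes(depleted_bundle, adj).set_index("sample_id")
        for sid in ("first_vs_last", "first_vs_internal", "internal_vs_last"):
            assert df_adj.loc[sid, "p_value"] >= df_raw.loc[sid, "p_value"] - 1e-12
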