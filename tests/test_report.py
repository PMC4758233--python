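import numpy as np
import pandas as pd
import pytest

from rateherit.report import (
    EXPECTED_SIGNS,
    class_difference_signs,
    class_summaries,
    domain_class_proportions,
    gc3_by_intron_presence,
    run_pipeline,
    stratify_by_intron,
)
from rateherit.synthetic_data import ClassParams, SimulationConfig, simulate_study


def small_config(seed=5, n_primary=60, n_secondary=40):
    return SimulationConfig(
        primary=ClassParams(
            n_genes=n_primary, dn_mean=0.02, dn_sd=0.016,
            ds_mean=0.147, ds_sd=0.044, cds_codons_mean=200.0,
        ),
        secondary=ClassParams(
            n_genes=n_secondary, dn_mean=0.026, dn_sd=0.016,
            ds_mean=0.157, ds_sd=0.043, cds_codons_mean=200.0,
            intronless_prob=0.22, intron_number_mean=4.3,
            utr5_mean=96.5, utr3_mean=192.9,
            expression_mean=4430.0, tau_mean=0.287,
            domain_lambda=1.26, go_lambda=10.91, po_lambda=22.48,
            gc3_mean=0.423, codon_bias=0.62,
        ),
        seed=seed,
    )


@pytest.fixture(scope="module")
def pipeline_run(tmp_path_factory):
    root = tmp_path_factory.mktemp("pipe")
    paths = simulate_study(small_config(), root / "bundle")
    cfg = {
        "paths": {k: str(v) for k, v in paths.items()},
        "out_dir": str(root / "out"),
    }
    return cfg, run_pipeline(cfg)


class TestStratifyByIntron:
    def test_group_boundaries(self):
        table = pd.DataFrame(
            {
                "class": ["primary", "secondary"] * 3,
                "intron_number": [0, 0, 10, 10, 11, 11],
                "dN": [0.01, 0.02, 0.01, 0.02, 0.01, 0.02],
                "dS": [0.1, 0.2, 0.1, 0.2, 0.1, 0.2],
                "omega": [0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
            }
        )
        out = stratify_by_intron(table)
        by_group = out.groupby("intron_group")["n_primary"].first()
        assert by_group["intronless"] == 1
        assert by_group["1-10_introns"] == 1  # 10 introns: "up to ten" inclusive
        assert by_group[">10_introns"] == 1

    def test_empty_group_reported_without_test(self):
        table = pd.DataFrame(
            {
                "class": ["primary", "secondary"],
                "intron_number": [0, 0],
                "dN": [0.01, 0.02],
                "dS": [0.1, 0.2],
                "omega": [0.1, 0.1],
            }
        )
        out = stratify_by_intron(table)
        sub = out[out["intron_group"] == ">10_introns"]
        assert (sub["n_primary"] == 0).all()
        assert sub["p"].isna().all()


class TestDomainClassProportions:
    def test_percentage_arithmetic(self):
        table = pd.DataFrame(
            {
                "class": ["primary"] * 10 + ["secondary"] * 4,
                "domain_number": [1] * 6 + [2] * 2 + [3, 5] + [1, 1, 1, 1],
            }
        )
        out = domain_class_proportions(table).set_index("domain_class")
        assert out.loc["single", "pct_primary"] == pytest.approx(60.0)
        assert out.loc["double", "pct_primary"] == pytest.approx(20.0)
        assert out.loc["multi", "pct_primary"] == pytest.approx(20.0)
        assert out.loc["single", "pct_secondary"] == pytest.approx(100.0)

    def test_equal_distributions_give_zero_z(self):
        table = pd.DataFrame(
            {
                "class": ["primary"] * 4 + ["secondary"] * 4,
                "domain_number": [1, 1, 2, 3] * 2,
            }
        )
        out = domain_class_proportions(table)
        assert np.allclose(out["z"].astype(float), 0.0, atol=1e-12)

    def test_zero_domain_genes_excluded_with_count(self):
        table = pd.DataFrame(
            {
                "class": ["primary"] * 3 + ["secondary"],
                "domain_number": [0, 1, 2, 1],
            }
        )
        out = domain_class_proportions(table)
        assert (out["n_excluded_zero"] == 1).all()
        assert (out["n_primary"] == 2).all()


class TestGc3ByIntronPresence:
    def test_shift_detected(self, rng):
        gc3_with = rng.normal(0.4, 0.03, size=200)
        gc3_less = rng.normal(0.5, 0.03, size=200)
        table = pd.DataFrame(
            {
                "class": ["primary"] * 400,
                "intron_number": [0] * 200 + [3] * 200,
                "gc3": np.concatenate([gc3_less, gc3_with]),
            }
        )
        out = gc3_by_intron_presence(table)
        row = out[out["class"] == "primary"].iloc[0]
        assert row["p"] < 0.01
        assert row["mean_gc3_intronless"] > row["mean_gc3_with_intron"]

    def test_null_distributions_usually_not_significant(self, rng):
        table = pd.DataFrame(
            {
                "class": ["secondary"] * 100,
                "intron_number": [0] * 50 + [2] * 50,
                "gc3": rng.normal(0.4, 0.05, size=100),
            }
        )
        out = gc3_by_intron_presence(table)
        assert out[out["class"] == "secondary"]["p"].iloc[0] > 0.05

    def test_missing_gc3_rows_excluded(self):
        table = pd.DataFrame(
            {
                "class": ["primary"] * 4,
                "intron_number": [0, 0, 1, 1],
                "gc3": [0.4, np.nan, 0.5, np.nan],
            }
        )
        out = gc3_by_intron_presence(table)
        row = out[out["class"] == "primary"].iloc[0]
        assert row["n_intronless"] == 1 and row["n_with_intron"] == 1


class TestPipeline:
    def test_counts_partition_class_map(self, pipeline_run):
        _, report = pipeline_run
        meta = report.metadata
        analyzed = set(
            report.analysis_table.loc[
                report.analysis_table["dS"].notna(), "gene_id"
            ]
        )
        excluded = {g for ids in report.exclusions.values() for g in ids}
        assert len(analyzed) + len(excluded) == meta["n_genes_class_map"]
        assert not analyzed & excluded

    def test_report_surfaces_present(self, pipeline_run):
        _, report = pipeline_run
        assert not report.table1.empty
        assert not report.correlation_table.empty
        assert report.pca_result is not None
        assert report.pca_result.component_variance_pct.sum() == pytest.approx(
            100.0, abs=1e-6
        )

    def test_output_files_written(self, pipeline_run):
        cfg, _ = pipeline_run
        from pathlib import Path

        out = Path(cfg["out_dir"])
        for name in (
            "features.tsv",
            "divergence.tsv",
            "table1.tsv",
            "table2_correlations.tsv",
            "intron_groups.tsv",
            "domain_classes.tsv",
            "gc3_by_intron.tsv",
            "qc_report.tsv",
        ):
            assert (out / name).exists(), name

    def test_deterministic_rerun(self, pipeline_run, tmp_path):
        cfg, _ = pipeline_run
        from pathlib import Path

        cfg2 = dict(cfg, out_dir=str(tmp_path / "out2"))
        run_pipeline(cfg2)
        for name in ("features.tsv", "table1.tsv", "table2_correlations.tsv"):
            a = (Path(cfg["out_dir"]) / name).read_bytes()
            b = (Path(cfg2["out_dir"]) / name).read_bytes()
            assert a == b, name

    def test_missing_expression_degrades_gracefully(self, pipeline_run, tmp_path):
        cfg, _ = pipeline_run
        cfg2 = dict(cfg, out_dir=str(tmp_path / "noexpr"))
        cfg2["paths"] = dict(cfg["paths"])
        cfg2["paths"]["expression_tsv"] = None
        report = run_pipeline(cfg2)
        assert report.analysis_table["expression_level"].isna().all()
        assert not report.table1.empty  # rate statistics still computed

    def test_class_summaries_have_both_classes(self, pipeline_run):
        _, report = pipeline_run
        t1 = report.table1
        assert set(t1["class"]) == {"primary", "secondary"}
        assert set(t1["variable"]) == {"dN", "dS", "omega"}
        within = t1[(t1["variable"] == "dS") & (t1["class"] == "primary")]
        assert (within["min"] <= within["max"]).all()


def test_class_difference_signs_reports_tracked_variables(pipeline_run=None):
    table = pd.DataFrame(
        {
            "class": ["primary", "primary", "secondary", "secondary"],
            "dN": [0.01, 0.02, 0.03, 0.04],
            "gene_length": [3000, 2800, 2000, 2200],
        }
    )
    signs = class_difference_signs(table)
    assert signs["dN"] == 1
    assert signs["gene_length"] == -1
    assert set(signs) <= set(EXPECTED_SIGNS)
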