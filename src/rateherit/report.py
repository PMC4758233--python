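"""Pipeline orchestration and the class-comparison analysis surfaces.

Runs QC -> divergence -> features -> expression -> statistics on one
input bundle and writes TSV tables: per-class divergence summaries
(mean, SD, CV, range, Mann–Whitney p), the per-variable class
comparison, the Spearman correlation battery of every feature against
dN/dS/omega, intron-group and domain-class stratifications, the
GC3-by-intron-presence comparison, and the PCA loading attribution.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import divergence as dv
from . import expression as xp
from . import features as ft
from . import seqio_qc as sq
from . import stats as st

logger = logging.getLogger("rateherit")

RATE_VARS = ["dN", "dS", "omega"]

#: feature battery correlated against the rates (Table-2 style)
CORRELATE_VARS = [
    "gene_length",
    "intron_number",
    "mean_intron_length",
    "utr5_length",
    "utr3_length",
    "gc_gene",
    "gc_utr5",
    "gc_utr3",
    "gc3",
    "enc",
    "domain_number",
    "expression_level",
    "tau",
    "po_count",
    "goslim_count",
]

#: variables entering the PCA (Table-3 style)
PCA_VARS = [
    "gene_length",
    "intron_number",
    "utr5_length",
    "utr3_length",
    "gc_utr5",
    "gc_utr3",
    "gc3",
    "domain_number",
    "expression_level",
    "tau",
    "po_count",
    "goslim_count",
]

#: expected direction of (secondary - primary) class mean differences
EXPECTED_SIGNS = {
    "dN": +1,
    "dS": +1,
    "omega": +1,
    "enc": +1,
    "tau": +1,
    "gc3": +1,
    "gene_length": -1,
    "utr5_length": -1,
    "utr3_length": -1,
    "intron_number": -1,
    "domain_number": -1,
    "expression_level": -1,
    "goslim_count": -1,
    "po_count": -1,
}

INTRON_GROUPS = (
    ("intronless", 0, 0),
    ("1-10_introns", 1, 10),   # "up to ten" includes 10
    (">10_introns", 11, None),
)


@dataclass
class ComparisonReport:
    """All analysis surfaces for one run."""

    analysis_table: pd.DataFrame
    table1: pd.DataFrame
    class_comparison: pd.DataFrame
    correlation_table: pd.DataFrame
    intron_groups: pd.DataFrame
    domain_classes: pd.DataFrame
    gc3_intron: pd.DataFrame
    pca_result: st.PCAResult | None
    qc_report: sq.QCReport | None
    exclusions: dict[str, list[str]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def class_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Table-1 style: per class and rate variable, mean/SD/CV/range + MWU p."""
    rows = []
    for var in RATE_VARS:
        groups = {
            label: table.loc[table["class"] == label, var].dropna()
            for label in ("primary", "secondary")
        }
        if all(len(g) >= 1 for g in groups.values()):
            p = st.mann_whitney_u(groups["primary"], groups["secondary"]).p_value
        else:
            p = np.nan
        for label, vals in groups.items():
            rows.append(
                {
                    "variable": var,
                    "class": label,
                    "n": len(vals),
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1),
                    "cv": (
                        st.coefficient_of_variation(vals)
                        if len(vals) > 1 and vals.mean() != 0
                        else np.nan
                    ),
                    "min": vals.min(),
                    "max": vals.max(),
                    "mwu_p": p,
                }
            )
    return pd.DataFrame(rows)


def class_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variable class means and Mann–Whitney test (all correlates)."""
    rows = []
    for var in CORRELATE_VARS:
        if var not in table:
            continue
        prim = table.loc[table["class"] == "primary", var].dropna()
        sec = table.loc[table["class"] == "secondary", var].dropna()
        if len(prim) == 0 or len(sec) == 0:
            continue
        res = st.mann_whitney_u(prim, sec)
        rows.append(
            {
                "variable": var,
                "n_primary": len(prim),
                "n_secondary": len(sec),
                "mean_primary": prim.mean(),
                "mean_secondary": sec.mean(),
                "U": res.statistic,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def correlation_battery(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of every feature vs dN, dS, omega on the pooled set."""
    rows = []
    for var in CORRELATE_VARS:
        if var not in table:
            continue
        row: dict = {"variable": var}
        for rate in RATE_VARS:
            x = table[var].astype(float)
            y = table[rate].astype(float)
            try:
                res = st.spearman_rho(x, y)
                row[f"rho_{rate}"] = res.statistic
                row[f"p_{rate}"] = res.p_value
            except ValueError:
                row[f"rho_{rate}"] = np.nan
                row[f"p_{rate}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def stratify_by_intron(table: pd.DataFrame) -> pd.DataFrame:
    """Between-class rate tests inside intron-number strata.

    Groups: intronless, 1–10 introns (10 inclusive), >10 introns.
    Empty groups are reported with n = 0 and no test.
    """
    rows = []
    for name, lo, hi in INTRON_GROUPS:
        mask = table["intron_number"] >= lo
        if hi is not None:
            mask &= table["intron_number"] <= hi
        sub = table[mask]
        for var in RATE_VARS:
            prim = sub.loc[sub["class"] == "primary", var].dropna()
            sec = sub.loc[sub["class"] == "secondary", var].dropna()
            if len(prim) >= 1 and len(sec) >= 1:
                res = st.mann_whitney_u(prim, sec)
                p, u = res.p_value, res.statistic
            else:
                p, u = np.nan, np.nan
            rows.append(
                {
                    "intron_group": name,
                    "variable": var,
                    "n_primary": len(prim),
                    "n_secondary": len(sec),
                    "mean_primary": prim.mean() if len(prim) else np.nan,
                    "mean_secondary": sec.mean() if len(sec) else np.nan,
                    "U": u,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def domain_class_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Single/double/multidomain percentages per class with z tests.

    Genes with zero annotated domains are excluded (flagged count in
    the output metadata column ``n_excluded_zero``).
    """
    rows = []
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    excluded: dict[str, int] = {}
    for label in ("primary", "secondary"):
        sub = table.loc[table["class"] == label, "domain_number"].dropna()
        excluded[label] = int((sub == 0).sum())
        sub = sub[sub >= 1]
        totals[label] = len(sub)
        counts[label] = {
            dc: int(sum(ft.domain_class(int(c)) == dc for c in sub))
            for dc in ("single", "double", "multi")
        }
    for dc in ("single", "double", "multi"):
        k1, n1 = counts["primary"][dc], totals["primary"]
        k2, n2 = counts["secondary"][dc], totals["secondary"]
        try:
            res = st.two_proportion_z(k1, n1, k2, n2)
            z, p = res.statistic, res.p_value
        except ValueError:
            z, p = np.nan, np.nan
        rows.append(
            {
                "domain_class": dc,
                "pct_primary": 100.0 * k1 / n1 if n1 else np.nan,
                "pct_secondary": 100.0 * k2 / n2 if n2 else np.nan,
                "n_primary": n1,
                "n_secondary": n2,
                "n_excluded_zero": excluded["primary"] + excluded["secondary"],
                "z": z,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def gc3_by_intron_presence(table: pd.DataFrame) -> pd.DataFrame:
    """Within each gene class, MWU of GC3: intronless vs intron-bearing."""
    rows = []
    for label in ("primary", "secondary"):
        sub = table[table["class"] == label].dropna(subset=["gc3", "intron_number"])
        intronless = sub.loc[sub["intron_number"] == 0, "gc3"]
        with_intron = sub.loc[sub["intron_number"] > 0, "gc3"]
        if len(intronless) >= 1 and len(with_intron) >= 1:
            res = st.mann_whitney_u(intronless, with_intron)
            p, u = res.p_value, res.statistic
        else:
            p, u = np.nan, np.nan
        rows.append(
            {
                "class": label,
                "n_intronless": len(intronless),
                "n_with_intron": len(with_intron),
                "mean_gc3_intronless": intronless.mean() if len(intronless) else np.nan,
                "mean_gc3_with_intron": with_intron.mean() if len(with_intron) else np.nan,
                "U": u,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def class_difference_signs(table: pd.DataFrame) -> dict[str, int]:
    """Sign of (secondary mean - primary mean) for every tracked variable."""
    signs = {}
    for var in EXPECTED_SIGNS:
        if var not in table:
            continue
        prim = table.loc[table["class"] == "primary", var].dropna()
        sec = table.loc[table["class"] == "secondary", var].dropna()
        if len(prim) == 0 or len(sec) == 0:
            continue
        signs[var] = int(np.sign(sec.mean() - prim.mean()))
    return signs


# ---------------------------------------------------------------------------
# pipeline


def load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def build_analysis_table(
    models: list[sq.GeneModel],
    class_map: pd.Series,
    div_table: pd.DataFrame | None = None,
    profiles: dict[str, xp.ExpressionProfile] | None = None,
    domain_counts: dict[str, int] | None = None,
    go_counts: dict[str, int] | None = None,
    po_counts: dict[str, int] | None = None,
    tau_floor: float = 1.0,
) -> pd.DataFrame:
    """Merge per-gene features, expression and rates into one table."""
    rows = []
    for m in models:
        gl, u5, u3, k, mil = ft.architecture_features(m)
        record = {
            "gene_id": m.gene_id,
            "class": class_map.get(m.gene_id),
            "gene_length": gl,
            "utr5_length": u5,
            "utr3_length": u3,
            "intron_number": k,
            "mean_intron_length": mil,
            "gc_gene": ft.gc_content(m.gene_seq) if m.gene_seq else None,
            "gc_utr5": ft.gc_content(m.utr5_seq) if m.utr5_seq else None,
            "gc_utr3": ft.gc_content(m.utr3_seq) if m.utr3_seq else None,
            "gc3": ft.gc3(m.cds_seq),
            "enc": ft.enc(m.cds_seq),
            "domain_number": (domain_counts or {}).get(m.gene_id, 0),
            "goslim_count": (go_counts or {}).get(m.gene_id, 0),
            "po_count": (po_counts or {}).get(m.gene_id, 0),
        }
        if profiles is not None and m.gene_id in profiles:
            prof = profiles[m.gene_id]
            record["expression_level"] = xp.expression_level(prof)
            record["tau"] = xp.tau(prof, floor=tau_floor)
        else:
            record["expression_level"] = None
            record["tau"] = None
        rows.append(record)
    table = pd.DataFrame(rows)
    if div_table is not None and not div_table.empty:
        rates = div_table[["gene_id", "dS", "dN", "omega"]]
        table = table.merge(rates, on="gene_id", how="left")
    else:
        table["dS"] = np.nan
        table["dN"] = np.nan
        table["omega"] = np.nan
    for col in table.columns:
        if col not in ("gene_id", "class"):
            table[col] = pd.to_numeric(table[col], errors="coerce")
    return table


def run_pipeline(config: dict | str | Path) -> ComparisonReport:
    """Execute the full comparison on one input bundle.

    Deterministic for fixed inputs. Missing optional inputs (expression,
    annotations) degrade gracefully to NA columns; every gene in the
    class map ends up analyzed or in a named exclusion list.
    """
    cfg = load_config(config)
    paths = cfg.get("paths", cfg)
    params = cfg.get("params", {})
    out_dir = Path(cfg.get("out_dir", params.get("out_dir", "rateherit_out")))
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.StreamHandler(sys.stderr)
    if not logger.handlers:
        logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    def stage(name):
        logger.info("stage: %s", name)

    stage("class map")
    class_df = pd.read_csv(paths["class_map_tsv"], sep="\t", dtype=str)
    class_map = class_df.set_index(class_df.columns[0])[class_df.columns[1]]
    universe = set(class_map.index)
    exclusions: dict[str, list[str]] = {
        "qc_fail": [],
        "no_ortholog_pair": [],
        "saturated_or_failed": [],
    }

    stage("gene models + QC")
    genome = sq.read_fasta(paths["genome_fasta"])
    models = sq.read_gff3(paths["gff3"], genome)
    models = [m for m in models if m.gene_id in universe]
    passed, qc_report, qc_rows = sq.apply_qc(models)
    exclusions["qc_fail"] = qc_report.failed_ids
    qc_report.to_tsv(out_dir / "qc_report.tsv", qc_rows)
    logger.info("QC: %d/%d genes pass", qc_report.n_pass, qc_report.n_input)

    stage("divergence")
    div_table = pd.DataFrame()
    if paths.get("pairs_fasta"):
        pairs = dv.pairs_from_fasta(paths["pairs_fasta"])
        pairs = [p for p in pairs if p.gene_id in universe]
        div_table = dv.batch_divergence(pairs)
        div_table.to_csv(out_dir / "divergence.tsv", sep="\t", index=False,
                         na_rep="NA")
        paired = set(div_table.loc[div_table["dS"].notna(), "gene_id"])
        flagged = set(div_table["gene_id"]) - paired
        exclusions["saturated_or_failed"] = sorted(flagged)
        exclusions["no_ortholog_pair"] = sorted(
            universe - set(div_table["gene_id"])
        )
    else:
        exclusions["no_ortholog_pair"] = sorted(universe)

    stage("expression")
    profiles = None
    if paths.get("expression_tsv"):
        profiles = xp.read_expression_matrix(paths["expression_tsv"])

    stage("annotation counts")
    domain_counts = ft.count_domains(paths["domains_tsv"]) if paths.get("domains_tsv") else {}
    go_counts = xp.term_count(paths["go_tsv"]) if paths.get("go_tsv") else {}
    po_counts = xp.term_count(paths["po_tsv"]) if paths.get("po_tsv") else {}

    stage("feature assembly")
    table = build_analysis_table(
        passed,
        class_map,
        div_table=div_table if not div_table.empty else None,
        profiles=profiles,
        domain_counts=domain_counts,
        go_counts=go_counts,
        po_counts=po_counts,
        tau_floor=float(params.get("tau_floor", 1.0)),
    )
    table.to_csv(out_dir / "features.tsv", sep="\t", index=False, na_rep="NA")

    stage("statistics")
    table1 = class_summaries(table)
    comparison = class_comparison(table)
    correlations = correlation_battery(table)
    intron_tbl = stratify_by_intron(table)
    domain_tbl = domain_class_proportions(table)
    gc3_tbl = gc3_by_intron_presence(table)

    pca_result = None
    pca_input = table[[v for v in PCA_VARS if v in table]].dropna()
    if len(pca_input) >= 2:
        try:
            pca_result = st.pca(
                pca_input, loading_threshold=float(params.get("loading_threshold", 0.5))
            )
        except ValueError as exc:
            logger.warning("PCA skipped: %s", exc)

    for name, df in (
        ("table1.tsv", table1),
        ("class_comparison.tsv", comparison),
        ("table2_correlations.tsv", correlations),
        ("intron_groups.tsv", intron_tbl),
        ("domain_classes.tsv", domain_tbl),
        ("gc3_by_intron.tsv", gc3_tbl),
    ):
        df.to_csv(out_dir / name, sep="\t", index=False, na_rep="NA")
    if pca_result is not None:
        pca_rows = []
        for j, pct in enumerate(pca_result.component_variance_pct):
            pca_rows.append(
                {
                    "component": f"PC{j + 1}",
                    "variance_pct": pct,
                    "retained": ",".join(pca_result.retained[j]),
                }
            )
        pd.DataFrame(pca_rows).to_csv(
            out_dir / "table3_pca.tsv", sep="\t", index=False
        )
        pca_result.loadings.to_csv(out_dir / "pca_loadings.tsv", sep="\t")

    n_analyzed = int(table["dS"].notna().sum())
    metadata = {
        "n_genes_class_map": len(universe),
        "n_qc_pass": qc_report.n_pass,
        "n_rate_bearing": n_analyzed,
        "exclusion_counts": {k: len(v) for k, v in exclusions.items()},
        "out_dir": str(out_dir),
    }
    logger.info("analyzed genes with rates: %d", n_analyzed)
    (out_dir / "run_log.txt").write_text(
        "\n".join(f"{k}: {v}" for k, v in metadata.items()) + "\n"
    )
    return ComparisonReport(
        analysis_table=table,
        table1=table1,
        class_comparison=comparison,
        correlation_table=correlations,
        intron_groups=intron_tbl,
        domain_classes=domain_tbl,
        gc3_intron=gc3_tbl,
        pca_result=pca_result,
        qc_report=qc_report,
        exclusions=exclusions,
        metadata=metadata,
    )
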