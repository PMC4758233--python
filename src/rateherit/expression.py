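"""Expression level, tissue-specificity index tau, and term counts.

tau = sum_j [1 - log S(i,j) / log S(i,max)] / (n - 1) over the n
tissues/conditions, where S(i,max) is the gene's highest expression.
tau is 0 for uniform expression and 1 for single-tissue expression.
Values are floored at 1 before taking logs, since the log-ratio form is
undefined below 1 (microarray intensities are large positive values, so
the floor does not bind on real-scale data).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from pathlib import Path

import pandas as pd


@dataclass
class ExpressionProfile:
    """One gene's expression across tissues/conditions."""

    gene_id: str
    values: list[float]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.sample_ids):
            raise ValueError(f"{self.gene_id}: values/sample_ids length mismatch")
        if any(v < 0 for v in self.values):
            raise ValueError(f"{self.gene_id}: negative expression value")


def expression_level(profile: ExpressionProfile) -> float:
    """Arithmetic mean expression over all samples."""
    if not profile.values:
        raise ValueError(f"{profile.gene_id}: empty profile")
    return sum(profile.values) / len(profile.values)


def tau(profile: ExpressionProfile, floor: float = 1.0) -> float | None:
    """Tissue-specificity index in [0, 1]; None when max <= floor.

    Values below ``floor`` are raised to it before logs. The maximal
    tissue contributes 0 to the sum; a tissue at the floor contributes 1.
    """
    n = len(profile.values)
    if n < 2:
        raise ValueError(f"{profile.gene_id}: tau requires >= 2 samples")
    vals = [max(v, floor) for v in profile.values]
    s_max = max(vals)
    if s_max <= floor:
        return None
    log_max = log(s_max / floor)
    total = sum(1.0 - log(v / floor) / log_max for v in vals)
    return total / (n - 1)


def term_count(table: str | Path | pd.DataFrame) -> dict[str, int]:
    """Distinct term ids per gene from a (gene_id, term_id) table.

    Duplicated rows collapse; absent genes count 0 (caller's universe).
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype=str)
    df.columns = ["gene_id", "term_id"]
    return df.groupby("gene_id")["term_id"].nunique().to_dict()


def read_expression_matrix(path: str | Path) -> dict[str, ExpressionProfile]:
    """Read a genes x samples TSV (first column gene_id, header row)."""
    df = pd.read_csv(path, sep="\t")
    gene_col = df.columns[0]
    sample_ids = list(df.columns[1:])
    if not sample_ids:
        raise ValueError(f"{path}: expression matrix has no sample columns")
    profiles = {}
    for _, row in df.iterrows():
        gid = str(row[gene_col])
        profiles[gid] = ExpressionProfile(
            gene_id=gid,
            values=[float(row[s]) for s in sample_ids],
            sample_ids=sample_ids,
        )
    return profiles
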