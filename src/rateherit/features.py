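"""Per-gene architecture, GC, codon-usage and domain-count features.

These are the candidate correlates of evolutionary rate: gene and UTR
lengths, intron number and mean length, GC content of gene and UTRs,
third-codon-position GC (GC3), Wright's effective number of codons
(ENc), and protein-domain counts.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._codons import CODON_TO_AA, DEGENERACY, FAMILIES, codons_of
from .seqio_qc import GeneModel, validate_cds


@dataclass
class GeneFeatureRecord:
    """The full per-gene feature vector consumed by the class comparison."""

    gene_id: str
    class_label: str | None = None
    gene_length: int | None = None
    utr5_length: int | None = None
    utr3_length: int | None = None
    intron_number: int | None = None
    mean_intron_length: float | None = None
    gc_gene: float | None = None
    gc_utr5: float | None = None
    gc_utr3: float | None = None
    gc3: float | None = None
    enc: float | None = None
    domain_number: int | None = None
    expression_level: float | None = None
    tau: float | None = None
    po_count: int | None = None
    goslim_count: int | None = None


FEATURE_TSV_COLUMNS = [
    "gene_id",
    "class",
    "gene_length",
    "utr5_length",
    "utr3_length",
    "intron_number",
    "mean_intron_length",
    "gc_gene",
    "gc_utr5",
    "gc_utr3",
    "gc3",
    "enc",
    "domain_number",
]


def architecture_features(
    model: GeneModel,
) -> tuple[int, int, int, int, float | None]:
    """Gene length, UTR lengths, intron number and mean intron length.

    Lengths are inclusive nucleotide counts; UTR length sums all
    segments on that side; mean intron length is None for intronless
    genes (intron length = inclusive inter-exon gap).
    """
    gene_length = model.end - model.start + 1
    utr5 = sum(e - s + 1 for s, e in model.utr5_segments)
    utr3 = sum(e - s + 1 for s, e in model.utr3_segments)
    gaps = model.intron_gaps
    intron_number = max(0, len(model.exons) - 1)
    mean_intron = (
        sum(e - s + 1 for s, e in gaps) / intron_number if intron_number else None
    )
    return gene_length, utr5, utr3, intron_number, mean_intron


def gc_content(seq: str) -> float | None:
    """(G+C)/(A+C+G+T); N excluded from both counts; None if no ACGT."""
    counts = Counter(seq.upper())
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        return None
    return (counts["G"] + counts["C"]) / denom


def gc3(cds_seq: str) -> float | None:
    """GC fraction at third positions of sense codons (stop excluded).

    Requires a quality-passing CDS. Codons that are not unambiguous
    sense codons (internal stops, ambiguity) are skipped.
    """
    ok, reasons = validate_cds(cds_seq)
    if not ok:
        raise ValueError(f"CDS fails quality rules: {reasons}")
    thirds = [c[2] for c in codons_of(cds_seq)[:-1] if c in CODON_TO_AA]
    if not thirds:
        return None
    return sum(1 for b in thirds if b in "GC") / len(thirds)


def _family_homozygosity(counts: list[int]) -> float | None:
    """Wright's F = (n sum(p_i^2) - 1)/(n - 1); None when n < 2."""
    n = sum(counts)
    if n < 2:
        return None
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(cds_seq: str) -> float | None:
    """Wright's (1990) effective number of codons.

    Codon usage of the CDS (terminal stop dropped) is grouped into
    synonymous families; per family with >= 2 observed codons the
    homozygosity F is computed and averaged within each degeneracy
    class; ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, clamped to [20, 61]
    (20 = one codon per amino acid, 61 = uniform usage). When no
    3-fold (Ile) family is observed, F3 is taken as (F2 + F4)/2; an
    unobserved 2-, 4- or 6-fold class makes ENc undefined (None).
    """
    ok, reasons = validate_cds(cds_seq)
    if not ok:
        raise ValueError(f"CDS fails quality rules: {reasons}")
    usage = Counter(c for c in codons_of(cds_seq)[:-1] if c in CODON_TO_AA)
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codon_list in FAMILIES.items():
        k = DEGENERACY[aa]
        if k == 1:
            continue
        f = _family_homozygosity([usage[c] for c in codon_list])
        if f is not None:
            per_class[k].append(f)
    fbar: dict[int, float] = {}
    for k, fs in per_class.items():
        if fs:
            fbar[k] = sum(fs) / len(fs)
    if 2 not in fbar or 4 not in fbar:
        warnings.warn("ENc undefined: too few observed synonymous families")
        return None
    if 3 not in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if 6 not in fbar:
        warnings.warn("ENc undefined: no 6-fold family observed")
        return None
    if any(fbar[k] <= 0 for k in (2, 3, 4, 6)):
        warnings.warn("ENc undefined: non-positive mean homozygosity")
        return None
    value = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return min(61.0, max(20.0, value))


def count_domains(table: str | Path | pd.DataFrame) -> dict[str, int]:
    """Per-gene domain-entry counts from a (gene_id, domain_id) table.

    Duplicate entries count; genes absent from the table count 0 (the
    caller supplies the gene universe).
    """
    df = _load_two_column(table, "domain_id")
    return df.groupby("gene_id")["domain_id"].size().to_dict()


def domain_class(count: int) -> str:
    """Bucket a domain count: 1 -> single, 2 -> double, >=3 -> multi."""
    if count < 1:
        raise ValueError("domain_class requires count >= 1 (0 is excluded/flagged)")
    return {1: "single", 2: "double"}.get(count, "multi")


def _load_two_column(table: str | Path | pd.DataFrame, value_name: str) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        df.columns = ["gene_id", value_name]
        return df
    df = pd.read_csv(table, sep="\t", dtype=str)
    df.columns = ["gene_id", value_name]
    return df


def feature_table(records: list[GeneFeatureRecord]) -> pd.DataFrame:
    """Assemble records into the canonical features DataFrame."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "class": r.class_label,
                "gene_length": r.gene_length,
                "utr5_length": r.utr5_length,
                "utr3_length": r.utr3_length,
                "intron_number": r.intron_number,
                "mean_intron_length": r.mean_intron_length,
                "gc_gene": r.gc_gene,
                "gc_utr5": r.gc_utr5,
                "gc_utr3": r.gc_utr3,
                "gc3": r.gc3,
                "enc": r.enc,
                "domain_number": r.domain_number,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_TSV_COLUMNS)


def write_feature_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
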