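"""Sequence/annotation input, gene-model assembly and CDS quality control.

Reads FASTA and GFF3, assembles one :class:`GeneModel` per (gene, isoform),
applies the coding-sequence quality rules (ATG start, canonical stop,
length a multiple of three) and selects the longest isoform per gene.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from ._codons import revcomp

VALID_ALPHABET = frozenset("ACGTN")

GFF3_COLUMNS = 9


class Gff3Error(ValueError):
    """Malformed or inconsistent GFF3 input."""


@dataclass
class GeneModel:
    """One gene isoform: coordinates, exon/UTR structure and sequences.

    Coordinates are 1-based inclusive (GFF3 convention). Exons and UTR
    segments are stored in genomic order regardless of strand; sequence
    fields are in transcript orientation (reverse-complemented for minus
    strand genes).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    utr5_segments: list[tuple[int, int]] = field(default_factory=list)
    utr3_segments: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    cds_seq: str = ""
    gene_seq: str = ""
    utr5_seq: str = ""
    utr3_seq: str = ""
    isoform_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.gene_id}: overlapping exons ({s1},{e1}) ({s2},{e2})"
                )
        for s, e in self.exons + self.utr5_segments + self.utr3_segments:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: segment ({s},{e}) outside gene bounds"
                )

    @property
    def intron_gaps(self) -> list[tuple[int, int]]:
        """Inclusive (start, end) of each inter-exon gap, genomic order."""
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]


@dataclass
class QCReport:
    """Outcome of the CDS quality filter over a set of genes."""

    n_input: int = 0
    n_pass: int = 0
    n_fail_start: int = 0
    n_fail_stop: int = 0
    n_fail_frame: int = 0
    failed_ids: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path, rows: list[tuple[str, bool, str]]) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tpass\treasons\n")
            for gene_id, ok, reasons in rows:
                fh.write(f"{gene_id}\t{int(ok)}\t{reasons}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase DNA string mapping.

    RNA (U) is converted to T. Duplicate ids and empty files are errors.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA id: {record.id}")
        seqs[record.id] = str(record.seq).upper().replace("U", "T")
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_attributes(col: str) -> dict[str, str]:
    attrs = {}
    for part in col.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _slice(genome: Mapping[str, str], chrom: str, segs: Iterable[tuple[int, int]]) -> str:
    seq = genome[chrom]
    return "".join(seq[s - 1 : e] for s, e in sorted(segs))


def read_gff3(path: str | Path, genome: Mapping[str, str]) -> list[GeneModel]:
    """Parse a GFF3 file into gene models, one per (gene, isoform).

    ``genome`` maps chromosome/contig id to its full nucleotide sequence
    and is used to fill the sequence fields. Minus-strand genes keep
    genomic-order coordinates but reverse-complemented sequences.
    """
    genes: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != GFF3_COLUMNS:
                raise Gff3Error(
                    f"{path}:{lineno}: expected {GFF3_COLUMNS} columns, got {len(cols)}"
                )
            chrom, _source, ftype, start, end, _score, strand, _frame, attr_col = cols
            start, end = int(start), int(end)
            attrs = _parse_attributes(attr_col)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise Gff3Error(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = {"chrom": chrom, "start": start, "end": end, "strand": strand}
            elif ftype == "mRNA":
                mid = attrs.get("ID")
                parent = attrs.get("Parent")
                if parent not in genes:
                    raise Gff3Error(f"{path}:{lineno}: mRNA Parent {parent!r} unknown")
                mrnas[mid] = {
                    "gene_id": parent,
                    "exons": [],
                    "utr5": [],
                    "utr3": [],
                    "cds": [],
                }
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR", "CDS"):
                parent = attrs.get("Parent")
                if parent not in mrnas:
                    raise Gff3Error(
                        f"{path}:{lineno}: {ftype} Parent {parent!r} unknown"
                    )
                key = {
                    "exon": "exons",
                    "five_prime_UTR": "utr5",
                    "three_prime_UTR": "utr3",
                    "CDS": "cds",
                }[ftype]
                mrnas[parent][key].append((start, end))

    models = []
    for mid, rec in mrnas.items():
        gene = genes[rec["gene_id"]]
        chrom, strand = gene["chrom"], gene["strand"]
        if chrom not in genome:
            raise Gff3Error(f"chromosome {chrom!r} absent from genome FASTA")

        def oriented(segs: list[tuple[int, int]]) -> str:
            s = _slice(genome, chrom, segs)
            return revcomp(s) if strand == "-" else s

        models.append(
            GeneModel(
                gene_id=rec["gene_id"],
                chrom=chrom,
                start=gene["start"],
                end=gene["end"],
                strand=strand,
                exons=rec["exons"],
                utr5_segments=sorted(rec["utr5"]),
                utr3_segments=sorted(rec["utr3"]),
                cds_segments=sorted(rec["cds"]),
                cds_seq=oriented(rec["cds"]),
                gene_seq=oriented([(gene["start"], gene["end"])]),
                utr5_seq=oriented(rec["utr5"]) if rec["utr5"] else "",
                utr3_seq=oriented(rec["utr3"]) if rec["utr3"] else "",
                isoform_id=mid,
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back to GFF3 (gene/mRNA/exon/UTR/CDS rows)."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    seen_genes: set[str] = set()
    for m in models:
        if m.gene_id not in seen_genes:
            seen_genes.add(m.gene_id)
            buf.write(
                f"{m.chrom}\trateherit\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
        buf.write(
            f"{m.chrom}\trateherit\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
            f"ID={m.isoform_id};Parent={m.gene_id}\n"
        )
        for ftype, segs in (
            ("exon", m.exons),
            ("five_prime_UTR", m.utr5_segments),
            ("three_prime_UTR", m.utr3_segments),
            ("CDS", m.cds_segments),
        ):
            for s, e in segs:
                buf.write(
                    f"{m.chrom}\trateherit\t{ftype}\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={m.isoform_id}\n"
                )
    Path(path).write_text(buf.getvalue())


def validate_cds(cds_seq: str) -> tuple[bool, list[str]]:
    """Apply the three CDS quality rules.

    A sequence passes iff it starts with ATG, ends with TAG/TAA/TGA and
    has length divisible by three. Returns (passed, violated-rule names).
    Internal stop codons are deliberately not checked.
    """
    if not cds_seq:
        raise ValueError("empty CDS")
    bad = set(cds_seq) - VALID_ALPHABET
    if bad:
        raise ValueError(f"invalid characters in CDS: {sorted(bad)}")
    reasons = []
    if not cds_seq.startswith("ATG"):
        reasons.append("no_start")
    if cds_seq[-3:] not in ("TAG", "TAA", "TGA"):
        reasons.append("no_stop")
    if len(cds_seq) % 3 != 0:
        reasons.append("frame")
    return (not reasons, reasons)


def select_longest_isoform(models: list[GeneModel]) -> GeneModel:
    """Longest-CDS isoform of one gene; ties broken by smallest isoform id."""
    if not models:
        raise ValueError("no isoforms supplied")
    gene_ids = {m.gene_id for m in models}
    if len(gene_ids) != 1:
        raise ValueError(f"isoforms from multiple genes: {sorted(gene_ids)}")
    return min(models, key=lambda m: (-len(m.cds_seq), m.isoform_id))


def apply_qc(
    models: list[GeneModel],
) -> tuple[list[GeneModel], QCReport, list[tuple[str, bool, str]]]:
    """Run the CDS filter over longest isoforms, one verdict per gene.

    Returns (passing models, summary report, per-gene TSV rows).
    """
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    report = QCReport(n_input=len(by_gene))
    passed: list[GeneModel] = []
    rows: list[tuple[str, bool, str]] = []
    for gene_id in sorted(by_gene):
        model = select_longest_isoform(by_gene[gene_id])
        ok, reasons = validate_cds(model.cds_seq)
        rows.append((gene_id, ok, ",".join(reasons)))
        if ok:
            report.n_pass += 1
            passed.append(model)
        else:
            report.failed_ids.append(gene_id)
            if "no_start" in reasons:
                report.n_fail_start += 1
            if "no_stop" in reasons:
                report.n_fail_stop += 1
            if "frame" in reasons:
                report.n_fail_frame += 1
    return passed, report, rows
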