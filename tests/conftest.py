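import numpy as np
import pytest

from rateherit.seqio_qc import write_fasta


@pytest.fixture
def rng():
    return np.random.default_rng(42)


TOY_GENOME = {
    # plus-strand gene: 11..42, exons 11-22 and 31-42 (intron 23-30,
    # length 8), CDS occupies the exons entirely (no UTRs)
    "chrA": "N" * 10 + "ATGAAACCCGGG" + "GTTTTTAG" + "TTTCCCGGGTAA" + "N" * 5,
    # minus-strand gene at 6..20: revcomp is ATGAAAAAAATGTAA
    "chrB": "GGGGG" + "TTACATTTTTTTCAT" + "CCCCC",
}

TOY_GFF3 = """##gff-version 3
chrA\ttoy\tgene\t11\t42\t.\t+\t.\tID=gA
chrA\ttoy\tmRNA\t11\t42\t.\t+\t.\tID=gA.1;Parent=gA
chrA\ttoy\texon\t11\t22\t.\t+\t.\tParent=gA.1
chrA\ttoy\texon\t31\t42\t.\t+\t.\tParent=gA.1
chrA\ttoy\tCDS\t11\t22\t.\t+\t.\tParent=gA.1
chrA\ttoy\tCDS\t31\t42\t.\t+\t.\tParent=gA.1
chrB\ttoy\tgene\t6\t20\t.\t-\t.\tID=gB
chrB\ttoy\tmRNA\t6\t20\t.\t-\t.\tID=gB.1;Parent=gB
chrB\ttoy\texon\t6\t20\t.\t-\t.\tParent=gB.1
chrB\ttoy\tCDS\t6\t20\t.\t-\t.\tParent=gB.1
"""


@pytest.fixture
def toy_annotation(tmp_path):
    """A two-gene GFF3 + genome pair (one plus, one minus strand)."""
    gff = tmp_path / "toy.gff3"
    gff.write_text(TOY_GFF3)
    genome_path = tmp_path / "toy.fa"
    write_fasta(TOY_GENOME, genome_path)
    return gff, TOY_GENOME, genome_path
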