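"""Standard nuclear genetic code lookup tables shared across modules.

Built once from Biopython's codon table so the package carries no
hand-typed copy of the code.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

NUCLEOTIDES = ("A", "C", "G", "T")

#: amino acid -> sorted tuple of its codons (synonymous family)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] = FAMILIES[_aa] + (_codon,)

#: amino acid -> family degeneracy (1, 2, 3, 4 or 6)
DEGENERACY: dict[str, int] = {aa: len(codons) for aa, codons in FAMILIES.items()}

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


def is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


def codons_of(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into consecutive triplets."""
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
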