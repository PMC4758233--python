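"""Pairwise dN/dS estimation by Nei–Gojobori (1986) counting.

For each aligned ortholog CDS pair: expected synonymous (S) and
nonsynonymous (N) sites are counted per codon and averaged over the two
sequences; observed differences are attributed by enumerating every
mutational pathway between differing codons, discarding pathways through
stop codons and averaging synonymous/nonsynonymous step counts over the
rest; proportions pS = Sd/S and pN = Nd/N are corrected for multiple
hits with the Jukes–Cantor formula d = -(3/4) ln(1 - 4p/3). The ratio
omega = dN/dS summarises selective constraint (omega < 1: purifying).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import log
from pathlib import Path

import pandas as pd

from ._codons import CODON_TO_AA, NUCLEOTIDES, SENSE_CODONS, STOP_CODONS


class PathwayBlockedError(ValueError):
    """Every mutational pathway between two codons passes through a stop."""


class SaturationError(ValueError):
    """Difference proportion >= 3/4: Jukes–Cantor correction undefined."""


@dataclass
class CodonPair:
    """A codon-aligned ortholog CDS pair (gaps '-' allowed, in frame)."""

    gene_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.gene_id}: aligned lengths differ")
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"{self.gene_id}: alignment length not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_columns(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass
class DivergenceEstimate:
    """NG86 site/difference counts and corrected distances for one pair."""

    gene_id: str
    n_codons_compared: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None
    skipped: dict = field(default_factory=dict)


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Expected synonymous and nonsynonymous sites of one sense codon.

    At each of the three positions, the synonymous fraction is the share
    of single-nucleotide changes to *sense* codons that preserve the
    amino acid (changes to stop codons are excluded from the
    denominator). Returns (s, n) with s + n = 3.
    """
    aa = CODON_TO_AA.get(codon)
    if aa is None:
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon!r} has no site counts")
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        sense = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            neighbor = codon[:pos] + nt + codon[pos + 1 :]
            neighbor_aa = CODON_TO_AA.get(neighbor)
            if neighbor_aa is None:
                continue
            sense += 1
            if neighbor_aa == aa:
                syn += 1
        if sense:
            s += syn / sense
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    All orderings of the differing positions are enumerated; pathways
    passing through a stop codon are discarded; step classifications are
    averaged over the remainder, so sd + nd equals the number of
    differing positions. Raises :class:`PathwayBlockedError` when no
    stop-free pathway exists.
    """
    for c in (codon_a, codon_b):
        if c not in CODON_TO_AA:
            raise ValueError(f"not an unambiguous sense codon: {c!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    total_s = total_n = 0.0
    n_legal = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        path_s = path_n = 0
        legal = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                legal = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                path_s += 1
            else:
                path_n += 1
            current = nxt
        if legal:
            n_legal += 1
            total_s += path_s
            total_n += path_n
    if n_legal == 0:
        raise PathwayBlockedError(f"{codon_a}->{codon_b}: all pathways hit a stop")
    return total_s / n_legal, total_n / n_legal


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; undefined at p >= 3/4."""
    if p >= 0.75:
        raise SaturationError(
            f"Jukes–Cantor correction undefined (saturation): p={p:.4f}"
        )
    if p == 0.0:
        return 0.0
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


_SKIP_KEYS = ("gap", "ambiguous", "stop", "pathway_blocked")


def estimate_divergence(pair: CodonPair) -> DivergenceEstimate:
    """NG86 estimate for one codon-aligned pair.

    Codon columns containing a gap, an ambiguous base, or a stop codon
    in either sequence are skipped and tallied; columns whose difference
    pathways are all stop-blocked likewise. omega is None when dS = 0.
    """
    skipped = dict.fromkeys(_SKIP_KEYS, 0)
    S = N = Sd = Nd = 0.0
    n_compared = 0
    for ca, cb in pair.codon_columns():
        if "-" in ca or "-" in cb:
            skipped["gap"] += 1
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            skipped["stop"] += 1
            continue
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            skipped["ambiguous"] += 1
            continue
        try:
            sd, nd = codon_differences(ca, cb)
        except PathwayBlockedError:
            skipped["pathway_blocked"] += 1
            continue
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += sd
        Nd += nd
        n_compared += 1
    if n_compared == 0:
        raise ValueError(f"{pair.gene_id}: no comparable codon columns")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = dN / dS if dS > 0 else None
    return DivergenceEstimate(
        gene_id=pair.gene_id,
        n_codons_compared=n_compared,
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega,
        skipped=skipped,
    )


_TABLE_COLUMNS = [
    "gene_id",
    "n_codons_compared",
    "S_sites",
    "N_sites",
    "Sd",
    "Nd",
    "pS",
    "pN",
    "dS",
    "dN",
    "omega",
    "flags",
]


def batch_divergence(pairs: list[CodonPair]) -> pd.DataFrame:
    """Estimate every pair; per-pair failures become flagged NA rows."""
    rows = []
    for pair in pairs:
        try:
            est = estimate_divergence(pair)
        except (SaturationError, ValueError) as exc:
            flag = "saturated" if isinstance(exc, SaturationError) else "failed"
            rows.append(
                {
                    "gene_id": pair.gene_id,
                    "n_codons_compared": pd.NA,
                    "flags": f"{flag}:{exc}",
                }
            )
            continue
        flags = ";".join(f"{k}={v}" for k, v in est.skipped.items() if v)
        rows.append(
            {
                "gene_id": est.gene_id,
                "n_codons_compared": est.n_codons_compared,
                "S_sites": est.S_sites,
                "N_sites": est.N_sites,
                "Sd": est.Sd,
                "Nd": est.Nd,
                "pS": est.pS,
                "pN": est.pN,
                "dS": est.dS,
                "dN": est.dN,
                "omega": est.omega,
                "flags": flags,
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def pairs_from_fasta(path: str | Path) -> list[CodonPair]:
    """Load aligned pairs from FASTA with ids '<gene>|a' and '<gene>|b'."""
    from .seqio_qc import read_fasta

    seqs = read_fasta(path)
    genes: dict[str, dict[str, str]] = {}
    for name, seq in seqs.items():
        gene, _, tag = name.rpartition("|")
        if tag not in ("a", "b") or not gene:
            raise ValueError(f"pair FASTA id {name!r} not of form '<gene>|a' or '<gene>|b'")
        genes.setdefault(gene, {})[tag] = seq
    pairs = []
    for gene in sorted(genes):
        members = genes[gene]
        if set(members) != {"a", "b"}:
            raise ValueError(f"gene {gene!r} lacks one of its two pair members")
        pairs.append(CodonPair(gene_id=gene, seq_a=members["a"], seq_b=members["b"]))
    return pairs


def precompute_tables() -> tuple[int, int]:
    """Fill the codon caches; returns (#codons, #codon-pair entries)."""
    n_pairs = 0
    for a in SENSE_CODONS:
        codon_site_counts(a)
        for b in SENSE_CODONS:
            try:
                codon_differences(a, b)
            except PathwayBlockedError:
                pass
            n_pairs += 1
    return len(SENSE_CODONS), n_pairs
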