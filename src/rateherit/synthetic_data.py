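"""Synthetic study generator: ortholog pairs, gene models, expression.

Emulates the statistical structure of a two-class comparison of
metabolic-pathway genes: two gene classes ("primary", "secondary") with
class-specific divergence targets (dN, dS), gene-architecture
distributions (UTR lengths, intron number/length), codon usage (GC3
target, within-family bias), expression level and tissue specificity,
and annotation-count distributions (domains, GO-slim, PO). Defaults
reproduce the class means of the Arabidopsis thaliana / A. lyrata
comparison the package analyses, so the analysis pipeline can be
exercised end to end without any external download.

Divergence is simulated by independent per-codon Bernoulli
substitutions, split evenly between the two descendant lineages and
calibrated in the currency of the package's own Nei–Gojobori estimator:
the per-lineage substitution probabilities are chosen so that the
expected estimated dS and dN equal the targets (no indels).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from ._codons import CODON_TO_AA, FAMILIES, NUCLEOTIDES, codons_of, revcomp
from .divergence import CodonPair, codon_site_counts
from .expression import ExpressionProfile
from .seqio_qc import GeneModel, write_fasta, write_gff3

# Amino-acid frequencies (%) approximating a plant proteome; used when
# sampling coding sequence composition.
AA_FREQS = {
    "A": 6.3, "R": 5.4, "N": 4.5, "D": 5.4, "C": 1.8, "Q": 3.5, "E": 6.7,
    "G": 6.4, "H": 2.3, "I": 5.3, "L": 9.5, "K": 6.4, "M": 2.4, "F": 4.3,
    "P": 4.8, "S": 9.0, "T": 5.1, "W": 1.2, "Y": 2.9, "V": 6.8,
}

STOP_CHOICES = ("TAA", "TGA", "TAG")

# Single-nucleotide mutation options per sense codon, precomputed as
# (position, neighbor-codon): synonymous targets and nonsynonymous
# *sense* targets (stops excluded).
_SYN_OPTIONS: dict[str, list[tuple[int, str]]] = {}
_NONSYN_OPTIONS: dict[str, list[tuple[int, str]]] = {}
for _codon, _aa in CODON_TO_AA.items():
    syn, nonsyn = [], []
    for _pos in range(3):
        for _nt in NUCLEOTIDES:
            if _nt == _codon[_pos]:
                continue
            _nbr = _codon[:_pos] + _nt + _codon[_pos + 1 :]
            _nbr_aa = CODON_TO_AA.get(_nbr)
            if _nbr_aa is None:
                continue
            (syn if _nbr_aa == _aa else nonsyn).append((_pos, _nbr))
    _SYN_OPTIONS[_codon] = syn
    _NONSYN_OPTIONS[_codon] = nonsyn


def _collision_loss(options: list[tuple[int, str]]) -> float:
    """Expected observed differences lost when both lineages hit a codon.

    Two independent uniform choices among the codon's mutation options:
    the same option cancels entirely (2 differences lost); different
    options at the same position overlap (1 lost); different positions
    lose nothing.
    """
    m = len(options)
    if m == 0:
        return 0.0
    per_pos: dict[int, int] = {}
    for pos, _ in options:
        per_pos[pos] = per_pos.get(pos, 0) + 1
    same_pos_pairs = sum(c * c for c in per_pos.values()) - m
    return 2.0 / m + same_pos_pairs / (m * m)


def _event_probability(n_capable: int, loss_sum: float, target_diffs: float) -> float:
    """Per-codon Bernoulli probability hitting an expected difference count.

    Solves 2*n*q - loss_sum*q^2 = target for q (smaller root), so the
    expectation of pathway-counted differences — net of double-hit
    collisions — equals the target.
    """
    if target_diffs <= 0 or n_capable == 0:
        return 0.0
    if loss_sum <= 0:
        q = target_diffs / (2.0 * n_capable)
    else:
        disc = 4.0 * n_capable * n_capable - 4.0 * loss_sum * target_diffs
        if disc < 0:
            raise ValueError("divergence target infeasible for this sequence length")
        q = (2.0 * n_capable - math.sqrt(disc)) / (2.0 * loss_sum)
    if q > 1.0:
        raise ValueError("divergence target infeasible for this sequence length")
    return q


@dataclass
class ClassParams:
    """Generator targets for one gene class."""

    n_genes: int
    dn_mean: float
    dn_sd: float
    ds_mean: float
    ds_sd: float
    cds_codons_mean: float = 470.0
    cds_codons_sigma: float = 0.35
    utr5_mean: float = 128.6
    utr3_mean: float = 231.1
    intronless_prob: float = 0.15
    intron_number_mean: float = 6.17
    intron_length_mean: float = 160.0
    utr5_gc: float = 0.3427
    utr3_gc: float = 0.2958
    gc3_mean: float = 0.412
    gc3_sd: float = 0.05
    gc3_intronless_shift: float = 0.10
    codon_bias: float = 0.72
    expression_mean: float = 9025.77
    expression_sigma: float = 1.0
    tau_mean: float = 0.236
    tau_sd: float = 0.10
    domain_lambda: float = 1.53
    go_lambda: float = 12.95
    po_lambda: float = 28.25


def default_primary(n_genes: int = 1035) -> ClassParams:
    return ClassParams(
        n_genes=n_genes, dn_mean=0.02, dn_sd=0.016, ds_mean=0.147, ds_sd=0.044
    )


def default_secondary(n_genes: int = 241) -> ClassParams:
    return ClassParams(
        n_genes=n_genes,
        dn_mean=0.026,
        dn_sd=0.016,
        ds_mean=0.157,
        ds_sd=0.043,
        utr5_mean=96.49,
        utr3_mean=192.87,
        intronless_prob=0.22,
        intron_number_mean=4.30,
        utr5_gc=0.3100,
        utr3_gc=0.2742,
        gc3_mean=0.423,
        codon_bias=0.62,
        expression_mean=4430.29,
        tau_mean=0.287,
        domain_lambda=1.26,
        go_lambda=10.91,
        po_lambda=22.48,
    )


@dataclass
class SimulationConfig:
    """Full generator configuration; defaults mirror the study conditions."""

    primary: ClassParams = field(default_factory=default_primary)
    secondary: ClassParams = field(default_factory=default_secondary)
    n_tissues: int = 20
    expression_noise_sd: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        for cp in (self.primary, self.secondary):
            if cp.n_genes <= 0:
                raise ValueError("gene counts must be positive")
            for t in (cp.dn_mean, cp.ds_mean):
                if not (0.0 < t < 0.75):
                    raise ValueError(f"rate target {t} outside (0, 0.75)")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")


def _codon_distribution(gc3_target: float, bias: float) -> tuple[list[str], np.ndarray]:
    """Sense-codon sampling distribution hitting an expected GC3.

    Within each synonymous family, codons are weighted by exp(bias) for
    the family's preferred codon and by a third-position GC factor g
    solved numerically so that the amino-acid-frequency-weighted
    expected GC3 equals the target (Met and Trp force G; if the target
    is outside the achievable span, g saturates at its bound).
    """
    if not (0.0 <= gc3_target <= 1.0):
        raise ValueError(f"gc3_target {gc3_target} outside [0, 1]")
    aa_order = sorted(AA_FREQS)
    freqs = np.array([AA_FREQS[a] for a in aa_order])
    freqs = freqs / freqs.sum()

    def family_weights(aa: str, g: float) -> tuple[list[str], np.ndarray]:
        codon_list = list(FAMILIES[aa])
        preferred = codon_list[0]
        w = np.array(
            [
                (math.exp(bias) if c == preferred else 1.0)
                * (g if c[2] in "GC" else 1.0 - g)
                for c in codon_list
            ]
        )
        return codon_list, w

    def expected_gc3(g: float) -> float:
        total = 0.0
        for aa, f in zip(aa_order, freqs):
            codon_list, w = family_weights(aa, g)
            p_gc = sum(
                wi for c, wi in zip(codon_list, w) if c[2] in "GC"
            ) / w.sum()
            total += f * p_gc
        return total

    lo, hi = expected_gc3(1e-9), expected_gc3(1.0 - 1e-9)
    if gc3_target <= lo:
        g = 1e-9
    elif gc3_target >= hi:
        g = 1.0 - 1e-9
    else:
        g = brentq(lambda x: expected_gc3(x) - gc3_target, 1e-9, 1.0 - 1e-9)

    codons: list[str] = []
    probs: list[float] = []
    for aa, f in zip(aa_order, freqs):
        codon_list, w = family_weights(aa, g)
        w = w / w.sum()
        codons.extend(codon_list)
        probs.extend(f * w)
    return codons, np.asarray(probs)


def simulate_cds(
    length_codons: int,
    gc3_target: float,
    rng: np.random.Generator,
    codon_bias: float = 0.0,
) -> str:
    """A quality-passing CDS: ATG start, stop end, no internal stops.

    ``length_codons`` counts the start and stop codons. The realised
    GC3 tracks the target (within sampling noise and the Met/Trp
    constraint) and ``codon_bias`` skews within-family codon usage
    toward one preferred codon per family (raising codon-usage bias,
    i.e. lowering ENc).
    """
    if length_codons < 10:
        raise ValueError("length_codons must be >= 10")
    codons, probs = _codon_distribution(gc3_target, codon_bias)
    body = rng.choice(codons, size=length_codons - 2, p=probs)
    stop = STOP_CHOICES[rng.integers(len(STOP_CHOICES))]
    return "ATG" + "".join(body) + stop


def _proportion_from_distance(d: float) -> float:
    """Invert the Jukes–Cantor correction: p = (3/4)(1 - exp(-4d/3))."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def evolve_pair(
    ancestor_cds: str,
    target_ds: float,
    target_dn: float,
    rng: np.random.Generator,
    gene_id: str = "pair",
) -> CodonPair:
    """Two descendants of one ancestor hitting NG86 divergence targets.

    Each lineage receives half the divergence: per codon, a synonymous
    (resp. nonsynonymous, to a sense codon) single-nucleotide change is
    applied with probability chosen so the expected pathway-counted
    differences equal p*S (resp. p*N) with p the JC-inverted target.
    Gap-free, equal length; no stop codons are created.
    """
    for t in (target_ds, target_dn):
        if not (0.0 <= t < 0.7):
            raise ValueError(f"divergence target {t} outside [0, 0.7)")
    codons = codons_of(ancestor_cds)
    sense_idx = [i for i, c in enumerate(codons) if c in CODON_TO_AA]
    if not sense_idx:
        raise ValueError("ancestor has no sense codons")
    S = sum(codon_site_counts(codons[i])[0] for i in sense_idx)
    N = sum(codon_site_counts(codons[i])[1] for i in sense_idx)
    syn_capable = [i for i in sense_idx if _SYN_OPTIONS[codons[i]]]
    nonsyn_capable = [i for i in sense_idx if _NONSYN_OPTIONS[codons[i]]]

    sd_total = _proportion_from_distance(target_ds) * S
    nd_total = _proportion_from_distance(target_dn) * N
    syn_loss = sum(_collision_loss(_SYN_OPTIONS[codons[i]]) for i in syn_capable)
    nonsyn_loss = sum(
        _collision_loss(_NONSYN_OPTIONS[codons[i]]) for i in nonsyn_capable
    )
    q_s = _event_probability(len(syn_capable), syn_loss, sd_total)
    q_n = _event_probability(len(nonsyn_capable), nonsyn_loss, nd_total)

    def descend() -> str:
        child = list(codons)
        if syn_capable:
            hits = np.asarray(syn_capable)[rng.random(len(syn_capable)) < q_s]
            for i in hits:
                options = _SYN_OPTIONS[child[i]]
                if options:
                    child[i] = options[rng.integers(len(options))][1]
        if nonsyn_capable:
            hits = np.asarray(nonsyn_capable)[rng.random(len(nonsyn_capable)) < q_n]
            for i in hits:
                options = _NONSYN_OPTIONS[child[i]]
                if options:
                    child[i] = options[rng.integers(len(options))][1]
        return "".join(child)

    return CodonPair(gene_id=gene_id, seq_a=descend(), seq_b=descend())


def simulate_expression(
    n_tissues: int,
    tau_target: float,
    level_target: float,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
) -> ExpressionProfile:
    """A profile with specificity tau_target and mean ~ level_target.

    One randomly placed maximal tissue at S_max, the others at
    S_max^(1 - tau_target) (which makes the specificity index equal the
    target exactly), with S_max solved so the profile mean matches the
    level target; optional multiplicative log-normal noise on the
    non-maximal tissues.
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    if not (0.0 <= tau_target <= 1.0):
        raise ValueError("tau_target must lie in [0, 1]")
    if level_target <= 1.0:
        raise ValueError("level_target must exceed the floor of 1")
    n, g = n_tissues, tau_target

    def mean_at(s_max: float) -> float:
        return (s_max + (n - 1) * s_max ** (1.0 - g)) / n

    s_max = brentq(lambda s: mean_at(s) - level_target, 1.0 + 1e-12, 1e15)
    others = np.full(n - 1, s_max ** (1.0 - g))
    if noise_sd > 0.0 and g > 0.0:
        others = np.maximum(
            1.0, others * np.exp(rng.normal(0.0, noise_sd, size=n - 1))
        )
        others = np.minimum(others, s_max)  # keep the designated maximum
    values = np.empty(n)
    max_pos = int(rng.integers(n))
    values[max_pos] = s_max
    values[[i for i in range(n) if i != max_pos]] = others
    return ExpressionProfile(
        gene_id="sim",
        values=values.tolist(),
        sample_ids=[f"tissue_{i + 1}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# whole-study generation


def _lognormal_mean(mean: float, sigma: float, rng: np.random.Generator) -> float:
    """Log-normal draw with the given arithmetic mean."""
    mu = math.log(mean) - sigma * sigma / 2.0
    return float(rng.lognormal(mu, sigma))


def _intron_count(cp: ClassParams, rng: np.random.Generator) -> int:
    """Zero-inflated Poisson with overall mean intron_number_mean."""
    if rng.random() < cp.intronless_prob:
        return 0
    lam = cp.intron_number_mean / (1.0 - cp.intronless_prob) - 1.0
    return 1 + int(rng.poisson(max(lam, 0.0)))


def _random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    if length <= 0:
        return ""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _assemble_gene(
    gene_id: str,
    cds: str,
    utr5: str,
    utr3: str,
    intron_lengths: list[int],
    strand: str,
    rng: np.random.Generator,
    flank: int = 50,
) -> tuple[GeneModel, str]:
    """Place UTR5+CDS+UTR3 on a contig with introns; return model + contig."""
    mature = utr5 + cds + utr3
    m_len = len(mature)
    k = len(intron_lengths)
    if k > 0:
        cuts = sorted(rng.choice(np.arange(1, m_len), size=k, replace=False).tolist())
    else:
        cuts = []
    introns = [
        "GT" + _random_dna(max(il, 6) - 4, 0.32, rng) + "AG" for il in intron_lengths
    ]

    # genomic position of mature coordinate m (1-based), before flanks
    bounds = cuts + [m_len]
    offsets = np.cumsum([0] + [len(i) for i in introns])

    def to_genomic(m: int) -> int:
        piece = sum(1 for c in cuts if c < m)
        return flank + m + int(offsets[piece])

    pieces = []
    prev = 0
    for c in bounds:
        pieces.append(mature[prev:c])
        prev = c
    body = "".join(
        p + (introns[i] if i < k else "") for i, p in enumerate(pieces)
    )
    contig = _random_dna(flank, 0.35, rng) + body + _random_dna(flank, 0.35, rng)

    gene_start = flank + 1
    gene_end = flank + len(body)
    exon_ranges = []
    prev = 0
    for c in bounds:
        if c > prev:
            exon_ranges.append((to_genomic(prev + 1), to_genomic(c)))
        prev = c

    def mapped_segments(a: int, b: int) -> list[tuple[int, int]]:
        """Mature range [a, b] -> genomic segments split at introns."""
        segs = []
        prev_c = 0
        for c in bounds:
            lo, hi = max(a, prev_c + 1), min(b, c)
            if lo <= hi:
                segs.append((to_genomic(lo), to_genomic(hi)))
            prev_c = c
        return segs

    u5, cl = len(utr5), len(cds)
    utr5_segs = mapped_segments(1, u5) if u5 else []
    cds_segs = mapped_segments(u5 + 1, u5 + cl)
    utr3_segs = mapped_segments(u5 + cl + 1, m_len) if utr3 else []

    if strand == "-":
        L = len(contig)
        contig = revcomp(contig)

        def flip(segs):
            return sorted((L - e + 1, L - s + 1) for s, e in segs)

        exon_ranges = flip(exon_ranges)
        utr5_segs = flip(utr5_segs)
        cds_segs = flip(cds_segs)
        utr3_segs = flip(utr3_segs)
        gene_start, gene_end = L - gene_end + 1, L - gene_start + 1

    model = GeneModel(
        gene_id=gene_id,
        chrom=f"chr_{gene_id}",
        start=gene_start,
        end=gene_end,
        strand=strand,
        exons=exon_ranges,
        utr5_segments=utr5_segs,
        utr3_segments=utr3_segs,
        cds_segments=cds_segs,
        cds_seq=cds,
        gene_seq="",  # filled by the reader on round-trip
        utr5_seq=utr5,
        utr3_seq=utr3,
        isoform_id=f"{gene_id}.1",
    )
    return model, contig


def simulate_study(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate a cross-consistent input bundle for the whole pipeline.

    Writes genome FASTA, GFF3, CDS FASTA, aligned ortholog-pair FASTA,
    expression matrix TSV, annotation TSVs (domains, GO-slim, PO), the
    gene->class map and a manifest recording config and seed. Returns
    the path of every file written.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    cds_seqs: dict[str, str] = {}
    pair_seqs: dict[str, str] = {}
    expr_rows: list[list] = []
    domain_rows: list[tuple[str, str]] = []
    go_rows: list[tuple[str, str]] = []
    po_rows: list[tuple[str, str]] = []
    class_rows: list[tuple[str, str]] = []

    for label, prefix, cp in (
        ("primary", "P", config.primary),
        ("secondary", "S", config.secondary),
    ):
        for i in range(cp.n_genes):
            gene_id = f"{prefix}{i + 1:05d}"
            class_rows.append((gene_id, label))

            n_codons = max(60, round(_lognormal_mean(cp.cds_codons_mean,
                                                     cp.cds_codons_sigma, rng)))
            k = _intron_count(cp, rng)
            gc3_t = float(
                np.clip(
                    rng.normal(cp.gc3_mean, cp.gc3_sd)
                    + (cp.gc3_intronless_shift if k == 0 else 0.0),
                    0.15,
                    0.95,
                )
            )
            cds = simulate_cds(n_codons, gc3_t, rng, codon_bias=cp.codon_bias)
            utr5 = _random_dna(round(rng.gamma(1.5, cp.utr5_mean / 1.5)),
                               cp.utr5_gc, rng)
            utr3 = _random_dna(round(rng.gamma(1.5, cp.utr3_mean / 1.5)),
                               cp.utr3_gc, rng)
            intron_lengths = [
                max(60, round(_lognormal_mean(cp.intron_length_mean, 0.5, rng)))
                for _ in range(k)
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            model, contig = _assemble_gene(
                gene_id, cds, utr5, utr3, intron_lengths, strand, rng
            )
            genome[model.chrom] = contig
            models.append(model)
            cds_seqs[gene_id] = cds

            ds_t = float(np.clip(rng.normal(cp.ds_mean, cp.ds_sd), 1e-3, 0.65))
            dn_t = float(np.clip(rng.normal(cp.dn_mean, cp.dn_sd), 5e-4, 0.65))
            pair = evolve_pair(cds, ds_t, dn_t, rng, gene_id=gene_id)
            pair_seqs[f"{gene_id}|a"] = pair.seq_a
            pair_seqs[f"{gene_id}|b"] = pair.seq_b

            level = max(2.0, _lognormal_mean(cp.expression_mean,
                                             cp.expression_sigma, rng))
            tau_t = float(np.clip(rng.normal(cp.tau_mean, cp.tau_sd), 0.01, 0.99))
            profile = simulate_expression(
                config.n_tissues, tau_t, level, rng,
                noise_sd=config.expression_noise_sd,
            )
            expr_rows.append([gene_id] + [f"{v:.4f}" for v in profile.values])

            for d in range(int(rng.poisson(cp.domain_lambda))):
                domain_rows.append((gene_id, f"PF{d + 1:05d}"))
            for t in range(int(rng.poisson(cp.go_lambda))):
                go_rows.append((gene_id, f"GO:{t + 1:07d}"))
            for t in range(int(rng.poisson(cp.po_lambda))):
                po_rows.append((gene_id, f"PO:{t + 1:07d}"))

    paths = {
        "genome_fasta": out / "genome.fa",
        "gff3": out / "annotation.gff3",
        "fasta_cds": out / "cds.fa",
        "pairs_fasta": out / "pairs.fa",
        "expression_tsv": out / "expression.tsv",
        "domains_tsv": out / "domains.tsv",
        "go_tsv": out / "goslim.tsv",
        "po_tsv": out / "po.tsv",
        "class_map_tsv": out / "class_map.tsv",
        "manifest": out / "manifest.json",
    }
    write_fasta(genome, paths["genome_fasta"])
    write_gff3(models, paths["gff3"])
    write_fasta(cds_seqs, paths["fasta_cds"])
    write_fasta(pair_seqs, paths["pairs_fasta"])

    sample_ids = [f"tissue_{i + 1}" for i in range(config.n_tissues)]
    with open(paths["expression_tsv"], "w") as fh:
        fh.write("gene_id\t" + "\t".join(sample_ids) + "\n")
        for row in expr_rows:
            fh.write("\t".join(row) + "\n")

    for key, header, rows in (
        ("domains_tsv", "gene_id\tdomain_id", domain_rows),
        ("go_tsv", "gene_id\tterm_id", go_rows),
        ("po_tsv", "gene_id\tterm_id", po_rows),
        ("class_map_tsv", "gene_id\tclass", class_rows),
    ):
        with open(paths[key], "w") as fh:
            fh.write(header + "\n")
            for a, b in rows:
                fh.write(f"{a}\t{b}\n")

    manifest = {
        "seed": config.seed,
        "n_tissues": config.n_tissues,
        "expression_noise_sd": config.expression_noise_sd,
        "primary": dataclasses.asdict(config.primary),
        "secondary": dataclasses.asdict(config.secondary),
        "files": {k: str(v) for k, v in paths.items()},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
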