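# Methods

This note documents the models, parameter choices and numerical
conventions behind `rateherit`, and what the synthetic-data tests do
and do not establish about real data.

## Divergence estimation

Pairwise dN/dS is estimated by Nei–Gojobori (1986) counting with
Jukes–Cantor correction, not by a maximum-likelihood codon model. The
analysis layer consumes only (dN, dS, ω) per gene, so a self-contained
counting estimator keeps the pipeline free of external binaries; exact
numerical agreement with ML estimators (codeml/GY94) is not a goal and
is not claimed. Differences to expect: NG86 weights all mutational
pathways equally (no transition/transversion bias) and JC ignores
codon-frequency structure, which biases dS slightly relative to ML on
real data while preserving ranks and class contrasts at the divergence
scales handled here (dS ≲ 0.4).

Conventions:

- Expected site counts exclude changes to stop codons from the
  per-position denominator; per codon, s + n = 3 exactly.
- Pathway averaging enumerates all orderings of the differing
  positions and discards any ordering passing through a stop. Codon
  pairs whose orderings are all stop-blocked are skipped and tallied
  (`pathway_blocked`) rather than attributed arbitrarily.
- Codon columns with a gap, an ambiguous base or a stop in either
  sequence are skipped and tallied.
- p ≥ 3/4 raises a saturation error; in batch mode the pair becomes a
  flagged NA row instead of aborting the run.
- ω is reported missing when dS = 0 (never infinite) and excluded from
  downstream statistics.
- Alignment is an input: pairs must be codon-aligned (gap runs in
  multiples of 3) or equal-length ungapped CDSs compared codon by
  codon. No alignment is performed in-repo.

## CDS quality control

Exactly three rules, applied independently to the literal sequence:
starts with ATG; ends with TAG/TAA/TGA; length divisible by three.
Every violated rule is reported. Internal stop codons are deliberately
*not* a failure — downstream per-codon computations simply skip
non-sense codons. Per gene, the longest-CDS isoform is analyzed; ties
break on the lexicographically smallest isoform id.

## Gene-architecture features

GFF3 coordinates are 1-based inclusive; intron length is the inclusive
inter-exon gap, next_exon_start − previous_exon_end − 1. UTR length is the sum of all UTR segments on that side;
genes without annotated UTRs get length 0 and are excluded from UTR-GC
statistics (GC of an empty string is undefined/missing). GC counts
exclude N from numerator and denominator.

GC3 is the plain third-position GC over all sense codons of the CDS
(terminal stop excluded) — not the synonymous-only GC3s variant; the
output header says `gc3` and this definition is fixed here.

## ENc

Wright's (1990) statistic with the 6-fold families (Leu, Ser, Arg)
treated as their own degeneracy class: ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
3/F̄₆, clamped to [20, 61]. Families observed with fewer than two
codons are excluded (F is undefined at n = 1). When no 3-fold (Ile)
family is observed, F̄₃ = (F̄₂ + F̄₄)/2 per Wright's recommendation; if
the 2-, 4- or 6-fold class is entirely unobserved, or a class mean
homozygosity is non-positive, ENc is reported missing with a warning —
no substitution rule exists for those cases and inventing one would be
arbitrary.

## Tissue specificity

τ uses the log-ratio form with expression floored at 1 before logs
(the form is undefined below 1; microarray-scale intensities never hit
the floor). τ is invariant to the logarithm base but — unlike the
linear-scale τ variant — **not** invariant to uniform rescaling of the
profile, since rescaling shifts both logs additively. Callers supplying
expression on other scales should normalise first. All supplied columns
are treated as "tissues and conditions"; no sample aggregation or
curation is performed.

## Statistics

- Mann–Whitney U: two-sided throughout; exact enumeration when the
  pooled sample is ≤ 12 with no ties, otherwise the tie-corrected
  normal approximation with continuity correction. A pooled sample with
  zero variance returns p = 1 with a flag.
- Spearman ρ: Pearson on midranks, t-approximation p with n − 2 df,
  pairwise deletion of missing pairs.
- Two-proportion z: pooled variance, two-sided; negative z when the
  first group's proportion is smaller.
- PCA: complete-case rows, correlation matrix, unrotated
  eigendecomposition (the SPSS-style default extraction). Loadings are
  eigenvector · √eigenvalue, i.e. variable–component correlations;
  each component's sign is fixed so its largest-magnitude loading is
  positive; the retained set per component is the variables with
  |loading| > 0.5 (configurable). Constant variables are an error
  (named); fewer complete cases than variables is a warning.
- No multiple-testing correction is applied anywhere; tables report
  raw p-values.
- "Up to ten introns" includes 10: the strata are {0}, {1–10}, {>10}.
- Domain-class proportions (single/double/multi = 1/2/≥3) are computed
  over genes with at least one annotated domain; zero-domain genes are
  excluded and counted.

## Synthetic-study generator

The generator emulates the statistical structure of the two-class
comparison; its defaults are the observed class conditions of the
Arabidopsis primary/secondary contrast (n = 1,035 vs 241 analyzed
genes, 20 tissues):

| quantity | primary | secondary |
|---|---|---|
| dN mean (SD) | 0.020 (0.016) | 0.026 (0.016) |
| dS mean (SD) | 0.147 (0.044) | 0.157 (0.043) |
| 5′/3′-UTR mean length (bp) | 128.6 / 231.1 | 96.5 / 192.9 |
| mean intron number | 6.17 | 4.30 |
| 5′/3′-UTR GC | 0.343 / 0.296 | 0.310 / 0.274 |
| GC3 mean | 0.412 | 0.423 |
| expression mean | 9,025.8 | 4,430.3 |
| τ mean | 0.236 | 0.287 |
| domain / GO-slim / PO Poisson λ | 1.53 / 12.95 / 28.25 | 1.26 / 10.91 / 22.48 |

Design choices where the conditions left the design open:

- **CDS length** ~ log-normal, mean 470 codons, both classes — chosen
  so realized gene length (UTRs + CDS + introns) reproduces the class
  means (≈2,763 vs ≈2,440 bp) given the UTR and intron distributions,
  consistent with coding length itself not differing between classes.
- **Intron number** ~ zero-inflated Poisson (intronless probability
  0.15/0.22; remainder 1 + Poisson, λ solved to preserve the class
  means). A plain Poisson at these means would generate essentially no
  intronless genes, leaving the intronless stratum and the
  GC3-by-intron-presence comparison empty.
- **Intron length** ~ log-normal, mean 160 bp, both classes (typical
  for *A. thaliana*; the class means do not differ).
- **GC3** ~ normal per class, with a +0.10 shift for intronless genes
  (reproducing the higher GC3 of intronless genes and the negative
  GC3–intron-number correlation).
- **Codon usage bias**: within each synonymous family one preferred
  codon is up-weighted by exp(b); b = 0.72 (primary) and 0.62
  (secondary) were calibrated once against the ENc class means
  (53.18 / 54.47) at the default CDS length and then frozen. The
  third-position GC factor is solved numerically per sequence so the
  expected GC3 equals the target despite the bias term and the
  Met/Trp-forced G.
- **Divergence simulation**: per-codon Bernoulli substitutions, split
  evenly between the two descendants, no indels. The event
  probabilities are calibrated in the estimator's own currency: the
  JC-inverted target proportion gives the expected difference count,
  and a closed-form collision correction (both lineages hitting the
  same codon cancels or merges differences) makes the expected
  *observed* count match. Mean estimated dS and dN land within ~2% of
  target at 500 codons.
- **Expression profiles**: one maximal tissue at S_max and the rest at
  S_max^(1−τ*), which makes the specificity index equal the target
  exactly; S_max is solved (Brent) so the profile mean matches the
  level target; mild log-normal noise (σ = 0.1) is added to non-maximal
  tissues. Because the log-ratio τ is not scale invariant, the solve
  replaces the more obvious construct-then-rescale approach.
- Strands are drawn at random; each gene sits on its own contig with
  50 bp flanks; introns carry GT…AG ends.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: cross-feature correlation structure
(features are drawn independently within class, apart from the
intron–GC3 coupling), so the PCA on synthetic bundles recovers only
weak block structure rather than the strong expression/gene-level
components seen in real data; microarray noise and probe effects;
indels and alignment error; ortholog misidentification; codon-model
effects (transition/transversion bias, codon-frequency bias); and any
real exclusion cascade (the default bundle passes QC completely — the
counts 1,035/241 are imposed, not produced by filtering).

## Problem sizes

Default test and acceptance runs use the full default bundle
(1,276 genes, ~470 codons each): one simulate+analyze cycle takes a
few seconds, and the direction-recovery check repeats it across 20
seeds. The calibration checks use 200 pairs of 500 codons; the
Mann–Whitney calibration and power checks use 1,000 and 500 replicates
at the observed sample sizes.

## Known limitations

- NG86+JC, not ML: absolute rates on real data will differ from codeml
  output; class contrasts and correlations are the supported use.
- The exact-Mann–Whitney threshold (pooled n ≤ 12, tie-free) is a
  desk-scale convenience; large-sample inference always uses the
  corrected normal approximation.
- τ depends on the floor convention for values below 1; data on
  log or ratio scales need rescaling before use.
- The GFF3 reader handles flat gene/mRNA/exon/UTR/CDS files with
  `ID`/`Parent` attributes; it is not a general GFF3 validator.
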