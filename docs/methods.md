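# Methods

This note documents the statistical machinery implemented in `codonbias`,
the conventions chosen where the literature leaves room, and what the
synthetic-data generators do and do not emulate.

## Input model and filtering

The unit of analysis is a set of coding sequences (CDS) from one genome —
typically the 40–80 annotated CDS of a chloroplast genome. Sequences enter
the statistics only if they (1) have length divisible by 3, (2) are at least
300 nt long, (3) contain only A/C/G/T, (4) start with ATG and end with
TAA/TAG/TGA, and (5) contain no in-frame internal stop. Rules are evaluated
in that fixed order and a rejected record reports the first rule it failed,
so filter reports are deterministic. Sequences with IUPAC ambiguity codes
fail rule 3 rather than raising; multi-copy genes (e.g. inverted-repeat
duplicates) are kept as distinct records. GenBank CDS features with joined
intervals are concatenated in feature order and minus-strand features
reverse-complemented, so FASTA and GenBank inputs of the same gene set give
identical results. The standard genetic code is used throughout; at the
codon-assignment level it is identical to the bacterial/plastid table, so
plastome CDS are handled correctly.

## Composition and usage statistics

* **GC1/GC2/GC3** are the percent G+C at each codon position over all codons
  of a gene or pooled species set; GC12 is the mean of GC1 and GC2. **GC3s**
  restricts GC3 to the 59 degenerate sense codons (excluding ATG, TGG and
  stops) and is NaN when no degenerate codon is observed.
* **RSCU** and **RFSC**: for amino acid *i* with *n_i* synonymous codons and
  counts X_ij, RFSC_ij = X_ij / Σ_j X_ij and RSCU_ij = RFSC_ij · n_i. Leu,
  Ser and Arg are single six-codon families; the three stop codons form one
  three-codon family that participates in RSCU/RFSC and the optimal-codon
  screen (but never in GC3s, L_aa, ENC or CAI). Families with zero total are
  flagged unobserved and excluded from classification. Species-level RSCU is
  computed on pooled (concatenated) counts, the standard practice when the
  alternative (averaging per-gene RSCU) is not stated.
* **High-frequency (HF) codons**: a codon is HF when its family share
  exceeds 0.6, or exceeds the family-average share by more than half of it
  (RFSC > 1.5/n_i). The published rule this implements is sometimes printed
  as "more than 0.5 times the average frequency", which read literally
  (RFSC > 0.5/n_i) would make nearly every codon HF; the excess reading is
  the only one consistent with HF sets of realistic size. Both the 0.6
  cutoff and the 0.5 excess multiplier are exposed as parameters.
* **L_aa** counts encoded amino acids: all codons minus stop codons.

## ENC

Per-gene codon-usage evenness is summarized by Wright's effective number of
codons. For each family observed n ≥ 2 times with within-family frequencies
p_j, the homozygosity estimate is F̂ = (n Σ p_j² − 1)/(n − 1). F̂ values are
averaged within degeneracy classes (9 twofold families, Ile as the single
threefold, 5 fourfold, 3 sixfold) and combined as

    ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆.

Non-positive F̂ (a small-sample artifact) are dropped from their class
average. A missing threefold class is imputed as the harmonic mean of F̄₂
and F̄₄; if a 2-, 4- or 6-fold class has no usable family the gene's ENC is
NaN. The estimate is clipped to [20, 61]: under exactly uniform usage the
bias-corrected F̂ slightly undershoots 1/k, so the raw combination
overshoots 61 and the clip makes the uniform limit exact. The expected
value under composition alone, plotted against GC3s as fraction s, is

    ENC_exp(s) = 2 + s + 29 / (s² + (1 − s)²),

so ENC_exp(0.5) = 60.5 and ENC_exp(0) = 31. This curve is the common
two-codon-family approximation; genes generated with uniform within-family
preferences sit within about one ENC unit of it (verified in the tests with
a 2-unit band), while selection-like sharp preferences fall far below.

## CAI

Relative adaptiveness weights come from a reference set of putatively
highly expressed genes: within each degenerate sense family w_j = X_j /
max_j' X_j', with zero counts smoothed to 0.5 before division, and Met, Trp
and stops excluded. A gene's CAI is the geometric mean of w over its
codons, computed via counts (order-invariant). Because no chloroplast
expression atlas is bundled, the default reference is the pooled counts of
the ENC-defined high-expression set below — the standard proxy when the
reference is unstated — and it is configurable.

## Bias-source diagnostics

* **PR2 plot**: per gene, y = A3/(A3+T3) and x = G3/(G3+C3) over third
  positions of the 59 degenerate sense codons. (0.5, 0.5) is the parity
  point expected when only mutation pressure, acting symmetrically on the
  two strands, shapes composition; coordinates are NaN when a denominator
  is zero.
* **Neutrality plot**: ordinary least squares of per-gene GC12 on GC3
  (percent scale; the slope is scale-invariant), with Pearson r and
  two-sided p. 100·slope is reported as the mutation-pressure share of the
  usage pattern and 100·(1 − slope) as the selection share.
* **Expression datasets**: genes ranked by ENC ascending (ties broken by
  gene id); the lowest-ENC ⌈f·N⌉ genes form the high-expression set and the
  highest-ENC ⌈f·N⌉ the low set. The extreme fraction f defaults to 10%,
  the common convention when a split is not stated; with ~50 genes per
  plastome this yields 5-gene sets, and downstream optimal-codon counts are
  sensitive to f by design.
* **Optimal codons**: ΔRSCU = RSCU(high) − RSCU(low) on the pooled counts
  of each set; a codon is optimal when RSCU(high) > 1 and ΔRSCU > 0.08.
  The stop family participates in the screen.

## Correspondence analysis

Each gene is a 59-dimensional per-gene RSCU vector (degenerate sense codons
only). Classical CA treats the genes × codons matrix N as a two-way table:
P = N/total, row/column masses r and c, standardized residuals
S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD S = UΣVᵀ. Principal inertias are
σ_k² (their sum equals Pearson's χ²/total — asserted against
`scipy.stats.chi2_contingency` in the tests), inertia fractions are
reported per axis, and row principal coordinates are D_r^{−1/2}UΣ. Axis
orientation is fixed by making the first nonzero codon loading of each
axis positive, so repeated runs are byte-identical. CA runs on RSCU values
rather than raw counts (the convention matching RSCU-based usage studies);
genes observing fewer than 3 families are dropped with a warning because
near-empty rows distort the chi-square geometry, and all-zero columns are
excluded from the decomposition. Axis–index correlations (GC3s, CAI, ENC,
L_aa, overall GC against axes 1–2) use Pearson r with two-sided p and
significance marks at 0.05/0.01; constant inputs are flagged rather than
propagating NaN.

An independent brute-force oracle (eigendecomposition of SSᵀ) reproduces
inertias and row coordinates to 1e−8 in the tests, so the SVD path is
cross-checked rather than self-certified.

## Model-organism frequency comparison

Codon usage tables are read and written in the Kazusa text format
("CODON freq (count)" entries, RNA or DNA alphabet, all 64 codons
required). Host tables are derived from pooled counts as per-thousand
frequencies. The host/model ratio is banded per codon: ≥ 2 or ≤ 0.5 marks
divergent usage (a poor heterologous-expression pairing), the open
interval (0.5, 2) similar usage; codons with zero model frequency are
reported as undefined, and the three band counts always total 64. Ratios
are taken on the per-thousand values as given, which makes the exact-ratio
boundary semantics unambiguous. No network retrieval is built in: tables
are consumed as local files, and the bundled analysis driver falls back to
clearly labelled synthetic stand-in tables when none are present.

## Synthetic data

`generate_cds_set` emulates a small AT-rich plastome gene complement:
48 genes by default, lengths uniform over 300–2400 nt (multiples of 3,
matching typical chloroplast CDS lengths), ATG start, sampled stop, no
internal stops — every generated gene passes the five filters by
construction. Within-family codon preferences are drawn per gene from a
symmetric Dirichlet whose concentration is the selection knob (None means
exactly uniform preferences, the mutation-only limit; small values give
sharp bias). A third-position tilt is then calibrated by bisection so the
gene's expected GC3 equals the target (0.275 by default, the AT-rich
plastome regime); calibration is needed because naively multiplying random
preferences by a GC factor inflates realized GC3 toward 0.5. Amino acids
are sampled uniformly, which bounds expected GC3 to [0.10, 1.0] (ATG and
TGG always end in G).

`generate_neutrality_set` plants a linear GC12–GC3 relationship: per gene a
GC3 target is uniform on [0.10, 0.70], the GC12 target is a + b·GC3 + ε
with Gaussian ε, and codons are sampled i.i.d. from position-specific base
distributions restricted to sense codons, with the third-position
distribution renormalized conditional on the first two bases so stop
exclusion cannot distort the GC12 marginal. Genes are 600 codons long by
default: realized compositions then scatter around their targets by
multinomial noise small enough that the errors-in-variables attenuation of
the fitted slope stays well inside its standard error at n = 200 (the
regression is on realized, not target, compositions — exactly what the
estimator sees on real data).

`uniform_usage_gene` is the analytic ENC fixture: every sense codon exactly
k times in seeded-shuffled order, giving exactly uniform within-family
usage, RSCU = 1 everywhere, a hand-enumerable GC3s, and ENC = 61 exactly.

What the generators do **not** emulate: real plastome gene-length and
amino-acid composition distributions, strand- and gene-specific mutation
asymmetries, correlated preferences among genes (operons, IR duplicates),
and phylogenetic correlation between sets. Passing tests therefore
demonstrate the estimators' correctness and calibration under controlled
codon-usage structure, not agreement with any particular real genome.

## Numerical conventions

Percentages and RSCU are reported to 2 decimals and slopes to 4 in TSV
reports; full precision is kept internally and in the JSON sidecar. ENC is
clipped to [20, 61]. Degenerate cases (empty tables, zero denominators,
constant regressors, genes with no usable ENC family) are flagged or raise
with named causes rather than returning silent zeros; pipeline stage
failures are reported with the stage name and later stages are skipped.

## Problem sizes

The bundled analysis runs nine synthetic sets of 44–52 genes (mirroring
small plastome CDS complements) and the tests use up to 200 genes for
regression-recovery checks and 1000 random count tables for the RSCU
invariants — sizes at which every stage completes in seconds while keeping
the statistical checks well-powered.
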