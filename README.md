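# codonbias

Codon usage bias analysis for chloroplast (and other small) CDS sets, built
around a comparative study of nine forage-legume plastomes: white clover
(*Trifolium repens*), yellow sweet clover, goat's rue and relatives, pea,
stylo and alfalfa. Synonymous codons are not used evenly; the pattern and
strength of that bias carry information about mutation pressure, natural
selection and expression level, and determine how well a foreign host will
translate a gene. This package implements the full analysis path from raw
coding sequences to bias diagnostics, as a reusable library
(`src/codonbias/`) with numbered analysis drivers (`analysis/`).

## What it computes

For each gene (and pooled per species), with X_ij the count of codon *j*
of amino acid *i* and n_i the family size:

* **Filtering** — five CDS quality rules (length ≥ 300 nt, multiple of 3,
  pure A/C/G/T, ATG…stop, no internal stop), with per-record reporting of
  the first failed rule.
* **Composition** — GC1/GC2/GC3 by codon position, GC12, and GC3s over the
  59 degenerate sense codons; L_aa.
* **RSCU / RFSC** — RSCU_ij = n_i · X_ij / Σ_j X_ij and
  RFSC_ij = X_ij / Σ_j X_ij, with high-frequency codons called at
  RFSC > 0.6 or RFSC > 1.5/n_i.
* **ENC** — Wright's effective number of codons,
  ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with
  F̂ = (nΣp² − 1)/(n − 1) per family, clipped to [20, 61], plus the
  composition-only expectation ENC_exp(s) = 2 + s + 29/(s² + (1 − s)²).
* **CAI** — geometric mean of relative adaptiveness weights w_j = X_j/max X
  from a reference gene set (default: the low-ENC decile).
* **PR2 plot** — A3/(A3+T3) vs G3/(G3+C3) third-position parity.
* **Neutrality plot** — OLS of GC12 on GC3 across genes; slope read as the
  mutation-pressure share of the usage pattern.
* **Optimal codons** — ENC-extreme high/low expression sets; codons with
  RSCU(high) > 1 and ΔRSCU > 0.08.
* **Correspondence analysis** — classical CA of the genes × 59 RSCU matrix
  (χ²-standardized residuals, SVD), axis inertia fractions and axis–index
  correlations (GC3s, CAI, ENC, L_aa, GC).
* **Model-organism comparison** — per-thousand codon frequencies (Kazusa
  table format) banded by host/model ratio: divergent at ≥ 2 or ≤ 0.5,
  similar in between.

See `docs/methods.md` for conventions, estimator details and limitations.

## Worked example

```python
from codonbias import SynthesisParams, generate_cds_set, run_species

records = generate_cds_set(SynthesisParams(n_genes=48, concentration=0.8,
                                           gc3=0.27, seed=7))
bundle = run_species(records, "demo")

row = bundle["composition"].iloc[0]
print(f"kept {bundle['n_kept']}/{bundle['n_input']} CDS, "
      f"L_aa={row.l_aa}, GC1/GC2/GC3 = {row.gc1}/{row.gc2}/{row.gc3}")
neut = bundle["neutrality"].iloc[0]
print(f"neutrality slope = {neut.slope}")
enc_tab = bundle["enc_plot"]
print(f"mean ENC = {enc_tab.enc.mean():.2f}, "
      f"mean expected ENC = {enc_tab.expected_enc.mean():.2f}")
opt = bundle["optimal_codons"].optimal
print(f"{len(opt)} optimal codons, top five: {', '.join(opt[:5])}")
```

prints

```
kept 48/48 CDS, L_aa=23201, GC1/GC2/GC3 = 46.63/39.48/27.39
neutrality slope = -0.2173
mean ENC = 33.01, mean expected ENC = 44.28
17 optimal codons, top five: GCA, CGT, GGT, AGT, AGA
```

Reading the output: the synthetic genome is AT-rich at third positions
(GC3 ≈ 27%), its genes sit ~11 ENC units below the composition-only
expectation (sharp within-family preferences, i.e. selection-like bias),
and the near-zero neutrality slope says third-position composition does not
drag the first two positions along — both diagnostics point away from pure
mutation pressure, as designed for this set. The optimal codons are those
overused by the most biased (putatively highly expressed) genes relative to
the least biased ones.

The numbered drivers run the same machinery over a nine-set synthetic
study (generate, composition/RSCU, bias sources, CA, model comparison) and
write their tables under `results/`:

```sh
cd analysis
python 01_simulate.py && python 02_composition_rscu.py
python 03_bias_sources.py && python 04_correspondence.py
python 05_model_comparison.py
```

## Analyzing the real genomes

`scripts/reproduce_study.py --fetch` downloads the nine RefSeq chloroplast
genomes (accessions in `codonbias.study`) into `data/genomes/` and reruns
the full per-species and cross-species analysis on them, printing the
composition table, RSCU extremes, shared HF codons, neutrality slopes, CA
inertia and optimal-codon totals. The library itself never touches the
network; the published-value tests in `tests/test_acceptance.py` operate on
those local flat files and fail with a pointer to the fetch script when the
files are absent.

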