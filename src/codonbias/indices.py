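"""Gene-level expression-related indices: ENC and CAI.

ENC follows Wright's estimator. For each synonymous family observed n >= 2
times with within-family codon frequencies p_j, the family homozygosity is

    F_hat = (n * sum_j p_j^2 - 1) / (n - 1)

F_hat values are averaged within degeneracy classes k in {2, 3, 4, 6}
(Ile is the only threefold family; Leu/Ser/Arg are sixfold) and combined as

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

The constant 2 accounts for Met and Trp. Non-positive F_hat values (a
small-sample artifact) are dropped from their class average; a missing
threefold class is imputed as the harmonic mean of the two- and fourfold
averages (CodonW's convention); a missing 2-, 4- or 6-fold class leaves ENC
undefined (NaN). The estimate is clipped to the meaningful range [20, 61]:
exactly uniform usage overshoots 61 through the finite-n bias correction
and is reported as 61.

CAI is the Sharp & Li geometric mean of relative adaptiveness weights
w_j = X_j / max_family X over a reference (putatively highly expressed)
gene set, computed over a gene's sense codons excluding Met, Trp and stops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genetics import CLASS_SIZES, DEGENERACY_CLASSES, FAMILIES, FAMILY_SIZE
from .metrics import CodonCountTable, GcComposition

ENC_MIN = 20.0
ENC_MAX = 61.0


def family_homozygosity(counts: dict[str, int]) -> float:
    """Wright's bias-corrected homozygosity F_hat for one family's counts.

    NaN when fewer than two codons were observed.
    """
    n = sum(counts.values())
    if n < 2:
        return math.nan
    s = sum((x / n) ** 2 for x in counts.values())
    return (n * s - 1.0) / (n - 1.0)


def enc(table: CodonCountTable) -> float:
    """Wright's effective number of codons for one gene, clipped to [20, 61].

    NaN when a required degeneracy class (2-, 4- or 6-fold) has no usable
    family.
    """
    class_mean: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = []
        for aa in aas:
            f = family_homozygosity({c: table.counts[c] for c in FAMILIES[aa]})
            if not math.isnan(f) and f > 0:
                fs.append(f)
        if fs:
            class_mean[k] = sum(fs) / len(fs)

    if 3 not in class_mean and 2 in class_mean and 4 in class_mean:
        # harmonic interpolation for the single threefold family (Ile)
        class_mean[3] = 2.0 / (1.0 / class_mean[2] + 1.0 / class_mean[4])
    if any(k not in class_mean for k in CLASS_SIZES):
        return math.nan
    value = 2.0 + sum(CLASS_SIZES[k] / class_mean[k] for k in CLASS_SIZES)
    return min(max(value, ENC_MIN), ENC_MAX)


def enc_expected(gc3s: float) -> float:
    """Expected ENC under composition (mutation) alone at third-position GC s.

    ENC_exp(s) = 2 + s + 29 / (s^2 + (1 - s)^2), s as a fraction in [0, 1].
    """
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s fraction must lie in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


def cai_weights(reference: CodonCountTable) -> dict[str, float]:
    """Relative adaptiveness w of each codon from a reference count table.

    Within each sense family (Met, Trp and stops excluded) the most used
    codon gets w = 1 and the rest their count ratio to it; zero counts are
    smoothed to 0.5 before division. A family absent from the reference gets
    w = 1 for all members (uninformative).
    """
    if reference.n_codons == 0:
        raise ValueError("empty reference set")
    weights: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        if aa == "*" or FAMILY_SIZE[aa] == 1:
            continue
        smoothed = {c: (reference.counts[c] if reference.counts[c] > 0 else 0.5)
                    for c in codons}
        top = max(smoothed.values())
        observed = any(reference.counts[c] > 0 for c in codons)
        for c in codons:
            weights[c] = smoothed[c] / top if observed else 1.0
    return weights


def cai(table: CodonCountTable, weights: dict[str, float]) -> float:
    """Codon adaptation index: geometric mean of w over the gene's codons.

    Only codons with a weight (degenerate sense codons) contribute.
    """
    log_sum = 0.0
    n = 0
    for codon, w in weights.items():
        cnt = table.counts[codon]
        if cnt:
            log_sum += cnt * math.log(w)
            n += cnt
    if n == 0:
        raise ValueError("gene has no codons eligible for CAI")
    return math.exp(log_sum / n)


@dataclass(frozen=True)
class GeneIndexRecord:
    """Per-gene scalar indices feeding the diagnostic plots."""

    gene_id: str
    gc: GcComposition
    enc: float
    cai: float
    l_aa: int
    pr2_x: float
    pr2_y: float
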