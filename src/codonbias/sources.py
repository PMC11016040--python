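"""Diagnostics for the source of codon bias, and optimal-codon screening.

* PR2 plot: per gene, y = A3/(A3+T3) against x = G3/(G3+C3) over third
  positions of degenerate sense codons; (0.5, 0.5) is the parity point where
  A = T and G = C, expected under mutation pressure alone.
* Neutrality plot: ordinary least squares of GC12 on GC3 across genes; a
  slope near 1 indicates mutation-driven composition, near 0 selection.
  100*slope is read as the mutation-pressure share, 100*(1-slope) as the
  selection share.
* Optimal codons: pooled RSCU of an ENC-defined high-expression gene set
  versus a low set; codons with RSCU_high > 1 and delta RSCU > 0.08 are
  called optimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .genetics import DEGENERATE_CODONS
from .indices import GeneIndexRecord
from .metrics import CodonCountTable, rscu_rfsc


@dataclass(frozen=True)
class Pr2Point:
    gene_id: str
    x: float  # G3/(G3+C3); NaN when G3+C3 == 0
    y: float  # A3/(A3+T3); NaN when A3+T3 == 0


def pr2_point(table: CodonCountTable, gene_id: str = "") -> Pr2Point:
    """Third-position parity coordinates over degenerate sense codons."""
    tallies = {b: 0 for b in "ACGT"}
    for codon in DEGENERATE_CODONS:
        tallies[codon[2]] += table.counts[codon]
    at = tallies["A"] + tallies["T"]
    gc = tallies["G"] + tallies["C"]
    y = tallies["A"] / at if at else math.nan
    x = tallies["G"] / gc if gc else math.nan
    return Pr2Point(gene_id=gene_id, x=x, y=y)


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n_genes: int
    stderr: float = float("nan")  # standard error of the slope

    @property
    def mutation_pct(self) -> float:
        return 100.0 * self.slope

    @property
    def selection_pct(self) -> float:
        return 100.0 - self.mutation_pct


def neutrality_fit(genes: list[GeneIndexRecord]) -> NeutralityFit:
    """OLS regression of per-gene GC12 on GC3 (percent scale)."""
    pts = [(g.gc.gc3, g.gc.gc12) for g in genes
           if not (math.isnan(g.gc.gc3) or math.isnan(g.gc.gc12))]
    if len(pts) < 3:
        raise ValueError("need at least 3 genes with defined GC12/GC3")
    x, y = zip(*pts)
    if len(set(x)) == 1:
        raise ValueError("GC3 is constant across genes; slope undefined")
    res = stats.linregress(x, y)
    return NeutralityFit(
        slope=res.slope,
        intercept=res.intercept,
        r=res.rvalue,
        p_value=res.pvalue,
        n_genes=len(pts),
        stderr=res.stderr,
    )


def select_expression_datasets(
    genes: list[GeneIndexRecord], fraction: float = 0.1
) -> tuple[set[str], set[str]]:
    """ENC-extreme gene sets: (putative high expression, low expression).

    Genes are ranked by ENC ascending with lexicographic gene-id tie-breaks;
    the lowest-ENC ceil(fraction*N) genes form the high-expression set (low
    ENC = strong bias), the highest-ENC ones the low-expression set.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    usable = sorted(
        (g for g in genes if not math.isnan(g.enc)),
        key=lambda g: (g.enc, g.gene_id),
    )
    m = math.ceil(fraction * len(usable))
    if 2 * m > len(usable):
        raise ValueError(
            f"{len(usable)} genes cannot provide two disjoint sets of {m}"
        )
    high = {g.gene_id for g in usable[:m]}
    low = {g.gene_id for g in usable[-m:]}
    return high, low


@dataclass
class OptimalCodonResult:
    high_ids: list[str]
    low_ids: list[str]
    delta_rscu: dict[str, float]
    rscu_high: dict[str, float]
    rscu_low: dict[str, float]
    optimal: list[str] = field(default_factory=list)


def optimal_codons(
    high: CodonCountTable,
    low: CodonCountTable,
    threshold: float = 0.08,
    high_ids: list[str] | None = None,
    low_ids: list[str] | None = None,
) -> OptimalCodonResult:
    """Codons with RSCU > 1 in the high set and delta RSCU > threshold.

    Delta RSCU is high minus low; the stop family participates in the
    screen like any other synonymous family.
    """
    rscu_h = rscu_rfsc(high).rscu
    rscu_l = rscu_rfsc(low).rscu
    delta = {c: rscu_h[c] - rscu_l[c] for c in rscu_h}
    optimal = sorted(
        (c for c in delta if rscu_h[c] > 1.0 and delta[c] > threshold),
        key=lambda c: (-delta[c], c),
    )
    return OptimalCodonResult(
        high_ids=sorted(high_ids or []),
        low_ids=sorted(low_ids or []),
        delta_rscu=delta,
        rscu_high=rscu_h,
        rscu_low=rscu_l,
        optimal=optimal,
    )
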