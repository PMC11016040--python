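"""Codon counting and composition statistics.

Implements the core bias descriptors: in-frame codon counts, positional GC
content (GC1/GC2/GC3, their mean, GC12, and GC3s over degenerate codons),
relative synonymous codon usage (RSCU), the relative frequency of synonymous
codons (RFSC), and the high-frequency (HF) codon rule.

For amino acid i with n_i synonymous codons and codon counts X_ij,

    RFSC_ij = X_ij / sum_j X_ij          (family share, sums to 1)
    RSCU_ij = RFSC_ij * n_i              (1 = unbiased within the family)

A codon is HF when its family share clearly exceeds the uniform expectation:
RFSC > 0.6, or RFSC > (1 + excess) / n_i with the default excess of 0.5
(i.e. more than 1.5x the family-average frequency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .genetics import (
    CODONS,
    DEGENERATE_CODONS,
    FAMILIES,
    FAMILY_SIZE,
    STOP_CODONS,
)
from .io import CdsRecord

_GC = frozenset("GC")


@dataclass
class CodonCountTable:
    """Integer counts for all 64 codons, for one gene or a pooled species set."""

    counts: dict[str, int]
    scope: str = "gene"

    def __post_init__(self) -> None:
        full = {c: 0 for c in CODONS}
        full.update(self.counts)
        unknown = set(full) - set(CODONS)
        if unknown:
            raise ValueError(f"unknown codons: {sorted(unknown)}")
        if any(v < 0 for v in full.values()):
            raise ValueError("negative codon count")
        self.counts = full

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in CODONS}
        return CodonCountTable(merged, scope="species")

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, dtype=int).reindex(list(CODONS))


def count_codons(
    records: CdsRecord | Iterable[CdsRecord],
) -> CodonCountTable:
    """Tally in-frame, non-overlapping codons; a list yields the pooled table."""
    if isinstance(records, CdsRecord):
        seqs = [records.sequence]
        scope = "gene"
    else:
        seqs = [r.sequence for r in records]
        scope = "species"
    counts = {c: 0 for c in CODONS}
    for seq in seqs:
        if len(seq) % 3:
            raise ValueError(f"sequence length {len(seq)} not divisible by 3")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
            else:
                raise ValueError(f"non-ACGT codon {codon!r} at position {i}")
    return CodonCountTable(counts, scope=scope)


@dataclass(frozen=True)
class GcComposition:
    """GC fractions (percent) by codon position."""

    gc1: float
    gc2: float
    gc3: float
    gc_mean: float
    gc12: float
    gc3s: float  # NaN when every codon is excluded from the GC3s set


def gc_by_position(table: CodonCountTable) -> GcComposition:
    """Positional GC percentages from a codon count table.

    GC3s is the third-position GC restricted to the 59 degenerate codons
    (Met, Trp and stops excluded); it is NaN when no degenerate codon was
    observed.
    """
    n = table.n_codons
    if n == 0:
        raise ValueError("empty codon count table")
    gc_pos = [0, 0, 0]
    for codon, cnt in table.counts.items():
        for k in range(3):
            if codon[k] in _GC:
                gc_pos[k] += cnt
    gc1, gc2, gc3 = (100.0 * g / n for g in gc_pos)

    n_syn = sum(table.counts[c] for c in DEGENERATE_CODONS)
    if n_syn == 0:
        gc3s = math.nan
    else:
        gc_syn = sum(table.counts[c] for c in DEGENERATE_CODONS if c[2] in _GC)
        gc3s = 100.0 * gc_syn / n_syn
    return GcComposition(
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc_mean=(gc1 + gc2 + gc3) / 3.0,
        gc12=(gc1 + gc2) / 2.0,
        gc3s=gc3s,
    )


@dataclass
class RscuTable:
    """Per-codon RSCU and RFSC with the synonymous-family structure attached."""

    rscu: dict[str, float]
    rfsc: dict[str, float]
    families: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: FAMILIES)
    n_i: Mapping[str, int] = field(default_factory=lambda: FAMILY_SIZE)
    unobserved_families: frozenset[str] = frozenset()


def rscu_rfsc(table: CodonCountTable) -> RscuTable:
    """RSCU and RFSC for every codon; zero-count families flagged unobserved.

    The three stop codons form one family of size 3; Met and Trp are
    single-codon families whose RSCU is 1 whenever observed.
    """
    if table.n_codons == 0:
        raise ValueError("empty codon count table")
    rscu: dict[str, float] = {}
    rfsc: dict[str, float] = {}
    unobserved = set()
    for aa, codons in FAMILIES.items():
        total = sum(table.counts[c] for c in codons)
        if total == 0:
            unobserved.add(aa)
            for c in codons:
                rscu[c] = rfsc[c] = 0.0
            continue
        n_i = FAMILY_SIZE[aa]
        for c in codons:
            share = table.counts[c] / total
            rfsc[c] = share
            rscu[c] = share * n_i
    return RscuTable(rscu=rscu, rfsc=rfsc, unobserved_families=frozenset(unobserved))


def classify_hf_codons(
    table: RscuTable, rfsc_cutoff: float = 0.6, excess: float = 0.5
) -> set[str]:
    """High-frequency codons: family share > cutoff, or > (1+excess)/n_i.

    Codons of unobserved families are never HF.
    """
    hf = set()
    for aa, codons in table.families.items():
        if aa in table.unobserved_families:
            continue
        threshold = (1.0 + excess) / table.n_i[aa]
        for c in codons:
            if table.rfsc[c] > rfsc_cutoff or table.rfsc[c] > threshold:
                hf.add(c)
    return hf


def amino_acid_count(table: CodonCountTable) -> int:
    """Total amino acids encoded (L_aa): all codons minus stop codons."""
    return table.n_codons - sum(table.counts[c] for c in STOP_CODONS)


def composition_row(species: str, table: CodonCountTable) -> dict:
    """One species row of the composition summary (Table-1 shape)."""
    gc = gc_by_position(table)
    return {
        "species": species,
        "n_codons": table.n_codons,
        "l_aa": amino_acid_count(table),
        "gc1": round(gc.gc1, 2),
        "gc2": round(gc.gc2, 2),
        "gc3": round(gc.gc3, 2),
        "gc_mean": round(gc.gc_mean, 2),
        "gc12": round(gc.gc12, 2),
        "gc3s": round(gc.gc3s, 2) if not math.isnan(gc.gc3s) else math.nan,
    }


def rscu_long_table(
    species: str, table: RscuTable, hf: set[str] | None = None
) -> pd.DataFrame:
    """Long-form per-codon RSCU/RFSC table (heatmap substrate)."""
    if hf is None:
        hf = classify_hf_codons(table)
    rows = []
    for aa, codons in FAMILIES.items():
        for c in codons:
            rows.append(
                {
                    "species": species,
                    "amino_acid": aa,
                    "codon": c,
                    "rscu": round(table.rscu[c], 4),
                    "rfsc": round(table.rfsc[c], 4),
                    "hf_flag": c in hf,
                }
            )
    return pd.DataFrame(rows)
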