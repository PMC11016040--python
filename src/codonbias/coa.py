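"""Correspondence analysis (CA) of per-gene RSCU vectors.

Each gene is a 59-dimensional RSCU vector (the 61 sense codons minus the
non-degenerate ATG and TGG; stops excluded). Classical CA treats the
genes x codons matrix N as a two-way table: with grand total t, correspondence
matrix P = N/t, row masses r and column masses c, the standardized residuals

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

are decomposed by SVD, S = U Sigma V^T. The squared singular values are the
principal inertias (their total equals the table's Pearson chi-square / t),
and row principal coordinates are D_r^{-1/2} U Sigma. Axis signs follow a
fixed convention (first nonzero column loading positive) so runs are
reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import DEGENERATE_CODONS, FAMILIES
from .indices import GeneIndexRecord
from .metrics import CodonCountTable, rscu_rfsc


@dataclass
class RscuMatrix:
    """Genes x 59 degenerate codons matrix of per-gene RSCU values."""

    genes: list[str]
    codons: list[str]
    values: np.ndarray  # shape (n_genes, 59)


@dataclass
class CoaResult:
    genes: list[str]
    row_coords: np.ndarray  # (n_genes, n_axes), principal coordinates
    inertia: np.ndarray  # all principal inertias, non-increasing
    inertia_fraction: np.ndarray  # same length, sums to 1 (0 if rank 0)
    n_axes: int

    @property
    def total_inertia(self) -> float:
        return float(self.inertia.sum())


def build_rscu_matrix(
    genes: list[tuple[str, CodonCountTable]], min_families: int = 3
) -> RscuMatrix:
    """Per-gene RSCU matrix over the 59 degenerate codons.

    Genes observing fewer than ``min_families`` synonymous families are
    dropped with a warning: their nearly empty RSCU rows distort the
    chi-square geometry.
    """
    ids, rows = [], []
    n_fam_total = sum(1 for aa in FAMILIES if aa != "*")
    for gid, table in genes:
        rt = rscu_rfsc(table)
        observed = n_fam_total - sum(
            1 for aa in rt.unobserved_families if aa != "*"
        )
        if observed < min_families:
            warnings.warn(
                f"gene {gid!r} observes {observed} families; dropped from CA",
                stacklevel=2,
            )
            continue
        ids.append(gid)
        rows.append([rt.rscu[c] for c in DEGENERATE_CODONS])
    return RscuMatrix(
        genes=ids, codons=list(DEGENERATE_CODONS), values=np.asarray(rows, float)
    )


def correspondence_analysis(m: RscuMatrix, n_axes: int = 4) -> CoaResult:
    """Classical CA of the RSCU matrix; see module docstring for conventions."""
    N = np.asarray(m.values, float)
    if N.ndim != 2 or N.shape[0] < 2:
        raise ValueError("need a matrix with at least 2 rows")
    if (N < 0).any():
        raise ValueError("negative table entries")
    total = N.sum()
    if total <= 0:
        raise ValueError("table grand total must be positive")

    # columns never used carry no mass; keep them out of the decomposition
    col_keep = N.sum(axis=0) > 0
    P = N[:, col_keep] / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)

    # fixed orientation: first nonzero codon loading of each axis positive
    for k in range(len(sig)):
        v = Vt[k]
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if nz.size and v[nz[0]] < 0:
            Vt[k] = -v
            U[:, k] = -U[:, k]

    rank = min(P.shape[0] - 1, P.shape[1] - 1)
    sig = sig[:rank] if rank > 0 else sig[:0]
    U = U[:, : len(sig)]
    inertia = sig**2
    tot_in = inertia.sum()
    frac = inertia / tot_in if tot_in > 0 else np.zeros_like(inertia)

    n_axes = min(n_axes, len(sig)) if len(sig) else 0
    if len(sig):
        coords = (U * sig) / np.sqrt(r)[:, None]
        coords = coords[:, :n_axes]
    else:
        coords = np.zeros((N.shape[0], 0))
    return CoaResult(
        genes=list(m.genes),
        row_coords=coords,
        inertia=inertia,
        inertia_fraction=frac,
        n_axes=n_axes,
    )


@dataclass(frozen=True)
class AxisCorrelation:
    index: str
    axis: int
    r: float
    p_value: float

    @property
    def mark(self) -> str:
        if math.isnan(self.r):
            return "na"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def axis_index_correlations(
    coa: CoaResult, indices: list[GeneIndexRecord], axes: tuple[int, ...] = (1, 2)
) -> pd.DataFrame:
    """Pearson correlation of codon-usage indices with CA axis coordinates.

    Rows: GC3s, CAI, ENC, L_aa and mean GC; columns r, p and a significance
    mark (** p<0.01, * p<0.05). Indices constant across genes are flagged
    'na'. Genes are aligned by id between the CA result and the index table.
    """
    by_id = {g.gene_id: g for g in indices}
    missing = [g for g in coa.genes if g not in by_id]
    if missing:
        raise ValueError(f"indices missing for genes: {missing[:5]}")
    aligned = [by_id[g] for g in coa.genes]
    series = {
        "GC3s": [g.gc.gc3s for g in aligned],
        "CAI": [g.cai for g in aligned],
        "ENC": [g.enc for g in aligned],
        "L_aa": [float(g.l_aa) for g in aligned],
        "GC": [g.gc.gc_mean for g in aligned],
    }
    rows = []
    for name, vals in series.items():
        vals = np.asarray(vals, float)
        for ax in axes:
            coord = coa.row_coords[:, ax - 1]
            ok = ~np.isnan(vals)
            if ok.sum() < 3 or vals[ok].std() == 0 or coord[ok].std() == 0:
                corr = AxisCorrelation(name, ax, math.nan, math.nan)
            else:
                r, p = stats.pearsonr(vals[ok], coord[ok])
                corr = AxisCorrelation(name, ax, r, p)
            rows.append(
                {
                    "index": name,
                    "axis": ax,
                    "r": corr.r,
                    "p": corr.p_value,
                    "mark": corr.mark,
                }
            )
    return pd.DataFrame(rows)
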