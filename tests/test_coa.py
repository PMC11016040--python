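"""Correspondence analysis: oracle equivalence and chi-square identities."""

import numpy as np
import pytest
from scipy import stats

from codonbias.coa import (
    RscuMatrix,
    axis_index_correlations,
    build_rscu_matrix,
    correspondence_analysis,
)
from codonbias.genetics import DEGENERATE_CODONS
from codonbias.indices import GeneIndexRecord
from codonbias.metrics import CodonCountTable, GcComposition
from conftest import random_count_table


def ca_oracle(N: np.ndarray):
    """Brute-force CA via eigendecomposition of the residual cross-product.

    Independent of the SVD route: principal inertias are the eigenvalues of
    S S^T and row coordinates come from its eigenvectors.
    """
    N = np.asarray(N, float)
    total = N.sum()
    P = N / total
    r, c = P.sum(axis=1), P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals, evecs = np.linalg.eigh(S @ S.T)
    order = np.argsort(evals)[::-1]
    rank = min(N.shape[0] - 1, N.shape[1] - 1)
    inertia = np.clip(evals[order][:rank], 0.0, None)
    U = evecs[:, order][:, :rank]
    coords = (U * np.sqrt(inertia)) / np.sqrt(r)[:, None]
    return inertia, coords


def _random_matrix(rng, shape=(20, 10)):
    return rng.integers(1, 40, size=shape).astype(float)


class TestCorrespondenceAnalysis:
    def test_matches_eigen_oracle(self, rng):
        for _ in range(5):
            N = _random_matrix(rng)
            m = RscuMatrix(
                genes=[f"g{i}" for i in range(N.shape[0])],
                codons=[f"c{j}" for j in range(N.shape[1])],
                values=N,
            )
            res = correspondence_analysis(m, n_axes=9)
            inertia_o, coords_o = ca_oracle(N)
            np.testing.assert_allclose(res.inertia, inertia_o, atol=1e-10)
            # coordinates agree per axis up to sign
            for k in range(res.n_axes):
                a, b = res.row_coords[:, k], coords_o[:, k]
                sign = np.sign(a @ b) or 1.0
                np.testing.assert_allclose(a, sign * b, atol=1e-8)

    def test_total_inertia_is_chisquare_over_total(self, rng):
        for _ in range(5):
            N = _random_matrix(rng)
            m = RscuMatrix(genes=list(map(str, range(20))),
                           codons=list(map(str, range(10))), values=N)
            res = correspondence_analysis(m)
            chi2 = stats.chi2_contingency(N, correction=False).statistic
            assert res.total_inertia == pytest.approx(
                chi2 / N.sum(), abs=1e-8
            )

    def test_identical_rows_zero_inertia(self):
        N = np.tile([1.0, 2.0, 3.0], (4, 1))
        m = RscuMatrix(genes=list("abcd"), codons=list("xyz"), values=N)
        res = correspondence_analysis(m)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association_single_axis(self):
        N = np.array([[10.0, 0.0], [0.0, 10.0]])
        m = RscuMatrix(genes=["a", "b"], codons=["x", "y"], values=N)
        res = correspondence_analysis(m)
        assert res.inertia_fraction[0] == pytest.approx(1.0)

    def test_inertia_fractions_non_increasing(self, rng):
        N = _random_matrix(rng)
        m = RscuMatrix(genes=list(map(str, range(20))),
                       codons=list(map(str, range(10))), values=N)
        res = correspondence_analysis(m)
        fr = res.inertia_fraction
        assert np.all(np.diff(fr) <= 1e-12)
        assert fr.sum() == pytest.approx(1.0)

    def test_oracle_agreement_on_row_scaled_tables(self, rng):
        """Implementation and oracle stay equal when rows are rescaled."""
        N = _random_matrix(rng)
        scales = rng.uniform(0.5, 5.0, size=N.shape[0])
        N2 = N * scales[:, None]
        m = RscuMatrix(genes=list(map(str, range(20))),
                       codons=list(map(str, range(10))), values=N2)
        res = correspondence_analysis(m)
        inertia_o, _ = ca_oracle(N2)
        np.testing.assert_allclose(res.inertia, inertia_o, atol=1e-10)

    def test_deterministic_sign_convention(self, rng):
        N = _random_matrix(rng)
        m = RscuMatrix(genes=list(map(str, range(20))),
                       codons=list(map(str, range(10))), values=N)
        a = correspondence_analysis(m).row_coords
        b = correspondence_analysis(m).row_coords
        np.testing.assert_array_equal(a, b)


class TestBuildRscuMatrix:
    def test_shape_and_excluded_columns(self, rng):
        genes = [(f"g{i}", random_count_table(rng)) for i in range(3)]
        m = build_rscu_matrix(genes, min_families=0)
        assert m.values.shape == (3, 59)
        for banned in ("ATG", "TGG", "TAA", "TAG", "TGA"):
            assert banned not in m.codons

    def test_phe_only_gene_row(self):
        t = CodonCountTable({"TTT": 1, "TTC": 1})
        m = build_rscu_matrix([("g", t)], min_families=0)
        row = dict(zip(m.codons, m.values[0]))
        assert row["TTT"] == 1.0 and row["TTC"] == 1.0
        assert sum(v for v in row.values()) == 2.0

    def test_sparse_genes_dropped_with_warning(self):
        rich = CodonCountTable({c: 2 for c in DEGENERATE_CODONS})
        poor = CodonCountTable({"TTT": 1, "TTC": 1})
        with pytest.warns(UserWarning, match="dropped"):
            m = build_rscu_matrix([("rich", rich), ("poor", poor)])
        assert m.genes == ["rich"]


def _gene_with(gid, cai_val, enc_val=50.0):
    gc = GcComposition(40, 40, 30, 110 / 3, 40, 30)
    return GeneIndexRecord(gene_id=gid, gc=gc, enc=enc_val, cai=cai_val,
                           l_aa=100, pr2_x=0.5, pr2_y=0.5)


class TestAxisIndexCorrelations:
    def _coa(self, coords):
        from codonbias.coa import CoaResult

        coords = np.asarray(coords, float)
        return CoaResult(
            genes=[f"g{i}" for i in range(coords.shape[0])],
            row_coords=coords,
            inertia=np.array([1.0, 0.5]),
            inertia_fraction=np.array([2 / 3, 1 / 3]),
            n_axes=2,
        )

    def test_index_equal_to_axis_gives_r_one(self):
        coords = np.column_stack([np.arange(10.0), np.ones(10)])
        coa = self._coa(coords)
        genes = [_gene_with(f"g{i}", cai_val=float(i)) for i in range(10)]
        table = axis_index_correlations(coa, genes)
        row = table[(table["index"] == "CAI") & (table.axis == 1)].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row["mark"] == "**"

    def test_constant_index_flagged(self):
        coords = np.column_stack([np.arange(10.0), np.ones(10)])
        coa = self._coa(coords)
        genes = [_gene_with(f"g{i}", cai_val=0.7) for i in range(10)]
        table = axis_index_correlations(coa, genes)
        assert (table[table["index"] == "CAI"]["mark"] == "na").all()

    def test_independent_noise_rarely_correlates(self):
        rng = np.random.default_rng(77)
        hits = 0
        reps = 100
        for _ in range(reps):
            coords = np.column_stack([rng.normal(size=100),
                                      rng.normal(size=100)])
            coa = self._coa(coords)
            genes = [_gene_with(f"g{i}", cai_val=float(rng.normal()))
                     for i in range(100)]
            table = axis_index_correlations(coa, genes)
            r = table[(table["index"] == "CAI") & (table.axis == 1)].iloc[0].r
            hits += abs(r) >= 0.3
        assert hits <= 2  # |r| < 0.3 in ~99% of null replicates

    def test_misaligned_genes_raise(self):
        coords = np.column_stack([np.arange(4.0), np.ones(4)])
        coa = self._coa(coords)
        genes = [_gene_with("other", 0.5)]
        with pytest.raises(ValueError, match="missing"):
            axis_index_correlations(coa, genes)
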