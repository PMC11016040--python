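"""PR2 coordinates, neutrality regression, expression sets, optimal codons."""

import math

import pytest

from codonbias.indices import GeneIndexRecord
from codonbias.metrics import CodonCountTable, GcComposition, count_codons
from codonbias.simulate import generate_neutrality_set
from codonbias.pipeline import gene_index_records
from codonbias.sources import (
    neutrality_fit,
    optimal_codons,
    pr2_point,
    select_expression_datasets,
)
from conftest import random_count_table


def _gene(gid, gc3=30.0, gc12=40.0, enc_val=50.0):
    gc = GcComposition(gc1=gc12, gc2=gc12, gc3=gc3, gc_mean=(2 * gc12 + gc3) / 3,
                       gc12=gc12, gc3s=gc3)
    return GeneIndexRecord(gene_id=gid, gc=gc, enc=enc_val, cai=0.5,
                           l_aa=100, pr2_x=0.5, pr2_y=0.5)


class TestPr2:
    def test_balanced_third_positions_center(self):
        # GGT/GGC/GGA/GGG have third bases T, C, A, G
        t = CodonCountTable({"GGT": 2, "GGC": 2, "GGA": 2, "GGG": 2})
        p = pr2_point(t)
        assert (p.x, p.y) == (0.5, 0.5)

    def test_all_t_and_c_lower_left(self):
        t = CodonCountTable({"GGT": 3, "GGC": 3})
        p = pr2_point(t)
        assert p.y == 0.0 and p.x == 0.0

    def test_hand_tallies(self):
        # third bases: A x1 (GGA), T x3 (GGT), G x3 (GGG), C x1 (GGC)
        t = CodonCountTable({"GGA": 1, "GGT": 3, "GGG": 3, "GGC": 1})
        p = pr2_point(t)
        assert p.x == pytest.approx(0.75)
        assert p.y == pytest.approx(0.25)

    def test_zero_denominator_flagged(self):
        p = pr2_point(CodonCountTable({"GGT": 5, "GGA": 5}))
        assert math.isnan(p.x) and not math.isnan(p.y)

    def test_non_degenerate_codons_ignored(self):
        base = CodonCountTable({"GGA": 1, "GGT": 3, "GGG": 3, "GGC": 1})
        with_singletons = CodonCountTable(
            {"GGA": 1, "GGT": 3, "GGG": 3, "GGC": 1, "ATG": 9, "TGG": 9,
             "TAA": 4}
        )
        assert pr2_point(base) == pr2_point(with_singletons)

    def test_codon_order_permutation_invariance(self):
        from codonbias.io import CdsRecord

        a = count_codons(CdsRecord("a", "ATG" + "GGAGGT" * 3 + "TAA"))
        b = count_codons(CdsRecord("b", "ATG" + "GGTGGA" * 3 + "TAA"))
        assert pr2_point(a) == pr2_point(b)


class TestNeutralityFit:
    def test_diagonal_points_slope_one(self):
        genes = [_gene(f"g{i}", gc3=v, gc12=v) for i, v in
                 enumerate((20.0, 30.0, 40.0, 50.0))]
        fit = neutrality_fit(genes)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.mutation_pct + fit.selection_pct == pytest.approx(100.0)

    def test_constant_gc12_slope_zero(self):
        genes = [_gene(f"g{i}", gc3=v, gc12=40.0) for i, v in
                 enumerate((20.0, 30.0, 40.0, 50.0))]
        fit = neutrality_fit(genes)
        assert fit.slope == pytest.approx(0.0)

    def test_degenerate_x_raises(self):
        genes = [_gene(f"g{i}", gc3=30.0, gc12=v) for i, v in
                 enumerate((20.0, 30.0, 40.0))]
        with pytest.raises(ValueError, match="constant"):
            neutrality_fit(genes)

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError):
            neutrality_fit([_gene("a"), _gene("b")])

    @pytest.mark.parametrize("planted", [0.0, 0.4, 1.0])
    def test_planted_slope_recovery(self, planted):
        recs = generate_neutrality_set(planted, noise_sd=0.02, n=200, seed=11)
        genes = gene_index_records([(r.id, count_codons(r)) for r in recs])
        fit = neutrality_fit(genes)
        assert abs(fit.slope - planted) <= 3 * fit.stderr

    def test_noise_free_diagonal_generator(self):
        recs = generate_neutrality_set(1.0, noise_sd=0.0, n=200, seed=5)
        genes = gene_index_records([(r.id, count_codons(r)) for r in recs])
        fit = neutrality_fit(genes)
        assert fit.slope == pytest.approx(1.0, abs=0.05)


class TestExpressionDatasets:
    def test_single_gene_extremes(self):
        genes = [_gene(f"g{i}", enc_val=30.0 + i) for i in range(10)]
        high, low = select_expression_datasets(genes, 0.1)
        assert high == {"g0"} and low == {"g9"}

    def test_tie_break_is_lexicographic(self):
        genes = [_gene(g, enc_val=40.0) for g in ("b", "a", "d", "c")]
        high, low = select_expression_datasets(genes, 0.25)
        assert high == {"a"} and low == {"d"}

    def test_half_fraction_partitions(self):
        genes = [_gene(f"g{i}", enc_val=30.0 + i) for i in range(4)]
        high, low = select_expression_datasets(genes, 0.5)
        assert high == {"g0", "g1"} and low == {"g2", "g3"}
        assert not high & low

    def test_overlapping_sets_rejected(self):
        genes = [_gene(f"g{i}", enc_val=30.0 + i) for i in range(3)]
        with pytest.raises(ValueError):
            select_expression_datasets(genes, 0.5)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 0.6])
    def test_fraction_domain(self, fraction):
        genes = [_gene(f"g{i}") for i in range(10)]
        with pytest.raises(ValueError):
            select_expression_datasets(genes, fraction)


class TestOptimalCodons:
    def test_hand_example_passes_both_rules(self):
        # high: GCT 18/40 of Ala -> RSCU 1.8; low: GCT 16/40 -> RSCU 1.6
        high = CodonCountTable({"GCT": 18, "GCA": 10, "GCC": 8, "GCG": 4})
        low = CodonCountTable({"GCT": 16, "GCA": 10, "GCC": 8, "GCG": 6})
        res = optimal_codons(high, low)
        assert res.rscu_high["GCT"] == pytest.approx(1.8)
        assert res.delta_rscu["GCT"] == pytest.approx(0.2)
        assert "GCT" in res.optimal

    def test_rscu_above_one_required(self):
        # GGG dominant in high set but RSCU_high still below 1? construct:
        # high: GGG share 0.2 -> RSCU 0.8; low: GGG share 0.05 -> RSCU 0.2
        high = CodonCountTable({"GGG": 20, "GGA": 40, "GGT": 20, "GGC": 20})
        low = CodonCountTable({"GGG": 5, "GGA": 55, "GGT": 20, "GGC": 20})
        res = optimal_codons(high, low)
        assert res.delta_rscu["GGG"] > 0.08
        assert "GGG" not in res.optimal

    def test_identical_sets_yield_empty(self, rng):
        t = random_count_table(rng)
        res = optimal_codons(t, t)
        assert res.optimal == []
        assert all(d == 0 for d in res.delta_rscu.values())

    def test_threshold_monotonicity(self, rng):
        high, low = random_count_table(rng), random_count_table(rng)
        sizes = [
            len(optimal_codons(high, low, threshold=th).optimal)
            for th in (0.02, 0.08, 0.2, 0.5)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_stop_family_participates(self):
        high = CodonCountTable({"TAA": 8, "TAG": 1, "TGA": 1})
        low = CodonCountTable({"TAA": 4, "TAG": 3, "TGA": 3})
        res = optimal_codons(high, low)
        assert "TAA" in res.optimal
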