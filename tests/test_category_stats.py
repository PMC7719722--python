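"""Pearson, scaled correlation matrices, quantile shift, modified histogram."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ncec import ExpressionMatrix, WT
from ncec.category_stats import (
    StatsError,
    UndefinedCorrelationError,
    category_correlation_matrix,
    modified_histogram,
    pearson,
    quantile_shift,
    quantile_sizes,
    whole_transcriptome_mva,
)

from conftest import matrix_from


class TestPearson:
    def test_self_and_anti_correlation(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_symmetry_and_textbook_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.normal(size=rng.integers(3, 30))
            y = rng.normal(size=x.size)
            r = pearson(x, y)
            assert r == pytest.approx(pearson(y, x), abs=0)
            expected = np.cov(x, y, ddof=0)[0, 1] / (x.std() * y.std())
            assert abs(r - expected) < 1e-12

    def test_constant_vector_is_an_error_not_zero(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1.0, 1.0, 1.0], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(StatsError):
            pearson([1, 2], [1, 2, 3])


class TestCategoryCorrelation:
    CATS = {f"g{i}": "angiogenesis" for i in range(4)}

    def _identity_matrix(self):
        vals = [10.0, 100.0, 1000.0, 50.0]
        cols = {f"{g}_{r}": vals for g in (WT, "etsrp_mut") for r in (1, 2)}
        return matrix_from(cols, genes=list(self.CATS))

    def test_identity_genotypes_scale_to_one(self):
        corr = category_correlation_matrix(self._identity_matrix(), self.CATS, "angiogenesis")
        assert np.allclose(corr.scaled.to_numpy(), 1.0)
        assert corr.reference == pytest.approx(1.0)

    def test_matches_hand_computed_entries(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(10, 1000, 4)
        cols = {f"WT_{r}": base * rng.uniform(0.8, 1.2, 4) for r in (1, 2)}
        cols["etsrp_mut_1"] = rng.uniform(10, 1000, 4)
        m = matrix_from(cols, genes=list(self.CATS))
        corr = category_correlation_matrix(m, self.CATS, "angiogenesis")
        log2 = np.log2(m.values + 1.0)
        for a, b in itertools.combinations(m.samples, 2):
            x, y = log2[a], log2[b]
            expected = np.corrcoef(x, y)[0, 1]
            assert corr.raw.loc[a, b] == pytest.approx(expected, abs=1e-12)
        ref = np.corrcoef(log2["WT_1"], log2["WT_2"])[0, 1]
        assert corr.reference == pytest.approx(ref, abs=1e-12)

    def test_small_category_rejected(self):
        m = self._identity_matrix()
        with pytest.raises(StatsError, match="at least 3"):
            category_correlation_matrix(m, {"g0": "neurogenesis"}, "neurogenesis")

    def test_scale_invariance_on_log2_profiles(self):
        # a constant log2 offset on one sample (a global intensity rescale)
        # leaves every Pearson statistic unchanged
        rng = np.random.default_rng(9)
        base = rng.uniform(4, 16, 6)
        cols = {
            "WT_1": base + rng.normal(0, 0.3, 6),
            "WT_2": base + rng.normal(0, 0.3, 6),
            "etsrp_mut_1": base + rng.normal(0, 1.0, 6),
        }
        cats = {f"g{i}": "angiogenesis" for i in range(6)}
        m = matrix_from(cols, genes=list(cats), log_state="log2")
        shifted_cols = dict(cols)
        shifted_cols["etsrp_mut_1"] = cols["etsrp_mut_1"] + 3.7
        m2 = matrix_from(shifted_cols, genes=list(cats), log_state="log2")
        c1 = category_correlation_matrix(m, cats, "angiogenesis")
        c2 = category_correlation_matrix(m2, cats, "angiogenesis")
        assert np.allclose(c1.raw.to_numpy(), c2.raw.to_numpy(), atol=1e-12)


class TestQuantileShift:
    def test_sizes_rule(self):
        assert quantile_sizes(8) == [2, 2, 2, 2]
        assert quantile_sizes(10) == [3, 3, 2, 2]
        assert quantile_sizes(7) == [2, 2, 2, 1]

    def test_identity_gives_zero_shifts_and_diagonal_transitions(self):
        vals = np.exp2(np.arange(1.0, 9.0))
        m = matrix_from({"WT_1": vals, "etsrp_mut_1": vals})
        cats = {f"g{i}": "all" for i in range(8)}
        qs = quantile_shift(m, cats, "all", mutant_labels=("etsrp_mut",))
        assert (qs.per_gene["etsrp_mut_rank_shift"] == 0).all()
        t = qs.transitions["etsrp_mut"].to_numpy()
        assert np.array_equal(np.diag(np.diag(t)), t)
        assert list(np.diag(t)) == qs.sizes

    def test_pair_swap_moves_exactly_two_genes_between_q2_q3(self):
        wt = np.exp2(np.arange(1.0, 9.0))  # genes g0..g7, ranks 1..8
        mut = wt.copy()
        mut[2], mut[5] = wt[5], wt[2]  # swap genes 3 and 6 (0-based 2 and 5)
        m = matrix_from({"WT_1": wt, "etsrp_mut_1": mut})
        cats = {f"g{i}": "all" for i in range(8)}
        qs = quantile_shift(m, cats, "all", mutant_labels=("etsrp_mut",))
        pg = qs.per_gene
        assert pg.loc["g2", "wt_quantile"] == "Q2"
        assert pg.loc["g2", "etsrp_mut_quantile"] == "Q3"
        assert pg.loc["g5", "wt_quantile"] == "Q3"
        assert pg.loc["g5", "etsrp_mut_quantile"] == "Q2"
        unchanged = [g for g in cats if g not in ("g2", "g5")]
        assert (pg.loc[unchanged, "etsrp_mut_rank_shift"] == 0).all()

    def test_occupancy_conserved_under_random_reranking(self):
        rng = np.random.default_rng(10)
        n = 37
        cats = {f"g{i:02d}": "all" for i in range(n)}
        m = matrix_from(
            {"WT_1": rng.uniform(10, 1e4, n), "etsrp_mut_1": rng.uniform(10, 1e4, n)},
            genes=list(cats),
        )
        qs = quantile_shift(m, cats, "all", mutant_labels=("etsrp_mut",))
        t = qs.transitions["etsrp_mut"]
        assert list(t.sum(axis=1)) == qs.sizes        # row sums: WT occupancy
        assert t.to_numpy().sum() == n
        assert sorted(t.sum(axis=0)) == sorted(qs.sizes)

    def test_fewer_than_four_genes_rejected(self):
        m = matrix_from({"WT_1": [1, 2, 3], "etsrp_mut_1": [1, 2, 3]})
        with pytest.raises(StatsError, match="quartiles"):
            quantile_shift(m, {f"g{i}": "all" for i in range(3)}, "all",
                           mutant_labels=("etsrp_mut",))


class TestModifiedHistogram:
    def test_identity_normalizes_to_one_everywhere(self):
        vals = np.exp2(np.linspace(4, 14, 12))
        cols = {f"{g}_{r}": vals for g in (WT, "etsrp_mut") for r in (1, 2, 3)}
        cats = {f"g{i}": "all" for i in range(12)}
        m = matrix_from(cols, genes=list(cats))
        hist = modified_histogram(m, cats, "all", bin_size=4, mutant_labels=("etsrp_mut",))
        assert np.allclose(hist.table["norm_etsrp_mut"], 1.0)
        assert hist.denominators["etsrp_mut"] == pytest.approx(1.0)

    def test_single_bin_composition_of_audited_pieces(self):
        rng = np.random.default_rng(11)
        n = 4
        cats = {f"g{i}": "all" for i in range(n)}
        base = rng.uniform(4, 14, n)
        cols = {
            "WT_1": np.exp2(base + rng.normal(0, 0.2, n)),
            "WT_2": np.exp2(base + rng.normal(0, 0.2, n)),
            "etsrp_mut_1": np.exp2(base + rng.normal(0, 0.6, n)),
            "etsrp_mut_2": np.exp2(base + rng.normal(0, 0.6, n)),
        }
        m = matrix_from(cols, genes=list(cats))
        hist = modified_histogram(m, cats, "all", bin_size=4, mutant_labels=("etsrp_mut",))
        log2 = np.log2(m.values + 1.0)
        wt_mean = log2[["WT_1", "WT_2"]].mean(axis=1)
        mut_mean = log2[["etsrp_mut_1", "etsrp_mut_2"]].mean(axis=1)
        raw = pearson(wt_mean, mut_mean)
        denom = whole_transcriptome_mva(m, WT, "etsrp_mut")
        assert hist.table["raw_etsrp_mut"].iloc[0] == pytest.approx(raw, abs=1e-12)
        assert hist.table["norm_etsrp_mut"].iloc[0] == pytest.approx(raw / denom, abs=1e-12)

    def test_trailing_small_bin_dropped(self):
        rng = np.random.default_rng(12)
        n = 11  # bins of 5 -> 5, 5, and a dropped 1-gene remainder
        cats = {f"g{i:02d}": "all" for i in range(n)}
        base = rng.uniform(4, 14, n)
        m = matrix_from(
            {"WT_1": np.exp2(base), "etsrp_mut_1": np.exp2(base + rng.normal(0, 0.4, n))},
            genes=list(cats),
        )
        hist = modified_histogram(m, cats, "all", bin_size=5, mutant_labels=("etsrp_mut",))
        assert list(hist.table["n_genes"]) == [5, 5]

    def test_nonpositive_denominator_is_an_error(self):
        n = 8
        cats = {f"g{i}": "all" for i in range(n)}
        up = np.exp2(np.linspace(4, 14, n))
        m = matrix_from({"WT_1": up, "WT_2": up, "etsrp_mut_1": up[::-1]}, genes=list(cats))
        with pytest.raises(StatsError, match="normalization undefined"):
            modified_histogram(m, cats, "all", bin_size=4, mutant_labels=("etsrp_mut",))

    def test_per_gene_mode(self):
        rng = np.random.default_rng(13)
        n = 6
        cats = {f"g{i}": "all" for i in range(n)}
        base = rng.uniform(4, 14, n)
        cols = {
            f"{g}_{r}": np.exp2(base + rng.normal(0, 0.3, n))
            for g in (WT, "etsrp_mut")
            for r in (1, 2, 3)
        }
        m = matrix_from(cols, genes=list(cats))
        hist = modified_histogram(m, cats, "all", mode="per_gene", mutant_labels=("etsrp_mut",))
        assert len(hist.table) == n
        assert hist.table["raw_etsrp_mut"].between(-1, 1).all()


def test_within_genotype_mva_high_on_default_run(default_chain):
    matrix = default_chain[2]
    assert whole_transcriptome_mva(matrix, WT, WT) > 0.849
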