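"""Correlation/FDR, Pareto PCA, Mantel, ANOVA and epistasis summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from seedmqtl import (
    PhenotypeTable,
    RilDesign,
    anova_reciprocal,
    bh_adjust,
    epistasis_groups,
    mantel_test,
    pca_pareto,
    pearson_fdr,
    simulate_ril_population,
)
from seedmqtl.core_io import AA, BB
from seedmqtl.multivariate import correlation_sign_split


class TestBhAdjust:
    def test_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_reference_step_up(self, p):
        p = np.asarray(p)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_brute_force_definition(self):
        rng = np.random.default_rng(0)
        p = rng.random(25)
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        for rank, i in enumerate(order, start=1):
            brute[i] = min(
                p[j] * m / (list(order).index(j) + 1)
                for j in order[rank - 1:]
            )
        np.testing.assert_allclose(bh_adjust(p), np.clip(brute, 0, 1), atol=1e-12)


class TestPearsonFdr:
    def test_self_correlation_via_duplicate_trait(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        table = PhenotypeTable(pd.DataFrame({"a": x, "b": x.copy()}))
        out = pearson_fdr(table)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_block_design_recovers_positive_sign_split(self):
        rng = np.random.default_rng(2)
        n, k = 300, 12
        latent = rng.standard_normal(n)
        cols = {
            f"t{j}": np.sqrt(0.8) * latent + np.sqrt(0.2) * rng.standard_normal(n)
            for j in range(k)
        }
        out = pearson_fdr(PhenotypeTable(pd.DataFrame(cols)))
        mean_r = out["r"].mean()
        assert 0.75 <= mean_r <= 0.85
        split = correlation_sign_split(out)
        assert split["all_pairs"]["positive"] > 0.9

    def test_zero_variance_trait_skipped(self):
        table = PhenotypeTable(
            pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        )
        assert len(pearson_fdr(table)) == 0


class TestPcaPareto:
    def test_two_point_column_hand_scaling(self):
        table = PhenotypeTable(pd.DataFrame({"a": [0.0, 2.0]}))
        res = pca_pareto(table, 1)
        # centered {-1, 1}, divided by sqrt(SD) = 2**0.25 -> +/- 0.8409
        np.testing.assert_allclose(
            sorted(res.scores["PC1"]), [-(2 ** -0.25), 2 ** -0.25], atol=1e-9
        )

    def test_rank_one_data_pc1_explains_everything(self):
        rng = np.random.default_rng(3)
        u = rng.standard_normal(30)
        v = rng.random(5) + 0.5
        table = PhenotypeTable(pd.DataFrame(np.outer(u, v),
                                            columns=[f"t{j}" for j in range(5)]))
        res = pca_pareto(table, 2)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_sum_to_one_and_scores_uncorrelated(self):
        rng = np.random.default_rng(4)
        table = PhenotypeTable(
            pd.DataFrame(rng.standard_normal((50, 8)),
                         columns=[f"t{j}" for j in range(8)])
        )
        res = pca_pareto(table, 8)
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        gram = res.scores.T @ res.scores
        off = gram.to_numpy() - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((40, 6)),
                          columns=[f"t{j}" for j in range(6)])
        r1 = pca_pareto(PhenotypeTable(df.copy()), 3)
        r2 = pca_pareto(PhenotypeTable(df.copy()), 3)
        np.testing.assert_array_equal(r1.variance_fraction, r2.variance_fraction)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)


class TestMantel:
    def test_identical_matrices_statistic_one(self):
        _, geno = simulate_ril_population(RilDesign(n_individuals=40), seed=1)
        r, p = mantel_test(geno, geno, n_perm=99)
        assert r == pytest.approx(1.0)
        assert p > 0  # (b+1)/(n+1) estimator never returns exactly zero

    def test_independent_populations_near_zero(self):
        _, a = simulate_ril_population(RilDesign(n_individuals=50), seed=2)
        _, b = simulate_ril_population(RilDesign(n_individuals=50), seed=3)
        r, p = mantel_test(a, b, n_perm=199, seed=4)
        assert abs(r) < 0.15
        assert p > 0.01

    def test_dimension_mismatch_rejected(self):
        _, a = simulate_ril_population(RilDesign(n_individuals=30), seed=5)
        _, b = simulate_ril_population(RilDesign(n_individuals=31), seed=5)
        with pytest.raises(Exception):
            mantel_test(a, b, n_perm=99)


class TestAnovaReciprocal:
    def _data(self, marker_effect=0.0, subset_effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = 200
        marker = pd.Series(rng.choice(["AA", "BB"], n))
        subset = pd.Series(rng.choice(["ColxC24", "C24xCol"], n))
        y = (
            marker_effect * (marker == "BB")
            + subset_effect * (subset == "C24xCol")
            + rng.standard_normal(n)
        )
        return pd.Series(y), marker, subset

    def test_planted_marker_effect_detected_subset_null(self):
        y, marker, subset = self._data(marker_effect=1.0, seed=1)
        p = anova_reciprocal(y, marker, subset)
        assert p["marker"] < 1e-6
        assert p["subset"] > 0.01
        assert p["interaction"] > 0.001

    def test_planted_subset_effect_detected(self):
        y, marker, subset = self._data(subset_effect=1.0, seed=2)
        p = anova_reciprocal(y, marker, subset)
        assert p["subset"] < 1e-6

    def test_permuted_trait_gives_uniformish_p(self):
        pvals = []
        for seed in range(20):
            y, marker, subset = self._data(seed=100 + seed)
            p = anova_reciprocal(y, marker, subset)
            pvals.append(p["marker"])
        assert 0.02 < np.mean(pvals) < 0.98
        assert min(pvals) > 1e-4 or sum(x < 0.05 for x in pvals) <= 4


class TestEpistasisGroups:
    def _geno_trait(self, masking=True, seed=0):
        rng = np.random.default_rng(seed)
        n = 400
        g1 = pd.Series(rng.choice([AA, BB], n))
        g2 = pd.Series(rng.choice([AA, BB], n))
        y = rng.standard_normal(n) * 0.3 + 5.0
        if masking:
            y = y + 1.5 * ((g1 == AA) & (g2 == BB))
        return pd.Series(y), g1, g2

    def test_masking_letter_pattern(self):
        y, g1, g2 = self._geno_trait(masking=True, seed=1)
        res = epistasis_groups(y, g1, g2)
        # locus-2 allele separates the groups only inside the AA class at locus 1
        assert res.letters["AA/BB"] != res.letters["AA/AA"]
        assert res.letters["BB/BB"] == res.letters["BB/AA"]
        assert res.anova_p < 1e-10

    def test_no_effect_shares_one_letter(self):
        y, g1, g2 = self._geno_trait(masking=False, seed=2)
        res = epistasis_groups(y, g1, g2)
        assert len(set(res.letters.values())) == 1

    def test_tukey_matches_studentized_range_oracle(self):
        # 4 groups x 5 observations; compare adjusted p to the direct formula
        rng = np.random.default_rng(3)
        data = {g: rng.normal(loc, 1.0, 5)
                for g, loc in zip("ABCD", [0.0, 0.5, 2.0, 2.2])}
        y = np.concatenate(list(data.values()))
        groups = np.repeat(list(data), 5)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tk = pairwise_tukeyhsd(y, groups)
        table = pd.DataFrame(tk.summary().data[1:],
                             columns=[str(c) for c in tk.summary().data[0]])
        k, n = 4, 20
        mse = np.mean([np.var(v, ddof=1) for v in data.values()])
        for _, row in table.iterrows():
            m1 = data[row["group1"]].mean()
            m2 = data[row["group2"]].mean()
            qstat = abs(m1 - m2) / np.sqrt(mse / 5)
            p_direct = stats.studentized_range.sf(qstat, k, n - k)
            assert float(row["p-adj"]) == pytest.approx(p_direct, abs=2e-3)

    def test_groups_smaller_than_minimum_omitted(self):
        y, g1, g2 = self._geno_trait(masking=False, seed=4)
        g1 = g1.copy()
        g1[(g1 == AA) & (g2 == AA)] = BB  # empty the AA/AA cell
        res = epistasis_groups(y, g1, g2)
        assert "AA/AA" not in res.letters
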