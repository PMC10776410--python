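"""Group-comparison statistics against brute-force oracles and worked examples."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from leukimm.stats import (
    adjust_pvalues,
    cluster_enrichment_or,
    differential_abundance,
    fisher_exact,
    kruskal_wallis,
    log2fc_of_medians,
    mann_whitney,
)


def _mwu_exact_bruteforce(a, b):
    """Two-sided exact MWU p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    na = len(a)

    def u_stat(idx):
        xa = pooled[list(idx)]
        xb = np.delete(pooled, list(idx))
        return np.sum(xa[:, None] > xb[None, :]) + 0.5 * np.sum(
            xa[:, None] == xb[None, :]
        )

    obs = u_stat(range(na))
    n_total = len(pooled)
    us = np.array(
        [u_stat(idx) for idx in itertools.combinations(range(n_total), na)]
    )
    mean_u = na * (n_total - na) / 2.0
    # two-sided: assignments at least as extreme (in |U - E[U]|) as observed
    return np.mean(np.abs(us - mean_u) >= np.abs(obs - mean_u) - 1e-12)


class TestMannWhitney:
    def test_worked_example(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            na = int(rng.integers(2, 6))
            nb = int(rng.integers(2, 6))
            pooled = rng.choice(1000, size=na + nb, replace=False).astype(float)
            a, b = pooled[:na], pooled[na:]
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(_mwu_exact_bruteforce(a, b), abs=1e-12)

    def test_exact_vs_asymptotic_agreement(self):
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(200):
            pooled = rng.choice(10_000, size=12, replace=False).astype(float)
            a, b = pooled[:6], pooled[6:]
            _, p_exact = mann_whitney(a, b)  # n = 12, tie-free -> exact
            from scipy.stats import mannwhitneyu

            p_approx = mannwhitneyu(a, b, method="asymptotic").pvalue
            diffs.append(abs(p_exact - min(p_approx, 1.0)))
        assert max(diffs) < 0.1 and np.mean(diffs) < 0.02

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1, 1], [1, 1], [1, 1]])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_h(self):
        # ranks 1..6, group mean ranks 1.5/3.5/5.5:
        # H = 12/(6*7) * sum n_i (rbar_i - 3.5)^2 = 12/42 * 16 = 4.5714
        h, _ = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7, abs=1e-12)

    def test_two_groups_consistent_with_mwu(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.4, 1, 20)
        _, p_kw = kruskal_wallis([a, b])
        _, p_mwu = mann_whitney(a, b)
        assert abs(p_kw - p_mwu) < 0.03

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestFisherExact:
    def test_worked_example_p(self):
        _, p = fisher_exact([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_haldane_corrected_or(self):
        or_, _ = fisher_exact([[2, 0], [0, 2]])
        assert or_ == pytest.approx(25.0)

    def test_independent_table(self):
        or_, p = fisher_exact([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)
        assert or_ == pytest.approx(1.0)

    def test_p_matches_hypergeometric_mass_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]])
            total, row1, col1 = a + b + c + d, a + b, a + c
            lo = max(0, row1 + col1 - total)
            hi = min(row1, col1)
            masses = hypergeom.pmf(np.arange(lo, hi + 1), total, col1, row1)
            p_oracle = masses[masses <= hypergeom.pmf(a, total, col1, row1) * (1 + 1e-9)].sum()
            assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_negative_entries_error(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])


class TestAdjustPvalues:
    def test_bonferroni(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.2], "bonferroni"), [0.02, 0.4]
        )

    def test_bh_stepup(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH"), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        for method in ("BH", "bonferroni"):
            np.testing.assert_allclose(adjust_pvalues([0.3], method), [0.3])

    def test_bh_matches_manual_stepup(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=25)
        order = np.argsort(p)
        m = len(p)
        stepped = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        manual = np.empty(m)
        manual[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adjust_pvalues(p, "BH"), manual, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 1), min_size=2, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_bh_permutation_invariance(self, pvals, rand):
        p = np.array(pvals)
        perm = np.array(rand.sample(range(len(p)), len(p)))
        adj_then_perm = adjust_pvalues(p, "BH")[perm]
        perm_then_adj = adjust_pvalues(p[perm], "BH")
        np.testing.assert_allclose(adj_then_perm, perm_then_adj, atol=1e-12)
        assert (adjust_pvalues(p, "BH") <= 1.0).all()


class TestLog2FC:
    def test_printed_median_pair(self):
        assert log2fc_of_medians(18.420, 9.303) == pytest.approx(0.986, abs=5e-4)

    def test_identity_and_power_of_two(self):
        assert log2fc_of_medians([3.0, 4.0], [3.0, 4.0]) == 0.0
        assert log2fc_of_medians(1.0, 16.0) == -4.0

    def test_degenerate_medians_warn(self):
        with pytest.warns(UserWarning):
            assert log2fc_of_medians(1.0, 0.0) == float("inf")
        with pytest.warns(UserWarning):
            assert log2fc_of_medians(0.0, 1.0) == float("-inf")


class TestDifferentialAbundance:
    def _table(self, a_vals, b_vals, name="ct"):
        rows = [{"sample_id": f"a{i}", "group": "A", name: v} for i, v in enumerate(a_vals)]
        rows += [{"sample_id": f"b{i}", "group": "B", name: v} for i, v in enumerate(b_vals)]
        return pd.DataFrame(rows)

    def test_worked_example(self):
        t = self._table([10, 12, 14], [1, 2, 3])
        res = differential_abundance(t, "A", "B")
        assert res.loc["ct", "log2fc_medians"] == pytest.approx(np.log2(6), abs=1e-12)
        assert res.loc["ct", "p_raw"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_no_flags(self):
        t = self._table([5, 6, 7], [5, 6, 7])
        res = differential_abundance(t, "A", "B")
        assert res.loc["ct", "log2fc_medians"] == 0.0
        assert not res["flagged"].any()

    def test_power_and_size_simulation(self):
        # one cell type planted at 2.5x between groups of 7 vs 7 samples
        # (clear of the |log2FC| > 1 flag boundary); a null cell type
        # alongside; 500 replicates
        rng = np.random.default_rng(5)
        flagged_planted = flagged_null = 0
        reps = 500
        for _ in range(reps):
            a_planted = rng.lognormal(np.log(10) + np.log(2.5), 0.25, 7)
            b_planted = rng.lognormal(np.log(10), 0.25, 7)
            a_null = rng.lognormal(np.log(5), 0.25, 7)
            b_null = rng.lognormal(np.log(5), 0.25, 7)
            t = pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(14)],
                    "group": ["A"] * 7 + ["B"] * 7,
                    "planted": np.r_[a_planted, b_planted],
                    "null": np.r_[a_null, b_null],
                }
            )
            res = differential_abundance(t, "A", "B")
            flagged_planted += bool(res.loc["planted", "flagged"])
            flagged_null += bool(res.loc["null", "flagged"])
        assert flagged_planted / reps >= 0.60
        assert flagged_null / reps <= 0.05

    def test_type_one_error_calibrated(self):
        # the exact 7v7 test's true size at alpha=0.05 is 0.0379 (attainable
        # level); 5000 replicates keep the Monte-Carlo error well inside the
        # [0.03, 0.07] band
        rng = np.random.default_rng(6)
        hits = 0
        reps = 5000
        for _ in range(reps):
            a = rng.lognormal(np.log(10), 0.3, 7)
            b = rng.lognormal(np.log(10), 0.3, 7)
            _, p = mann_whitney(a, b)
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_too_few_samples_error(self):
        t = self._table([1], [2, 3])
        with pytest.raises(ValueError):
            differential_abundance(t, "A", "B")


class TestClusterEnrichmentOR:
    def test_worked_example(self):
        assert cluster_enrichment_or(90, 10, 1000, 9000) == pytest.approx(81.0)

    def test_equal_rates(self):
        assert cluster_enrichment_or(10, 90, 100, 900) == pytest.approx(1.0)

    def test_zero_cell_haldane(self):
        or_ = cluster_enrichment_or(5, 0, 10, 100)
        assert np.isfinite(or_)
        assert or_ == pytest.approx((5.5 / 0.5) / (10.5 / 100.5))

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            cluster_enrichment_or(-1, 2, 3, 4)
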