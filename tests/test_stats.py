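"""Welch comparisons and grade/OD concordance against independent oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cishquant.errors import ConfigurationError, InsufficientDataError
from cishquant.stats import (
    compare_all_groups,
    comparisons_to_frame,
    grade_od_concordance,
    welch_t_test,
)


def welch_oracle(a, b):
    """Closed-form Welch-Satterthwaite evaluation, independent of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_frozen_toy_example(self):
        t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert df == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(0.0213116, abs=1e-6)

    def test_identical_samples_give_vacuous_test(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_equal_means_convention(self):
        t, df, p = welch_t_test([2, 2, 2], [2, 2])
        assert (t, p) == (0.0, 1.0)

    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 6)
        t1, *_ = welch_t_test(a, b)
        t2, *_ = welch_t_test(a + 17.3, b + 17.3)
        assert t1 == pytest.approx(t2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 12))
        b = rng.normal(0.5, 2, rng.integers(3, 12))
        t, df, p = welch_t_test(a, b)
        to, dfo, po = welch_oracle(a, b)
        assert t == pytest.approx(to, abs=1e-12)
        assert df == pytest.approx(dfo, abs=1e-12)
        assert p == pytest.approx(po, abs=1e-12)
        # Welch-Satterthwaite df bounds
        assert min(len(a), len(b)) - 1 <= df <= len(a) + len(b) - 2

    def test_equals_pooled_t_for_balanced_equal_variance_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 0.5  # same spread, same n
        t_w, df_w, _ = welch_t_test(a, b)
        t_p = sps.ttest_ind(a, b, equal_var=True)
        assert t_w == pytest.approx(float(t_p.statistic), abs=1e-12)
        assert df_w == pytest.approx(len(a) + len(b) - 2, abs=1e-12)

    def test_agrees_with_permutation_oracle(self):
        """Two-tailed Welch p within 3 Monte-Carlo SE of a permutation p."""
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(1.0, 1.0, 8)
        t_obs, _, p_welch = welch_t_test(a, b)

        pooled = np.concatenate([a, b])
        n_perm = 20000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t_perm, *_ = welch_oracle(perm[:8], perm[8:])
            count += abs(t_perm) >= abs(t_obs)
        p_perm = (count + 1) / (n_perm + 1)
        se = math.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_welch - p_perm) <= 3 * se + 1e-3

    def test_tiny_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            welch_t_test([1.0], [2.0, 3.0])


class TestGroupComparisons:
    @staticmethod
    def toy_table(seed=0, groups=("CA", "CA-N", "HGIN", "HGIN-N", "LGIN", "LGIN-N")):
        rng = np.random.default_rng(seed)
        rows = []
        for g in groups:
            for s in range(4):
                for rep in range(3):
                    rows.append({"sample_id": f"{g}-{s}", "group": g,
                                 "replicate": rep, "mean_od": rng.normal(0.5, 0.1)})
        return pd.DataFrame(rows)

    def test_all_fifteen_pairs_emitted(self):
        comps = compare_all_groups(self.toy_table(), ["mean_od"])
        assert len(comps) == len(list(combinations(range(6), 2))) == 15
        frame = comparisons_to_frame(comps)
        assert set(frame.columns) >= {"metric", "t", "df", "p", "p_holm", "significant"}

    def test_replicates_averaged_before_testing(self):
        table = self.toy_table(seed=3, groups=("CA", "CA-N"))
        comps = compare_all_groups(table, ["mean_od"])
        assert comps[0].n_a == comps[0].n_b == 4  # samples, not 12 replicates
        per_sample = table.groupby(["sample_id", "group"])["mean_od"].mean().reset_index()
        a = per_sample.loc[per_sample.group == "CA", "mean_od"]
        b = per_sample.loc[per_sample.group == "CA-N", "mean_od"]
        t, df, p = welch_t_test(a, b)
        assert comps[0].p_two_tailed == pytest.approx(p, abs=1e-12)

    def test_significance_flag_matches_alpha(self):
        comps = compare_all_groups(self.toy_table(seed=5), ["mean_od"], alpha=0.5)
        for c in comps:
            assert c.significant == (c.p_two_tailed < 0.5)
            assert c.p_holm >= c.p_two_tailed - 1e-15

    def test_unknown_metric_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            compare_all_groups(self.toy_table(), ["no_such_metric"])


class TestConcordance:
    def test_perfect_monotone_agreement(self):
        res = grade_od_concordance([1, 2, 3, 4], [0.2, 0.4, 0.6, 0.8])
        assert res.rs == pytest.approx(1.0)
        assert res.ols_slope == pytest.approx(0.2)

    def test_perfect_antitone_agreement(self):
        res = grade_od_concordance([1, 2, 3, 4], [0.8, 0.6, 0.4, 0.2])
        assert res.rs == pytest.approx(-1.0)

    def test_constant_grades_flagged_missing(self):
        res = grade_od_concordance([2, 2, 2, 2], [0.1, 0.5, 0.3, 0.9])
        assert np.isnan(res.rs)

    def test_independent_grades_rarely_significant(self):
        """Permutation-style null: random grade/OD pairings give small |rs|
        and p > 0.05 in most repetitions."""
        rng = np.random.default_rng(11)
        n_sig, reps = 0, 60
        for _ in range(reps):
            grades = rng.integers(1, 5, 34)
            ods = rng.uniform(0.2, 0.95, 34)
            res = grade_od_concordance(grades, ods)
            n_sig += res.p_rs < 0.05
        assert n_sig <= 9  # ~5% expected; allow generous binomial slack

    def test_rank_correlation_invariant_to_monotone_od_transform(self):
        rng = np.random.default_rng(2)
        grades = rng.integers(1, 5, 30)
        ods = rng.uniform(0.2, 0.95, 30)
        r1 = grade_od_concordance(grades, ods).rs
        r2 = grade_od_concordance(grades, np.exp(3 * ods)).rs
        assert r1 == pytest.approx(r2, abs=1e-12)
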