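import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wrrc.listener import simulate_cohort
from wrrc.scoring import score_cohort
from wrrc.stats import (
    MEASURES,
    bonferroni_alpha,
    friedman,
    mann_whitney,
    normality_screen,
    pairwise_posthoc,
    run_full_analysis,
    shared_variance_pct,
    spearman_with_shared_variance,
    wilcoxon_signed_rank,
)


class TestNormalityScreen:
    def test_symmetric_sample_zero_skew(self):
        z_s, z_k, ok = normality_screen(np.array([-2, -1, 0, 1, 2] * 5))
        assert z_s == pytest.approx(0.0, abs=1e-12)
        assert ok

    def test_right_skewed_flagged(self):
        x = np.random.default_rng(0).exponential(size=26)
        z_s, z_k, ok = normality_screen(x)
        assert z_s > 1.96
        assert not ok

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            normality_screen([1, 2, 3, 4, 5])

    def test_se_formula(self):
        # n = 26: SE_skew = sqrt(6*26*25 / (24*27*29)) = 0.4556...
        x = np.random.default_rng(1).normal(size=26)
        z_s, _, _ = normality_screen(x)
        se = np.sqrt(6 * 26 * 25 / (24 * 27 * 29))
        assert z_s == pytest.approx(sps.skew(x, bias=False) / se)


class TestFriedman:
    def test_hand_example_statistic(self):
        # 3 subjects each scoring (1,2,3): chi2 = 12/(3*3*4)*(9+36+81) - 3*3*4 = 6
        res = friedman([[1, 2, 3]] * 3)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 2
        # asymptotic tail of that statistic is the classic 0.0498...
        assert sps.chi2.sf(res.statistic, 2) == pytest.approx(0.0498, abs=5e-4)
        # ...but at n=3 the exact permutation p applies: 6 of 6^3 orderings
        assert res.p == pytest.approx(6 / 216)

    def test_identical_columns(self):
        res = friedman(np.full((10, 3), 7.0))
        assert res.statistic == 0.0
        assert res.p == 1.0
        assert not res.significant

    def test_matches_scipy_large_n(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = rng.integers(10, 30, size=(26, 3)).astype(float)
            mine = friedman(m)
            ref = sps.friedmanchisquare(*m.T)
            assert mine.statistic == pytest.approx(ref.statistic)
            assert mine.p == pytest.approx(ref.pvalue)

    def test_exact_p_agrees_with_subsampled_permutation_oracle(self):
        rng = np.random.default_rng(5)
        m = rng.integers(10, 30, size=(8, 3)).astype(float)
        res = friedman(m)
        perms = list(itertools.permutations(range(3)))
        hit = 0
        n_mc = 4000
        orac = np.random.default_rng(7)
        for _ in range(n_mc):
            mm = np.array([row[list(perms[orac.integers(6)])] for row in m])
            hit += friedman(mm).statistic >= res.statistic - 1e-9
        assert abs(res.p - hit / n_mc) < 0.03

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(12, 3))
        a = friedman(m)
        b = friedman(np.exp(m))  # strictly monotone per-subject transform
        assert a.statistic == pytest.approx(b.statistic)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(15, 3))
        a = friedman(m)
        b = friedman(m[rng.permutation(15)])
        assert a.statistic == pytest.approx(b.statistic)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            friedman([[1, 2]])


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0

    def test_equal_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0

    def test_exact_agrees_with_pairwise_count_oracle(self):
        # oracle: enumerate all C(10,5) labelings, computing U by pairwise
        # comparison counts (ties worth 1/2) — a different route than the
        # implementation's rank-sum enumeration
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.integers(0, 10, size=5).astype(float)
            b = rng.integers(0, 10, size=5).astype(float)
            res = mann_whitney(a, b)
            pool = np.concatenate([a, b])
            mu = 12.5
            u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert res.statistic == pytest.approx(u_obs)
            total = extreme = 0
            for combo in itertools.combinations(range(10), 5):
                sa = pool[list(combo)]
                sb = np.delete(pool, list(combo))
                u = sum((x > y) + 0.5 * (x == y) for x in sa for y in sb)
                total += 1
                extreme += abs(u - mu) >= abs(u_obs - mu) - 1e-9
            assert res.p == pytest.approx(extreme / total)

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 30, size=10).astype(float)
        b = rng.integers(0, 30, size=16).astype(float)
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1])


class TestSpearman:
    def test_perfect_monotone(self):
        r, p, shared = spearman_with_shared_variance([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r == pytest.approx(1.0)
        assert shared == 100.0

    def test_shared_variance_printed_values(self):
        assert shared_variance_pct(0.438) == 19.2
        assert shared_variance_pct(0.437) == 19.1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            spearman_with_shared_variance([1, 2, 3, 4, 5], [1, 2, 3, 4])


class TestPosthoc:
    def test_bonferroni_alphas(self):
        assert bonferroni_alpha(0.05, 3) == 0.017
        assert bonferroni_alpha(0.01, 3) == 0.003

    def test_identical_columns_nothing_flagged(self):
        m = np.full((10, 3), 5.0)
        rows = pairwise_posthoc(m, ["RH", "NR", "UnSc"])
        assert len(rows) == 3
        assert not any(r.significant for r in rows)
        assert all(r.alpha_adjusted == 0.017 for r in rows)

    def test_wilcoxon_alternative(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(20, 3))
        m[:, 0] += 2.0
        rows = pairwise_posthoc(m, ["RH", "NR", "UnSc"], method="wilcoxon")
        assert rows[0].method == "wilcoxon signed-rank"
        assert rows[0].significant

    def test_wilcoxon_identical(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p == 1.0


class TestFullAnalysis:
    def test_identical_scores_nothing_significant(self):
        df = pd.DataFrame(
            {
                "listener_id": [f"l{i}" for i in range(10)],
                "sex": ["male"] * 5 + ["female"] * 5,
                **{m: [20] * 10 for m in MEASURES},
            }
        )
        rep = run_full_analysis(df)
        assert not any(t.significant for t in rep.omnibus)
        assert rep.posthoc == {}
        assert not any(t.significant for t in rep.sex_contrasts)
        assert not any(c.significant for c in rep.correlations)

    def test_structure_on_default_cohort(self):
        rep = run_full_analysis(score_cohort(simulate_cohort(seed=0)))
        assert len(rep.omnibus) == 3
        assert sum(len(v) for v in rep.posthoc.values()) <= 9
        assert len(rep.sex_contrasts) == 9
        assert len(rep.correlations) >= 3
        assert all(r.alpha_adjusted == 0.017 for v in rep.posthoc.values() for r in v)

    def test_default_cohort_sign_pattern_seed0(self):
        rep = run_full_analysis(score_cohort(simulate_cohort(seed=0)))
        assert rep.omnibus[0].significant
        flags = {r.pair: r.significant for r in rep.posthoc["total"]}
        assert flags[("RH", "NR")] and flags[("RH", "UnSc")]
        assert not flags[("NR", "UnSc")]

    def test_report_serializes(self):
        rep = run_full_analysis(score_cohort(simulate_cohort(seed=1)))
        d = rep.to_dict()
        assert set(d) == {
            "normality",
            "omnibus",
            "posthoc",
            "sex_contrasts",
            "correlations",
            "correlation_followups",
        }
        assert isinstance(rep.to_json(), str)
        assert "Omnibus" in rep.to_text()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            run_full_analysis(pd.DataFrame({"RH": [1, 2], "sex": ["male", "female"]}))
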