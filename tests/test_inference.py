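import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from fixelcouple import inference as inf
from fixelcouple.synthetic_cohort import CohortGenerator, GeneratorConfig, cohort_dataframe
from conftest import make_atlas, make_subject
from test_coupling_core import pearson_oracle, subject_from_vectors


class TestBonferroni:
    @pytest.mark.parametrize(
        "base,k,expected", [(0.01, 4, 0.0025), (0.05, 1, 0.05), (0.01, 2, 0.005)]
    )
    def test_threshold(self, base, k, expected):
        assert inf.bonferroni_threshold(base, k) == expected

    def test_invalid_metric_count(self):
        with pytest.raises(ValueError):
            inf.bonferroni_threshold(0.01, 0)


class TestBhFdr:
    def test_hand_step_up_example(self):
        # by hand: 0.04*4/4=0.04; min(0.03*4/3, .04)=0.04; etc.
        q = inf.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert inf.bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_p_unchanged(self):
        assert np.allclose(inf.bh_fdr([0.2] * 5), 0.2)

    def test_matches_statsmodels_cross_check(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1.0, 37)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(inf.bh_fdr(p), q_sm, atol=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        p=st.lists(
            st.floats(1e-6, 1.0), min_size=1, max_size=30
        )
    )
    def test_order_invariant_and_idempotent(self, p):
        p = np.asarray(p)
        q = inf.bh_fdr(p)
        perm = np.argsort(p)[::-1]
        q_perm = inf.bh_fdr(p[perm])
        assert np.allclose(q_perm, q[perm], atol=1e-12)
        # adjusted values dominate raw ones, stay in (0, 1], and preserve
        # the significance ordering
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = inf.fisher_z_compare(0.4, 50, 0.4, 80)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # atanh(0.5)=0.549306, atanh(0.3)=0.309520; se=sqrt(2/97)=0.143592
        z, _ = inf.fisher_z_compare(0.5, 100, 0.3, 100)
        assert z == pytest.approx(1.6699, abs=1e-3)

    def test_antisymmetric_in_group_order(self):
        z1, p1 = inf.fisher_z_compare(0.5, 60, 0.2, 90)
        z2, p2 = inf.fisher_z_compare(0.2, 90, 0.5, 60)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            inf.fisher_z_compare(1.0, 50, 0.3, 50)


def _toy_cohort(rng, n_per_group, n_nodes=8, separation=0.0):
    atlas = make_atlas(n_nodes, dmn_nodes=(0, 1))
    subjects = []
    for group, n in n_per_group.items():
        for k in range(n):
            s = make_subject(
                rng, atlas, subject_id=f"{group}{k}", group=group, density=1.0
            )
            if separation and group == "AD":
                # push SC-FC coupling up in AD
                fc = s.matrices["FC"]
                sc = s.matrices["FD"]
                w = fc.weights + separation * (
                    sc.weights - np.nanmean(sc.weights)
                ) / np.nanstd(sc.weights)
                s.matrices["FC"] = type(fc)("FC", np.where(fc.present, w, np.nan), fc.present)
            subjects.append(s)
    return subjects


class TestPermutationTest:
    def test_add_one_p_floor(self, rng):
        subjects = _toy_cohort(
            rng, {"CN": 15, "AD": 15}, n_nodes=6, separation=5.0
        )
        res = inf.permutation_test(
            subjects, "AD", "CN", n_perm=200, seed=1, min_subjects=10
        )
        assert res.table["p"].min() >= 1.0 / 201.0
        # strongly separated edges sit at the floor
        assert (res.table["p"] == 1.0 / 201.0).any()

    def test_exhaustive_matches_brute_force_enumeration(self, rng):
        subjects = _toy_cohort(rng, {"CN": 3, "AD": 3}, n_nodes=5)
        res = inf.permutation_test(
            subjects, "AD", "CN", exhaustive=True, min_subjects=3
        )
        assert res.n_permutations == 20  # C(6,3)
        # independent brute force: correlate per edge with the covariance
        # formula over every 3/3 split
        from fixelcouple.coupling_core import stack_edges

        x, y = stack_edges(subjects, "FD")
        labels = np.array([s.group for s in subjects])
        idx_ad = np.flatnonzero(labels == "AD")
        idx_cn = np.flatnonzero(labels == "CN")

        def diff(ia, ib):
            out = np.empty(x.shape[1])
            for e in range(x.shape[1]):
                out[e] = pearson_oracle(x[ia, e], y[ia, e]) - pearson_oracle(
                    x[ib, e], y[ib, e]
                )
            return out

        observed = diff(idx_ad, idx_cn)
        count = np.zeros(x.shape[1])
        allidx = np.arange(6)
        for combo in itertools.combinations(allidx, 3):
            ia = np.asarray(combo)
            ib = np.setdiff1d(allidx, ia)
            count += np.abs(diff(ia, ib)) >= np.abs(observed) - 1e-12
        expected_p = count / 20.0
        assert np.allclose(res.table["p"].to_numpy(), expected_p)

    def test_null_p_values_are_uniform(self):
        cfg = GeneratorConfig(
            n_per_group={"CN": 30, "MCI": 30}, n_nodes=16, dmn_size=4, seed=21
        )
        cohort = CohortGenerator(cfg).generate()
        res = inf.permutation_test(
            cohort.subjects, "CN", "MCI", n_perm=300, seed=2
        )
        p = res.table["p"].dropna().to_numpy()
        assert len(p) >= 90  # edges on the shared fixel mask
        stat = sps.kstest(p, "uniform")
        assert stat.pvalue > 0.01

    def test_identical_groups_rejected(self, rng):
        subjects = _toy_cohort(rng, {"CN": 4})
        with pytest.raises(ValueError):
            inf.permutation_test(subjects, "CN", "CN")

    def test_node_level_runs_and_flags(self, rng):
        subjects = _toy_cohort(rng, {"CN": 15, "AD": 15}, n_nodes=6)
        res = inf.permutation_test(
            subjects, "AD", "CN", level="node", n_perm=150, seed=3,
            min_subjects=10,
        )
        assert len(res.table) == 6
        assert res.table["p"].between(0, 1).all()

    def test_pooled_fdr_across_comparisons(self, rng):
        subjects = _toy_cohort(rng, {"CN": 12, "MCI": 12, "AD": 12}, n_nodes=6)
        results = [
            inf.permutation_test(
                subjects, a, b, n_perm=120, seed=4, min_subjects=10
            )
            for a, b in [("AD", "CN"), ("MCI", "CN")]
        ]
        inf.pool_fdr(results)
        pooled_p = np.concatenate([r.table["p"] for r in results])
        pooled_q = np.concatenate([r.table["q_fdr"] for r in results])
        ok = np.isfinite(pooled_p)
        assert np.allclose(pooled_q[ok], inf.bh_fdr(pooled_p[ok]))


class TestAncova:
    @staticmethod
    def _simulated_frame(n_per_group, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for group, n in n_per_group.items():
            shift = {"CN": 0.0, "MCI": effect, "AD": 2 * effect}[group]
            for _ in range(n):
                age = rng.normal(73, 8)
                sex = "F" if rng.random() < 0.5 else "M"
                rows.append(
                    {
                        "group": group,
                        "age": age,
                        "sex": sex,
                        "coupling": shift
                        + 0.005 * (age - 73)
                        + rng.normal(0, 1),
                    }
                )
        return pd.DataFrame(rows)

    def test_residual_df_at_reference_sizes(self):
        df = self._simulated_frame({"CN": 225, "MCI": 142, "AD": 25}, seed=1)
        res = inf.ancova_group_effect(df, "coupling")
        assert res.df_resid == 387
        assert all(c.df_resid == 387 for c in res.contrasts)

    def test_f_matches_normal_equations_oracle(self):
        df = self._simulated_frame({"CN": 20, "MCI": 15, "AD": 10}, seed=2)
        res = inf.ancova_group_effect(df, "coupling")
        y = df["coupling"].to_numpy()
        g_mci = (df["group"] == "MCI").astype(float)
        g_ad = (df["group"] == "AD").astype(float)
        sex_f = (df["sex"] == "F").astype(float)
        ones = np.ones(len(df))
        X_full = np.column_stack([ones, g_mci, g_ad, df["age"], sex_f])
        X_red = np.column_stack([ones, df["age"], sex_f])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        f_oracle = ((rss(X_red) - rss(X_full)) / 2) / (
            rss(X_full) / (len(df) - 5)
        )
        assert res.f_stat == pytest.approx(f_oracle, abs=1e-8)

    def test_contrasts_match_dummy_coefficient_oracle(self):
        # without interactions, adjusted group-mean differences equal
        # dummy-coefficient differences from the normal equations
        df = self._simulated_frame({"CN": 30, "MCI": 25, "AD": 20}, seed=3, effect=0.5)
        res = inf.ancova_group_effect(df, "coupling")
        y = df["coupling"].to_numpy()
        g_cn = (df["group"] == "CN").astype(float)
        g_mci = (df["group"] == "MCI").astype(float)
        sex_f = (df["sex"] == "F").astype(float)
        X = np.column_stack([np.ones(len(df)), g_cn, g_mci, df["age"], sex_f])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        est = {c.pair: c.estimate for c in res.contrasts}
        assert est[("AD", "CN")] == pytest.approx(-beta[1], abs=1e-8)
        assert est[("AD", "MCI")] == pytest.approx(-beta[2], abs=1e-8)
        assert est[("CN", "MCI")] == pytest.approx(beta[1] - beta[2], abs=1e-8)

    def test_null_group_effect_p_roughly_uniform(self):
        ps = []
        for seed in range(40):
            df = self._simulated_frame({"CN": 25, "MCI": 20, "AD": 15}, seed=seed)
            ps.append(inf.ancova_group_effect(df, "coupling").p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestChiSquare:
    def test_reference_sex_by_group_table(self):
        # M:F counts per group: CN 88:137, MCI 79:63, AD 18:7
        res = inf.chi_square_independence([[88, 137], [79, 63], [18, 7]])
        assert res.chi2 == pytest.approx(16.131, abs=0.005)
        assert res.df == 2
        assert res.adjusted_residuals[0, 1] == pytest.approx(3.72, abs=0.005)

    def test_proportional_table_gives_zero(self):
        res = inf.chi_square_independence([[10, 20], [20, 40], [5, 10]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            inf.chi_square_independence([[0, 0], [3, 4]])


class TestOutcomeTests:
    def test_identical_distributions_give_high_tukey_p(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 40)
        df = pd.DataFrame(
            {
                "group": np.repeat(["CN", "MCI", "AD"], 40),
                "score": np.tile(base, 3),
            }
        )
        res = inf.outcome_group_tests(df, "score")
        assert (res.tukey["p_adj"] > 0.9).all()

    def test_tukey_matches_studentized_range_oracle(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "group": np.repeat(["CN", "MCI", "AD"], [20, 15, 10]),
                "score": np.concatenate(
                    [
                        rng.normal(0.0, 1, 20),
                        rng.normal(0.6, 1, 15),
                        rng.normal(1.4, 1, 10),
                    ]
                ),
            }
        )
        res = inf.outcome_group_tests(df, "score")
        # independent oracle: Tukey-Kramer via the studentized range
        groups = ["AD", "CN", "MCI"]  # statsmodels sorts labels
        stats = {
            g: (df.loc[df.group == g, "score"].mean(), (df.group == g).sum())
            for g in groups
        }
        n = len(df)
        k = 3
        sse = sum(
            ((df.loc[df.group == g, "score"] - stats[g][0]) ** 2).sum()
            for g in groups
        )
        mse = sse / (n - k)
        for _, row in res.tukey.iterrows():
            m1, n1 = stats[row["group1"]]
            m2, n2 = stats[row["group2"]]
            q = abs(m2 - m1) / np.sqrt(mse / 2 * (1 / n1 + 1 / n2))
            p_oracle = sps.studentized_range.sf(q, k, n - k)
            assert row["p_adj"] == pytest.approx(p_oracle, abs=1e-8)

    def test_planted_ordering_separates_all_groups(self):
        cfg = GeneratorConfig(n_nodes=12, dmn_size=3, seed=22)
        cohort = CohortGenerator(cfg).generate()
        df = cohort_dataframe(cohort)
        res = inf.outcome_group_tests(df, "mmse")
        assert (res.tukey["p_adj"] < 0.05).all()
        assert (res.ranksum["q_fdr"] < 0.05).all()

    def test_tiny_group_rejected(self):
        df = pd.DataFrame(
            {"group": ["CN", "CN", "AD"], "score": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            inf.outcome_group_tests(df, "score")
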