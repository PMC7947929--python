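import itertools

import numpy as np
import pandas as pd
import pytest

import oracles
from gmsimnet.stats import (
    adjusted_association,
    ancova_group_effect,
    bh_fdr,
    demographics_tests,
    edge_group_ttests,
    posthoc_pairwise,
    residualized_spearman,
)


def make_cohort(n_per_group=30, seed=0, groups=("HC", "MCI", "AD"),
                group_shift=None, metric_noise=1.0):
    """Null cohort with optional additive group shifts on metric_a."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for i in range(n_per_group):
            rows.append(dict(
                subject_id=f"{g}{i:03d}", group=g,
                age=rng.normal(73, 6), sex=int(rng.random() < 0.5),
                education=float(np.clip(rng.normal(16, 2.5), 8, 20)),
                metric_a=rng.normal(0, metric_noise)
                + (group_shift or {}).get(g, 0.0),
                metric_b=rng.normal(0, metric_noise),
                score_x=rng.normal(25, 3),
            ))
    return pd.DataFrame(rows)


class TestBH:
    def test_stepup_bounds_example(self):
        q, rej = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        assert rej.all()  # each p_(k) <= 0.05 * k / 4

    def test_none_rejected(self):
        _, rej = bh_fdr(np.array([0.5, 0.6, 0.7]), 0.05)
        assert not rej.any()

    def test_single_p(self):
        q, rej = bh_fdr(np.array([0.04]), 0.05)
        assert rej[0] and q[0] == pytest.approx(0.04)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        q, _ = bh_fdr(p, 0.05)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_oracle_equality_exhaustive_small_vectors(self):
        """Match step-up enumeration on a grid of p-vectors up to length 6."""
        grid = [0.001, 0.012, 0.049, 0.051, 0.2, 0.9]
        rng = np.random.default_rng(0)
        for m in range(1, 7):
            for _ in range(30):
                p = np.array(rng.choice(grid, size=m))
                q_pkg, rej_pkg = bh_fdr(p, 0.05)
                q_orc, rej_orc = oracles.bh_stepup(p, 0.05)
                np.testing.assert_allclose(q_pkg, q_orc, atol=1e-12)
                np.testing.assert_array_equal(rej_pkg, rej_orc)
        # plus every permutation of one mixed vector
        base = [0.004, 0.011, 0.03, 0.06, 0.5]
        for perm in itertools.permutations(base):
            p = np.array(perm)
            q_pkg, rej_pkg = bh_fdr(p, 0.05)
            q_orc, rej_orc = oracles.bh_stepup(p, 0.05)
            np.testing.assert_allclose(q_pkg, q_orc, atol=1e-12)
            np.testing.assert_array_equal(rej_pkg, rej_orc)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.5]), 0.05)


class TestDemographics:
    def test_identical_groups_zero_statistics(self):
        df = make_cohort(10, seed=3)
        base = df[df.group == "HC"].copy()
        parts = []
        for g in ("HC", "MCI", "AD"):
            part = base.copy()
            part["group"] = g
            parts.append(part)
        same = pd.concat(parts, ignore_index=True)
        res = demographics_tests(same, score_columns=("score_x",))
        kw = res[res.test == "kruskal"].iloc[0]
        chi = res[res.test == "chi2"].iloc[0]
        assert kw.statistic == pytest.approx(0.0, abs=1e-9)
        assert chi.statistic == pytest.approx(0.0, abs=1e-9)

    def test_balanced_contingency_chi2_zero(self):
        rows = []
        for g in ("HC", "MCI", "AD"):
            rows += [dict(subject_id=f"{g}{i}", group=g, age=70.0,
                          education=16.0, sex=i % 2) for i in range(20)]
        df = pd.DataFrame(rows)
        res = demographics_tests(df, continuous=(), score_columns=())
        assert res.iloc[0].statistic == pytest.approx(0.0)

    def test_kruskal_matches_rank_oracle(self):
        samples = ([1, 2, 3], [4, 5, 6], [7, 8, 9])
        rows = []
        for g, s in zip(("HC", "MCI", "AD"), samples):
            rows += [dict(subject_id=f"{g}{i}", group=g, age=70.0,
                          education=16.0, sex=0, score_x=float(v))
                     for i, v in enumerate(s)]
        df = pd.DataFrame(rows)
        res = demographics_tests(df, continuous=(), categorical=(),
                                 score_columns=("score_x",))
        h_expected = oracles.kruskal_h([np.array(s, float) for s in samples])
        assert res.iloc[0].statistic == pytest.approx(h_expected, abs=1e-10)
        assert h_expected == pytest.approx(7.2)

    def test_small_group_informative_error(self):
        df = make_cohort(5)
        df = df[~((df.group == "AD") & (df.subject_id != "AD000"))]
        with pytest.raises(ValueError, match="AD"):
            demographics_tests(df)


class TestAncova:
    def test_planted_shift_detected(self):
        df = make_cohort(20, seed=1, group_shift={"AD": 2.0})
        res = ancova_group_effect(df, ["metric_a", "metric_b"])
        row = res[res.term == "metric_a"].iloc[0]
        assert row.significant and row.q < 0.05
        assert not res[res.term == "metric_b"].iloc[0].significant

    def test_null_type1_rate_controlled(self):
        hits = 0
        total = 0
        for seed in range(20):
            df = make_cohort(20, seed=100 + seed)
            res = ancova_group_effect(df, ["metric_a", "metric_b"])
            hits += int(res.significant.sum())
            total += len(res)
        # BH at 0.05 over null metrics: rejection rate well under nominal
        assert hits / total <= 0.05 + 1.645 * np.sqrt(0.05 * 0.95 / total)

    def test_covariate_only_signal_not_attributed_to_group(self):
        df = make_cohort(40, seed=5)
        df["metric_a"] = 0.5 * df["age"] + np.random.default_rng(5).normal(
            0, 1, len(df))
        res = ancova_group_effect(df, ["metric_a"])
        assert res.iloc[0].p > 0.05

    def test_collinear_covariates_named(self):
        df = make_cohort(10, seed=0)
        df["age2"] = df["age"] * 1.0
        with pytest.raises(ValueError, match="age"):
            ancova_group_effect(df, ["metric_a"],
                                covariates=("age", "age2", "sex"))

    def test_result_carries_n_after_listwise_drop(self):
        df = make_cohort(20, seed=2)
        df.loc[df.index[:7], "metric_a"] = np.nan
        res = ancova_group_effect(df, ["metric_a"])
        assert res.iloc[0].n == len(df) - 7


class TestPosthoc:
    def test_ordered_means_all_contrasts_significant(self):
        df = make_cohort(25, seed=7,
                         group_shift={"HC": 0.0, "MCI": 2.0, "AD": 4.0},
                         metric_noise=1.0)
        res = posthoc_pairwise(df, ["metric_a"])
        assert res.significant.all()
        # "ga-gb" estimate is gb minus ga in clinical order HC < MCI < AD
        est = dict(zip(res.contrast, res.estimate))
        assert est["HC-AD"] > est["HC-MCI"] > 0
        assert est["MCI-AD"] > 0

    def test_single_shifted_group_two_contrasts(self):
        df = make_cohort(25, seed=42, group_shift={"AD": 3.0})
        res = posthoc_pairwise(df, ["metric_a"])
        sig = {r.contrast: r.significant for r in res.itertuples()}
        assert sig["HC-AD"] and sig["MCI-AD"]
        assert not sig["HC-MCI"]

    def test_null_groups_nominal_rate(self):
        n_sig = 0
        n_tot = 0
        for seed in range(10):
            df = make_cohort(20, seed=300 + seed)
            res = posthoc_pairwise(df, ["metric_a", "metric_b"])
            n_sig += int((res.p < 0.05).sum())
            n_tot += len(res)
        assert n_sig / n_tot < 0.12  # nominal 5% plus simulation slack


class TestEdgeTtests:
    def _edges(self, n_per_group, n_edges, seed, shift_edges=0, shift=0.0,
               groups=("HC", "AD")):
        df = make_cohort(n_per_group, seed=seed, groups=groups)
        rng = np.random.default_rng(seed + 1)
        cols = {}
        for e in range(n_edges):
            v = rng.normal(0, 1, len(df))
            if e < shift_edges:
                v = v + shift * (df.group == "AD").values
            cols[f"edge_{e:04d}"] = v
        return pd.concat([df, pd.DataFrame(cols, index=df.index)], axis=1)

    def test_null_edges_no_discoveries(self):
        df = self._edges(30, 500, seed=11)
        res = edge_group_ttests(df, [f"edge_{e:04d}" for e in range(500)])
        assert res.significant.mean() <= 0.01

    def test_shifted_edges_recovered_with_sign(self):
        df = self._edges(30, 500, seed=12, shift_edges=50, shift=1.5)
        res = edge_group_ttests(df, [f"edge_{e:04d}" for e in range(500)])
        shifted = res[res.term.isin([f"edge_{e:04d}" for e in range(50)])]
        assert shifted.significant.mean() > 0.5
        assert (shifted[shifted.significant].direction == "increase").all()

    def test_swapping_labels_flips_t_signs(self):
        df = self._edges(15, 20, seed=13)
        res1 = edge_group_ttests(df, [f"edge_{e:04d}" for e in range(20)])
        swapped = df.copy()
        swapped["group"] = swapped["group"].map({"HC": "AD", "AD": "HC"})
        res2 = edge_group_ttests(swapped,
                                 [f"edge_{e:04d}" for e in range(20)])
        # same subjects with HC/AD labels exchanged: every t flips sign
        np.testing.assert_allclose(res1.statistic.values,
                                   -res2.statistic.values, atol=1e-9)

    def test_families_are_per_group_pair(self):
        df = self._edges(15, 10, seed=14, groups=("HC", "MCI", "AD"))
        res = edge_group_ttests(df, [f"edge_{e:04d}" for e in range(10)])
        assert set(res.contrast) == {"HC-MCI", "HC-AD", "MCI-AD"}
        assert (res.groupby("contrast").size() == 10).all()


class TestAdjustedAssociation:
    def test_monotone_outcome_rho_one(self):
        df = make_cohort(20, seed=20)
        df["outcome"] = np.exp(df["metric_a"])  # monotone in the metric
        df["age"] = 70.0  # constant covariate: residualization only centers
        rho, p, n = residualized_spearman(df, "metric_a", "outcome",
                                          covariates=("age",))
        assert rho == pytest.approx(1.0)

    def test_confound_driven_outcome_rho_near_zero(self):
        rng = np.random.default_rng(31)
        df = make_cohort(67, seed=31)
        df["metric_a"] = 0.8 * df["age"] + rng.normal(0, 1, len(df))
        df["outcome"] = 0.8 * df["age"] + rng.normal(0, 1, len(df))
        rho, _, n = residualized_spearman(df, "metric_a", "outcome")
        assert n >= 200
        assert abs(rho) < 0.1

    def test_negative_slope_recovered(self):
        rng = np.random.default_rng(22)
        df = make_cohort(25, seed=22)
        df["tau_like"] = -2.0 * df["metric_a"] + rng.normal(0, 1, len(df))
        res = adjusted_association(df, "metric_a", "tau_like")
        row = res[res.group == "AD"].iloc[0]
        assert row.rho < 0 and row.p < 0.05

    def test_insufficient_cases_error(self):
        df = make_cohort(3, seed=23)
        with pytest.raises(ValueError, match="insufficient"):
            residualized_spearman(df[df.group == "AD"], "metric_a", "score_x")

    def test_underpowered_stratum_nan_but_n_recorded(self):
        df = make_cohort(30, seed=24)
        df.loc[df.group == "AD", "score_x"] = np.nan
        res = adjusted_association(df, "metric_a", "score_x")
        ad = res[res.group == "AD"].iloc[0]
        assert np.isnan(ad.rho) and ad.n == 0

    def test_spearman_matches_allpairs_oracle(self):
        rng = np.random.default_rng(25)
        x = rng.normal(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 1, 40)
        df = pd.DataFrame(dict(x=x, y=y, c=np.zeros(40)))
        df["c"] = rng.normal(0, 1, 40)
        rho, _, _ = residualized_spearman(df, "x", "y", covariates=("c",))
        # oracle: residualize by hand, all-pairs rank correlation
        X = np.column_stack([np.ones(40), df["c"]])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert rho == pytest.approx(oracles.spearman_rho(rx, ry), abs=1e-12)
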