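"""Rank statistics, effect sizes, OLS layer and the scenario driver."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qt1bbb import CohortSpec, simulate_cohort
from qt1bbb.cohort_stats import (
    classify_memory,
    compare_rois,
    dunn_posthoc,
    fit_linear_model,
    glass_delta,
    kruskal_wallis,
    run_group_analyses,
)


# -------------------------------------------------------------- oracles

def rank_with_ties(x):
    """Mid-rank assignment, written independently of scipy."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kw_h_oracle(groups):
    """Tie-corrected H from first principles."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rank_with_ties(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts)
    return h / (1.0 - tie / (n**3 - n)) if tie else h


def mann_whitney_z_oracle(a, b):
    """Large-sample rank-sum z with tie correction (Mann-Whitney route)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    n = n1 + n2
    ranks = rank_with_ties(np.concatenate([a, b]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    return (u - n1 * n2 / 2.0) / np.sqrt(var)


def ols_normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


# -------------------------------------------------------- kruskal-wallis

class TestKruskalWallis:
    def test_hand_ranked_two_group_value(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27.0 / 7.0, rel=1e-12)

    def test_three_singletons(self):
        h, _ = kruskal_wallis([[1], [2], [3]])
        assert h == pytest.approx(2.0, rel=1e-12)

    def test_all_identical_defined_as_null(self):
        assert kruskal_wallis([[5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_first_principles_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 6, rng.integers(3, 9)).astype(float)
                  for _ in range(rng.integers(2, 5))]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kw_h_oracle(groups), rel=1e-10)


class TestDunnPosthoc:
    def test_identical_groups_give_adjusted_p_one(self):
        p, _ = dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert p.iloc[0, 1] == 1.0

    def test_bonferroni_capping_at_one(self):
        # three groups -> 3 comparisons; any raw p > 1/3 must cap at 1
        rng = np.random.default_rng(0)
        p, _ = dunn_posthoc([rng.normal(size=6) for _ in range(3)])
        assert float(p.values.max()) <= 1.0
        assert np.all(np.diag(p.values) == 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_group_z_matches_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, 8).astype(float)
        b = rng.integers(0, 10, 11).astype(float)
        _, z = dunn_posthoc([a, b])
        assert abs(z.iloc[0, 1]) == pytest.approx(abs(mann_whitney_z_oracle(a, b)),
                                                  rel=1e-10)

    def test_holm_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc=m, size=7) for m in (0.0, 0.3, 1.0)]
        p_bonf, _ = dunn_posthoc(groups, "bonferroni")
        p_holm, _ = dunn_posthoc(groups, "holm")
        off = ~np.eye(3, dtype=bool)
        assert np.all(p_holm.values[off] <= p_bonf.values[off] + 1e-15)

    def test_chi_square_approximation_consistent_with_exact_permutation(self):
        """On tiny samples the chi-square omnibus p tracks the exact
        permutation distribution of H (consistency band, not equality)."""
        groups = [[1.0, 4.0, 2.5], [3.0, 5.0], [6.0, 0.5]]
        h_obs, p_chi2 = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = total = 0
        for perm in itertools.permutations(range(len(pooled))):
            arr = pooled[list(perm)]
            gs, start = [], 0
            for s in sizes:
                gs.append(arr[start : start + s])
                start += s
            if kw_h_oracle(gs) >= h_obs - 1e-12:
                count += 1
            total += 1
        p_exact = count / total
        assert abs(p_chi2 - p_exact) < 0.12


class TestGlassDelta:
    def test_equal_means_give_zero(self):
        d, large = glass_delta([1.0, 2.0, 3.0], [0.0, 2.0, 4.0])
        assert d == 0.0 and not large

    def test_hand_computed_value_and_large_flag(self):
        # reference {0,1,2}: mean 1, sample SD 1; ROI mean 2 -> delta 1
        d, large = glass_delta([2.0, 2.0, 2.0], [0.0, 1.0, 2.0])
        assert d == pytest.approx(1.0) and large

    def test_sign_flips_when_roi_reflected_about_reference_mean(self):
        ref = [0.0, 1.0, 2.0]
        roi = np.array([2.0, 2.5, 3.0])
        d1, _ = glass_delta(roi, ref)
        d2, _ = glass_delta(2.0 * np.mean(ref) - roi, ref)
        assert d2 == pytest.approx(-d1, rel=1e-12)

    def test_zero_reference_sd_rejected(self):
        with pytest.raises(ValueError):
            glass_delta([1.0, 2.0], [5.0, 5.0, 5.0])

    def test_corrected_estimator_nearly_unbiased_over_replicates(self):
        """With the small-sample correction the mean estimate sits within
        0.08 of the true standardized difference for d in {0, 0.5, 1.5}
        at reference n = 14 (the raw estimator carries the known E[1/s]
        bias of about 6.5% at this sample size)."""
        rng = np.random.default_rng(2024)
        for d_true in (0.0, 0.5, 1.5):
            est = [
                glass_delta(rng.normal(d_true, 1.0, 14), rng.normal(0.0, 1.0, 14),
                            small_sample_correction=True)[0]
                for _ in range(2000)
            ]
            assert abs(np.mean(est) - d_true) < 0.08

    def test_correction_rescales_raw_value_by_j_factor(self):
        from scipy.special import gammaln

        roi, ref = [2.0, 3.0, 4.0], [0.0, 1.0, 2.0, 3.0]
        raw, _ = glass_delta(roi, ref)
        corr, _ = glass_delta(roi, ref, small_sample_correction=True)
        m = len(ref) - 1
        j = np.exp(gammaln(m / 2) - gammaln((m - 1) / 2)) / np.sqrt(m / 2)
        assert corr == pytest.approx(raw * j, rel=1e-12)


class TestLinearModel:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows)

    def test_exact_fit_on_noiseless_line(self):
        t = self._table(
            [{"value": 1 + 2 * d, "duration": d, "latency": 30.0, "roi": "cortex"}
             for d in (1.0, 2.0, 5.0, 9.0)]
        )
        res = fit_linear_model(t, terms=("duration",), roi_term=False)
        assert res.params["Intercept"] == pytest.approx(1.0, abs=1e-10)
        assert res.params["duration"] == pytest.approx(2.0, abs=1e-10)

    def test_interaction_coefficient_reads_slope_difference(self):
        rows = []
        for d in (2.0, 10.0, 20.0, 40.0):
            rows.append({"value": 0.5 + 0.001 * d, "duration": d, "roi": "cortex"})
            rows.append({"value": 0.6 + 0.002 * d, "duration": d, "roi": "piriform"})
        res = fit_linear_model(self._table(rows), terms=("duration",), interactions=True)
        inter = [k for k in res.params.index if "duration:" in k and "piriform" in k]
        assert res.params[inter[0]] == pytest.approx(0.001, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_coefficients_match_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rois = rng.choice(["cortex", "piriform", "amygdala"], 20)
        t = pd.DataFrame(
            {
                "value": rng.normal(size=20),
                "duration": rng.uniform(2, 44, 20),
                "latency": rng.uniform(18, 266, 20),
                "roi": rois,
            }
        )
        res = fit_linear_model(t)
        # design matrix built by hand: intercept, duration, latency, dummies
        X = np.column_stack(
            [np.ones(20), t["duration"], t["latency"]]
            + [(rois == r).astype(float) for r in ("amygdala", "piriform")]
        )
        beta = ols_normal_equations(X, t["value"].to_numpy())
        got = res.params
        assert got["Intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert got["duration"] == pytest.approx(beta[1], abs=1e-8)
        assert got["latency"] == pytest.approx(beta[2], abs=1e-8)

    def test_rank_deficiency_reported_with_aliased_columns(self):
        t = self._table(
            [{"value": v, "duration": d, "latency": 2 * d, "roi": "cortex"}
             for v, d in zip((1.0, 2.0, 3.0, 4.0), (1.0, 2.0, 3.0, 4.0))]
        )
        with pytest.raises(ValueError, match="aliased"):
            fit_linear_model(t)

    def test_duration_slope_recovery_rate(self):
        """Injected slope recovered within 2 SE in >= 93% of replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            d = rng.uniform(2, 44, 37)
            y = 0.02 + 0.001 * d + rng.normal(0, 0.02, 37)
            t = pd.DataFrame({"value": y, "duration": d, "roi": "cortex"})
            res = fit_linear_model(t, terms=("duration",), roi_term=False)
            hits += abs(res.params["duration"] - 0.001) < 2 * res.bse["duration"]
        assert hits / n_rep >= 0.93


class TestClassifyMemory:
    @pytest.mark.parametrize("score,expected", [(89.0, "impaired"), (90.0, "unimpaired"),
                                                (110.0, "unimpaired"), (89.999, "impaired")])
    def test_strict_cutoff_at_90(self, score, expected):
        assert classify_memory(score) == expected

    def test_missing_score_yields_none(self):
        assert classify_memory(float("nan")) is None
        assert classify_memory(None) is None


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortSpec(seed=11))


class TestScenarioDriver:

    def test_unknown_side_absent_from_ipsilateral(self, cohort):
        res = run_group_analyses(cohort, scenarios=("ipsilateral",))
        unknown_ids = set(cohort.loc[cohort["side"] == "unknown", "subject"])
        known = cohort[cohort["side"].isin(["left", "right"])]
        n_expected = known[known["kind"] == "ni"]
        n_expected = n_expected[n_expected["hemisphere"] == n_expected["side"]]
        tab = res.tables["ipsilateral"]
        assert int(tab[tab["kind"] == "ni"]["n"].iloc[0]) == len(n_expected)
        assert unknown_ids  # cohort does contain unknown-side subjects

    def test_results_invariant_to_row_order(self, cohort):
        shuffled = cohort.sample(frac=1.0, random_state=3).reset_index(drop=True)
        r1 = run_group_analyses(cohort)
        r2 = run_group_analyses(shuffled)
        for name in r1.tables:
            pd.testing.assert_frame_equal(r1.tables[name], r2.tables[name])

    def test_group_comparison_reports_all_rois_vs_cortex(self, cohort):
        res = run_group_analyses(cohort, scenarios=("group_roi_comparison",))
        tab = res.tables["group_roi_comparison"]
        for group in ("TLE", "ETLE"):
            sub = tab[(tab["group"] == group) & (tab["kind"] == "ni")]
            assert set(sub["roi"]) == {"hippocampus", "amygdala", "piriform"}
        assert ((tab["dunn_p"] >= 0) & (tab["dunn_p"] <= 1)).all()

    def test_duration_regression_recovers_injected_slope_sign(self, cohort):
        res = run_group_analyses(cohort, scenarios=("duration_regression",))
        tab = res.tables["duration_regression"]
        main = tab[(tab["kind"] == "ni") & (tab["model"] == "main")
                   & (tab["term"] == "duration")]
        assert main["beta"].iloc[0] > 0
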