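import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from dyadsync.io_core import STIMULI, AnalysisConfig, CovariateRecord, ValidationError
from dyadsync.stats import (
    bh_adjust,
    code_parent_ratio,
    cohens_d_from_samples,
    cohens_d_pooled,
    mann_whitney,
    power_two_sample,
    run_condition_analysis,
    run_covariate_analysis,
    run_stimulus_analysis,
    spearman,
)


def exact_mw_p(a, b, sided="two-sided"):
    """Exact Mann-Whitney p by enumerating every group labeling."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_of(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y) + \
            0.5 * sum(1 for x in sample_a for y in sample_b if x == y)

    u_obs = u_of(a, b)
    n2 = len(b)
    mid = n1 * n2 / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_of(ga, gb)
        if sided == "two-sided":
            hit = abs(u - mid) >= abs(u_obs - mid) - 1e-12
        elif sided == "greater":
            hit = u >= u_obs - 1e-12
        else:
            hit = u <= u_obs + 1e-12
        count += hit
        total += 1
    return count / total


class TestMannWhitney:
    def test_disjoint_small_samples_exact(self):
        # all C(6,3)=20 labelings; the observed split is one of two extremes
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(exact_mw_p([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle_at_small_n(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=4)
        b = rng.normal(1.0, size=5)
        for sided in ("two-sided", "greater", "less"):
            _, p = mann_whitney(a, b, sided)
            assert p == pytest.approx(exact_mw_p(a, b, sided), abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_one_sided_no_larger_than_two_sided(self, rng):
        a = rng.normal(1.0, size=30)
        b = rng.normal(0.0, size=25)
        _, p2 = mann_whitney(a, b, "two-sided")
        _, p1 = mann_whitney(a, b, "greater")
        assert p1 <= p2

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestBhAdjust:
    def test_single_p_with_family_of_one_unchanged(self):
        assert bh_adjust([0.03], m=1)[0] == pytest.approx(0.03)

    def test_partial_family_uses_supplied_ranks_with_full_divisor(self):
        adj = bh_adjust([0.001, 0.004], m=10)
        np.testing.assert_allclose(adj, [0.01, 0.02])

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.uniform(size=15)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_matches_statsmodels_for_complete_families(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=20)
        adj = bh_adjust(p, m=20)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_step_up_properties_hold_for_any_input(self, p):
        adj = bh_adjust(p)
        p_arr = np.asarray(p)
        assert ((adj >= p_arr - 1e-12) & (adj <= 1.0 + 1e-15)).all()
        order = np.argsort(p_arr, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        # enlarging the assumed family can only make values less significant
        adj_wider = bh_adjust(p, m=len(p) + 10)
        assert (adj_wider >= adj - 1e-12).all()


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert cohens_d_pooled(1.0, 0.5, 10, 1.0, 0.7, 12) == 0.0

    def test_summary_stats_equal_raw_samples(self, rng):
        a = rng.normal(0.0, 1.0, size=40)
        b = rng.normal(0.5, 1.3, size=55)
        d_raw = cohens_d_from_samples(a, b)
        d_sum = cohens_d_pooled(a.mean(), a.std(ddof=1), a.size,
                                b.mean(), b.std(ddof=1), b.size)
        assert d_raw == pytest.approx(d_sum, abs=1e-12)

    def test_zero_pooled_sd_with_unequal_means_is_an_error(self):
        with pytest.raises(ValidationError):
            cohens_d_pooled(0.0, 0.0, 5, 1.0, 0.0, 5)


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = spearman(x, x ** 2)
        assert rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_p_matches_exact_permutation_oracle_at_n5(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rho_obs, _ = spearman(x, y)
        rx = sstats.rankdata(x)
        hits = total = 0
        for perm in itertools.permutations(sstats.rankdata(y)):
            rho = np.corrcoef(rx, perm)[0, 1]
            hits += abs(rho) >= abs(rho_obs) - 1e-12
            total += 1
        p_exact = hits / total
        res = sstats.spearmanr(x, y)
        # scipy's t approximation should sit near the exact permutation p
        assert res.pvalue == pytest.approx(p_exact, abs=0.1)

    def test_constant_vector_returns_missing(self):
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and np.isnan(p)


class TestPower:
    def test_null_limit_equals_alpha(self):
        assert power_two_sample(1e-9, 130, 0.05) == pytest.approx(0.05, abs=1e-4)

    def test_analytic_and_monte_carlo_agree(self):
        analytic = power_two_sample(0.5, 60, 0.05)
        mc = power_two_sample(0.5, 60, 0.05, method="monte_carlo", n_reps=10_000, seed=2)
        se = np.sqrt(analytic * (1 - analytic) / 10_000)
        assert abs(mc - analytic) <= 3 * se


class TestParentRatio:
    @pytest.mark.parametrize("choice,score", [
        ("0:5", 0.0), ("1:4", 0.2), ("2:3", 0.4), ("3:2", 0.6), ("4:1", 0.8), ("5:0", 1.0),
    ])
    def test_coding(self, choice, score):
        assert code_parent_ratio(choice) == pytest.approx(score)

    def test_unknown_option_rejected(self):
        for bad in ("6:0", "2:2", "a:b", ""):
            with pytest.raises(ValidationError):
                code_parent_ratio(bad)


# --------------------------------------------------------------------------
# Campaign-level tests on synthetic synchrony tables
# --------------------------------------------------------------------------


def synthetic_table(rng, n_dyads=24, effect_channels=(), effect=0.3,
                    effect_stimuli=None, pairing="true"):
    """Directly simulated MCC2 table: baseline Beta-like noise, with a TOG
    shift on selected channels (optionally restricted to stimuli)."""
    rows = []
    for d in range(n_dyads):
        for cond in ("SEP", "TOG"):
            for ch in range(1, 21):
                for stim in STIMULI:
                    base = rng.normal(0.05, 0.1)
                    bump = 0.0
                    if cond == "TOG" and ch in effect_channels and (
                        effect_stimuli is None or stim in effect_stimuli
                    ):
                        bump = effect
                    rows.append({
                        "dyad_id": f"d{d + 1:02d}", "condition": cond, "channel": ch,
                        "stimulus": stim, "mcc2": np.clip(base + bump, -1, 1),
                        "best_lag_s": 0.0, "n_trials_used": 3, "pairing": pairing,
                    })
    return pd.DataFrame(rows)


class TestConditionAnalysis:
    def test_designed_effect_detected_and_nulls_clean(self):
        rng = np.random.default_rng(8)
        table = synthetic_table(rng, effect_channels=(3, 7, 11, 13))
        res = run_condition_analysis(table)
        sig = {r.scope["channel"] for r in res if r.significant}
        assert sig == {3, 7, 11, 13}

    def test_reported_n_equals_rows_in_scope(self):
        rng = np.random.default_rng(9)
        table = synthetic_table(rng, n_dyads=10)
        table.loc[table.sample(frac=0.1, random_state=1).index, "mcc2"] = np.nan
        res = run_condition_analysis(table)
        for r in res:
            ch = r.scope["channel"]
            rows = table[(table.channel == ch) & (table.pairing == "true")]
            for cond in ("SEP", "TOG"):
                n_expected = rows[(rows.condition == cond)].mcc2.notna().sum()
                assert r.group_summaries[cond][2] == n_expected

    def test_untestable_channel_flagged(self):
        rng = np.random.default_rng(10)
        table = synthetic_table(rng, n_dyads=4)
        table.loc[(table.channel == 5) & (table.condition == "TOG"), "mcc2"] = np.nan
        res = run_condition_analysis(table)
        r5 = next(r for r in res if r.scope["channel"] == 5)
        assert not r5.testable


class TestStimulusAnalysis:
    def test_only_coupled_stimuli_flagged(self):
        rng = np.random.default_rng(11)
        carriers = ("infant_laughter", "adult_laughter", "static")
        table = synthetic_table(rng, effect_channels=(7,), effect=0.35,
                                effect_stimuli=carriers)
        res = run_stimulus_analysis(table, [7])
        flagged = {r.scope["stimulus"] for r in res if r.significant}
        assert flagged == set(carriers)

    def test_one_sided_p_no_larger_than_two_sided(self):
        rng = np.random.default_rng(12)
        table = synthetic_table(rng, effect_channels=(7,), effect=0.15)
        res = run_stimulus_analysis(table, [7])
        sub = table[(table.channel == 7) & (table.pairing == "true")]
        for r in res:
            rows = sub[sub.stimulus == r.scope["stimulus"]]
            sep = rows[rows.condition == "SEP"].mcc2
            tog = rows[rows.condition == "TOG"].mcc2
            _, p2 = mann_whitney(sep, tog, "two-sided")
            assert r.p_raw <= p2 + 1e-12


def _covariates(rng, n_dyads, ratio_effect=0.0, parity_shift=0.0):
    from dyadsync.io_core import RATIO_SCORES
    recs, bumps = [], {}
    for i in range(n_dyads):
        m_ratio = float(rng.choice(RATIO_SCORES))
        f_ratio = float(rng.choice(RATIO_SCORES))
        parity = "primiparous" if rng.random() < 0.5 else "multiparous"
        recs.append(CovariateRecord(f"d{i + 1:02d}", 30.0 + rng.normal(0, 3),
                                    33.0 + rng.normal(0, 3), parity, m_ratio, f_ratio))
        bump = ratio_effect * (m_ratio + f_ratio) / 2
        if parity == "primiparous":
            bump += parity_shift
        bumps[f"d{i + 1:02d}"] = bump
    return recs, bumps


class TestCovariateAnalysis:
    def _table_with_bumps(self, rng, bumps):
        table = synthetic_table(rng, n_dyads=len(bumps))
        table["mcc2"] += table.dyad_id.map(bumps).fillna(0.0)
        return table

    def test_ratio_effect_recovered_with_positive_rho(self):
        signs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            covs, bumps = _covariates(rng, 24, ratio_effect=0.12)
            table = self._table_with_bumps(rng, bumps)
            res = run_covariate_analysis(table, covs, [3, 7, 11, 13])
            pooled = next(r for r in res if r.test == "spearman"
                          and r.scope["channel"] == "all-channels"
                          and r.scope["covariate"] == "average_parent_ratio")
            signs.append(pooled.statistic > 0)
        assert np.mean(signs) >= 0.95

    def test_shuffled_covariate_centred_on_zero(self):
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            covs, bumps = _covariates(rng, 24, ratio_effect=0.0)
            table = self._table_with_bumps(rng, bumps)
            res = run_covariate_analysis(table, covs, [])
            pooled = next(r for r in res if r.test == "spearman"
                          and r.scope["covariate"] == "average_parent_ratio")
            rhos.append(pooled.statistic)
        assert abs(np.mean(rhos)) < 0.05

    def test_parity_shift_detected_in_most_seeds(self):
        detected = []
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            covs, bumps = _covariates(rng, 24, parity_shift=0.08)  # ~d=0.8 vs 0.1 SD
            table = self._table_with_bumps(rng, bumps)
            res = run_covariate_analysis(table, covs, [])
            pooled = next(r for r in res if r.scope.get("covariate") == "parity")
            detected.append(pooled.testable and pooled.p_raw < 0.05)
        assert np.mean(detected) >= 0.7
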