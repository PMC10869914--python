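"""Error metrics, rank tests (with enumeration oracles), Bland-Altman."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ppgresp as pr
from ppgresp.evaluation import EvaluationPair


def _pair(diffs, ref=20.0):
    d = np.asarray(diffs, float)
    return EvaluationPair(ref + d, np.full(d.size, ref))


def exact_ranksum_p(a, b):
    """Oracle: two-sided exact Mann-Whitney p by enumerating assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(a)

    def u_stat(group_a, group_b):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in group_a for y in group_b)

    u_obs = u_stat(a, b)
    mu = len(a) * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def kruskal_by_definition(groups):
    """Oracle: H from mid-ranks of the pooled sample, with tie correction."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n_tot = pooled.size
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - (n_tot + 1) / 2) ** 2
        start += g.size
    h *= 12.0 / (n_tot * (n_tot + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n_tot**3 - n_tot)
    return h / tie


class TestErrorMetrics:
    def test_identity_gives_zero(self):
        p = _pair([0.0, 0.0, 0.0])
        assert pr.rmse(p) == 0.0
        assert pr.mae(p) == 0.0

    def test_unit_residuals(self):
        assert pr.rmse(_pair([1, -1, 1, -1])) == pytest.approx(1.0)

    def test_hand_computed_values(self):
        p = _pair([3.0, 0.0, -4.0])
        assert pr.rmse(p) == pytest.approx(np.sqrt(25.0 / 3.0))
        assert pr.mae(p) == pytest.approx(7.0 / 3.0)

    def test_constant_residual_mae(self):
        assert pr.mae(_pair([-2.5] * 6)) == pytest.approx(2.5)

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=40),
    )
    @settings(deadline=None, max_examples=200)
    def test_rmse_dominates_mae(self, diffs):
        p = _pair(diffs)
        assert pr.rmse(p) >= pr.mae(p) - 1e-12


class TestCompareMethods:
    def test_exact_ranksum_small_groups(self):
        report = pr.compare_methods(
            {"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6])}
        )
        # single pair: Bonferroni multiplier is 1
        assert report.pairwise_p("a", "b") == pytest.approx(0.100)
        assert report.pairwise_p("a", "b") == pytest.approx(
            exact_ranksum_p([1, 2, 3], [4, 5, 6])
        )

    def test_identical_groups_capped_at_one(self):
        report = pr.compare_methods(
            {"a": np.array([1.0, 2, 3]), "b": np.array([1.0, 2, 3])}
        )
        assert report.pairwise_p("a", "b") == 1.0

    def test_h_statistic_matches_definition(self):
        groups = {
            "a": np.array([1.0, 2.0]),
            "b": np.array([3.0, 4.0]),
            "c": np.array([5.0, 6.0]),
        }
        report = pr.compare_methods(groups)
        assert report.df == 2
        assert report.H == pytest.approx(
            kruskal_by_definition(list(groups.values()))
        )

    def test_bonferroni_multiplier_counts_pairs(self):
        rng = np.random.default_rng(0)
        groups = {f"m{i}": rng.normal(i, 1, 10) for i in range(4)}
        report = pr.compare_methods(groups)
        assert len(report.pairwise) == 6
        raw = stats.mannwhitneyu(
            groups["m0"], groups["m1"], alternative="two-sided"
        ).pvalue
        assert report.pairwise_p("m0", "m1") == pytest.approx(min(1.0, raw * 6))

    def test_short_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            report = pr.compare_methods(
                {"a": np.arange(5.0), "b": np.arange(5.0) + 1, "c": np.array([1.0])}
            )
        assert report.df == 1

    def test_single_method_returns_none(self):
        with pytest.warns(UserWarning):
            assert pr.compare_methods({"a": np.arange(5.0)}) is None

    def test_null_uniform_p(self):
        # permutation sanity: under exchangeability the global p is ~Uniform
        rng = np.random.default_rng(123)
        alpha_hits = 0
        reps = 400
        for _ in range(reps):
            vals = rng.normal(size=20)
            groups = {"a": vals[:10], "b": vals[10:]}
            rep = pr.compare_methods(groups)
            if rep.p_global < 0.05:
                alpha_hits += 1
        lo, hi = stats.binom.interval(0.999, reps, 0.05)
        assert lo <= alpha_hits <= hi


class TestBlandAltman:
    def test_identical_pairs(self):
        ba = pr.bland_altman(_pair([0.0, 0.0, 0.0]))
        assert ba.bias == 0.0 and ba.sd_diff == 0.0
        assert (ba.loa_lo, ba.loa_hi) == (0.0, 0.0)
        assert ba.equality_line_contained

    def test_closed_form_example(self):
        ba = pr.bland_altman(_pair([0.0, 1.0, 2.0]))
        t975 = stats.t.ppf(0.975, 2)  # 4.3027
        assert ba.bias == pytest.approx(1.0, abs=1e-9)
        assert ba.sd_diff == pytest.approx(1.0, abs=1e-9)
        assert ba.loa_lo == pytest.approx(-0.96, abs=1e-9)
        assert ba.loa_hi == pytest.approx(2.96, abs=1e-9)
        assert ba.ci_lo == pytest.approx(1 - t975 / np.sqrt(3), abs=1e-9)
        assert ba.ci_hi == pytest.approx(1 + t975 / np.sqrt(3), abs=1e-9)

    def test_zero_variance_constant_diff(self):
        ba = pr.bland_altman(_pair([1.0] * 4))
        assert (ba.loa_lo, ba.loa_hi) == (1.0, 1.0)
        assert (ba.ci_lo, ba.ci_hi) == (1.0, 1.0)
        assert not ba.equality_line_contained

    def test_bias_is_mean_difference(self):
        rng = np.random.default_rng(8)
        est, ref = rng.normal(20, 3, 50), rng.normal(20, 3, 50)
        ba = pr.bland_altman(EvaluationPair(est, ref))
        assert ba.bias == pytest.approx(est.mean() - ref.mean())

    def test_normal_ci_variant_narrower(self):
        p = _pair([0.0, 1.0, 2.0, 0.5])
        t_ci = pr.bland_altman(p, ci_method="t")
        n_ci = pr.bland_altman(p, ci_method="normal")
        assert n_ci.ci_hi - n_ci.ci_lo < t_ci.ci_hi - t_ci.ci_lo

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            pr.bland_altman(_pair([1.0]))


@pytest.fixture(scope="module")
def clean_report():
    records = [
        pr.generate_record(
            replace(pr.clean_params(duration_s=120.0), noise_sd=0.01, seed=s)
        )[0]
        for s in range(6)
    ]
    return pr.evaluate_dataset(records, max_segments=2)


class TestEvaluateDataset:
    def test_clean_records_low_error(self, clean_report):
        for m in pr.METHODS:
            assert clean_report.summaries[m].mae < 1.0

    def test_no_significant_differences_on_equal_difficulty(self, clean_report):
        assert all(p > 0.05 for p in clean_report.rank_mae.pairwise.values())

    def test_reports_complete(self, clean_report):
        assert set(clean_report.summaries) == set(pr.METHODS)
        assert clean_report.rank_rmse.df == 7
        for m in pr.METHODS:
            ba = clean_report.bland_altman[m]
            assert ba is not None
            assert ba.loa_lo <= ba.bias <= ba.loa_hi

    def test_rmse_ge_mae_per_method(self, clean_report):
        for m in pr.METHODS:
            s = clean_report.summaries[m]
            assert s.rmse >= s.mae - 1e-12

    def test_single_record_skips_rank_tests(self):
        rec = pr.generate_record(pr.clean_params(duration_s=120.0))[0]
        with pytest.warns(UserWarning):
            report = pr.evaluate_dataset([rec], max_segments=2)
        assert report.rank_mae is None
        assert report.summaries["RISSDV"].mae < 1.0

    def test_missing_reference_rejected(self):
        rec = pr.generate_record(pr.clean_params(duration_s=60.0))[0]
        rec.resp = None
        with pytest.raises(ValueError, match="reference"):
            pr.evaluate_dataset([rec])

    def test_missing_pulse_robustness_ordering(self):
        records = [
            pr.generate_record(
                replace(pr.clean_params(duration_s=60.0), p_missing=0.1, noise_sd=0.01, seed=s)
            )[0]
            for s in range(8)
        ]
        report = pr.evaluate_dataset(records, max_segments=1)
        assert (
            np.median([v[1] for v in report.summaries["RISSDV"].per_record.values()])
            <= np.median([v[1] for v in report.summaries["RIFV"].per_record.values()])
        )
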