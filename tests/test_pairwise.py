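import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from improcoord import (
    AnalysisConfig,
    DegenerateSeriesError,
    Segmentation,
    ValidationError,
    action_correlation,
    all_pairs,
    build_recording,
    causal_density,
    check_stationarity_and_detrend,
    compare_to_null,
    granger_pvalues,
    intention_correlation,
    mean_slider_distance,
    null_distribution,
    scramble,
    select_max_lag,
    sonic_organization,
)
from improcoord.pairwise_coordination import block_permutation_pvalue, phase_randomize

from conftest import make_profiles


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def rank_with_midranks(values):
    """Exhaustive midrank computation, independent of scipy's ranking."""
    values = list(values)
    ranks = []
    for v in values:
        below = sum(1 for w in values if w < v)
        ties = sum(1 for w in values if w == v)
        ranks.append(below + (ties + 1) / 2.0)
    return np.array(ranks)


def spearman_oracle(a, b):
    ra, rb = rank_with_midranks(a), rank_with_midranks(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))


def paired_t_oracle(real, null):
    d = np.asarray(real) - np.asarray(null)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t, 2 * stats.t.sf(abs(t), n - 1)


# ---------------------------------------------------------------------------
# Stationarity / detrending
# ---------------------------------------------------------------------------

class TestStationarity:
    def test_white_noise_left_unchanged(self):
        x = np.random.default_rng(0).normal(size=300)
        out, detrended = check_stationarity_and_detrend(x)
        assert not detrended
        np.testing.assert_array_equal(out, x)

    def test_ramp_is_detrended_to_zero(self):
        t = np.arange(300, dtype=float)
        out, detrended = check_stationarity_and_detrend(3.0 + 0.01 * t)
        assert detrended
        np.testing.assert_allclose(out, 0, atol=1e-8)

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            check_stationarity_and_detrend(np.ones(100))


# ---------------------------------------------------------------------------
# Granger tests
# ---------------------------------------------------------------------------

class TestGranger:
    def test_matches_statsmodels_f_test(self):
        """Dual route: our restricted/unrestricted OLS F vs. the statsmodels
        Granger machinery, on short series at several model orders."""
        from statsmodels.tsa.stattools import grangercausalitytests

        rng = np.random.default_rng(7)
        for n, lag in [(30, 1), (40, 2), (50, 3), (50, 5)]:
            x = rng.normal(size=n)
            y = 0.5 * np.concatenate([[0], x[:-1]]) + rng.normal(size=n)
            p_xy, _ = granger_pvalues(x, y, lag)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm_res = grangercausalitytests(
                    np.column_stack([y, x]), maxlag=[lag], verbose=False
                )
            assert abs(p_xy - sm_res[lag][0]["ssr_ftest"][1]) <= 1e-8

    def test_one_way_coupling_detected_in_one_direction_only(self):
        """The driven direction is always significant; the reverse direction
        behaves like a null test (rejecting at roughly alpha)."""
        rng = np.random.default_rng(2)
        reverse_hits = 0
        n_draws = 40
        for _ in range(n_draws):
            x = rng.normal(size=600)
            y = np.concatenate([[0], x[:-1]]) + 0.5 * rng.normal(size=600)
            p_xy, p_yx = granger_pvalues(x, y, 3)
            assert p_xy < 1e-6
            reverse_hits += p_yx < 0.05
        assert reverse_hits / n_draws < 0.25

    def test_deterministic_shift_gives_near_zero_p(self):
        x = np.random.default_rng(3).normal(size=200)
        y = np.concatenate([[0.0], x[:-1]])
        p_xy, _ = granger_pvalues(x, y, 1)
        assert p_xy < 1e-30

    def test_null_pvalues_uniform(self):
        """Calibration: on independent white noise the directed p-value is
        uniform on [0, 1] (KS check over many draws)."""
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(300):
            x = rng.normal(size=120)
            y = rng.normal(size=120)
            p_xy, p_yx = granger_pvalues(x, y, 2)
            pvals.extend([p_xy, p_yx])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            granger_pvalues(np.ones(50), np.random.default_rng(0).normal(size=50), 2)


class TestCausalDensity:
    def test_mutual_coupling_gives_one(self):
        rng = np.random.default_rng(5)
        n = 600
        x = np.zeros(n)
        y = np.zeros(n)
        e1, e2 = rng.normal(size=n), rng.normal(size=n)
        for t in range(1, n):
            x[t] = 0.5 * y[t - 1] + e1[t]
            y[t] = 0.5 * x[t - 1] + e2[t]
        cfg = AnalysisConfig(max_lag=2)
        assert causal_density(x, y, cfg) == 1.0

    def test_one_way_coupling_gives_half(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=600)
        y = np.concatenate([[0], x[:-1]]) + 0.5 * rng.normal(size=600)
        assert causal_density(x, y, AnalysisConfig(max_lag=2)) == 0.5

    def test_symmetric_in_pair_order(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=300), rng.normal(size=300)
        cfg = AnalysisConfig(max_lag=3)
        assert causal_density(x, y, cfg) == causal_density(y, x, cfg)

    def test_continuous_scale_option(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=300), rng.normal(size=300)
        d = causal_density(x, y, AnalysisConfig(max_lag=3, density_scale="fstat"))
        assert d >= 0 and d not in (0.0, 0.5, 1.0)


class TestLagSelection:
    def test_recovers_true_order_two(self):
        """Bivariate system with order-2 dynamics; IC scan should pick 2.
        Series are squashed into [0,1] so they are valid intention rows
        (the affine transform does not change the lag structure)."""
        rng = np.random.default_rng(10)
        n = 800
        x = np.zeros(n)
        y = np.zeros(n)
        ex, ey = rng.normal(size=n), rng.normal(size=n)
        for t in range(2, n):
            x[t] = 0.4 * x[t - 1] - 0.35 * x[t - 2] + 0.3 * y[t - 2] + ex[t]
            y[t] = 0.4 * y[t - 1] - 0.35 * y[t - 2] + 0.3 * x[t - 2] + ey[t]

        def squash(v):
            return (v - v.min()) / (v.max() - v.min())

        profiles = make_profiles(2)
        rec = build_recording(
            profiles,
            {"M01": np.zeros(n, dtype=int), "M02": np.ones(n, dtype=int)},
            {"M01": squash(x), "M02": squash(y)},
            Segmentation((0, n)),
        )
        assert select_max_lag(rec, range(1, 7), dimension="intentions") == 2

    def test_single_candidate_returned(self, tiny_recording):
        assert select_max_lag(tiny_recording, [1], dimension="intentions") == 1


# ---------------------------------------------------------------------------
# Surrogates
# ---------------------------------------------------------------------------

class TestScramble:
    @given(st.lists(st.floats(allow_nan=False, allow_infinity=False), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_preserves_multiset(self, values):
        out = scramble(np.array(values), np.random.default_rng(0))
        assert sorted(out.tolist()) == sorted(values)

    def test_length_one_identity(self):
        assert scramble(np.array([3.0]), np.random.default_rng(0))[0] == 3.0

    def test_seed_reproducibility(self):
        x = np.arange(100.0)
        a = scramble(x, np.random.default_rng(42))
        b = scramble(x, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_phase_randomize_preserves_spectrum(self):
        x = np.random.default_rng(1).normal(size=128)
        s = phase_randomize(x, np.random.default_rng(2))
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(s)), np.abs(np.fft.rfft(x)), atol=1e-8
        )


class TestNullDistribution:
    def test_causal_density_null_mean_near_alpha(self):
        """On an independent pair, each scrambled direction is a fresh null
        F test, so the surrogate causal-density mean sits near alpha."""
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=400), rng.normal(size=400)
        cfg = AnalysisConfig(max_lag=2, n_surrogates=200, rng_seed=11)

        def density(a, b):
            p1, p2 = granger_pvalues(a, b, cfg.max_lag)
            return (float(p1 < cfg.alpha) + float(p2 < cfg.alpha)) / 2.0

        summary = null_distribution(x, y, density, cfg)
        # binomial MC error on 400 directed tests: sd ~ 0.011
        assert abs(summary.mean - cfg.alpha) < 0.04

    def test_abs_rho_null_matches_permutation_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 2, 200).astype(float)
        b = rng.integers(0, 2, 200).astype(float)
        cfg = AnalysisConfig(n_surrogates=300, rng_seed=12)
        summary = null_distribution(
            a, b, lambda u, v: abs(stats.spearmanr(u, v)[0]), cfg
        )
        # direct permutation oracle with its own rng
        orng = np.random.default_rng(99)
        oracle = np.mean(
            [
                abs(stats.spearmanr(orng.permutation(a), orng.permutation(b))[0])
                for _ in range(300)
            ]
        )
        assert abs(summary.mean - oracle) < 0.02

    def test_single_surrogate_has_undefined_sd(self):
        rng = np.random.default_rng(13)
        cfg = AnalysisConfig(n_surrogates=1)
        summary = null_distribution(
            rng.normal(size=50), rng.normal(size=50), mean_slider_distance, cfg
        )
        assert summary.sd is None and summary.samples.size == 1


# ---------------------------------------------------------------------------
# Correlation metrics
# ---------------------------------------------------------------------------

class TestCorrelations:
    def test_identical_actions_rho_one(self):
        a = np.array([0, 1, 1, 0, 1, 0])
        rho, _, _ = action_correlation(a, a)
        assert rho == pytest.approx(1.0)

    def test_complement_rho_minus_one(self):
        a = np.array([0, 1, 1, 0, 1, 0])
        rho, _, cls = action_correlation(a, 1 - a)
        assert rho == pytest.approx(-1.0)
        assert cls == "negative"

    def test_spearman_matches_exhaustive_rank_oracle(self):
        a = np.array([0, 0, 1, 1, 0, 1])
        b = np.array([1, 0, 1, 0, 0, 1])
        rho, _, _ = action_correlation(a, b)
        assert rho == pytest.approx(spearman_oracle(a, b), abs=1e-12)

    def test_sonic_organization_sign_invariance(self):
        rng = np.random.default_rng(14)
        a = rng.integers(0, 2, 80)
        b = rng.integers(0, 2, 80)
        assert sonic_organization(a, b) == pytest.approx(sonic_organization(1 - a, b))

    def test_sonic_organization_independent_pair_near_zero(self):
        rng = np.random.default_rng(15)
        a = rng.integers(0, 2, 2000)
        b = rng.integers(0, 2, 2000)
        # null |rho| scale for length n is ~ 1/sqrt(n)
        assert sonic_organization(a, b) < 5 / np.sqrt(2000)

    def test_pearson_identity_and_complement(self):
        x = np.random.default_rng(16).uniform(0, 1, 50)
        assert intention_correlation(x, x)[0] == pytest.approx(1.0)
        assert intention_correlation(x, 1 - x)[0] == pytest.approx(-1.0)

    def test_pearson_matches_analytic_mixture(self):
        """x and y = (x + independent noise) have analytic correlation
        1/sqrt(1 + s^2) for unit-variance x and noise sd s."""
        rng = np.random.default_rng(17)
        n, s = 200_00, 1.0
        base = rng.normal(size=n)
        y = base + s * rng.normal(size=n)
        # squash into [0,1] linearly (correlation invariant)
        def unit(v):
            return (v - v.min()) / (v.max() - v.min())
        rho, _, _ = intention_correlation(unit(base), unit(y))
        assert rho == pytest.approx(1 / np.sqrt(1 + s**2), abs=0.03)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            action_correlation(np.ones(10, dtype=int), np.array([0, 1] * 5))

    def test_block_permutation_pvalue_in_range(self):
        rng = np.random.default_rng(18)
        x, y = rng.normal(size=200), rng.normal(size=200)
        p = block_permutation_pvalue(
            x, y, lambda u, v: stats.pearsonr(u, v)[0], block_s=20,
            n_permutations=99, rng=rng,
        )
        assert 0 < p <= 1


class TestMeanSliderDistance:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([0.3, 0.7], [0.3, 0.7], 0.0),
            ([0.0, 0.0], [1.0, 1.0], 1.0),
            ([0.2, 0.4], [0.5, 0.0], 0.35),
        ],
    )
    def test_examples(self, x, y, expected):
        assert mean_slider_distance(np.array(x), np.array(y)) == pytest.approx(expected)

    @given(
        st.lists(st.floats(0, 1), min_size=3, max_size=20).flatmap(
            lambda x: st.tuples(
                st.just(x),
                st.lists(st.floats(0, 1), min_size=len(x), max_size=len(x)),
                st.lists(st.floats(0, 1), min_size=len(x), max_size=len(x)),
            )
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_is_a_metric(self, triple):
        x, y, z = (np.array(v) for v in triple)
        dxy = mean_slider_distance(x, y)
        assert dxy == pytest.approx(mean_slider_distance(y, x))
        assert dxy <= mean_slider_distance(x, z) + mean_slider_distance(z, y) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mean_slider_distance(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# Real-vs-null comparison
# ---------------------------------------------------------------------------

class TestCompareToNull:
    def test_identical_vectors_give_zero_t(self):
        v = np.arange(10.0)
        res = compare_to_null(v, v)
        assert res.t == 0 and res.d is None and res.degenerate

    def test_constant_shift_flagged_degenerate(self):
        v = np.arange(10.0)
        res = compare_to_null(v + 1.0, v)
        assert res.degenerate and res.p == 0.0

    def test_matches_textbook_paired_t(self):
        rng = np.random.default_rng(19)
        real = rng.normal(0.3, 1, 40)
        null = rng.normal(0.0, 1, 40)
        res = compare_to_null(real, null)
        t_oracle, p_oracle = paired_t_oracle(real, null)
        assert res.t == pytest.approx(t_oracle, abs=1e-10)
        assert res.p == pytest.approx(p_oracle, abs=1e-10)
        assert res.df == 39

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            compare_to_null([1.0], [0.5])


# ---------------------------------------------------------------------------
# Whole-ensemble driver
# ---------------------------------------------------------------------------

class TestAllPairs:
    def test_pair_count_and_symmetric_fields(self, tiny_recording):
        cfg = AnalysisConfig(max_lag=2, n_surrogates=3, rng_seed=0)
        pairs = all_pairs(tiny_recording, "actions", cfg)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.sonic_organization == pytest.approx(abs(p.rho))
        assert p.causal_density in (0.0, 0.5, 1.0)

    def test_degenerate_pair_flagged_not_dropped(self):
        profiles = make_profiles(3)
        actions = {
            "M01": np.r_[np.ones(30, dtype=int), np.zeros(70, dtype=int)],
            "M02": np.r_[np.zeros(40, dtype=int), np.ones(60, dtype=int)],
            "M03": np.ones(100, dtype=int),  # constant: degenerate partner
        }
        rec = build_recording(profiles, actions, {}, Segmentation((0, 100)))
        cfg = AnalysisConfig(max_lag=2, n_surrogates=2, rng_seed=0)
        pairs = all_pairs(rec, "actions", cfg)
        assert len(pairs) == 3
        degenerate = [p for p in pairs if p.degenerate]
        assert len(degenerate) == 2  # both pairs involving M03
        assert all("constant" in p.degenerate_reason for p in degenerate)
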