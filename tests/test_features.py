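"""Feature battery: literal-definition oracles, closed-form examples,
identities, and degenerate-input conventions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hrvstress as hs
from hrvstress.cohort import ParticipantState
from hrvstress.features import (
    EntropyParams,
    correlation_sums,
    dfa_fluctuations,
    FEATURE_DOMAINS,
    NONLINEAR_FAMILIES,
)

# ---------------------------------------------------------------------------
# literal-definition oracles (double loops, kept deliberately naive)
# ---------------------------------------------------------------------------

def apen_oracle(x, m=2, r_factor=0.2):
    x = np.asarray(x, float)
    n = x.size
    r = r_factor * np.std(x, ddof=1)

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in templates:
            c = 0
            for tj in templates:
                if max(abs(a - b) for a, b in zip(ti, tj)) <= r:
                    c += 1
            total += math.log(c / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m=2, r_factor=0.2):
    x = np.asarray(x, float)
    n = x.size
    r = r_factor * np.std(x, ddof=1)

    def count(mm):
        templates = [x[i:i + mm] for i in range(n - m)]  # N-m templates
        c = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if max(abs(a - b) for a, b in zip(templates[i], templates[j])) <= r:
                    c += 1
        return c

    a, b = count(m + 1), count(m)
    return -math.log(a / b)


def dfa_fluct_oracle(x, n):
    x = np.asarray(x, float)
    y = np.cumsum(x - x.mean())
    n_boxes = y.size // n
    sq = []
    for b in range(n_boxes):
        seg = y[b * n:(b + 1) * n]
        t = np.arange(n)
        coef = np.polyfit(t, seg, 1)
        sq.extend((seg - np.polyval(coef, t)) ** 2)
    return math.sqrt(np.mean(sq))


def corr_sum_oracle(x, m, delay, radii):
    x = np.asarray(x, float)
    vecs = [x[i:i + (m - 1) * delay + 1:delay] for i in range(x.size - (m - 1) * delay)]
    out = []
    for r in radii:
        c = 0
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                if math.dist(vecs[i], vecs[j]) < r:
                    c += 1
        out.append(c / (len(vecs) * (len(vecs) - 1) / 2))
    return np.array(out)


class TestEntropyOracles:
    def test_apen_matches_double_loop_oracle(self):
        x = np.random.default_rng(10).normal(850, 40, 120)
        assert hs.approximate_entropy(x) == pytest.approx(apen_oracle(x), abs=1e-12)

    def test_sampen_matches_double_loop_oracle(self):
        x = np.random.default_rng(11).normal(850, 40, 200)
        assert hs.sample_entropy(x) == pytest.approx(sampen_oracle(x), abs=1e-12)

    def test_constant_series_entropies_zero(self):
        c = np.full(200, 800.0)
        assert hs.approximate_entropy(c) == 0.0
        assert hs.sample_entropy(c) == 0.0

    def test_alternation_is_nearly_perfectly_regular(self):
        x = np.tile([800.0, 860.0], 150)
        assert hs.approximate_entropy(x) < 0.05
        assert hs.sample_entropy(x) == 0.0  # every m-match extends

    def test_sampen_no_matches_flagged_nan(self):
        # (0,0) templates match at length m, but every extension hits a
        # distinct spike farther apart than the tolerance: A = 0
        x = np.concatenate([[0.0, 0.0, 10.0 * k] for k in range(1, 11)])
        assert math.isnan(hs.sample_entropy(x))

    def test_sampen_does_not_decrease_with_simulator_noise(self):
        from scipy.stats import spearmanr

        levels = [2.0, 6.0, 12.0, 24.0]
        means = []
        for noise in levels:
            vals = []
            for seed in range(10):
                cfg = hs.CohortConfig(noise_sd_ms=noise, phase_duration_s=120.0)
                st_ = ParticipantState("p", "HC", 850.0, 40.0, 25.0, 1.0, 0.095, 0.25)
                s = hs.simulate_phase_rri(
                    st_, 0.0, "rest1", cfg, np.random.default_rng(seed)
                )
                vals.append(hs.sample_entropy(s.intervals_ms))
            means.append(np.mean(vals))
        rho, _ = spearmanr(levels, means)
        assert rho > 0


class TestDFA:
    def test_fluctuations_match_per_box_oracle(self):
        x = np.random.default_rng(12).normal(850, 30, 300)
        for n in (4, 7, 16, 33, 64):
            ours = dfa_fluctuations(x, np.array([n]))[0]
            assert ours == pytest.approx(dfa_fluct_oracle(x, n), abs=1e-9)

    def test_white_noise_alpha1_near_half(self):
        x = np.random.default_rng(42).normal(size=10_000)
        a1, a2 = hs.dfa(x)
        assert 0.4 <= a1 <= 0.6
        assert 0.4 <= a2 <= 0.6

    def test_brownian_motion_alpha1_near_three_halves(self):
        x = np.cumsum(np.random.default_rng(42).normal(size=10_000))
        a1, _ = hs.dfa(x)
        assert 1.35 <= a1 <= 1.65

    def test_too_short_series_rejected(self):
        with pytest.raises(hs.InsufficientDataError, match="130"):
            hs.dfa(np.random.default_rng(0).normal(size=100))


class TestCorrelationDimension:
    def test_correlation_sums_match_pair_counting_oracle(self):
        x = np.random.default_rng(13).normal(850, 30, 80)
        radii = np.array([5.0, 20.0, 60.0, 150.0])
        ours = correlation_sums(x, 3, 1, radii)
        assert np.allclose(ours, corr_sum_oracle(x, 3, 1, radii), atol=1e-12)

    def test_constant_series_dimension_zero(self):
        assert hs.correlation_dimension(np.full(300, 800.0)) == 0.0

    def test_limit_cycle_dimension_near_one(self):
        t = np.arange(400) * 0.85
        x = 850 + 30 * np.sin(2 * np.pi * 0.1 * t)
        assert 0.8 <= hs.correlation_dimension(x) <= 1.3


class TestArtifactCorrection:
    def test_clean_series_untouched(self):
        x = np.full(100, 800.0)
        out, n = hs.correct_artifacts(x)
        assert n == 0 and np.array_equal(out, x)

    def test_single_ectopic_restored_by_spline(self):
        x = np.full(120, 800.0)
        x[60] = 300.0
        out, n = hs.correct_artifacts(x)
        assert n == 1
        assert abs(out[60] - 800.0) < 1.0

    def test_too_many_artifacts_rejected(self):
        rng = np.random.default_rng(0)
        x = np.full(100, 800.0)
        idx = rng.choice(100, 40, replace=False)
        x[idx] = rng.choice([300.0, 1600.0], size=40)
        with pytest.raises(hs.QualityError):
            hs.correct_artifacts(x)


class TestTimeDomain:
    def test_constant_series_degenerate_values(self):
        f = hs.time_domain_features(np.full(375, 800.0))
        assert f["mean_rri"] == pytest.approx(0.8)
        assert f["sdnn"] == 0 and f["rmssd"] == 0 and f["pnn50"] == 0
        assert f["tri"] == 1.0

    def test_alternating_10ms_rmssd(self):
        f = hs.time_domain_features(np.tile([800.0, 810.0], 100))
        assert f["rmssd"] == pytest.approx(10.0)
        assert f["pnn50"] == 0.0

    def test_alternating_60ms_pnn50_saturates(self):
        f = hs.time_domain_features(np.tile([800.0, 860.0], 100))
        assert f["pnn50"] == 100.0

    def test_tri_at_least_one_and_tinn_nonnegative(self):
        x = np.random.default_rng(3).normal(850, 50, 400)
        f = hs.time_domain_features(x)
        assert f["tri"] >= 1.0
        assert f["tinn"] >= 0.0


def _pure_tone_series(a_lf, a_hf, seed=0):
    cfg = hs.CohortConfig(noise_sd_ms=0.0, freq_jitter_sd=0.0)
    st_ = ParticipantState("p", "HC", 850.0, a_lf, a_hf, 1.0, 0.095, 0.25)
    return hs.simulate_phase_rri(st_, 0.0, "rest1", cfg, np.random.default_rng(seed))


class TestSpectral:
    def test_hf_only_power_concentrates_in_hf_band(self):
        s = _pure_tone_series(0.0, 25.0)
        f = hs.spectral_features(s.intervals_ms)
        assert f["hf_nu"] > 90.0
        assert f["lf_hf"] < 0.1
        # >90% of LF+HF power in HF
        assert math.exp(f["log_hf"]) / (
            math.exp(f["log_hf"]) + math.exp(f["log_lf"])
        ) > 0.9 or f["log_lf"] == -np.inf

    def test_lf_only_power_concentrates_in_lf_band(self):
        s = _pure_tone_series(40.0, 0.0)
        assert hs.spectral_features(s.intervals_ms)["lf_nu"] > 90.0

    def test_normalized_units_sum_to_100(self):
        for seed in range(5):
            x = np.random.default_rng(seed).normal(850, 40, 350)
            f = hs.spectral_features(x)
            assert f["lf_nu"] + f["hf_nu"] == pytest.approx(100.0, abs=1e-9)

    def test_doubling_variability_increases_total_log_power(self):
        s1 = _pure_tone_series(20.0, 12.0, seed=4)
        s2 = _pure_tone_series(40.0, 24.0, seed=4)
        f1 = hs.spectral_features(s1.intervals_ms)
        f2 = hs.spectral_features(s2.intervals_ms)
        assert f2["log_tot"] > f1["log_tot"]

    def test_short_series_single_segment_warning(self):
        x = np.random.default_rng(1).normal(850, 40, 100)  # ~85 s
        with pytest.warns(UserWarning, match="single-segment"):
            hs.spectral_features(x)


class TestPoincare:
    def test_constant_series_zero(self):
        assert hs.poincare(np.full(50, 800.0)) == (0.0, 0.0)

    def test_alternating_sd1(self):
        sd1, _ = hs.poincare(np.tile([800.0, 810.0], 100))
        assert sd1 == pytest.approx(10.0 / math.sqrt(2), abs=1e-9)

    @given(st.lists(st.floats(min_value=400, max_value=1500), min_size=5, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_poincare_identities(self, vals):
        x = np.asarray(vals)
        sd1, sd2 = hs.poincare(x)
        d = np.diff(x)
        rmssd = math.sqrt(np.mean(d ** 2))
        sdnn = np.std(x, ddof=1)
        assert sd1 == pytest.approx(rmssd / math.sqrt(2), rel=1e-9, abs=1e-12)
        assert sd1 ** 2 + sd2 ** 2 == pytest.approx(2 * sdnn ** 2, rel=1e-6, abs=1e-9)


class TestExtractFeatures:
    def test_canonical_order_and_count(self, small_cohort):
        _, cohort = small_cohort
        v = hs.extract_features(cohort[0])
        assert list(v.index) == list(hs.FEATURE_NAMES)
        assert len(v) == 20
        assert v.notna().all()

    def test_domain_partition(self):
        domains = [FEATURE_DOMAINS[f] for f in hs.FEATURE_NAMES]
        assert domains.count("time") == 6
        assert domains.count("frequency") == 7
        assert domains.count("nonlinear") == 7
        assert len(set(NONLINEAR_FAMILIES.values())) == 5

    def test_deterministic(self, small_cohort):
        _, cohort = small_cohort
        a = hs.extract_features(cohort[3])
        b = hs.extract_features(cohort[3])
        assert a.equals(b)

    def test_constant_series_degenerate_conventions(self):
        v = hs.extract_features(np.full(375, 800.0))
        assert v["apen"] == 0 and v["sampen"] == 0
        assert v["sd1"] == 0 and v["sd2"] == 0
        assert v["tri"] == 1.0 and v["cordim"] == 0.0
        # spectral powers are undefined for a flat series and flagged
        assert np.isnan(v["log_hf"]) and np.isnan(v["lf_hf"])

    def test_entropy_params_validation(self):
        with pytest.raises(ValueError):
            EntropyParams(m=0)
        with pytest.raises(ValueError):
            EntropyParams(r_factor=0.0)
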