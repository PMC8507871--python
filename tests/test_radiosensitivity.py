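"""Resensitization kinetics and cumulative LQ survival."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zmtcp import (
    FractionationSchedule,
    ResensitizationParams,
    alpha_at,
    beta_at,
    cumulative_log_survival,
    time_mean_alpha_beta,
)

# independent scalar transcription of the kinetics, used as the oracle


def oracle_alpha(t, a0, am, b):
    w = math.exp(-b * t * t / 2.0)
    return a0 * w + am * (1.0 - w)


def oracle_beta(t, a0, am, b0, b):
    return b0 * (oracle_alpha(t, a0, am, b) / a0) ** 2


params_strategy = st.builds(
    ResensitizationParams,
    alpha0=st.floats(0.01, 0.5),
    alpha_m=st.floats(0.5, 1.5),
    beta0=st.floats(0.005, 0.2),
    b=st.floats(0.0, 2.0),
)


class TestAlphaBeta:
    def test_alpha_starts_hypoxic(self, stock_params):
        assert alpha_at(0.0, stock_params) == stock_params.alpha0

    def test_no_resensitization_keeps_alpha_constant(self):
        p = ResensitizationParams(0.12, 0.23, 0.0267, b=0.0)
        for t in (0.0, 7.0, 100.0):
            assert alpha_at(t, p) == p.alpha0

    def test_alpha_day14_matches_oracle(self, stock_params):
        expected = oracle_alpha(14.0, 0.12, 0.23, 0.066)
        assert expected == pytest.approx(0.2298, abs=5e-5)  # frozen value
        assert alpha_at(14.0, stock_params) == pytest.approx(expected, rel=1e-12)

    def test_beta_starts_at_beta0(self, stock_params):
        assert beta_at(0.0, stock_params) == pytest.approx(stock_params.beta0)

    def test_beta_asymptote_is_oer_scaled(self, stock_params):
        ratio = stock_params.alpha_m / stock_params.alpha0
        assert beta_at(1e4, stock_params) == pytest.approx(
            stock_params.beta0 * ratio**2, rel=1e-9
        )
        assert stock_params.beta_m == pytest.approx(stock_params.beta0 * ratio**2)

    def test_beta_day14_matches_oracle(self, stock_params):
        expected = oracle_beta(14.0, 0.12, 0.23, 0.12 / 4.5, 0.066)
        assert expected == pytest.approx(0.0978, abs=5e-5)  # frozen value
        assert beta_at(14.0, stock_params) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("fn", [alpha_at, beta_at])
    def test_negative_time_rejected(self, fn, stock_params):
        with pytest.raises(ValueError):
            fn(-1.0, stock_params)

    @settings(max_examples=50, deadline=None)
    @given(p=params_strategy, t=st.floats(0, 200))
    def test_alpha_monotone_and_bounded(self, p, t):
        a = alpha_at(t, p)
        assert p.alpha0 - 1e-12 <= a <= p.alpha_m + 1e-12
        assert alpha_at(t + 1.0, p) >= a - 1e-12

    @settings(max_examples=50, deadline=None)
    @given(p=params_strategy, t=st.floats(0, 200))
    def test_beta_identity(self, p, t):
        assert beta_at(t, p) == pytest.approx(
            p.beta0 * (alpha_at(t, p) / p.alpha0) ** 2, rel=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(p=params_strategy, t=st.floats(0, 200))
    def test_alpha_beta_ratio_non_increasing(self, p, t):
        r1 = alpha_at(t, p) / beta_at(t, p)
        r2 = alpha_at(t + 1.0, p) / beta_at(t + 1.0, p)
        assert r2 <= r1 + 1e-9


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha0=-0.1, alpha_m=0.2, beta0=0.02, b=0.1),
            dict(alpha0=0.1, alpha_m=0.2, beta0=-0.02, b=0.1),
            dict(alpha0=0.1, alpha_m=0.2, beta0=0.02, b=-0.1),
            dict(alpha0=0.3, alpha_m=0.2, beta0=0.02, b=0.1),  # ordering
        ],
    )
    def test_bad_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ResensitizationParams(**kwargs)

    @pytest.mark.parametrize(
        "times,doses",
        [
            ([0, 14], [14]),          # length mismatch
            ([], []),                 # empty
            ([1, 14], [14, 14]),      # first time nonzero
            ([0, 14, 7], [11] * 3),   # not increasing
            ([0, 14], [14, 0]),       # non-positive dose
        ],
    )
    def test_bad_schedule_rejected(self, times, doses):
        with pytest.raises(ValueError):
            FractionationSchedule(times, doses)

    def test_schedule_roundtrip(self, sched_2f):
        assert FractionationSchedule.from_dict(sched_2f.to_dict()) == sched_2f


class TestCumulativeSurvival:
    def test_first_fraction_sees_initial_sensitivities(self, stock_params):
        s = FractionationSchedule([0], [5.0])
        expected = -(stock_params.alpha0 * 5 + stock_params.beta0 * 25)
        assert cumulative_log_survival(s, stock_params, 1) == pytest.approx(expected)

    def test_b_zero_reduces_to_classic_lq(self):
        p = ResensitizationParams(0.12, 0.23, 0.0267, b=0.0)
        s = FractionationSchedule([0, 7, 14, 21], [6.0] * 4)
        expected = -4 * (0.12 * 6 + 0.0267 * 36)
        assert cumulative_log_survival(s, p, 4) == pytest.approx(expected, rel=1e-12)

    def test_two_clinical_fractions_match_oracle(self, stock_params, sched_2f):
        expected = -sum(
            oracle_alpha(t, 0.12, 0.23, 0.066) * 14
            + oracle_beta(t, 0.12, 0.23, 0.12 / 4.5, 0.066) * 196
            for t in (0.0, 14.0)
        )
        assert expected == pytest.approx(-29.3, abs=0.05)  # frozen value
        assert cumulative_log_survival(sched_2f, stock_params, 2) == pytest.approx(
            expected, rel=1e-12
        )

    def test_k_out_of_range(self, stock_params, sched_2f):
        for k in (0, 3):
            with pytest.raises(ValueError):
                cumulative_log_survival(sched_2f, stock_params, k)

    @settings(max_examples=40, deadline=None)
    @given(p=params_strategy)
    def test_additive_and_monotone_in_k(self, p):
        s = FractionationSchedule([0, 3, 9, 20], [4, 5, 3, 6])
        vals = [cumulative_log_survival(s, p, k) for k in range(1, 5)]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))
        # additivity: per-fraction increments equal alpha*d + beta*d^2 at T_k
        for k in range(1, 4):
            t, d = s.times[k], s.doses[k]
            inc = -(alpha_at(t, p) * d + beta_at(t, p) * d**2)
            assert vals[k] - vals[k - 1] == pytest.approx(inc, rel=1e-9)


class TestTimeMeanAlphaBeta:
    def test_b_zero_gives_static_ratio(self):
        p = ResensitizationParams(0.12, 0.23, 0.0267, b=0.0)
        s = FractionationSchedule([0, 7, 14], [11] * 3)
        assert time_mean_alpha_beta(s, p) == pytest.approx(0.12 / 0.0267)

    def test_single_fraction_gives_static_ratio(self, stock_params):
        s = FractionationSchedule([0], [14.0])
        assert time_mean_alpha_beta(s, stock_params) == pytest.approx(4.5)

    def test_three_fraction_clinical_value(self, stock_params, sched_3f):
        expected = np.mean(
            [
                0.12**2 / ((0.12 / 4.5) * oracle_alpha(t, 0.12, 0.23, 0.066))
                for t in (0.0, 14.0, 28.0)
            ]
        )
        assert expected == pytest.approx(3.07, abs=0.01)  # frozen value
        assert time_mean_alpha_beta(sched_3f, stock_params) == pytest.approx(
            expected, rel=1e-12
        )
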