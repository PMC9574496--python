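"""Process metrics: Nash-Sutcliffe E, NAR, balances, rates, chemostat identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acidnit.metrics import (
    NitrogenBalance,
    alkalinity_limited_fraction,
    fit_report,
    hydraulic_retention_time,
    model_efficiency,
    net_growth_rate_from_srt,
    nitrite_accumulation_ratio,
    nitrogen_loss_fraction,
    volumetric_rates,
)


class TestModelEfficiency:
    def test_perfect_fit(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert model_efficiency(y, y) == 1.0

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert model_efficiency(y, np.full_like(y, y.mean())) == pytest.approx(0.0)

    def test_hand_worked_five_point_example(self):
        assert model_efficiency([1, 2, 3, 4, 5], [1, 2, 3, 4, 6]) == pytest.approx(0.9)

    def test_worse_than_mean_is_negative(self):
        assert model_efficiency([1, 2, 3], [3, 1, 5]) < 0.0

    def test_constant_measured_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            model_efficiency([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            model_efficiency([1, 2, 3], [1, 2])

    @given(
        scale=st.floats(0.1, 100.0),
        offset=st.floats(-50.0, 50.0),
    )
    @settings(deadline=None)
    def test_affine_invariance(self, scale, offset):
        y_m = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y_s = np.array([1.1, 1.9, 3.2, 4.0, 4.8])
        e0 = model_efficiency(y_m, y_s)
        e1 = model_efficiency(scale * y_m + offset, scale * y_s + offset)
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_report_fields(self):
        rep = fit_report([1.0, 2.0], [1.0, 1.5])
        assert rep.n == 2
        assert rep.E <= 1.0
        assert np.allclose(rep.residuals, [0.0, 0.5])


class TestNAR:
    @pytest.mark.parametrize(
        "tnn, no3, expected",
        [(770.0, 230.0, 77.0), (100.0, 0.0, 100.0), (0.0, 50.0, 0.0)],
    )
    def test_values(self, tnn, no3, expected):
        assert nitrite_accumulation_ratio(tnn, no3) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            nitrite_accumulation_ratio(0.0, 0.0)

    @given(tnn=st.floats(0.0, 5000.0), no3=st.floats(0.001, 5000.0))
    @settings(deadline=None)
    def test_bounded_and_monotone_in_nitrate(self, tnn, no3):
        nar = nitrite_accumulation_ratio(tnn, no3)
        assert 0.0 <= nar <= 100.0
        assert nitrite_accumulation_ratio(tnn, no3 * 2) <= nar


class TestChemostatIdentities:
    def test_minimum_srt_gives_printed_growth_rate(self):
        mu = net_growth_rate_from_srt(1.6)
        assert mu == pytest.approx(0.625)
        assert round(mu, 1) == 0.6

    def test_identity_and_limit(self):
        assert net_growth_rate_from_srt(1.0) == 1.0
        assert net_growth_rate_from_srt(1e9) == pytest.approx(0.0, abs=1e-8)

    def test_strictly_decreasing(self):
        srts = np.linspace(0.5, 50, 40)
        mus = [net_growth_rate_from_srt(s) for s in srts]
        assert all(b < a for a, b in zip(mus, mus[1:]))

    def test_nonpositive_srt_rejected(self):
        with pytest.raises(ValueError):
            net_growth_rate_from_srt(0.0)

    @pytest.mark.parametrize("v, q, expected", [(12.0, 6.0, 2.0), (12.0, 7.5, 1.6)])
    def test_hrt(self, v, q, expected):
        assert hydraulic_retention_time(v, q) == pytest.approx(expected)

    def test_hrt_zero_flow_rejected(self):
        with pytest.raises(ValueError):
            hydraulic_retention_time(12.0, 0.0)


class TestAlkalinityLimit:
    def test_urine_one_to_one_ratio_gives_half(self):
        assert alkalinity_limited_fraction(0.2, 0.2) == pytest.approx(0.5)

    def test_extremes(self):
        assert alkalinity_limited_fraction(0.0, 0.1) == 0.0
        assert alkalinity_limited_fraction(1.0, 0.1) == 1.0

    def test_zero_tan_rejected(self):
        with pytest.raises(ValueError):
            alkalinity_limited_fraction(0.1, 0.0)


class TestNitrogenLoss:
    def test_closed_balance_zero_loss(self):
        bal = NitrogenBalance(influent=1000.0, effluent=900.0, storage_change=100.0)
        assert nitrogen_loss_fraction(bal) == pytest.approx(0.0)

    def test_arithmetic(self):
        bal = NitrogenBalance(influent=1000.0, effluent=850.0, storage_change=50.0)
        assert nitrogen_loss_fraction(bal) == pytest.approx(10.0)

    def test_zero_influent_rejected(self):
        with pytest.raises(ValueError):
            nitrogen_loss_fraction(NitrogenBalance(influent=0.0, effluent=0.0, storage_change=0.0))


class TestVolumetricRates:
    def test_steady_state_balance(self):
        t = np.linspace(0, 10, 101)
        n = len(t)
        rates = volumetric_rates(
            t, Q=np.full(n, 6.0), volume=12.0,
            TAN_in=np.full(n, 2000.0), TAN=np.full(n, 1000.0), NO3=np.full(n, 100.0),
        )
        assert np.allclose(rates["AOR"], 500.0)
        assert np.allclose(rates["NOR"], 50.0)

    def test_no_flow_constant_concentration_zero_rate(self):
        t = np.linspace(0, 5, 51)
        n = len(t)
        rates = volumetric_rates(
            t, Q=np.zeros(n), volume=12.0,
            TAN_in=np.full(n, 2000.0), TAN=np.full(n, 500.0), NO3=np.full(n, 10.0),
        )
        assert np.allclose(rates["AOR"], 0.0)
        assert np.allclose(rates["NOR"], 0.0)

    def test_pure_dilution_cancels(self):
        # washout with no reaction: accumulation exactly balances the load
        t = np.linspace(0, 10, 2001)
        hrt = 2.0
        tan = 2000.0 * (1 - np.exp(-t / hrt))
        n = len(t)
        rates = volumetric_rates(
            t, Q=np.full(n, 6.0), volume=12.0,
            TAN_in=np.full(n, 2000.0), TAN=tan, NO3=np.zeros(n),
        )
        assert np.max(np.abs(rates["AOR"][1:-1])) < 1.0  # mg-N/(L d), discretization error

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError):
            volumetric_rates(
                np.linspace(0, 1, 11), np.ones(10), 12.0, np.ones(11), np.ones(11), np.ones(11)
            )
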