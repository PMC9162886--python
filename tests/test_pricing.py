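"""Cost-effectiveness algebra: ICER, value-based price, bands, concordance."""

from decimal import Decimal

import pytest
from hypothesis import given, settings, strategies as st

from vbpricer.money import CurrencyMismatchError, ExchangeRateTable, Money, round_to_euro
from vbpricer.pricing import (
    CEAInputs,
    Concordance,
    OutcomeKind,
    UndefinedICERError,
    WTPThreshold,
    cea_inputs_to_eur,
    classify_concordance,
    icer,
    incremental_cost,
    other_costs_from_delta,
    price_band,
    survival_gain_one_year,
    value_based_price,
    vbp_warnings,
)

EUR = lambda x: Money(Decimal(x), "EUR")  # noqa: E731

money_amounts = st.decimals(min_value=Decimal("0"), max_value=Decimal("1e6"), places=2)
gains = st.decimals(min_value=Decimal("0.0001"), max_value=Decimal("5"), places=4)
wtps = st.decimals(min_value=Decimal("1"), max_value=Decimal("200000"), places=2)


def eur_inputs(gain, cost_b, othercosts_a, kind=OutcomeKind.QALY):
    return CEAInputs(
        gain=gain, outcome_kind=kind, cost_b=EUR(cost_b), othercosts_a=EUR(othercosts_a)
    )


class TestIcer:
    def test_zero_incremental_cost_gives_zero(self):
        assert icer(EUR(1000), EUR(1000), "1.5", "1.0") == 0

    def test_published_delta_cost_over_gain(self):
        # 15702 / 0.138 by long division = 113782.6086...
        got = icer(EUR(15702), EUR(0), Decimal("0.138"), 0)
        assert got.quantize(Decimal("0.01")) == Decimal("113782.61")

    def test_equal_effectiveness_is_undefined_and_names_dominance(self):
        with pytest.raises(UndefinedICERError, match="B dominates"):
            icer(EUR(2000), EUR(1000), 1, 1)
        with pytest.raises(UndefinedICERError, match="A dominates"):
            icer(EUR(500), EUR(1000), 1, 1)

    def test_mixed_currencies_rejected(self):
        with pytest.raises(CurrencyMismatchError):
            icer(Money(1, "GBP"), EUR(1), 2, 1)

    def test_sign_preserved_when_one_arm_dominates_on_one_axis(self):
        assert icer(EUR(500), EUR(1000), 2, 1) < 0

    @given(
        cost_a=money_amounts, cost_b=money_amounts,
        qalys_b=st.decimals(min_value=0, max_value=10, places=3),
        dq=st.decimals(min_value=Decimal("0.001"), max_value=5, places=3),
    )
    @settings(derandomize=True, max_examples=200)
    def test_incremental_cost_round_trip(self, cost_a, cost_b, qalys_b, dq):
        """incremental_cost(icer(...), dQ) recovers cost_A - cost_B."""
        value = icer(EUR(cost_a), EUR(cost_b), qalys_b + dq, qalys_b)
        back = incremental_cost(value, dq)
        assert abs(back - (cost_a - cost_b)) < Decimal("1e-18")


def test_incremental_cost_published_product():
    assert incremental_cost(60_000, Decimal("0.048")) == Decimal("2880.000")
    assert incremental_cost(12345, 0) == 0


class TestValueBasedPrice:
    W60 = WTPThreshold(60_000)

    @pytest.mark.parametrize(
        ("gain", "cost_b", "othercosts_a", "expected"),
        [
            (Decimal("0.048"), 0, 0, Decimal(2880)),
            (Decimal("0.13"), 0, 0, Decimal(7800)),
            (Decimal("0"), 0, 0, Decimal(0)),
        ],
    )
    def test_zero_cost_rows(self, gain, cost_b, othercosts_a, expected):
        got = value_based_price(self.W60, eur_inputs(gain, cost_b, othercosts_a))
        assert got == expected

    def test_gbp_row_after_conversion_rounds_to_published_price(self):
        rates = ExchangeRateTable(rates={"GBP": Decimal("0.833")})
        inputs = CEAInputs(
            gain=Decimal("1.07"),
            outcome_kind=OutcomeKind.QALY,
            cost_b=Money(10_704, "GBP"),
            othercosts_a=Money(26_471, "GBP"),
        )
        got = value_based_price(self.W60, cea_inputs_to_eur(inputs, rates))
        assert round_to_euro(got) == 45_272

    def test_non_eur_inputs_rejected(self):
        inputs = CEAInputs(
            gain=1, outcome_kind=OutcomeKind.QALY,
            cost_b=Money(1, "GBP"), othercosts_a=EUR(0),
        )
        with pytest.raises(CurrencyMismatchError):
            value_based_price(self.W60, inputs)

    def test_negative_result_returned_with_warning_not_error(self):
        inputs = eur_inputs(Decimal("0.01"), 0, 10_000)
        got = value_based_price(self.W60, inputs)
        assert got == Decimal(-9400)
        assert "negative_vbp" in vbp_warnings(inputs, got)

    def test_non_positive_gain_warns(self):
        inputs = eur_inputs(Decimal("-0.1"), 500, 0)
        got = value_based_price(self.W60, inputs)
        assert "non_positive_gain" in vbp_warnings(inputs, got)

    def test_life_year_proxy_flagged(self):
        inputs = eur_inputs(Decimal("0.048"), 0, 0, kind=OutcomeKind.LIFE_YEAR)
        assert "life_year_proxy" in vbp_warnings(inputs, Decimal(2880))

    @given(gain=gains, cost_b=money_amounts, oc=money_amounts, w=wtps)
    @settings(derandomize=True, max_examples=300)
    def test_recomputed_icer_at_the_vbp_equals_the_threshold(self, gain, cost_b, oc, w):
        """Pricing at a threshold then recomputing the ICER returns it exactly."""
        inputs = eur_inputs(gain, cost_b, oc)
        vbp = value_based_price(WTPThreshold(w), inputs)
        got = icer(EUR(vbp) + EUR(oc), EUR(cost_b), gain, 0)
        assert got == w

    @given(gain=gains, cost_b=money_amounts, oc=money_amounts, w1=wtps, w2=wtps)
    @settings(derandomize=True, max_examples=200)
    def test_affine_in_threshold_with_slope_gain(self, gain, cost_b, oc, w1, w2):
        inputs = eur_inputs(gain, cost_b, oc)
        v1 = value_based_price(WTPThreshold(w1), inputs)
        v2 = value_based_price(WTPThreshold(w2), inputs)
        assert v1 - v2 == (w1 - w2) * gain
        # intercept at w -> 0 is cost_B - othercosts_A
        assert v1 - w1 * gain == cost_b - oc

    @given(gain=gains, cost_b=money_amounts, oc=money_amounts,
           bump=st.decimals(min_value=Decimal("0.01"), max_value=100, places=2))
    @settings(derandomize=True, max_examples=200)
    def test_monotonicity(self, gain, cost_b, oc, bump):
        base = value_based_price(self.W60, eur_inputs(gain, cost_b, oc))
        assert value_based_price(self.W60, eur_inputs(gain + bump, cost_b, oc)) > base
        assert value_based_price(self.W60, eur_inputs(gain, cost_b + bump, oc)) > base
        assert value_based_price(self.W60, eur_inputs(gain, cost_b, oc + bump)) < base


class TestSurvivalGain:
    @pytest.mark.parametrize(
        ("a", "b", "expected"),
        [("0.804", "0.756", "0.048"), ("0.36", "0.23", "0.13"), ("0.5", "0.5", "0")],
    )
    def test_one_year_survival_differences(self, a, b, expected):
        assert survival_gain_one_year(Decimal(a), Decimal(b)) == Decimal(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="proportion"):
            survival_gain_one_year(Decimal("1.2"), Decimal("0.5"))
        with pytest.raises(ValueError, match="proportion"):
            survival_gain_one_year(Decimal("0.5"), Decimal("-0.1"))

    @given(
        a=st.decimals(min_value=0, max_value=1, places=3),
        b=st.decimals(min_value=0, max_value=1, places=3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_antisymmetry(self, a, b):
        assert survival_gain_one_year(a, b) == -survival_gain_one_year(b, a)


class TestOtherCostsFromDelta:
    @pytest.mark.parametrize(
        ("delta", "price", "currency", "expected"),
        [
            ("15702", "7000", "EUR", "8702"),
            ("19267", "12431", "BRL", "6836"),
            ("5000", "5000", "EUR", "0"),
        ],
    )
    def test_decomposition(self, delta, price, currency, expected):
        got = other_costs_from_delta(
            Money(Decimal(delta), currency), Money(Decimal(price), currency)
        )
        assert got == Money(Decimal(expected), currency)

    def test_currency_mismatch_rejected(self):
        with pytest.raises(CurrencyMismatchError):
            other_costs_from_delta(Money(1, "EUR"), Money(1, "BRL"))

    def test_negative_result_allowed(self):
        got = other_costs_from_delta(EUR(100), EUR(300))
        assert got.amount == -200


class TestPriceBand:
    def test_band_halves_when_costs_are_zero(self):
        low, high = price_band(
            eur_inputs(Decimal("0.13"), 0, 0),
            WTPThreshold(60_000), WTPThreshold(30_000),
        )
        assert (low, high) == (Decimal(3900), Decimal(7800))

    def test_degenerate_cases(self):
        assert price_band(eur_inputs(0, 100, 100)) == (0, 0)
        w = WTPThreshold(50_000)
        low, high = price_band(eur_inputs(Decimal("0.1"), 10, 20), w, w)
        assert low == high

    def test_reversed_thresholds_rejected(self):
        with pytest.raises(ValueError, match="must not exceed"):
            price_band(eur_inputs(1, 0, 0), WTPThreshold(30_000), WTPThreshold(60_000))

    @given(gain=gains, cost_b=money_amounts, oc=money_amounts)
    @settings(derandomize=True, max_examples=200)
    def test_ordered_for_non_negative_gain(self, gain, cost_b, oc):
        low, high = price_band(eur_inputs(gain, cost_b, oc))
        assert low <= high
        # band width is exactly the threshold spread times the gain
        assert high - low == Decimal(30_000) * gain


class TestConcordance:
    @pytest.mark.parametrize(
        ("vbp", "real", "expected"),
        [
            (6578, 6500, Concordance.CONCORDANT),
            (2880, 13_000, Concordance.REAL_ABOVE_VBP),
            (45_272, 22_000, Concordance.VBP_ABOVE_REAL),
        ],
    )
    def test_reference_device_grouping(self, vbp, real, expected):
        assert classify_concordance(Decimal(vbp), Decimal(real)) is expected

    def test_band_edges_are_concordant(self):
        assert classify_concordance(1000, 1200) is Concordance.CONCORDANT
        assert classify_concordance(1000, 800) is Concordance.CONCORDANT
        assert classify_concordance(1000, Decimal("1200.01")) is Concordance.REAL_ABOVE_VBP

    def test_non_positive_prices_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            classify_concordance(0, 100)
        with pytest.raises(ValueError, match="positive"):
            classify_concordance(100, Decimal("-5"))
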