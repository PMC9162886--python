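"""Price one device from its published cost-effectiveness parameters.

A mitral valve repair system whose reference CEA reports a lifetime QALY
gain of 1.07 per patient, comparator costs of GBP 10,704 and non-device
intervention costs of GBP 26,471.  We convert to euro at 0.833 GBP per
EUR and evaluate the value-based price at both thresholds.
"""

from decimal import Decimal

from vbpricer import (
    CEAInputs,
    ExchangeRateTable,
    Money,
    OutcomeKind,
    PRIMARY_WTP,
    SECONDARY_WTP,
    cea_inputs_to_eur,
    price_band,
    round_to_euro,
)

rates = ExchangeRateTable(rates={"EUR": 1, "GBP": Decimal("0.833")})
inputs = CEAInputs(
    gain=Decimal("1.07"),
    outcome_kind=OutcomeKind.QALY,
    cost_b=Money(10_704, "GBP"),
    othercosts_a=Money(26_471, "GBP"),
    time_horizon_months="lifetime",
)

low, high = price_band(cea_inputs_to_eur(inputs, rates), PRIMARY_WTP, SECONDARY_WTP)
print(f"value-based price band: EUR {round_to_euro(low)} - {round_to_euro(high)}")
print("the high end is the highest acceptable price (60,000 EUR/QALY);")
print("the low end reflects the stricter 30,000 EUR/QALY threshold.")
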