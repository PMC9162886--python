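# vbpricer

Value-based pricing of high-technology medical devices from published
cost-effectiveness parameters.

Health-technology-assessment (HTA) committees routinely approve class
IIb/III and active implantable devices whose market prices were set by the
manufacturer, with no objective link to the health gain the device
delivers. When a cost-effectiveness analysis (CEA) of the device exists —
in a curated registry or in a regional HTA report citing a peer-reviewed
model — a *value-based price* can be derived from it: the device price at
which the intervention's incremental cost-effectiveness ratio equals a
willingness-to-pay (WTP) threshold. `vbpricer` implements that derivation
as a reusable, exactly-tested pipeline: screen a device portfolio for CEA
availability, convert costs to euro, compute a price band under two
thresholds, and classify each device's real market price against its
value-based one.

## The algebra

For a new intervention A against a comparator B, with per-patient
effectiveness gain ΔE = QALYs_A − QALYs_B:

```
ICER = (cost_A − cost_B) / ΔE,        cost_A = price_A + othercosts_A
```

Setting the ICER equal to a WTP threshold *w* and solving for the device
price gives the value-based price

```
VBP(w) = w · ΔE − othercosts_A + cost_B
```

Evaluated at a primary threshold of €60,000/QALY (the highest acceptable
price) and a secondary €30,000/QALY, this yields a price band per device.
When only a one-year survival difference is published, the difference in
survival proportions is used as a life-year gain (implicit utility weight
1) and flagged. All monetary arithmetic is exact decimal; currency
conversion uses explicit "units per euro" rate tables.

A synthetic-data module provides two-arm discounted Markov cohort models
(the model class behind most published device CEAs) and a portfolio
generator in which only ~21% of devices carry usable CEA parameters, so
the entire pipeline can be exercised and property-tested without external
data.

## Worked example

The package ships a reference portfolio of five cardiology devices with
published CEA parameters, plus the exchange rates the original pricing
exercise used (€1.00 = GBP 0.833 = R$ 5.15):

```
$ python examples/reference_case_study.py
device              VBP 30k  VBP 60k    real  concordance
neovasc_reducer        2426     6566    6500  concordant
amds                   1440     2880   13000  real_above_vbp
cardioband             3900     7800   22000  real_above_vbp
pascal                13172    45272   22000  vbp_above_real
cardia_ultrasept       2679     3579    4243  concordant
tally: {'concordant': 2, 'real_above_vbp': 2, 'vbp_above_real': 1}
```

Each row is a price band in euro (VBP at €30,000 and €60,000 per QALY)
next to the real Italian market price. Two devices are priced close to
their value (within ±20%), two are sold well above the price their health
gain justifies, and one — the only lifetime-horizon model — is worth more
than it costs. The same computation is available from the shell:

```
vbpricer reproduce                  # recompute and check the bundled case study
vbpricer compute --devices my.csv --rates rates.json --out results.csv
vbpricer simulate --n 24 --seed 7   # synthetic portfolio end-to-end
```

See `examples/` for scripts covering single-device pricing, the bundled
case study and synthetic portfolio generation, and `docs/methods.md` for
the model, conventions and limitations.

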