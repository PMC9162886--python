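"""Reprice the bundled five-device reference portfolio.

Loads the packaged fixture (five cardiology devices with published CEA
parameters and the exchange rates their pricing exercise used), runs the
full pipeline and prints each device's price band, its real market price
and the concordance class at a +/-20% band.
"""

from vbpricer import concordance_tally, datasets, round_to_euro, run_pipeline

records = datasets.load_reference_portfolio()
rates = datasets.load_reference_rates()
report = run_pipeline(records, rates)

print(f"{'device':<18}{'VBP 30k':>9}{'VBP 60k':>9}{'real':>8}  concordance")
for res in report.results:
    print(
        f"{res.device_id:<18}"
        f"{round_to_euro(res.vbp_secondary_eur):>9}"
        f"{round_to_euro(res.vbp_primary_eur):>9}"
        f"{round_to_euro(res.real_price_eur):>8}  {res.concordance.value}"
    )
tally = concordance_tally(report.results)
print("tally:", {c.value: n for c, n in tally.items()})
print("VBP 60k is the highest acceptable price; a real price far above it")
print("means the market charges more than the device's health gain is worth.")
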