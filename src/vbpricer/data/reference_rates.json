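{
  "as_of": "as printed in the source table (rates used for the reference analysis)",
  "eur_per_unit_convention": "units_per_eur",
  "rates": {
    "EUR": 1,
    "GBP": 0.833,
    "BRL": 5.15
  }
}
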