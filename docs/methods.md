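# Methods

## The pricing model

`vbpricer` prices a device by inverting the incremental
cost-effectiveness ratio. For intervention A versus comparator B the ICER
is `(cost_A − cost_B) / (QALYs_A − QALYs_B)`; splitting
`cost_A = price_A + othercosts_A` and substituting a willingness-to-pay
threshold *w* for the ICER gives the value-based price

    VBP(w) = w · gain − othercosts_A + cost_B .

The identity is affine in *w* with slope equal to the gain, so a pair of
thresholds defines a price band whose width is exactly
`(w_primary − w_secondary) · gain`. The package treats the €60,000/QALY
price as the highest acceptable one and the €30,000/QALY price as the low
end of the proposal range; both defaults are configurable
(`RunConfig`, `WTPThreshold`).

Key assumptions inherited from this framing:

- `cost_B` stays aggregate. Splitting the comparator's cost into price
  and other costs is unnecessary when solving for the price of A only.
- When a source reports only an aggregate incremental cost, the
  non-device costs of A are recovered as `delta_cost − device_price`
  (`other_costs_from_delta`).
- When a source reports only one-year survival proportions, their
  difference enters as a life-year gain with implicit utility weight 1
  and no discounting over the single year
  (`survival_gain_one_year`); every result produced this way carries a
  `life_year_proxy` warning, because a life-year is worth at most one
  QALY and the resulting price is an upper bound on the QALY-based one.

## Numerical conventions

- All pricing arithmetic is exact `decimal.Decimal`; floats entering the
  API are converted through their shortest repr so `0.13` means 0.13.
  Whole-euro rounding (half away from zero) happens only at the
  presentation layer — CSV writers, the CLI, printed tables.
- Exchange rates follow the "units of foreign currency per one euro"
  convention, so conversion to euro is a division, quantized half-up to
  6 decimal places by default. The packaged table carries the rates of
  the reference exercise (GBP 0.833, BRL 5.15 per euro) with an as-of
  note; purchasing-power-parity adjustment is out of scope, so rates for
  other periods or price-level corrections must be supplied by the user.
- A negative VBP is returned as-is and flagged (`negative_vbp`): it
  carries information — the device cannot be cost-effective at any
  positive price at that threshold. A non-positive gain likewise warns
  rather than errors; a portfolio tool must not crash on a dominated
  device. Concordance classification, by contrast, requires strictly
  positive prices and is reported as undefined otherwise.
- Concordance uses a relative band on `real/VBP − 1` with a ±20% default.
  Published judgements of "similar" versus "markedly higher" prices are
  qualitative; the band makes them reproducible, and on the reference
  portfolio it yields the published grouping (2 concordant, 2
  real-above, 1 VBP-above).
- The first reference device's published price (€6,578) was evidently
  computed from an unrounded QALY gain; exact arithmetic on the printed
  inputs (gain 0.138) gives €6,566, 0.18% away. The package computes from
  the printed inputs and compares that row at 0.2% relative tolerance;
  the other four rows reproduce exactly after whole-euro rounding.

## The synthetic CEA generator

Published device CEAs are mostly cohort state-transition models, so the
stand-in generator (`markov.py`) is a two-arm, time-homogeneous Markov
cohort model: occupancy is propagated `n_cycles` steps; per-cycle QALY
and cost rewards use the state membership at the cycle's start (no
half-cycle correction — the convention with an exact geometric closed
form, used as a test oracle to 1e-10); rewards in cycle *t* are
discounted by `(1+r)^(−t·cycle_years)`; the device price enters arm A
once, undiscounted, at t = 0.

`random_markov_spec` draws alive/dead models sized to the magnitudes seen
in practice: 36 monthly cycles, 3% annual discount, alive-state utility
U(0.6, 0.9), comparator monthly death probability U(0.005, 0.03), target
QALY gain log-normal around 0.1 (the intervention arm's hazard is solved
by Brent root-finding so the simulated gain hits the target), annual care
costs and device prices log-normal around €8,000 — spanning roughly the
€10³–10⁵ range of real device CEAs. The alive-state annual cost is capped
at €30,000, which guarantees a positive VBP at €60,000/QALY for every
generated model (annual cost / utility stays below the threshold).

`generate_portfolio` emulates a regional approval workload:
`round(n · 0.21)` devices (half-up, so 24 → 5) receive simulated CEA
inputs tagged as registry-sourced; the rest carry a market price only.
Real prices are the VBP at €60,000/QALY times `exp(ε)`,
ε ~ N(0, 0.5²) by default — wide enough to produce the mix of concordant
prices and multi-fold outliers a real portfolio shows, and collapsing to
exact concordance at sd = 0.

What the generator does *not* emulate: the heterogeneous structures of
real published models (multi-state disease pathways, time-dependent
hazards, probabilistic sensitivity analysis), correlated costs and
effects, or reporting gaps within a single CEA. Passing tests therefore
demonstrate the pricing algebra, the screening logic and the simulator's
internal consistency — not that any specific external model is
reproduced.

## Design choices where the design was open

- The core recovery identity — pricing at the implied ICER returns the
  generating device price — is the headline property test linking the
  simulator to the pricing algebra; it holds to arithmetic precision
  (asserted at 1e-12) because both sides are evaluated in decimal.
- Screening accepts exactly two provenance classes (CEA registry entry,
  HTA report citing a peer-reviewed model); records with parameters but
  other or unstated provenance are screened out.
- Pipeline failures are isolated per device: an HTA committee workload is
  batch-like, so one malformed record must not abort the run. Failures
  are returned alongside results, never silently dropped.
- The headline eligibility percentage is integer-rounded (5/24 → 21%);
  machine output keeps one decimal (20.8).
- Problem sizes in the test suite are small by design — the reference
  portfolio has five devices, synthetic portfolios a few dozen, the
  round-trip identity runs on 1,000 random inputs — because the method is
  closed-form per device and nothing is gained from larger runs.

## Known limitations

- Transferring costs between health systems by exchange rate alone is
  crude; the package deliberately implements nothing beyond explicit rate
  tables, leaving PPP or price-level adjustment to the user.
- The life-year proxy overstates QALY gains whenever utility < 1; the
  warning flag is the only mitigation.
- The 19 screened-out devices in the bundled 24-row portfolio are
  labelled synthetic placeholders: their real identities and prices were
  never published, so only the counts are meaningful.
- No probabilistic sensitivity analysis or net-monetary-benefit framing;
  the output is a deterministic price band per device.
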