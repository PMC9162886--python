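"""Synthetic two-arm Markov cohort models and portfolio generation.

Published device CEAs are usually decision-analytic cohort models; this
module provides a generic discrete-time, time-homogeneous state-transition
model that produces the discounted cost and QALY totals such an analysis
would report, plus a portfolio generator that emulates the empirical
structure of a regional device-approval workload: only a minority of
devices (about one in five) carry usable cost-effectiveness parameters,
and real market prices scatter log-normally around value-based ones.

The simulator is a stand-in for the heterogeneous external models a real
screening exercise would cite, not a replication of any of them.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import Decimal
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .money import Money, as_decimal
from .pricing import (
    CEAInputs,
    OutcomeKind,
    PRIMARY_WTP,
    SourceKind,
    SourceRef,
    value_based_price,
)
from .portfolio import DeviceRecord

__all__ = [
    "Arm",
    "MarkovModelSpec",
    "ArmOutcome",
    "simulate_arm",
    "make_cea_inputs",
    "two_state_spec",
    "random_markov_spec",
    "generate_portfolio",
]

ROW_SUM_TOL = 1e-12


class Arm(str, enum.Enum):
    A = "A"  # new intervention (carries the device price at cycle 0)
    B = "B"  # comparator / standard of care


@dataclass(frozen=True)
class MarkovModelSpec:
    """A two-arm, time-homogeneous Markov cohort model.

    Both arms share the state space, utilities and per-state cycle costs;
    they differ in their transition matrices and in the one-off device
    price charged (undiscounted, at cycle 0) in arm A.  Utilities are per
    cycle-year in [0, 1]; cycle costs are EUR per state per cycle; the
    annual discount rate applies to both costs and QALYs.
    """

    states: Tuple[str, ...]
    absorbing: Tuple[bool, ...]
    transition_a: np.ndarray
    transition_b: np.ndarray
    initial_distribution: np.ndarray
    cycle_length_months: float
    n_cycles: int
    utilities: np.ndarray
    cycle_costs_eur: np.ndarray
    device_price_a: Money
    annual_discount_rate: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.states)
        if len(self.absorbing) != n:
            raise ValueError("absorbing flags must match number of states")
        for name in ("transition_a", "transition_b", "initial_distribution",
                     "utilities", "cycle_costs_eur"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for arm, mat in (("A", self.transition_a), ("B", self.transition_b)):
            if mat.shape != (n, n):
                raise ValueError(f"arm {arm} transition matrix must be {n}x{n}")
            if (mat < 0).any():
                raise ValueError(f"arm {arm} transition matrix has negative entries")
            if np.abs(mat.sum(axis=1) - 1).max() > ROW_SUM_TOL:
                raise ValueError(f"arm {arm} transition matrix rows must sum to 1")
        if abs(self.initial_distribution.sum() - 1) > ROW_SUM_TOL:
            raise ValueError("initial distribution must sum to 1")
        if (self.initial_distribution < 0).any():
            raise ValueError("initial distribution must be non-negative")
        if not ((self.utilities >= 0) & (self.utilities <= 1)).all():
            raise ValueError("state utilities must lie in [0, 1]")
        if self.cycle_length_months <= 0 or self.n_cycles <= 0:
            raise ValueError("cycle length and cycle count must be positive")
        if self.annual_discount_rate < 0:
            raise ValueError("annual discount rate must be >= 0")
        if self.device_price_a.currency != "EUR":
            raise ValueError("device price must be expressed in EUR")

    def transition(self, arm: Arm) -> np.ndarray:
        return self.transition_a if Arm(arm) is Arm.A else self.transition_b

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_months / 12.0


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals and the cohort occupancy trace for one arm.

    ``occupancy`` has ``n_cycles + 1`` rows: the distribution before each
    cycle's transition plus the final distribution; each row sums to 1.
    """

    discounted_qalys: float
    discounted_cost: Money
    occupancy: np.ndarray


def simulate_arm(spec: MarkovModelSpec, arm: Arm) -> ArmOutcome:
    """Propagate the cohort and accumulate discounted QALYs and costs.

    Rewards for cycle ``t`` use the state occupancy at the cycle's start
    (membership before that cycle's transition), with no half-cycle
    correction: reward = occupancy . (utility x cycle-years) and
    occupancy . cycle-costs, discounted by ``(1 + r)^(-t * cycle_years)``.
    The device price enters arm A undiscounted at t = 0.
    """
    mat = spec.transition(arm)
    n = spec.n_cycles
    occupancy = np.empty((n + 1, len(spec.states)))
    occupancy[0] = spec.initial_distribution
    for t in range(n):
        occupancy[t + 1] = occupancy[t] @ mat
    cyl = spec.cycle_length_years
    t_idx = np.arange(n)
    disc = (1.0 + spec.annual_discount_rate) ** (-t_idx * cyl)
    start_occ = occupancy[:n]
    qalys = float(disc @ (start_occ @ (spec.utilities * cyl)))
    cost = float(disc @ (start_occ @ spec.cycle_costs_eur))
    total = Money(as_decimal(cost), "EUR")
    if Arm(arm) is Arm.A:
        total = total + spec.device_price_a
    return ArmOutcome(discounted_qalys=qalys, discounted_cost=total, occupancy=occupancy)


def make_cea_inputs(spec: MarkovModelSpec) -> Tuple[CEAInputs, Optional[Decimal]]:
    """Assemble pricing inputs and the implied ICER from the two arms.

    The gain is the discounted QALY difference A minus B; arm A's cost is
    split back into the device price and everything else (``othercosts_a``);
    arm B's total discounted cost stays aggregate.  The implied ICER is
    ``(price_A + othercosts_a - cost_b) / gain`` — ``None`` when the gain
    is exactly zero, in which case the inputs are still returned.
    """
    out_a = simulate_arm(spec, Arm.A)
    out_b = simulate_arm(spec, Arm.B)
    gain = as_decimal(out_a.discounted_qalys) - as_decimal(out_b.discounted_qalys)
    othercosts_a = out_a.discounted_cost - spec.device_price_a
    cost_b = out_b.discounted_cost
    inputs = CEAInputs(
        gain=gain,
        outcome_kind=OutcomeKind.QALY,
        cost_b=cost_b,
        othercosts_a=othercosts_a,
        time_horizon_months=int(round(spec.n_cycles * spec.cycle_length_months)),
        source=SourceRef(tag="synthetic two-state Markov cohort model",
                         kind=SourceKind.CEA_REGISTRY),
    )
    if gain == 0:
        return inputs, None
    implied_icer = (
        spec.device_price_a.amount + othercosts_a.amount - cost_b.amount
    ) / gain
    return inputs, implied_icer


# ---------------------------------------------------------------------------
# Randomised model specs and portfolio generation


def two_state_spec(
    p_death_a: float,
    p_death_b: float,
    *,
    n_cycles: int = 36,
    cycle_length_months: float = 1.0,
    utility_alive: float = 1.0,
    cycle_cost_alive_eur: float = 0.0,
    device_price_eur: float = 0.0,
    annual_discount_rate: float = 0.0,
) -> MarkovModelSpec:
    """Alive/dead cohort model with constant per-cycle death probabilities."""

    def mat(p: float) -> np.ndarray:
        return np.array([[1.0 - p, p], [0.0, 1.0]])

    return MarkovModelSpec(
        states=("alive", "dead"),
        absorbing=(False, True),
        transition_a=mat(p_death_a),
        transition_b=mat(p_death_b),
        initial_distribution=np.array([1.0, 0.0]),
        cycle_length_months=cycle_length_months,
        n_cycles=n_cycles,
        utilities=np.array([utility_alive, 0.0]),
        cycle_costs_eur=np.array([cycle_cost_alive_eur, 0.0]),
        device_price_a=Money(as_decimal(device_price_eur), "EUR"),
        annual_discount_rate=annual_discount_rate,
    )


def _discounted_qalys_const_hazard(
    p: float, n_cycles: int, cyl: float, utility: float, rate: float
) -> float:
    t = np.arange(n_cycles)
    disc = (1.0 + rate) ** (-t * cyl)
    return float(utility * cyl * np.sum(disc * (1.0 - p) ** t))


def random_markov_spec(
    rng: np.random.Generator,
    *,
    n_cycles: int = 36,
    annual_discount_rate: float = 0.03,
) -> MarkovModelSpec:
    """Draw a plausible device CEA model around published magnitudes.

    The comparator's monthly death probability, the alive-state utility
    and costs are drawn first; a target QALY gain is drawn log-normally
    around 0.1 (the order of magnitude typical for device CEAs) and the
    intervention arm's hazard is solved by root-finding so the simulated
    gain hits the target.  Annual care costs and device prices are drawn
    log-normally around 8,000 EUR, spanning roughly the 1e3 to 1e5 EUR
    range seen in practice; the alive-state annual cost is capped at
    30,000 EUR, which keeps the value-based price at the 60,000 EUR/QALY
    threshold positive for every generated model.
    """
    p_b = float(rng.uniform(0.005, 0.03))
    utility = float(rng.uniform(0.6, 0.9))
    cyl = 1.0 / 12.0
    q_b = _discounted_qalys_const_hazard(p_b, n_cycles, cyl, utility, annual_discount_rate)
    q_max = _discounted_qalys_const_hazard(0.0, n_cycles, cyl, utility, annual_discount_rate)
    target_gain = float(rng.lognormal(mean=math.log(0.1), sigma=0.6))
    target_gain = min(max(target_gain, 1e-4), 0.9 * (q_max - q_b))

    def gap(p_a: float) -> float:
        return (
            _discounted_qalys_const_hazard(p_a, n_cycles, cyl, utility, annual_discount_rate)
            - q_b
            - target_gain
        )

    p_a = float(brentq(gap, 0.0, p_b, xtol=1e-14))
    annual_cost = min(float(rng.lognormal(mean=math.log(8_000.0), sigma=0.5)), 30_000.0)
    device_price = float(rng.lognormal(mean=math.log(8_000.0), sigma=0.6))
    return two_state_spec(
        p_death_a=p_a,
        p_death_b=p_b,
        n_cycles=n_cycles,
        cycle_length_months=1.0,
        utility_alive=utility,
        cycle_cost_alive_eur=annual_cost / 12.0,
        device_price_eur=round(device_price, 2),
        annual_discount_rate=annual_discount_rate,
    )


def generate_portfolio(
    n: int,
    eligible_fraction: float = 0.21,
    price_noise_sd: float = 0.5,
    seed: int = 0,
) -> List[DeviceRecord]:
    """Generate a synthetic device portfolio with partial CEA coverage.

    ``round(n * eligible_fraction)`` devices (half-up) receive CEA inputs
    simulated from randomised Markov models; the rest carry a market price
    only, mirroring the devices a screening exercise must set aside.  Each
    eligible device's real price is its value-based price at the
    60,000 EUR/QALY threshold times ``exp(eps)`` with
    ``eps ~ Normal(0, price_noise_sd^2)``, so ``price_noise_sd = 0`` makes
    every device exactly concordant.  Fully reproducible given ``seed``.
    """
    if not 0 <= eligible_fraction <= 1:
        raise ValueError("eligible_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_eligible = int(math.floor(n * eligible_fraction + 0.5))
    eligible_idx = set(rng.permutation(n)[:n_eligible].tolist())
    records: List[DeviceRecord] = []
    for i in range(n):
        device_id = f"dev{i + 1:03d}"
        if i in eligible_idx:
            spec = random_markov_spec(rng)
            inputs, _ = make_cea_inputs(spec)
            vbp_primary = value_based_price(PRIMARY_WTP, inputs)
            eps = float(rng.normal(0.0, price_noise_sd)) if price_noise_sd > 0 else 0.0
            real = vbp_primary * as_decimal(math.exp(eps))
            records.append(
                DeviceRecord(
                    device_id=device_id,
                    name=f"synthetic device {i + 1}",
                    description="synthetic device with Markov-model CEA",
                    comparator="standard of care",
                    real_unit_price=Money(real, "EUR"),
                    cea=inputs,
                )
            )
        else:
            price = float(rng.lognormal(mean=math.log(8_000.0), sigma=0.8))
            records.append(
                DeviceRecord(
                    device_id=device_id,
                    name=f"synthetic device {i + 1}",
                    description="synthetic device without published CEA",
                    comparator="standard of care",
                    real_unit_price=Money(as_decimal(round(price, 2)), "EUR"),
                    cea=None,
                )
            )
    return records
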