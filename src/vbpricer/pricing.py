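"""Cost-effectiveness algebra for value-based device pricing.

A new intervention A (device plus its delivery costs) is compared with a
comparator B.  The incremental cost-effectiveness ratio is

    ICER = (cost_A - cost_B) / (QALYs_A - QALYs_B)

and, writing ``gain`` for the QALY difference and splitting
``cost_A = price_A + othercosts_A``, the device price at which the ICER
equals a willingness-to-pay threshold ``w`` is the *value-based price*

    VBP = w * gain - othercosts_A + cost_B.

Evaluating the same formula at a lower, secondary threshold yields a price
band whose upper end is the highest acceptable price.  All arithmetic is
exact decimal; rounding to whole euros is left to the presentation layer
(:func:`vbpricer.money.round_to_euro`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from decimal import Decimal
from typing import List, Optional, Tuple, Union

from .money import (
    CurrencyMismatchError,
    ExchangeRateTable,
    Money,
    Numberish,
    as_decimal,
    to_eur,
)

__all__ = [
    "OutcomeKind",
    "SourceKind",
    "SourceRef",
    "WTPThreshold",
    "CEAInputs",
    "Concordance",
    "VBPResult",
    "UndefinedICERError",
    "PRIMARY_WTP",
    "SECONDARY_WTP",
    "DEFAULT_BAND_FRACTION",
    "icer",
    "incremental_cost",
    "value_based_price",
    "survival_gain_one_year",
    "other_costs_from_delta",
    "price_band",
    "classify_concordance",
    "cea_inputs_to_eur",
    "vbp_warnings",
]

#: Sentinel accepted for :attr:`CEAInputs.time_horizon_months`.
LIFETIME = "lifetime"

DEFAULT_BAND_FRACTION = Decimal("0.2")


class UndefinedICERError(ZeroDivisionError):
    """Both arms have identical effectiveness, so the ICER is undefined."""


class OutcomeKind(str, enum.Enum):
    QALY = "QALY"
    LIFE_YEAR = "life_year"


class SourceKind(str, enum.Enum):
    """Provenance classes accepted for a published cost-effectiveness model."""

    CEA_REGISTRY = "CEA_registry"
    HTA_REPORT = "HTA_report"


@dataclass(frozen=True)
class SourceRef:
    """Free-text citation tag plus the provenance class of the CEA."""

    tag: str
    kind: SourceKind


@dataclass(frozen=True)
class WTPThreshold:
    """Willingness-to-pay threshold in EUR per QALY gained (strictly > 0)."""

    value: Decimal

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", as_decimal(self.value))
        if self.value <= 0:
            raise ValueError(f"WTP threshold must be > 0, got {self.value}")


#: Primary threshold: the price it implies is the highest acceptable one.
PRIMARY_WTP = WTPThreshold(Decimal(60_000))
#: Secondary threshold for the lower end of the proposed price band.
SECONDARY_WTP = WTPThreshold(Decimal(30_000))


@dataclass(frozen=True)
class CEAInputs:
    """Published cost-effectiveness parameters for one device.

    ``gain`` is the per-patient effectiveness gain of A over B, in QALYs or
    (flagged via ``outcome_kind``) life-years when the source reports only a
    survival difference.  ``cost_b`` is the comparator's total cost, kept
    aggregate — splitting it into price and other costs is unnecessary when
    solving for the price of A.  ``othercosts_a`` is every cost of
    delivering A except the device's own price.
    """

    gain: Decimal
    outcome_kind: OutcomeKind
    cost_b: Money
    othercosts_a: Money
    time_horizon_months: Union[int, str] = LIFETIME
    source: Optional[SourceRef] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gain", as_decimal(self.gain))
        object.__setattr__(self, "outcome_kind", OutcomeKind(self.outcome_kind))
        if isinstance(self.time_horizon_months, str):
            if self.time_horizon_months != LIFETIME:
                raise ValueError(
                    "time_horizon_months must be a positive integer or "
                    f"{LIFETIME!r}, got {self.time_horizon_months!r}"
                )
        elif self.time_horizon_months <= 0:
            raise ValueError("time_horizon_months must be positive")

    @property
    def in_eur(self) -> bool:
        return self.cost_b.currency == "EUR" and self.othercosts_a.currency == "EUR"


class Concordance(str, enum.Enum):
    """How the real market price relates to the value-based price."""

    CONCORDANT = "concordant"
    REAL_ABOVE_VBP = "real_above_vbp"
    VBP_ABOVE_REAL = "vbp_above_real"


@dataclass
class VBPResult:
    """Value-based price band for one device, compared with its real price.

    Monetary fields are unrounded EUR decimals; ``warnings`` carries flags
    such as ``life_year_proxy`` (survival difference used as the gain with
    implicit utility weight 1), ``negative_vbp`` and ``non_positive_gain``.
    """

    device_id: str
    vbp_primary_eur: Decimal
    vbp_secondary_eur: Decimal
    real_price_eur: Decimal
    ratio_real_to_vbp_primary: Optional[Decimal]
    concordance: Optional[Concordance]
    warnings: List[str] = field(default_factory=list)


def icer(
    cost_a: Money,
    cost_b: Money,
    qalys_a: Numberish,
    qalys_b: Numberish,
) -> Decimal:
    """Incremental cost-effectiveness ratio of A versus B, in cost per QALY.

    Signs are preserved: a negative ICER means one arm dominates on one
    axis (cheaper but worse, or dearer but better, depending on which
    difference is negative) and must be interpreted with both differences
    in view.

    Raises
    ------
    UndefinedICERError
        If the two arms have identical effectiveness; the message names
        the dominance situation.
    CurrencyMismatchError
        If the two costs are in different currencies.
    """
    if cost_a.currency != cost_b.currency:
        raise CurrencyMismatchError(
            f"ICER needs both costs in one currency, got "
            f"{cost_a.currency} and {cost_b.currency}"
        )
    qalys_a = as_decimal(qalys_a)
    qalys_b = as_decimal(qalys_b)
    if qalys_a == qalys_b:
        dc = cost_a.amount - cost_b.amount
        if dc == 0:
            situation = "the arms are equivalent on both axes"
        elif dc > 0:
            situation = "B dominates (equal effectiveness, A costs more)"
        else:
            situation = "A dominates (equal effectiveness, A costs less)"
        raise UndefinedICERError(
            f"ICER undefined for equal effectiveness: {situation}"
        )
    return (cost_a.amount - cost_b.amount) / (qalys_a - qalys_b)


def incremental_cost(icer_value: Numberish, gain: Numberish) -> Decimal:
    """Incremental cost of A versus B implied by an ICER and a QALY gain."""
    return as_decimal(icer_value) * as_decimal(gain)


def value_based_price(wtp: WTPThreshold, inputs: CEAInputs) -> Decimal:
    """Device price at which A's ICER equals the threshold, in EUR.

    Computes ``wtp * gain - othercosts_a + cost_b`` exactly; both monetary
    inputs must already be in EUR (convert with
    :func:`cea_inputs_to_eur` first).  A negative result is returned as-is:
    it signals that the device cannot be cost-effective at any positive
    price at this threshold.  ``gain <= 0`` is likewise allowed — use
    :func:`vbp_warnings` to surface both situations.
    """
    if not inputs.in_eur:
        raise CurrencyMismatchError(
            "value_based_price needs EUR inputs; got "
            f"cost_b in {inputs.cost_b.currency}, "
            f"othercosts_a in {inputs.othercosts_a.currency}"
        )
    return (
        wtp.value * inputs.gain
        - inputs.othercosts_a.amount
        + inputs.cost_b.amount
    )


def vbp_warnings(inputs: CEAInputs, vbp: Decimal) -> List[str]:
    """Warning flags a pricing result should carry for these inputs."""
    flags: List[str] = []
    if inputs.outcome_kind is OutcomeKind.LIFE_YEAR:
        flags.append("life_year_proxy")
    if inputs.gain <= 0:
        flags.append("non_positive_gain")
    if vbp < 0:
        flags.append("negative_vbp")
    return flags


def survival_gain_one_year(surv_a: Numberish, surv_b: Numberish) -> Decimal:
    """Effectiveness gain from one-year survival proportions, in life-years.

    ``surv_a - surv_b`` over a 12-month horizon is the expected life-year
    difference attributable to treatment at one year, usable as the gain
    term of the pricing formula with ``outcome_kind = life_year`` when no
    utility-weighted estimate is published.  No discounting is applied over
    the single year.
    """
    surv_a = as_decimal(surv_a)
    surv_b = as_decimal(surv_b)
    for name, s in (("surv_a", surv_a), ("surv_b", surv_b)):
        if not (0 <= s <= 1):
            raise ValueError(f"{name} must be a proportion in [0, 1], got {s}")
    return surv_a - surv_b


def other_costs_from_delta(delta_cost: Money, device_price: Money) -> Money:
    """Recover non-device intervention costs from an aggregate cost delta.

    Published CEAs often report only the total incremental cost of A versus
    B; subtracting the device's own price leaves ``othercosts_a``.  Both
    amounts must share a currency.  A negative result is returned (with the
    caller expected to flag it), since a delta below the device price is
    arithmetically possible in dominated comparisons.
    """
    return delta_cost - device_price


def price_band(
    inputs: CEAInputs,
    wtp_primary: WTPThreshold = PRIMARY_WTP,
    wtp_secondary: WTPThreshold = SECONDARY_WTP,
) -> Tuple[Decimal, Decimal]:
    """Proposed price range ``(low, high)`` for a device, in EUR.

    The low end is the value-based price at the secondary threshold, the
    high end the one at the primary threshold — the highest acceptable
    price.  For a non-negative gain the band is ordered low <= high.
    """
    if wtp_secondary.value > wtp_primary.value:
        raise ValueError(
            f"secondary threshold ({wtp_secondary.value}) must not exceed "
            f"primary ({wtp_primary.value})"
        )
    return (
        value_based_price(wtp_secondary, inputs),
        value_based_price(wtp_primary, inputs),
    )


def classify_concordance(
    vbp_primary: Numberish,
    real_price: Numberish,
    band_fraction: Numberish = DEFAULT_BAND_FRACTION,
) -> Concordance:
    """Classify a real price against the value-based price.

    ``concordant`` when the real price is within ``band_fraction``
    (default +/-20%) of the VBP, otherwise ``real_above_vbp`` or
    ``vbp_above_real``.  Published judgements of "very similar" versus
    "markedly higher" are qualitative; the band makes the comparison
    reproducible and is configurable.
    """
    vbp_primary = as_decimal(vbp_primary)
    real_price = as_decimal(real_price)
    band_fraction = as_decimal(band_fraction)
    if vbp_primary <= 0 or real_price <= 0:
        raise ValueError(
            "concordance classification needs positive prices; got "
            f"vbp={vbp_primary}, real={real_price} (inspect warnings instead)"
        )
    rel = real_price / vbp_primary - 1
    if rel > band_fraction:
        return Concordance.REAL_ABOVE_VBP
    if -rel > band_fraction:
        return Concordance.VBP_ABOVE_REAL
    return Concordance.CONCORDANT


def cea_inputs_to_eur(
    inputs: CEAInputs, rates: ExchangeRateTable, places: int = 6
) -> CEAInputs:
    """Copy of ``inputs`` with both cost terms converted to EUR.

    The gain is dimensionless in currency and passes through untouched.
    Raises :class:`vbpricer.money.MissingRateError` if a currency is not
    in the table.
    """
    return replace(
        inputs,
        cost_b=to_eur(inputs.cost_b, rates, places=places),
        othercosts_a=to_eur(inputs.othercosts_a, rates, places=places),
    )
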