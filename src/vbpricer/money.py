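"""Exact-decimal monetary amounts and currency conversion.

All monetary arithmetic in the package goes through :class:`Money`, a
currency-tagged :class:`~decimal.Decimal` amount.  Cross-currency maths is
deliberately impossible without an explicit :class:`ExchangeRateTable`,
whose rates follow the "1 EUR = X foreign units" convention (so conversion
*to* euro is a division).  Health-economic inputs are routinely published in
the currency of the originating study, and silent float conversion is a
classic source of irreproducible cost-effectiveness numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Union

__all__ = [
    "Money",
    "ExchangeRateTable",
    "CurrencyMismatchError",
    "MissingRateError",
    "to_eur",
    "round_to_euro",
    "as_decimal",
]

#: Aliases accepted in file input and normalised to ISO-style codes.
CURRENCY_ALIASES: Mapping[str, str] = {
    "R$": "BRL",
    "€": "EUR",
    "£": "GBP",
    "$": "USD",
}

Numberish = Union[Decimal, int, str, float]


class CurrencyMismatchError(ValueError):
    """Arithmetic attempted between amounts in different currencies."""


class MissingRateError(KeyError):
    """A currency code has no entry in the exchange-rate table."""

    def __init__(self, code: str) -> None:
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"no exchange rate for currency {self.code!r}"


def as_decimal(value: Numberish) -> Decimal:
    """Convert to :class:`Decimal` without inheriting binary-float noise.

    Floats are converted through their shortest ``repr`` so that e.g.
    ``0.13`` becomes ``Decimal('0.13')`` rather than the 55-digit binary
    expansion ``Decimal(0.13)`` would give.
    """
    if isinstance(value, Decimal):
        return value
    if isinstance(value, float):
        return Decimal(repr(value))
    return Decimal(value)


def normalize_currency(code: str) -> str:
    code = code.strip()
    return CURRENCY_ALIASES.get(code, code.upper())


@dataclass(frozen=True)
class Money:
    """An amount tagged with a currency code (``EUR``, ``GBP``, ``BRL``, ...).

    Addition, subtraction and comparison are defined only between equal
    currencies; anything else raises :class:`CurrencyMismatchError`.
    Scalar multiplication is allowed.  No implicit rounding ever happens.
    """

    amount: Decimal
    currency: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "amount", as_decimal(self.amount))
        object.__setattr__(self, "currency", normalize_currency(self.currency))

    def _check(self, other: "Money", op: str) -> None:
        if not isinstance(other, Money):
            raise TypeError(f"cannot {op} Money and {type(other).__name__}")
        if other.currency != self.currency:
            raise CurrencyMismatchError(
                f"cannot {op} {self.currency} and {other.currency}; "
                "convert explicitly first"
            )

    def __add__(self, other: "Money") -> "Money":
        self._check(other, "add")
        return Money(self.amount + other.amount, self.currency)

    def __sub__(self, other: "Money") -> "Money":
        self._check(other, "subtract")
        return Money(self.amount - other.amount, self.currency)

    def __neg__(self) -> "Money":
        return Money(-self.amount, self.currency)

    def __mul__(self, k: Numberish) -> "Money":
        return Money(self.amount * as_decimal(k), self.currency)

    __rmul__ = __mul__

    def __lt__(self, other: "Money") -> bool:
        self._check(other, "compare")
        return self.amount < other.amount

    def __le__(self, other: "Money") -> bool:
        self._check(other, "compare")
        return self.amount <= other.amount

    def __str__(self) -> str:
        return f"{self.currency} {self.amount}"


@dataclass(frozen=True)
class ExchangeRateTable:
    """Units of foreign currency per one euro, with an as-of date string.

    The direction is fixed as foreign-units-per-EUR (``1 EUR = 0.833 GBP``
    is stored as ``{"GBP": 0.833}``) to remove reciprocal ambiguity; the
    as-of date travels with the table so users can supply rates matching
    the period of the source cost data.
    """

    rates: Mapping[str, Decimal]
    as_of: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for code, rate in self.rates.items():
            code = normalize_currency(code)
            rate = as_decimal(rate)
            if rate <= 0:
                raise ValueError(f"rate for {code} must be > 0, got {rate}")
            clean[code] = rate
        clean.setdefault("EUR", Decimal(1))
        if clean["EUR"] != 1:
            raise ValueError(f"EUR must map to exactly 1, got {clean['EUR']}")
        object.__setattr__(self, "rates", clean)

    def rate(self, currency: str) -> Decimal:
        code = normalize_currency(currency)
        try:
            return self.rates[code]
        except KeyError:
            raise MissingRateError(code) from None

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ExchangeRateTable":
        """Load ``{"as_of": ..., "rates": {"EUR": 1, "GBP": 0.833, ...}}``."""
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh, parse_float=Decimal, parse_int=Decimal)
        return cls(rates=payload["rates"], as_of=str(payload.get("as_of", "")))


def to_eur(m: Money, rates: ExchangeRateTable, places: int = 6) -> Money:
    """Convert ``m`` to euro by exact-decimal division by its rate.

    The quotient is rounded half-up to ``places`` decimal places
    (default 6); pass a larger ``places`` if downstream algebra needs more.
    """
    if m.currency == "EUR":
        return m
    quotient = m.amount / rates.rate(m.currency)
    quantum = Decimal(1).scaleb(-places)
    return Money(quotient.quantize(quantum, rounding=ROUND_HALF_UP), "EUR")


def round_to_euro(amount: Decimal) -> Decimal:
    """Presentation rounding: nearest whole euro, ties away from zero."""
    return amount.quantize(Decimal(1), rounding=ROUND_HALF_UP)
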