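"""Run configuration for the pricing pipeline and its CLI."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Optional, Union

import yaml

from .money import as_decimal
from .pricing import DEFAULT_BAND_FRACTION, WTPThreshold

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Thresholds and knobs for one pipeline run.

    Defaults follow the reference analysis: a primary willingness-to-pay
    threshold of 60,000 EUR/QALY (whose price is the highest acceptable
    one), a secondary threshold of 30,000 EUR/QALY for the low end of the
    price band, a +/-20% concordance band and 6-decimal currency
    conversion.  Precedence when used from the CLI: flags > config file >
    these defaults.
    """

    wtp_primary: Decimal = Decimal(60_000)
    wtp_secondary: Decimal = Decimal(30_000)
    band_fraction: Decimal = DEFAULT_BAND_FRACTION
    conversion_places: int = 6

    def __post_init__(self) -> None:
        self.wtp_primary = as_decimal(self.wtp_primary)
        self.wtp_secondary = as_decimal(self.wtp_secondary)
        self.band_fraction = as_decimal(self.band_fraction)
        if self.wtp_primary <= 0 or self.wtp_secondary <= 0:
            raise ValueError("WTP thresholds must be > 0")
        if self.wtp_secondary > self.wtp_primary:
            raise ValueError(
                f"secondary threshold ({self.wtp_secondary}) must not exceed "
                f"primary ({self.wtp_primary})"
            )
        if self.band_fraction < 0:
            raise ValueError("band_fraction must be >= 0")

    @property
    def primary_threshold(self) -> WTPThreshold:
        return WTPThreshold(self.wtp_primary)

    @property
    def secondary_threshold(self) -> WTPThreshold:
        return WTPThreshold(self.wtp_secondary)

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        """Load a YAML mapping of config fields; ``overrides`` win."""
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)
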