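"""Device-portfolio I/O, CEA-availability screening and the pricing pipeline.

A portfolio is a flat table, one row per device, mirroring the pricing
formula's symbols (``gain``, ``cost_b``, ``othercosts_a``, each cost with
its own currency column).  Devices whose rows carry no usable
cost-effectiveness parameters — the common case in practice — are kept and
counted, but only screened-in devices reach the pricing step.

CSV is the primary on-disk format (UTF-8, "." decimal separator regardless
of locale); a JSON list of row objects with the same field names is
accepted as a sidecar alternative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .money import ExchangeRateTable, Money, as_decimal, round_to_euro
from .pricing import (
    CEAInputs,
    Concordance,
    DEFAULT_BAND_FRACTION,
    OutcomeKind,
    PRIMARY_WTP,
    SECONDARY_WTP,
    SourceKind,
    SourceRef,
    VBPResult,
    WTPThreshold,
    cea_inputs_to_eur,
    classify_concordance,
    price_band,
    vbp_warnings,
)
from .money import to_eur

__all__ = [
    "DeviceRecord",
    "ScreeningSummary",
    "PipelineResult",
    "PortfolioValidationError",
    "ACCEPTED_SOURCE_KINDS",
    "read_portfolio",
    "write_portfolio",
    "screen",
    "run_pipeline",
    "write_results",
    "write_price_comparison_long",
    "concordance_tally",
]

logger = logging.getLogger(__name__)

#: Provenance classes accepted at screening: a curated cost-effectiveness
#: registry entry or a regional HTA report citing a peer-reviewed model.
ACCEPTED_SOURCE_KINDS = frozenset({SourceKind.CEA_REGISTRY, SourceKind.HTA_REPORT})

COLUMNS = [
    "device_id",
    "name",
    "description",
    "comparator",
    "real_price",
    "real_price_currency",
    "cea_available",
    "gain",
    "outcome_kind",
    "cost_b",
    "cost_b_currency",
    "othercosts_a",
    "othercosts_a_currency",
    "time_horizon_months",
    "source",
    "source_kind",
]


class PortfolioValidationError(ValueError):
    """One or more portfolio rows failed validation; lists row numbers."""

    def __init__(self, problems: Sequence[str]) -> None:
        self.problems = list(problems)
        super().__init__(
            "invalid portfolio rows:\n  " + "\n  ".join(self.problems)
        )


@dataclass(frozen=True)
class DeviceRecord:
    """One portfolio row: identity, real unit price, optional CEA inputs."""

    device_id: str
    name: str
    real_unit_price: Money
    description: str = ""
    comparator: str = ""
    cea: Optional[CEAInputs] = None

    def __post_init__(self) -> None:
        if self.real_unit_price.amount <= 0:
            raise ValueError(
                f"device {self.device_id}: real unit price must be > 0, "
                f"got {self.real_unit_price}"
            )


@dataclass(frozen=True)
class ScreeningSummary:
    """Counts of devices with usable cost-effectiveness data."""

    n_total: int
    n_eligible: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_eligible <= self.n_total:
            raise ValueError(
                f"need 0 <= n_eligible <= n_total, got "
                f"{self.n_eligible}/{self.n_total}"
            )

    @property
    def pct_eligible(self) -> float:
        """Eligible percentage to one decimal place (machine output)."""
        if self.n_total == 0:
            return 0.0
        return round(100.0 * self.n_eligible / self.n_total, 1)

    @property
    def pct_eligible_int(self) -> int:
        """Integer-rounded headline percentage."""
        return int(round(100.0 * self.n_eligible / self.n_total)) if self.n_total else 0


@dataclass
class PipelineResult:
    """Pricing results plus the screening summary and isolated failures."""

    results: List[VBPResult]
    summary: ScreeningSummary
    failures: List[Tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Reading and writing portfolios


def _parse_bool(raw: str) -> bool:
    return str(raw).strip().lower() in {"1", "true", "yes", "y"}


def _row_to_record(row: dict, rates: Optional[ExchangeRateTable]) -> DeviceRecord:
    price = Money(as_decimal(str(row["real_price"])), str(row["real_price_currency"]))
    cea = None
    if _parse_bool(row.get("cea_available", "")):
        horizon_raw = str(row["time_horizon_months"]).strip()
        horizon: Union[int, str]
        horizon = horizon_raw if horizon_raw == "lifetime" else int(horizon_raw)
        source = None
        if str(row.get("source", "")).strip():
            source = SourceRef(
                tag=str(row["source"]).strip(),
                kind=SourceKind(str(row["source_kind"]).strip()),
            )
        cea = CEAInputs(
            gain=as_decimal(str(row["gain"])),
            outcome_kind=OutcomeKind(str(row["outcome_kind"]).strip()),
            cost_b=Money(as_decimal(str(row["cost_b"])), str(row["cost_b_currency"])),
            othercosts_a=Money(
                as_decimal(str(row["othercosts_a"])),
                str(row["othercosts_a_currency"]),
            ),
            time_horizon_months=horizon,
            source=source,
        )
        if rates is not None:
            # fail fast with a row-level message rather than mid-pipeline
            rates.rate(cea.cost_b.currency)
            rates.rate(cea.othercosts_a.currency)
    return DeviceRecord(
        device_id=str(row["device_id"]).strip(),
        name=str(row.get("name", "")).strip(),
        description=str(row.get("description", "")).strip(),
        comparator=str(row.get("comparator", "")).strip(),
        real_unit_price=price,
        cea=cea,
    )


def read_portfolio(
    path: Union[str, Path],
    rates: Optional[ExchangeRateTable] = None,
) -> List[DeviceRecord]:
    """Read a device portfolio from CSV (or a JSON list of row objects).

    Every monetary field is parsed as an exact decimal together with its
    currency column.  Malformed rows are collected and reported together in
    a :class:`PortfolioValidationError` naming each offending row number.
    An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            raw_rows = json.load(fh)
        rows = [dict(r) for r in raw_rows]
    else:
        try:
            frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            frame = pd.DataFrame(columns=COLUMNS)
        rows = frame.to_dict(orient="records")
    if not rows:
        logger.warning("portfolio file %s contains no device rows", path)
        return []

    records: List[DeviceRecord] = []
    problems: List[str] = []
    for i, row in enumerate(rows, start=2):  # row 1 is the header
        try:
            records.append(_row_to_record(row, rates))
        except (KeyError, ValueError, InvalidOperation) as exc:
            problems.append(f"row {i} ({row.get('device_id', '?')}): {exc}")
    if problems:
        raise PortfolioValidationError(problems)
    return records


def write_portfolio(records: Iterable[DeviceRecord], path: Union[str, Path]) -> None:
    """Write records in the flat CSV schema read by :func:`read_portfolio`."""
    rows = []
    for rec in records:
        row = {
            "device_id": rec.device_id,
            "name": rec.name,
            "description": rec.description,
            "comparator": rec.comparator,
            "real_price": str(rec.real_unit_price.amount),
            "real_price_currency": rec.real_unit_price.currency,
            "cea_available": "true" if rec.cea else "false",
            "gain": "" if rec.cea is None else str(rec.cea.gain),
            "outcome_kind": "" if rec.cea is None else rec.cea.outcome_kind.value,
            "cost_b": "" if rec.cea is None else str(rec.cea.cost_b.amount),
            "cost_b_currency": "" if rec.cea is None else rec.cea.cost_b.currency,
            "othercosts_a": "" if rec.cea is None else str(rec.cea.othercosts_a.amount),
            "othercosts_a_currency": (
                "" if rec.cea is None else rec.cea.othercosts_a.currency
            ),
            "time_horizon_months": (
                "" if rec.cea is None else str(rec.cea.time_horizon_months)
            ),
            "source": "" if rec.cea is None or rec.cea.source is None else rec.cea.source.tag,
            "source_kind": (
                ""
                if rec.cea is None or rec.cea.source is None
                else rec.cea.source.kind.value
            ),
        }
        rows.append(row)
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Screening and the pipeline


def screen(
    records: Sequence[DeviceRecord],
) -> Tuple[List[DeviceRecord], ScreeningSummary]:
    """Split a portfolio into pricing-eligible devices and a count summary.

    A device is eligible when it carries CEA inputs whose provenance is one
    of the two accepted source classes (CEA registry entry or HTA report);
    a record with parameters but unstated provenance is not eligible.
    Input records are never mutated.
    """
    eligible = [
        r
        for r in records
        if r.cea is not None
        and r.cea.source is not None
        and r.cea.source.kind in ACCEPTED_SOURCE_KINDS
    ]
    summary = ScreeningSummary(n_total=len(records), n_eligible=len(eligible))
    logger.info(
        "screening: %d of %d devices carry usable CEA data (%s%%)",
        summary.n_eligible,
        summary.n_total,
        summary.pct_eligible,
    )
    return eligible, summary


def run_pipeline(
    records: Sequence[DeviceRecord],
    rates: ExchangeRateTable,
    wtp_primary: WTPThreshold = PRIMARY_WTP,
    wtp_secondary: WTPThreshold = SECONDARY_WTP,
    band_fraction: Decimal = DEFAULT_BAND_FRACTION,
) -> PipelineResult:
    """Screen, convert to EUR, price and classify a whole portfolio.

    For each eligible device: convert its cost terms to EUR, evaluate the
    value-based price at both thresholds, compare with the real price and
    classify concordance.  Deterministic given its inputs; results keep the
    input order.  A failure on one device is recorded in
    ``PipelineResult.failures`` and does not abort the batch.
    """
    if wtp_secondary.value > wtp_primary.value:
        raise ValueError("secondary threshold must not exceed primary")
    eligible, summary = screen(records)
    results: List[VBPResult] = []
    failures: List[Tuple[str, str]] = []
    for rec in eligible:
        try:
            results.append(
                _price_device(rec, rates, wtp_primary, wtp_secondary, band_fraction)
            )
        except Exception as exc:  # noqa: BLE001 - per-device isolation
            logger.error("device %s failed: %s", rec.device_id, exc)
            failures.append((rec.device_id, str(exc)))
    return PipelineResult(results=results, summary=summary, failures=failures)


def _price_device(
    rec: DeviceRecord,
    rates: ExchangeRateTable,
    wtp_primary: WTPThreshold,
    wtp_secondary: WTPThreshold,
    band_fraction: Decimal,
) -> VBPResult:
    assert rec.cea is not None
    inputs = cea_inputs_to_eur(rec.cea, rates)
    logger.debug(
        "device %s EUR inputs: gain=%s cost_b=%s othercosts_a=%s",
        rec.device_id,
        inputs.gain,
        inputs.cost_b,
        inputs.othercosts_a,
    )
    low, high = price_band(inputs, wtp_primary, wtp_secondary)
    real_eur = to_eur(rec.real_unit_price, rates)
    warnings = vbp_warnings(inputs, high)
    ratio: Optional[Decimal] = None
    concordance: Optional[Concordance] = None
    if high > 0 and real_eur.amount > 0:
        ratio = real_eur.amount / high
        concordance = classify_concordance(high, real_eur.amount, band_fraction)
    else:
        warnings.append("concordance_undefined")
    if warnings:
        logger.info("device %s warnings: %s", rec.device_id, ";".join(warnings))
    return VBPResult(
        device_id=rec.device_id,
        vbp_primary_eur=high,
        vbp_secondary_eur=low,
        real_price_eur=real_eur.amount,
        ratio_real_to_vbp_primary=ratio,
        concordance=concordance,
        warnings=warnings,
    )


def concordance_tally(results: Sequence[VBPResult]) -> dict:
    """Count results per concordance class (None excluded)."""
    tally = {c: 0 for c in Concordance}
    for res in results:
        if res.concordance is not None:
            tally[res.concordance] += 1
    return tally


# ---------------------------------------------------------------------------
# Results writers


def write_results(results: Sequence[VBPResult], path: Union[str, Path]) -> None:
    """Write one CSV row per priced device, monetary values in whole euros.

    The ratio of real price to primary VBP keeps three decimals; warnings
    are serialised as semicolon-joined tokens.
    """
    rows = []
    for res in results:
        rows.append(
            {
                "device_id": res.device_id,
                "vbp_secondary_eur": str(round_to_euro(res.vbp_secondary_eur)),
                "vbp_primary_eur": str(round_to_euro(res.vbp_primary_eur)),
                "real_price_eur": str(round_to_euro(res.real_price_eur)),
                "ratio_real_to_vbp_primary": (
                    ""
                    if res.ratio_real_to_vbp_primary is None
                    else str(
                        res.ratio_real_to_vbp_primary.quantize(Decimal("0.001"))
                    )
                ),
                "concordance": "" if res.concordance is None else res.concordance.value,
                "warnings": ";".join(res.warnings),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "device_id",
            "vbp_secondary_eur",
            "vbp_primary_eur",
            "real_price_eur",
            "ratio_real_to_vbp_primary",
            "concordance",
            "warnings",
        ],
    ).to_csv(path, index=False)


def write_price_comparison_long(
    results: Sequence[VBPResult],
    path: Union[str, Path],
    wtp_primary: WTPThreshold = PRIMARY_WTP,
    wtp_secondary: WTPThreshold = SECONDARY_WTP,
) -> None:
    """Long-format price table (device x threshold x price kind).

    One row per bar of a grouped price-comparison chart: the value-based
    price at each threshold plus the real price, whole-euro rounded.
    Suitable for direct plotting; no figure is rendered here.
    """
    rows = []
    for res in results:
        rows.append(
            {
                "device_id": res.device_id,
                "price_kind": "value_based",
                "wtp_eur_per_qaly": str(wtp_primary.value),
                "price_eur": str(round_to_euro(res.vbp_primary_eur)),
            }
        )
        rows.append(
            {
                "device_id": res.device_id,
                "price_kind": "value_based",
                "wtp_eur_per_qaly": str(wtp_secondary.value),
                "price_eur": str(round_to_euro(res.vbp_secondary_eur)),
            }
        )
        rows.append(
            {
                "device_id": res.device_id,
                "price_kind": "real",
                "wtp_eur_per_qaly": "",
                "price_eur": str(round_to_euro(res.real_price_eur)),
            }
        )
    pd.DataFrame(
        rows, columns=["device_id", "price_kind", "wtp_eur_per_qaly", "price_eur"]
    ).to_csv(path, index=False)
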