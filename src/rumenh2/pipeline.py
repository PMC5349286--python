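"""Wiring from measurement records to treatment-level [2H] reports.

``ledgers_frame`` computes the per-vessel-day [2H] ledger under both
caproate scenarios; ``h2_balance_report`` averages it over days then
vessels into the familiar rows-by-treatments layout (with SEM); smaller
helpers produce the greenhouse-gas and descriptive summaries. Computation
is always per experimental unit first, aggregation afterwards.

Treatments that received nitrate carry an unquantified extra [2H] sink
(nitrate reduction), so their consumption totals, balance and recovery are
reported only when a nitrate sink estimate (mmol [2H]/d) is supplied
explicitly; per-product rows are always reported.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conversions import DEFAULT_CONSTANTS, PhysicalConstants, molar_volume
from .records import VesselDayRecord
from .sinks import GwpCoefficients, co2_equivalents
from .stoichiometry import SCENARIOS, build_flux_table, ledger
from .summaries import aggregate_by_treatment, records_summary

#: Ledger report rows, matching the reference-table row keys.
REPORT_ROWS: tuple[str, ...] = (
    "acetate_production", "butyrate_production",
    "caproate_production_sc1", "caproate_production_sc2",
    "total_production_sc1", "total_production_sc2",
    "formate_consumption", "propionate_consumption", "valerate_consumption",
    "caproate_consumption_sc1", "caproate_consumption_sc2",
    "heptanoate_consumption", "methane_consumption", "hydrogen_consumption",
    "total_consumption_sc1", "total_consumption_sc2",
    "balance_mmol_sc1", "balance_mmol_sc2",
    "recovery_pct_sc1", "recovery_pct_sc2",
)

_PRODUCT_ROW = {"ch4": "methane", "h2": "hydrogen"}

#: Rows withheld for nitrate-dosed treatments unless a sink is supplied.
_INCOMPLETE_ROWS = tuple(r for r in REPORT_ROWS
                         if r.startswith(("total_consumption", "balance", "recovery")))


def ledgers_frame(records: Iterable[VesselDayRecord],
                  constants: PhysicalConstants = DEFAULT_CONSTANTS,
                  gas_mmol: Mapping[str, Mapping[str, float]] | None = None,
                  ) -> pd.DataFrame:
    """Per-record [2H] ledger under both scenarios, one row per vessel-day.

    ``gas_mmol`` optionally maps treatment -> per-gas mmol/d, overriding the
    records' own gas volumes (use when per-gas moles are known on a better
    basis than total volume x percentage).
    """
    rows = []
    for record in records:
        fluxes = build_flux_table(
            record, constants,
            gas_mmol=None if gas_mmol is None else gas_mmol.get(record.treatment))
        row: dict[str, object] = {"vessel": record.vessel_id,
                                  "treatment": record.treatment,
                                  "day": record.day}
        for scenario in SCENARIOS:
            sc = scenario.lower()
            led = ledger(fluxes, scenario)
            for product, value in led.produced.items():
                name = _PRODUCT_ROW.get(product, product)
                key = (f"{name}_production_{sc}" if product == "caproate"
                       else f"{name}_production")
                row[key] = value
            for product, value in led.consumed.items():
                name = _PRODUCT_ROW.get(product, product)
                key = (f"{name}_consumption_{sc}" if product == "caproate"
                       else f"{name}_consumption")
                row[key] = value
            row.setdefault(f"caproate_production_{sc}", 0.0)
            row.setdefault(f"caproate_consumption_{sc}", 0.0)
            row[f"total_production_{sc}"] = led.produced_total
            row[f"total_consumption_{sc}"] = led.consumed_total
            row[f"balance_mmol_{sc}"] = led.balance
            row[f"recovery_pct_{sc}"] = led.recovery
        rows.append(row)
    return pd.DataFrame(rows)


def _nitrate_dosed(records: Sequence[VesselDayRecord]) -> set[str]:
    return {r.treatment for r in records
            if (r.nitrate or 0.0) > 0.0 or (r.nitrite or 0.0) > 0.0}


def h2_balance_report(records: Sequence[VesselDayRecord],
                      constants: PhysicalConstants = DEFAULT_CONSTANTS,
                      gas_mmol: Mapping[str, Mapping[str, float]] | None = None,
                      nitrate_sink: Mapping[str, float] | None = None,
                      ) -> pd.DataFrame:
    """Treatment-mean [2H] balance table (rows x treatments, plus SEM).

    Ledgers are computed per vessel-day, averaged within vessel, then
    averaged over vessels; SEM is across vessels. For nitrate-dosed
    treatments the totals/balance/recovery cells are NaN unless
    ``nitrate_sink`` supplies that treatment's [2H] sink (mmol/d), in which
    case it is added to total consumption and the balance recomputed.
    """
    frame = ledgers_frame(records, constants, gas_mmol)
    treatments = list(dict.fromkeys(frame["treatment"]))
    nitrate_sink = dict(nitrate_sink or {})
    incomplete = _nitrate_dosed(records) - set(nitrate_sink)

    report = pd.DataFrame(index=list(REPORT_ROWS),
                          columns=treatments + ["SEM"], dtype=float)
    report.index.name = "item"
    for row in REPORT_ROWS:
        if row not in frame.columns:
            continue
        agg = aggregate_by_treatment(frame, row)
        for trt in treatments:
            if trt in agg.index:
                report.loc[row, trt] = agg.loc[trt, "mean"]
        # single pooled-SEM column, as reference tables print: mean over treatments
        report.loc[row, "SEM"] = agg["sem"].mean()

    for trt in treatments:
        sink = nitrate_sink.get(trt)
        if sink is not None:
            for sc in ("sc1", "sc2"):
                consumed = report.loc[f"total_consumption_{sc}", trt] + sink
                produced = report.loc[f"total_production_{sc}", trt]
                report.loc[f"total_consumption_{sc}", trt] = consumed
                report.loc[f"balance_mmol_{sc}", trt] = produced - consumed
                report.loc[f"recovery_pct_{sc}", trt] = 100.0 * consumed / produced
        elif trt in incomplete:
            report.loc[list(_INCOMPLETE_ROWS), trt] = np.nan
    return report


def display_round(report: pd.DataFrame) -> pd.DataFrame:
    """Round a ledger report for display: totals/balances to 1 decimal,
    per-product entries to 2, matching the conventional table layout."""
    rounded = report.copy()
    for row in rounded.index:
        decimals = 1 if row.startswith(("total_", "balance", "recovery",
                                        "acetate_production",
                                        "butyrate_production")) else 2
        rounded.loc[row] = rounded.loc[row].round(decimals)
    return rounded


def ghg_report(records: Sequence[VesselDayRecord],
               gwp: GwpCoefficients = GwpCoefficients()) -> pd.DataFrame:
    """CO2-equivalent gas production per treatment (L/d), mean and SEM.

    Per-gas volumes are total gas x fraction; the CO2-eq total is their
    GWP-weighted sum.
    """
    rows = []
    for r in records:
        if r.gas_total is None or not r.gas_fractions:
            continue
        volumes = {g: r.gas_total * pct / 100.0
                   for g, pct in r.gas_fractions.items()}
        rows.append({"vessel": r.vessel_id, "treatment": r.treatment,
                     "day": r.day, "gas_total_l": r.gas_total,
                     "ghg_co2eq_l": co2_equivalents(volumes, gwp)})
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("no gas measurements in records")
    out = {}
    for col in ("gas_total_l", "ghg_co2eq_l"):
        agg = aggregate_by_treatment(frame, col)
        out[f"{col}_mean"] = agg["mean"]
        out[f"{col}_sem"] = agg["sem"]
    return pd.DataFrame(out)


def ghg_from_gas_mmol(gas_mmol: Mapping[str, float],
                      constants: PhysicalConstants = DEFAULT_CONSTANTS,
                      gwp: GwpCoefficients = GwpCoefficients()) -> float:
    """CO2-eq volume (L/d) from per-gas daily moles."""
    vm = molar_volume(constants)
    volumes = {g: mmol * vm for g, mmol in gas_mmol.items()}  # mL/d
    return co2_equivalents(volumes, gwp) / 1000.0


def summary_report(records: Sequence[VesselDayRecord]) -> pd.DataFrame:
    """Treatment mean/SEM of the descriptive per-record summaries."""
    per_record = records_summary(records)
    value_cols = [c for c in per_record.columns
                  if c not in ("vessel", "treatment", "day")]
    out: dict[str, pd.Series] = {}
    for col in value_cols:
        agg = aggregate_by_treatment(per_record, col)
        out[f"{col}_mean"] = agg["mean"]
        out[f"{col}_sem"] = agg["sem"]
    return pd.DataFrame(out)


def run_pipeline(records: Sequence[VesselDayRecord],
                 constants: PhysicalConstants = DEFAULT_CONSTANTS,
                 gas_mmol: Mapping[str, Mapping[str, float]] | None = None,
                 nitrate_sink: Mapping[str, float] | None = None,
                 ) -> dict[str, pd.DataFrame]:
    """All result tables for one set of records.

    Returns ``{"ledgers": per-record ledgers, "h2_balance": treatment
    report, "ghg": CO2-eq table, "summaries": descriptive table}``.
    """
    if not records:
        raise ValueError("no records supplied")
    bundle = {
        "ledgers": ledgers_frame(records, constants, gas_mmol),
        "h2_balance": h2_balance_report(records, constants, gas_mmol,
                                        nitrate_sink).reset_index(),
        "summaries": summary_report(records).reset_index(),
    }
    try:
        bundle["ghg"] = ghg_report(records).reset_index()
    except ValueError:
        pass  # no gas data: GHG table simply absent
    return bundle
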