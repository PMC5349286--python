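"""Measurement records for a vessel x day fermentation design, and their CSV I/O.

One :class:`VesselDayRecord` holds everything measured on one fermentation
vessel on one study day: outflow VFA concentration and molar profile,
alcohols, nitrogen species, gas production and composition, dissolved H2,
substrate masses and microbial nitrogen. Missing measurements are ``None``
(or absent map entries) and are never conflated with measured zeros — a
nitrate concentration of 0.00 mM in a control vessel is a measurement.

The reader accepts tidy CSV (one row per vessel-day, wide analyte columns,
header mandatory) with documented column aliases; the writer emits CSV plus
a JSON twin with identical content so results round-trip losslessly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: VFA end products carried in the molar profile (mol/100 mol of the VFA sum).
VFA_PRODUCTS: tuple[str, ...] = (
    "formate",
    "acetate",
    "propionate",
    "butyrate",
    "isobutyrate",
    "valerate",
    "isovalerate",
    "caproate",
    "heptanoate",
)

#: Branched-chain VFA: measured and carried, but excluded from the [2H] ledger.
BRANCHED_CHAIN_VFA: tuple[str, ...] = ("isobutyrate", "isovalerate")

#: Acids whose molar shares are normalized to sum to 100. Formate is
#: reported on the same mol/100 mol basis but outside the normalized sum
#: (the printed profiles sum to 100 only over these eight).
NORMALIZED_VFA: tuple[str, ...] = tuple(p for p in VFA_PRODUCTS if p != "formate")

#: Fermentation gases; percentages are of this four-gas sum.
GASES: tuple[str, ...] = ("ch4", "h2", "co2", "n2o")

ALCOHOLS: tuple[str, ...] = ("ethanol", "n_propanol")


class SchemaError(ValueError):
    """A required column is missing or the file layout is unusable."""


class RecordValidationError(ValueError):
    """A record violates a physical or compositional invariant."""


def _check_nonneg(name: str, value: float | None, context: str = "") -> None:
    if value is not None and value < 0:
        raise RecordValidationError(f"{context}{name} must be >= 0, got {value}")


@dataclass
class VesselDayRecord:
    """All measurements taken on one vessel on one study day.

    Concentrations are mM, gas totals L/d, gas fractions % of the four-gas
    sum, dissolved H2 uM, masses g DM, microbial N mg/d. ``None`` / missing
    map entries mean "not measured".
    """

    vessel_id: str
    treatment: str
    day: int
    vfa_total: float | None = None
    vfa_profile: dict[str, float] = field(default_factory=dict)
    alcohols: dict[str, float] = field(default_factory=dict)
    ammonium: float | None = None
    nitrate: float | None = None
    nitrite: float | None = None
    gas_total: float | None = None
    gas_fractions: dict[str, float] = field(default_factory=dict)
    dissolved_h2: float | None = None
    substrate_in: float | None = None
    residue: float | None = None
    microbial_n: float | None = None
    om_fermented: float | None = None

    def __post_init__(self) -> None:
        self.day = int(self.day)
        ctx = f"vessel {self.vessel_id!r} day {self.day}: "
        for name in ("vfa_total", "ammonium", "nitrate", "nitrite", "gas_total",
                     "dissolved_h2", "substrate_in", "residue", "microbial_n",
                     "om_fermented"):
            _check_nonneg(name, getattr(self, name), ctx)
        for product, share in self.vfa_profile.items():
            if product not in VFA_PRODUCTS:
                raise RecordValidationError(f"{ctx}unknown VFA product {product!r}")
            _check_nonneg(f"vfa_profile[{product}]", share, ctx)
        for alcohol, conc in self.alcohols.items():
            if alcohol not in ALCOHOLS:
                raise RecordValidationError(f"{ctx}unknown alcohol {alcohol!r}")
            _check_nonneg(f"alcohols[{alcohol}]", conc, ctx)
        for gas, frac in self.gas_fractions.items():
            if gas not in GASES:
                raise RecordValidationError(f"{ctx}unknown gas {gas!r}")
            if not 0.0 <= frac <= 100.0:
                raise RecordValidationError(
                    f"{ctx}gas fraction {gas} must be in [0, 100] %, got {frac}")
        if all(p in self.vfa_profile for p in NORMALIZED_VFA):
            total = sum(self.vfa_profile[p] for p in NORMALIZED_VFA)
            if abs(total - 100.0) > 0.5:
                raise RecordValidationError(
                    f"{ctx}VFA profile (excluding formate) must sum to "
                    f"100 +/- 0.5, got {total:.3f}")

    def has_full_profile(self) -> bool:
        """True when every VFA product has a molar share."""
        return all(p in self.vfa_profile for p in VFA_PRODUCTS)


# Canonical column names and their accepted aliases (all matched
# case-insensitively, with '-'/' ' treated as '_').
_MANDATORY = ("vessel", "treatment", "day")

_SCALAR_COLUMNS: dict[str, tuple[str, ...]] = {
    "vfa_total": ("vfa_total", "vfa_total_mm", "total_vfa", "total_vfa_mm", "tvfa"),
    "ammonium": ("ammonium", "ammonium_mm", "nh4", "nh4_mm"),
    "nitrate": ("nitrate", "nitrate_mm", "no3", "no3_mm"),
    "nitrite": ("nitrite", "nitrite_mm", "no2", "no2_mm"),
    "gas_total": ("gas_total", "gas_total_l", "total_gas", "total_gas_l", "gp"),
    "dissolved_h2": ("dissolved_h2", "dissolved_h2_um", "dh2", "dh2_um"),
    "substrate_in": ("substrate_in", "substrate_in_g", "dm_in", "substrate_g"),
    "residue": ("residue", "residue_g", "dm_residue"),
    "microbial_n": ("microbial_n", "microbial_n_mg", "mn"),
    "om_fermented": ("om_fermented", "om_fermented_g", "omf"),
}

_PROFILE_COLUMNS = {p: (p, f"{p}_pct", f"{p}_mol_pct") for p in VFA_PRODUCTS}
_ALCOHOL_COLUMNS = {
    "ethanol": ("ethanol", "ethanol_mm", "etoh"),
    "n_propanol": ("n_propanol", "n_propanol_mm", "propanol", "propoh"),
}
_GAS_COLUMNS = {g: (f"{g}_pct", g, f"{g}_percent") for g in GASES}

_VESSEL_ALIASES = ("vessel", "vessel_id", "fermenter", "fermenter_id")
_TREATMENT_ALIASES = ("treatment", "trt", "diet", "substrate")
_DAY_ALIASES = ("day", "study_day", "d")


def column_aliases() -> dict[str, tuple[str, ...]]:
    """Accepted spellings for every input column, keyed by canonical name."""
    table: dict[str, tuple[str, ...]] = {
        "vessel": _VESSEL_ALIASES,
        "treatment": _TREATMENT_ALIASES,
        "day": _DAY_ALIASES,
    }
    table.update(_SCALAR_COLUMNS)
    table.update(_PROFILE_COLUMNS)
    table.update(_ALCOHOL_COLUMNS)
    table.update(_GAS_COLUMNS)
    return table


def _normalize(name: str) -> str:
    return name.strip().lower().replace("-", "_").replace(" ", "_")


def _resolve_columns(columns: Sequence[str]) -> tuple[dict[str, str], list[str]]:
    """Map canonical field -> actual column name; also return unknown columns."""
    normalized = {_normalize(c): c for c in columns}
    mapping: dict[str, str] = {}
    claimed: set[str] = set()
    for canonical, aliases in column_aliases().items():
        for alias in aliases:
            if alias in normalized:
                mapping[canonical] = normalized[alias]
                claimed.add(normalized[alias])
                break
    unknown = [c for c in columns if c not in claimed]
    return mapping, unknown


def _cell(row: pd.Series, col: str | None) -> float | None:
    if col is None:
        return None
    value = row[col]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_records(path: str | Path, *, delimiter: str = ",",
                 on_unknown: str = "warn") -> list[VesselDayRecord]:
    """Read a tidy CSV of vessel-day measurements.

    Parameters
    ----------
    path : path-like
        CSV file with a header row; one row per (vessel, day).
    delimiter : str
        Field delimiter, default comma.
    on_unknown : {"warn", "ignore", "error"}
        What to do with unrecognized columns. They are never silently
        dropped: "warn" emits a UserWarning listing them.

    Returns
    -------
    list of VesselDayRecord
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter)
    mapping, unknown = _resolve_columns(list(frame.columns))
    missing = [m for m in _MANDATORY if m not in mapping]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"accepted aliases: {[column_aliases()[m] for m in missing]}")
    if unknown:
        if on_unknown == "error":
            raise SchemaError(f"{path}: unknown column(s) {unknown}")
        if on_unknown == "warn":
            import warnings

            warnings.warn(f"{path}: ignoring unknown column(s) {unknown}",
                          UserWarning, stacklevel=2)

    records: list[VesselDayRecord] = []
    for idx, row in frame.iterrows():
        profile = {p: v for p in VFA_PRODUCTS
                   if (v := _cell(row, mapping.get(p))) is not None}
        alcohols = {a: v for a in ALCOHOLS
                    if (v := _cell(row, mapping.get(a))) is not None}
        fractions = {g: v for g in GASES
                     if (v := _cell(row, mapping.get(g))) is not None}
        try:
            records.append(VesselDayRecord(
                vessel_id=str(row[mapping["vessel"]]),
                treatment=str(row[mapping["treatment"]]),
                day=int(row[mapping["day"]]),
                vfa_total=_cell(row, mapping.get("vfa_total")),
                vfa_profile=profile,
                alcohols=alcohols,
                ammonium=_cell(row, mapping.get("ammonium")),
                nitrate=_cell(row, mapping.get("nitrate")),
                nitrite=_cell(row, mapping.get("nitrite")),
                gas_total=_cell(row, mapping.get("gas_total")),
                gas_fractions=fractions,
                dissolved_h2=_cell(row, mapping.get("dissolved_h2")),
                substrate_in=_cell(row, mapping.get("substrate_in")),
                residue=_cell(row, mapping.get("residue")),
                microbial_n=_cell(row, mapping.get("microbial_n")),
                om_fermented=_cell(row, mapping.get("om_fermented")),
            ))
        except RecordValidationError as err:
            raise RecordValidationError(f"{path} row {idx + 2}: {err}") from err
    return records


def records_to_frame(records: Iterable[VesselDayRecord]) -> pd.DataFrame:
    """Flatten records into the same tidy layout the reader accepts."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "vessel": r.vessel_id, "treatment": r.treatment, "day": r.day,
            "vfa_total": r.vfa_total, "ammonium": r.ammonium,
            "nitrate": r.nitrate, "nitrite": r.nitrite,
            "gas_total": r.gas_total, "dissolved_h2": r.dissolved_h2,
            "substrate_in": r.substrate_in, "residue": r.residue,
            "microbial_n": r.microbial_n, "om_fermented": r.om_fermented,
        }
        for p in VFA_PRODUCTS:
            row[p] = r.vfa_profile.get(p)
        for a in ALCOHOLS:
            row[a] = r.alcohols.get(a)
        for g in GASES:
            row[f"{g}_pct"] = r.gas_fractions.get(g)
        rows.append(row)
    return pd.DataFrame(rows)


def write_records(records: Iterable[VesselDayRecord], path: str | Path) -> None:
    """Write records as tidy CSV (round-trips through :func:`read_records`)."""
    records_to_frame(records).to_csv(path, index=False)


def write_results(tables: Mapping[str, pd.DataFrame], directory: str | Path) -> None:
    """Write each result table as ``<name>.csv`` plus a ``<name>.json`` twin.

    The JSON twin carries the identical content in record orientation so
    downstream tooling never needs to re-parse CSV; both round-trip through
    :func:`read_results` within 1e-9.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(directory / f"{name}.csv", index=False)
        payload = {"columns": list(table.columns),
                   "rows": json.loads(table.to_json(orient="values"))}
        (directory / f"{name}.json").write_text(
            json.dumps(payload, indent=1, allow_nan=True))


def read_results(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read back every table written by :func:`write_results` (from the JSON twins)."""
    directory = Path(directory)
    out: dict[str, pd.DataFrame] = {}
    for path in sorted(directory.glob("*.json")):
        payload = json.loads(path.read_text())
        out[path.stem] = pd.DataFrame(payload["rows"], columns=payload["columns"])
    return out
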