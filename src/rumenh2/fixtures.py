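"""Treatment-mean reference tables from the source RUSITEC experiment.

The package ships the printed treatment means (and SEM column) of the
study's substrate-composition, gas, fermentation, microbial-protein and
[2H]-balance tables as read-only fixtures. They serve three purposes:
worked-example inputs for the pipeline, calibration targets for tests, and
default treatment profiles for the synthetic-data generator.

Treatments: CON (control), NIT (nitrate), NOP (3-nitrooxypropanol),
AQ (anthraquinone). Values are stored exactly as printed; entries the study
deliberately did not compute (NIT [2H] consumption totals and balances,
because the nitrate sink was unquantified) are ``None``.
"""

from __future__ import annotations

from types import MappingProxyType, SimpleNamespace
from typing import Mapping

import pandas as pd

from .records import VesselDayRecord

TREATMENTS: tuple[str, ...] = ("CON", "NIT", "NOP", "AQ")

#: Daily nitrate dose for NIT, mg NO3-/vessel/d.
NITRATE_DOSE_MG = 803.0
#: Molar mass of the nitrate anion, g/mol.
NITRATE_MOLAR_MASS = 62.004
#: Daily dose of the NOP active compound (1,3-propanediol mononitrate), mg/d.
NOP_DOSE_MG = 5.0
#: Molar mass of 1,3-propanediol mononitrate (C3H7NO4), g/mol.
NOP_MOLAR_MASS = 121.09
#: Substrate offered per vessel, g DM/d.
SUBSTRATE_DM_G = 10.0


def _table(rows: dict[str, tuple]) -> Mapping[str, Mapping[str, float | None]]:
    cols = TREATMENTS + ("SEM",)
    return MappingProxyType({
        label: MappingProxyType(dict(zip(cols, values)))
        for label, values in rows.items()
    })


# Substrate ingredient and chemical composition (% of DM).
_T1 = _table({
    "corn_silage":              (60.0, 60.0, 60.0, 60.0, None),
    "barley_grain":             (28.0, 28.0, 28.0, 28.0, None),
    "urea":                     (4.26, 0.0, 4.26, 4.26, None),
    "calcium_carbonate":        (4.50, 0.0, 4.50, 4.50, None),
    "calcium_ammonium_nitrate": (0.0, 10.7, 0.0, 0.0, None),
    "nop_active":               (0.0, 0.0, 0.05, 0.0, None),
    "nop_carrier":              (0.38, 0.38, 0.38, 0.38, None),
    "dicalcium_phosphate":      (2.86, 0.92, 2.81, 2.86, None),
    "om_pct_dm":                (89.2, 92.3, 89.7, 93.1, None),
    "cp_pct_dm":                (17.9, 18.8, 23.6, 23.6, None),
    "npn_pct_dm":               (2.00, 2.00, 2.00, 2.00, None),
    "ndf_pct_dm":               (39.7, 35.1, 36.5, 39.7, None),
    "adf_pct_dm":               (20.3, 17.1, 17.6, 19.8, None),
})

# Gas production (L/d), composition (% of the CH4+H2+CO2+N2O sum),
# dissolved H2 (uM) and substrate disappearance (%).
_T3 = _table({
    "gas_total":         (0.74, 0.54, 0.63, 0.76, 0.066),
    "ghg_co2eq":         (1.00, 0.16, 0.34, 0.83, 0.122),
    "ch4_pct":           (17.1, 3.6, 5.0, 12.6, 0.84),
    "h2_pct":            (2.0, 1.0, 10.3, 6.6, 0.99),
    "co2_pct":           (80.9, 95.4, 84.7, 80.9, 1.19),
    "n2o_pct":           (0.00, 0.04, 0.00, 0.00, 0.006),
    "dissolved_h2":      (40.8, 28.7, 53.7, 9.7, 3.79),
    "dm_disappearance":  (47.9, 43.3, 46.6, 45.7, 2.07),
    "om_disappearance":  (47.9, 45.2, 48.1, 46.6, 1.97),
    "cp_disappearance":  (77.4, 69.5, 78.6, 75.4, 1.97),
})

# Fermentation variables: pH, total VFA (mM), VFA molar profile
# (mol/100 mol), ratios, alcohols/ammonium/nitrate/nitrite (mM).
_T4 = _table({
    "ph":          (6.92, 6.95, 6.97, 6.96, 0.016),
    "vfa_total":   (65.5, 50.9, 59.7, 63.8, 4.02),
    "formate":     (5.76, 5.52, 7.21, 5.68, 0.664),
    "acetate":     (52.1, 68.1, 44.7, 46.5, 0.82),
    "propionate":  (12.6, 11.3, 13.8, 11.3, 0.69),
    "butyrate":    (15.3, 13.5, 17.4, 16.3, 0.47),
    "isobutyrate": (0.56, 0.30, 0.53, 0.47, 0.022),
    "valerate":    (5.56, 4.05, 8.26, 5.92, 0.187),
    "isovalerate": (7.61, 0.84, 6.03, 6.83, 0.268),
    "caproate":    (4.72, 1.43, 6.96, 9.50, 0.671),
    "heptanoate":  (1.57, 0.48, 2.31, 3.15, 0.222),
    "a_to_p":      (4.16, 6.36, 3.28, 4.18, 0.391),
    "ab_to_p":     (5.38, 7.57, 4.54, 5.64, 0.431),
    "ethanol":     (5.89, 9.92, 7.68, 4.25, 0.600),
    "n_propanol":  (0.19, 0.16, 0.41, 0.16, 0.044),
    "ammonium":    (14.1, 11.3, 19.2, 19.6, 0.54),
    "nitrate":     (0.00, 0.27, 0.00, 0.00, 0.053),
    "nitrite":     (0.00, 0.03, 0.00, 0.00, 0.008),
})

# Microbial nitrogen production (mg/d) and efficiency of microbial protein
# synthesis (g microbial N / kg OM fermented).
_T5 = _table({
    "microbial_n_total":  (59.8, 69.7, 54.2, 51.7, 2.68),
    "microbial_n_sap":    (33.6, 36.6, 33.8, 30.4, 1.64),
    "microbial_n_wap":    (5.6, 4.8, 4.9, 4.4, 0.58),
    "microbial_n_liquid": (22.4, 28.8, 15.6, 16.9, 2.42),
    "emps":               (15.9, 18.5, 14.1, 13.3, 0.91),
})

# [2H] balance (mmol/d; recovery in %). SC1: caproate via propionyl-CoA
# condensation (a [2H] sink); SC2: caproate via acetyl-CoA condensation
# (a [2H] source). NIT consumption totals/balances were not computed.
_T7 = _table({
    "acetate_production":        (42.7, 43.1, 33.4, 37.2, 2.53),
    "butyrate_production":       (12.5, 8.7, 13.1, 13.1, 1.08),
    "caproate_production_sc1":   (0.0, 0.0, 0.0, 0.0, 0.0),
    "caproate_production_sc2":   (3.88, 0.92, 5.01, 7.51, 0.302),
    "total_production_sc1":      (55.2, 51.8, 46.5, 50.3, 3.54),
    "total_production_sc2":      (59.1, 52.7, 51.5, 57.9, 3.41),
    "formate_consumption":       (2.33, 1.65, 2.58, 2.25, 0.157),
    "propionate_consumption":    (5.17, 3.71, 5.25, 4.53, 0.549),
    "valerate_consumption":      (2.28, 1.33, 3.09, 2.35, 0.193),
    "caproate_consumption_sc1":  (7.75, 1.83, 10.02, 15.02, 0.605),
    "caproate_consumption_sc2":  (0.0, 0.0, 0.0, 0.0, 0.0),
    "heptanoate_consumption":    (1.29, 0.30, 1.66, 2.49, 0.100),
    "methane_consumption":       (4.54, 0.24, 1.00, 3.79, 0.562),
    "hydrogen_consumption":      (0.16, 0.03, 0.46, 0.65, 0.096),
    "total_consumption_sc1":     (23.5, None, 24.0, 30.8, 1.08),
    "total_consumption_sc2":     (15.8, None, 13.7, 16.0, 0.89),
    "balance_mmol_sc1":          (31.7, None, 21.4, 19.9, 2.50),
    "balance_mmol_sc2":          (43.3, None, 36.2, 42.1, 1.71),
    "recovery_pct_sc1":          (42.4, None, 54.3, 61.2, 2.99),
    "recovery_pct_sc2":          (26.6, None, 27.7, 27.5, 1.14),
})

TABLES: Mapping[str, Mapping[str, Mapping[str, float | None]]] = MappingProxyType({
    "T1": _T1, "T3": _T3, "T4": _T4, "T5": _T5, "T7": _T7,
})


class FixtureTable:
    """Read-only view of one reference table, indexable by treatment."""

    def __init__(self, table_id: str, data: Mapping[str, Mapping[str, float | None]]):
        self.table_id = table_id
        self._data = data

    def rows(self) -> tuple[str, ...]:
        return tuple(self._data)

    def value(self, row: str, treatment: str) -> float | None:
        try:
            return self._data[row][treatment]
        except KeyError as err:
            raise KeyError(
                f"{self.table_id}: no cell ({row!r}, {treatment!r})") from err

    def sem(self, row: str) -> float | None:
        return self.value(row, "SEM")

    def __getitem__(self, treatment: str) -> SimpleNamespace:
        if treatment not in TREATMENTS:
            raise KeyError(f"{self.table_id}: unknown treatment {treatment!r}")
        return SimpleNamespace(**{row: vals[treatment]
                                  for row, vals in self._data.items()})

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {col: [self._data[row][col] for row in self._data]
             for col in TREATMENTS + ("SEM",)},
            index=list(self._data))
        frame.index.name = "item"
        return frame


def fixture(table_id: str) -> FixtureTable:
    """Return one reference table (``T1``, ``T3``, ``T4``, ``T5`` or ``T7``)."""
    try:
        return FixtureTable(table_id, TABLES[table_id])
    except KeyError as err:
        raise KeyError(
            f"unknown table id {table_id!r}; known: {sorted(TABLES)}") from err


def mean_record(treatment: str) -> VesselDayRecord:
    """Build a :class:`VesselDayRecord` from one treatment's printed means.

    The record represents the "average vessel-day" of that treatment and is
    directly usable as pipeline input (the worked example of the README).
    Residue and OM fermented are derived from the 10 g DM/d substrate, its
    OM content and the printed disappearance fractions.
    """
    if treatment not in TREATMENTS:
        raise KeyError(f"unknown treatment {treatment!r}")
    t1, t3, t4, t5 = (fixture(t)[treatment] for t in ("T1", "T3", "T4", "T5"))
    om_in = SUBSTRATE_DM_G * t1.om_pct_dm / 100.0
    return VesselDayRecord(
        vessel_id=f"{treatment}-mean",
        treatment=treatment,
        day=0,
        vfa_total=t4.vfa_total,
        vfa_profile={p: getattr(t4, p) for p in (
            "formate", "acetate", "propionate", "butyrate", "isobutyrate",
            "valerate", "isovalerate", "caproate", "heptanoate")},
        alcohols={"ethanol": t4.ethanol, "n_propanol": t4.n_propanol},
        ammonium=t4.ammonium,
        nitrate=t4.nitrate,
        nitrite=t4.nitrite,
        gas_total=t3.gas_total,
        gas_fractions={"ch4": t3.ch4_pct, "h2": t3.h2_pct,
                       "co2": t3.co2_pct, "n2o": t3.n2o_pct},
        dissolved_h2=t3.dissolved_h2,
        substrate_in=SUBSTRATE_DM_G,
        residue=SUBSTRATE_DM_G * (1.0 - t3.dm_disappearance / 100.0),
        microbial_n=t5.microbial_n_total,
        om_fermented=om_in * t3.om_disappearance / 100.0,
    )


def reference_gas_mmol(treatment: str) -> dict[str, float]:
    """Per-gas daily moles (mmol/d) consistent with the printed [2H] table.

    The printed total-gas volume times the printed percentages does not
    reconcile with the gas rows of the [2H] balance table (the basis of the
    percentages relative to total bag volume is ambiguous), so worked
    examples take gas moles backed out of that table directly: CH4 flux =
    its [2H] consumption / 4, gaseous H2 flux = its [2H] consumption / 1.
    """
    t7 = fixture("T7")[treatment]
    return {"ch4": t7.methane_consumption / 4.0,
            "h2": t7.hydrogen_consumption / 1.0}
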