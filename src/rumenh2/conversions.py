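"""Unit physics for fermentation gas and outflow accounting.

Everything downstream of the raw bench measurements needs the same four
conversions: an ideal-gas molar volume at incubator temperature, gas volume
to moles, outflow concentration to a daily molar flux, and the saliva
dilution rate of the vessel. They are collected here with explicit unit
bookkeeping (mL vs L, mM vs mmol/d) so the stoichiometric ledger can stay
unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Universal gas constant, J/(mol K).
GAS_CONSTANT = 8.314

#: Rounded molar volume (L/mol) conventionally used in rumen gas work at
#: 39 degC and 1.013e5 Pa; selectable via ``PhysicalConstants(molar_volume="paper")``.
ROUNDED_MOLAR_VOLUME_39C = 25.6


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical configuration of the fermentation system.

    Parameters
    ----------
    temperature : float
        Incubation temperature in K. Default 312.15 K (39 degC).
    pressure : float
        Headspace pressure in Pa. Default 1.013e5 Pa.
    outflow_volume : float
        Daily artificial-saliva infusion (= outflow) in L/d. Default 0.626.
    vessel_volume : float
        Working volume of one fermentation vessel in mL. Default 900.
    molar_volume : str
        ``"exact"`` (default) uses R*T/P; ``"paper"`` forces the rounded
        25.6 L/mol so printed report tables can be reproduced bit-for-bit.
    """

    temperature: float = 312.15
    pressure: float = 1.013e5
    outflow_volume: float = 0.626
    vessel_volume: float = 900.0
    molar_volume: str = "exact"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.pressure <= 0:
            raise ValueError(f"pressure must be > 0 Pa, got {self.pressure}")
        if self.outflow_volume < 0:
            raise ValueError(f"outflow_volume must be >= 0, got {self.outflow_volume}")
        if self.vessel_volume <= 0:
            raise ValueError(f"vessel_volume must be > 0, got {self.vessel_volume}")
        if self.molar_volume not in ("exact", "paper"):
            raise ValueError(f"molar_volume must be 'exact' or 'paper', got {self.molar_volume!r}")


DEFAULT_CONSTANTS = PhysicalConstants()


def molar_volume(constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Ideal-gas molar volume in L/mol at the system temperature and pressure.

    Computed as R*T/P (m^3/mol) and converted to L/mol. At the defaults
    (312.15 K, 1.013e5 Pa) this is 25.62 L/mol, i.e. 25.6 to 3 s.f.; with
    ``molar_volume="paper"`` the rounded 25.6 is returned exactly.
    """
    if constants.molar_volume == "paper":
        return ROUNDED_MOLAR_VOLUME_39C
    return GAS_CONSTANT * constants.temperature / constants.pressure * 1000.0


def gas_volume_to_mmol(volume_ml: float, molar_volume_l: float) -> float:
    """Convert a daily gas volume (mL/d) to mmol/d.

    mL/d divided by L/mol gives mmol/d directly (the factor 1000 from
    mL -> L cancels the one from mol -> mmol).
    """
    if volume_ml < 0:
        raise ValueError(f"gas volume must be >= 0 mL, got {volume_ml}")
    if molar_volume_l <= 0:
        raise ValueError(f"molar volume must be > 0 L/mol, got {molar_volume_l}")
    return volume_ml / molar_volume_l


def mmol_to_gas_volume(mmol: float, molar_volume_l: float) -> float:
    """Inverse of :func:`gas_volume_to_mmol`: mmol/d to mL/d."""
    if molar_volume_l <= 0:
        raise ValueError(f"molar volume must be > 0 L/mol, got {molar_volume_l}")
    return mmol * molar_volume_l


def concentration_to_daily_flux(concentration_mm: float, outflow_l: float) -> float:
    """Daily molar flux (mmol/d) of a solute leaving the vessel.

    The vessel is at steady state under constant saliva infusion, so the
    daily outflow of a solute is its outflow concentration (mM) times the
    daily infused volume (L/d).
    """
    if concentration_mm < 0:
        raise ValueError(f"concentration must be >= 0 mM, got {concentration_mm}")
    if outflow_l < 0:
        raise ValueError(f"outflow must be >= 0 L/d, got {outflow_l}")
    return concentration_mm * outflow_l


def dilution_rate(infusion_ml_per_d: float, vessel_volume_ml: float) -> float:
    """Fractional turnover of the vessel liquid phase, %/h.

    626 mL/d into a 900 mL vessel gives 2.9 %/h.
    """
    if vessel_volume_ml <= 0:
        raise ValueError(f"vessel volume must be > 0 mL, got {vessel_volume_ml}")
    if infusion_ml_per_d < 0:
        raise ValueError(f"infusion must be >= 0 mL/d, got {infusion_ml_per_d}")
    return infusion_ml_per_d / 24.0 / vessel_volume_ml * 100.0


def mass_to_mmol(mass_mg: float, molar_mass_g_per_mol: float) -> float:
    """Convert a daily mass dose (mg/d) to mmol/d given a molar mass (g/mol)."""
    if mass_mg < 0:
        raise ValueError(f"mass must be >= 0 mg, got {mass_mg}")
    if molar_mass_g_per_mol <= 0:
        raise ValueError(f"molar mass must be > 0 g/mol, got {molar_mass_g_per_mol}")
    return mass_mg / molar_mass_g_per_mol
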