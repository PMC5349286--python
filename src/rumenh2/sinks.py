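"""Auxiliary electron sinks and greenhouse-gas aggregation.

Besides the stoichiometric ledger, a methanogenesis-inhibition experiment
needs four side calculations:

* CO2-equivalent aggregation of the four fermentation gases with 100-year
  global warming potentials;
* the nitrate electron sink (dissimilatory nitrate reduction to ammonium
  and denitrification both draw ~4 [2H] per mol nitrate) and the extent of
  nitrate reduction;
* the [2H] incorporated into microbial biomass, estimated from daily
  microbial nitrogen production;
* the dissolved-H2 supersaturation factor Sf, the ratio of measured
  dissolved H2 to the Henry's-law concentration in equilibrium with the
  gaseous H2 partial pressure.

Every coefficient is explicit configuration; nothing here has hidden
defaults beyond the documented ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .fixtures import NITRATE_MOLAR_MASS


@dataclass(frozen=True)
class GwpCoefficients:
    """100-year global warming potentials (dimensionless, CO2 = 1)."""

    gwp: Mapping[str, float] = field(default_factory=lambda: {
        "co2": 1.0, "h2": 5.6, "ch4": 28.0, "n2o": 265.0})

    def __post_init__(self) -> None:
        for gas, value in self.gwp.items():
            if value < 0:
                raise ValueError(f"GWP for {gas} must be >= 0, got {value}")
        if self.gwp.get("co2") != 1.0:
            raise ValueError("CO2 GWP must be 1 by definition")


def co2_equivalents(per_gas_volumes: Mapping[str, float],
                    gwp: GwpCoefficients = GwpCoefficients()) -> float:
    """Total greenhouse gas as CO2-equivalent volume (same units as input).

    Sum over gases of volume x GWP. Because every GWP >= 1, the result is
    never below the raw summed volume, with equality only for pure CO2.
    """
    total = 0.0
    for gas, volume in per_gas_volumes.items():
        gas = gas.lower()
        if volume < 0:
            raise ValueError(f"volume for {gas} must be >= 0, got {volume}")
        if gas not in gwp.gwp:
            raise KeyError(f"no GWP configured for gas {gas!r}")
        total += volume * gwp.gwp[gas]
    return total


@dataclass(frozen=True)
class NitratePathwayConfig:
    """How nitrate consumption maps to [2H].

    Both DNRA (NO3- -> NH4+, 8 e-) and denitrification to N2O draw about
    4 [2H] per mol nitrate, so the default rule charges ``h2_per_nitrate``
    [2H] per mol of nitrate that disappeared (intake minus outflow).
    ``nitrite_rule`` optionally credits back the partial reduction state of
    outflowing nitrite: NO3- -> NO2- uses only 1 [2H], so nitrite that
    leaves the vessel should not be charged the full 4.
    """

    h2_per_nitrate: float = 4.0
    nitrate_molar_mass: float = NITRATE_MOLAR_MASS
    nitrite_rule: str = "ignore"  # "ignore" | "partial_credit"

    def __post_init__(self) -> None:
        if self.h2_per_nitrate <= 0:
            raise ValueError("h2_per_nitrate must be > 0")
        if self.nitrite_rule not in ("ignore", "partial_credit"):
            raise ValueError(f"unknown nitrite_rule {self.nitrite_rule!r}")


def nitrate_h2_sink(intake: float, nitrate_out: float, nitrite_out: float = 0.0,
                    n2o: float = 0.0,
                    config: NitratePathwayConfig = NitratePathwayConfig(),
                    ) -> float:
    """[2H] diverted to nitrate reduction, mmol/d.

    Default rule: ``h2_per_nitrate x (intake - nitrate_out)`` with all
    quantities in mmol/d. Under ``nitrite_rule="partial_credit"`` the
    outflowing nitrite is charged only 1 [2H] (its actual reduction state)
    instead of the full coefficient. The N2O branch is not charged extra by
    default: denitrified N also draws ~4 [2H]/mol NO3- and is a trace flow
    (~0.02 % of the dose) in the source experiment.
    """
    for name, value in (("intake", intake), ("nitrate_out", nitrate_out),
                        ("nitrite_out", nitrite_out), ("n2o", n2o)):
        if value < 0:
            raise ValueError(f"{name} must be >= 0 mmol/d, got {value}")
    if nitrate_out + nitrite_out > intake + 1e-9:
        raise ValueError(
            f"nitrate + nitrite outflow ({nitrate_out + nitrite_out:.4g}) "
            f"exceeds intake ({intake:.4g}) mmol/d")
    sink = config.h2_per_nitrate * (intake - nitrate_out)
    if config.nitrite_rule == "partial_credit":
        sink -= (config.h2_per_nitrate - 1.0) * nitrite_out
    return sink


def nitrate_reduction_extent(intake: float, nitrate_out: float,
                             nitrite_out: float = 0.0) -> float:
    """Upper bound on the % of supplied nitrate fully reduced to ammonium."""
    if intake <= 0:
        raise ValueError("nitrate intake must be > 0 mmol/d for an extent")
    if nitrate_out < 0 or nitrite_out < 0:
        raise ValueError("outflows must be >= 0 mmol/d")
    if nitrate_out + nitrite_out > intake + 1e-9:
        raise ValueError("outflow exceeds intake")
    return 100.0 * (intake - nitrate_out - nitrite_out) / intake


@dataclass(frozen=True)
class MicrobialH2Config:
    """[2H] cost of microbial biomass synthesis.

    Two bases are supported:

    * ``per_mg_n`` (default): ``coefficient`` mmol [2H] per mg microbial N.
      The shipped value is calibrated so that the control treatment of the
      reference experiment (59.8 mg N/d) costs 1.62 mmol [2H]/d.
    * ``per_g_cells``: the literature chain — ``coefficient`` mol [2H] per g
      dry cells, cells reconstructed from N via protein (N x 6.25 is not
      used directly: g protein = mg N / 1000 / n_per_protein, g cells =
      g protein / cp_per_cell).
    """

    basis: str = "per_mg_n"
    coefficient: float = 1.62 / 59.8  # mmol [2H] per mg microbial N
    cp_per_cell: float = 0.545        # g crude protein per g dry cell
    n_per_protein: float = 0.16       # g N per g microbial protein

    def __post_init__(self) -> None:
        if self.basis not in ("per_mg_n", "per_g_cells"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.coefficient < 0:
            raise ValueError("coefficient must be >= 0")
        for name in ("cp_per_cell", "n_per_protein"):
            value = getattr(self, name)
            if not 0.0 < value <= 10.0:
                raise ValueError(f"{name} must be in (0, 10], got {value}")


#: Literature chain preset: 0.41 mol [2H] per g dry microbial cells.
LITERATURE_MICROBIAL_CONFIG = MicrobialH2Config(
    basis="per_g_cells", coefficient=0.41)


def microbial_h2_sink(microbial_n: float,
                      config: MicrobialH2Config = MicrobialH2Config(),
                      ) -> float:
    """[2H] used for microbial biomass synthesis, mmol/d.

    Linear in microbial N for any configuration, so treatment ratios are
    coefficient-independent.
    """
    if microbial_n < 0:
        raise ValueError(f"microbial N must be >= 0 mg/d, got {microbial_n}")
    if config.basis == "per_mg_n":
        return config.coefficient * microbial_n
    g_cells = microbial_n / 1000.0 / config.n_per_protein / config.cp_per_cell
    return config.coefficient * g_cells * 1000.0  # mol -> mmol


@dataclass(frozen=True)
class HenryConfig:
    """Henry's-law constant for H2 at system temperature.

    No default is shipped: the user must supply a constant (uM dissolved H2
    per atm of H2 partial pressure) together with a provenance note.
    """

    henry_constant: float  # uM per atm
    reference: str = ""

    def __post_init__(self) -> None:
        if self.henry_constant <= 0:
            raise ValueError("henry_constant must be > 0 uM/atm")


def supersaturation_factor(dh2_measured: float, h2_partial_pressure: float,
                           config: HenryConfig) -> float:
    """Sf = measured dissolved H2 / Henry's-law equilibrium concentration.

    Sf = 1 at gas-liquid equilibrium; Sf > 1 means the liquid phase holds
    more H2 than the headspace partial pressure can explain (mass-transfer
    limitation from liquid to gas).
    """
    if dh2_measured < 0:
        raise ValueError(f"dissolved H2 must be >= 0 uM, got {dh2_measured}")
    if h2_partial_pressure <= 0:
        raise ValueError(
            f"H2 partial pressure must be > 0 atm for Sf, got {h2_partial_pressure}")
    return dh2_measured / (config.henry_constant * h2_partial_pressure)
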