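"""The metabolic-hydrogen ([2H]) ledger for rumen fermentation end products.

One [2H] is one reducing-equivalent pair (2 e- + 2 H+, i.e. one
H2-equivalent). Fermentation of glucose to each end product either releases
[2H] (acetate, butyrate, caproate via acetyl-CoA) or consumes it (formate,
propionate, valerate, caproate via propionyl-CoA, heptanoate, methane,
gaseous H2). The ledger multiplies each product's daily molar flux
(mmol/d) by its signed stoichiometric coefficient (mol [2H]/mol product)
and totals sources and sinks separately.

Caproate can arise from two condensation routes with opposite [2H] sign, so
every ledger is computed under a named scenario:

* ``SC1`` — all caproate from propionyl-CoA condensation: -4 [2H]/mol (sink).
* ``SC2`` — all caproate from 2 acetyl-CoA condensation: +2 [2H]/mol (source).

Branched-chain VFA (isobutyrate, isovalerate/2-methylbutyrate) derive from
amino-acid fermentation rather than glucose and are excluded from the
ledger; their fluxes are carried for descriptive summaries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import conversions
from .conversions import PhysicalConstants, DEFAULT_CONSTANTS
from .records import BRANCHED_CHAIN_VFA, VesselDayRecord

SCENARIOS: tuple[str, ...] = ("SC1", "SC2")


@dataclass(frozen=True)
class ReactionStoichiometry:
    """One end product's [2H] coefficient.

    ``h2_coefficient`` is mol [2H] per mol product: positive = released
    during the product's synthesis, negative = consumed. ``pathway`` is
    ``"default"`` except for the two caproate routes (``"SC1"``/``"SC2"``).
    """

    product: str
    h2_coefficient: int
    pathway: str = "default"


#: The shipped registry. Gaseous H2 is scored -1: each mol of H2 vented is
#: one [2H] pair leaving the system (it has no synthesis reaction row).
DEFAULT_REGISTRY: tuple[ReactionStoichiometry, ...] = (
    ReactionStoichiometry("formate", -1),
    ReactionStoichiometry("acetate", +2),
    ReactionStoichiometry("propionate", -1),
    ReactionStoichiometry("butyrate", +2),
    ReactionStoichiometry("valerate", -1),
    ReactionStoichiometry("caproate", -4, pathway="SC1"),
    ReactionStoichiometry("caproate", +2, pathway="SC2"),
    ReactionStoichiometry("heptanoate", -2),
    ReactionStoichiometry("ch4", -4),
    ReactionStoichiometry("h2", -1),
)

#: Alternative spellings accepted for registry products.
PRODUCT_ALIASES: Mapping[str, str] = {
    "methane": "ch4",
    "hydrogen": "h2",
    "gaseous_h2": "h2",
    "gh2": "h2",
}

#: Products that participate in the ledger (canonical names).
LEDGER_PRODUCTS: tuple[str, ...] = tuple(dict.fromkeys(
    entry.product for entry in DEFAULT_REGISTRY))


def canonical_product(product: str) -> str:
    return PRODUCT_ALIASES.get(product, product)


def h2_coefficient(product: str, scenario: str | None = None,
                   registry: Iterable[ReactionStoichiometry] = DEFAULT_REGISTRY,
                   ) -> int:
    """Signed mol [2H] per mol of ``product``; caproate resolved by scenario."""
    product = canonical_product(product)
    entries = [e for e in registry if e.product == product]
    if not entries:
        raise KeyError(f"unknown end product {product!r}; "
                       f"registry has {sorted({e.product for e in registry})}")
    if len(entries) == 1 and entries[0].pathway == "default":
        return entries[0].h2_coefficient
    if scenario is None:
        raise ValueError(f"{product!r} is scenario-dependent; pass scenario "
                         f"from {SCENARIOS}")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; known: {SCENARIOS}")
    for entry in entries:
        if entry.pathway == scenario:
            return entry.h2_coefficient
    raise KeyError(f"no {product!r} entry for scenario {scenario!r}")


@dataclass
class FluxTable:
    """Daily molar fluxes (mmol/d) of fermentation end products for one unit.

    ``fluxes`` maps product -> mmol/d over the ledger products plus the
    branched-chain VFA, which are carried but never scored (``excluded``).
    """

    unit_id: str
    fluxes: dict[str, float] = field(default_factory=dict)
    excluded: tuple[str, ...] = BRANCHED_CHAIN_VFA

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for product, flux in self.fluxes.items():
            name = canonical_product(product)
            if flux < 0:
                raise ValueError(
                    f"{self.unit_id}: flux for {name} must be >= 0 mmol/d, "
                    f"got {flux}")
            clean[name] = float(flux)
        self.fluxes = clean

    def ledger_fluxes(self) -> dict[str, float]:
        """Fluxes that participate in the [2H] ledger."""
        return {p: f for p, f in self.fluxes.items()
                if p in LEDGER_PRODUCTS and p not in self.excluded}

    def scaled(self, k: float) -> "FluxTable":
        return FluxTable(self.unit_id,
                         {p: k * f for p, f in self.fluxes.items()},
                         self.excluded)


def build_flux_table(record: VesselDayRecord,
                     constants: PhysicalConstants = DEFAULT_CONSTANTS,
                     gas_mmol: Mapping[str, float] | None = None) -> FluxTable:
    """Turn one vessel-day record into daily molar fluxes.

    VFA flux (mmol/d) = total VFA (mM) x molar share / 100 x daily outflow
    (L/d). Gas fluxes are taken from ``gas_mmol`` (mmol/d per gas) when
    supplied; otherwise they are derived from the record's total gas volume
    and percentages via the ideal-gas molar volume. Per-gas moles should be
    preferred whenever available, because total-bag volume x percentage is
    not always on the same basis as the four-gas sum.
    """
    if record.vfa_profile and record.vfa_total is None:
        raise ValueError(
            f"{record.vessel_id}: VFA profile present without total VFA "
            "concentration; cannot form molar fluxes")
    fluxes: dict[str, float] = {}
    if record.vfa_total is not None:
        for product, share in record.vfa_profile.items():
            fluxes[product] = conversions.concentration_to_daily_flux(
                record.vfa_total * share / 100.0, constants.outflow_volume)
    if gas_mmol is not None:
        for gas, mmol in gas_mmol.items():
            fluxes[canonical_product(gas)] = mmol
    elif record.gas_total is not None and record.gas_fractions:
        vm = conversions.molar_volume(constants)
        for gas, pct in record.gas_fractions.items():
            fluxes[gas] = conversions.gas_volume_to_mmol(
                record.gas_total * 1000.0 * pct / 100.0, vm)
    return FluxTable(unit_id=f"{record.vessel_id}/d{record.day}", fluxes=fluxes)


def h2_production(fluxes: FluxTable, scenario: str,
                  registry: Iterable[ReactionStoichiometry] = DEFAULT_REGISTRY,
                  ) -> tuple[dict[str, float], float]:
    """Per-product and total [2H] released (mmol/d) under ``scenario``.

    Only products whose scenario-resolved coefficient is positive
    contribute; everything else contributes zero here.
    """
    produced: dict[str, float] = {}
    for product, flux in fluxes.ledger_fluxes().items():
        coeff = h2_coefficient(product, scenario, registry)
        if coeff > 0:
            produced[product] = coeff * flux
    return produced, sum(produced.values())


def h2_consumption(fluxes: FluxTable, scenario: str,
                   registry: Iterable[ReactionStoichiometry] = DEFAULT_REGISTRY,
                   ) -> tuple[dict[str, float], float]:
    """Per-product and total [2H] consumed (mmol/d) under ``scenario``."""
    consumed: dict[str, float] = {}
    for product, flux in fluxes.ledger_fluxes().items():
        coeff = h2_coefficient(product, scenario, registry)
        if coeff < 0:
            consumed[product] = -coeff * flux
    return consumed, sum(consumed.values())


def h2_balance(produced_total: float, consumed_total: float,
               ) -> tuple[float, float | None]:
    """Balance (produced - consumed, mmol/d) and recovery (%).

    Recovery = 100 x consumed / produced; it is ``None`` (never infinite)
    when nothing was produced.
    """
    if produced_total < 0 or consumed_total < 0:
        raise ValueError("totals must be >= 0 mmol/d")
    balance = produced_total - consumed_total
    recovery = (100.0 * consumed_total / produced_total
                if produced_total > 0 else None)
    return balance, recovery


@dataclass
class H2Ledger:
    """Complete [2H] accounting for one experimental unit under one scenario."""

    unit_id: str
    scenario: str
    produced: dict[str, float]
    produced_total: float
    consumed: dict[str, float]
    consumed_total: float
    balance: float
    recovery: float | None


def ledger(fluxes: FluxTable, scenario: str,
           registry: Iterable[ReactionStoichiometry] = DEFAULT_REGISTRY,
           ) -> H2Ledger:
    """Compute the full [2H] ledger for one flux table."""
    produced, produced_total = h2_production(fluxes, scenario, registry)
    consumed, consumed_total = h2_consumption(fluxes, scenario, registry)
    balance, recovery = h2_balance(produced_total, consumed_total)
    return H2Ledger(fluxes.unit_id, scenario, produced, produced_total,
                    consumed, consumed_total, balance, recovery)
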