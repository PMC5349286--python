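"""Stoichiometric coefficients, flux building, and ledger invariants."""

import pytest

from rumenh2 import (
    FluxTable,
    VesselDayRecord,
    build_flux_table,
    h2_balance,
    h2_coefficient,
    h2_consumption,
    h2_production,
    ledger,
)
from rumenh2.stoichiometry import DEFAULT_REGISTRY, LEDGER_PRODUCTS, SCENARIOS

from conftest import random_flux_tables


def brute_force_totals(fluxes: FluxTable, scenario: str):
    """Independent oracle: one pass over the registry, no produced/consumed
    grouping — positive terms and negative terms summed directly."""
    produced = consumed = 0.0
    for entry in DEFAULT_REGISTRY:
        if entry.pathway not in ("default", scenario):
            continue
        flux = fluxes.ledger_fluxes().get(entry.product, 0.0)
        term = entry.h2_coefficient * flux
        if term >= 0:
            produced += term
        else:
            consumed -= term
    return produced, consumed


class TestCoefficients:
    @pytest.mark.parametrize("product, scenario, expected", [
        ("formate", None, -1),
        ("acetate", None, +2),
        ("propionate", None, -1),
        ("butyrate", None, +2),
        ("valerate", None, -1),
        ("caproate", "SC1", -4),
        ("caproate", "SC2", +2),
        ("heptanoate", None, -2),
        ("methane", None, -4),   # alias for ch4
        ("ch4", "SC1", -4),
        ("hydrogen", None, -1),  # gaseous H2: one [2H] pair per mol vented
    ])
    def test_registry_values(self, product, scenario, expected):
        assert h2_coefficient(product, scenario) == expected

    def test_caproate_requires_a_scenario(self):
        with pytest.raises(ValueError, match="scenario"):
            h2_coefficient("caproate")

    def test_unknown_product_rejected(self):
        with pytest.raises(KeyError, match="octanoate"):
            h2_coefficient("octanoate")

    def test_coefficients_are_integers(self):
        assert all(isinstance(e.h2_coefficient, int) for e in DEFAULT_REGISTRY)


class TestBuildFluxTable:
    def test_control_acetate_flux_chain(self, mean_records):
        fluxes = build_flux_table(mean_records["CON"])
        # 65.5 mM x 52.1/100 x 0.626 L/d; x2 [2H]/mol gives the printed 42.7
        assert fluxes.fluxes["acetate"] == pytest.approx(21.36, abs=5e-3)
        assert round(2 * fluxes.fluxes["acetate"], 1) == 42.7

    def test_nop_valerate_flux(self, mean_records):
        fluxes = build_flux_table(mean_records["NOP"])
        assert fluxes.fluxes["valerate"] == pytest.approx(3.09, abs=5e-3)

    def test_zero_total_vfa_gives_zero_fluxes(self, mean_records):
        record = VesselDayRecord("z", "CON", 0, vfa_total=0.0,
                                 vfa_profile=mean_records["CON"].vfa_profile)
        fluxes = build_flux_table(record)
        assert all(v == 0.0 for v in fluxes.fluxes.values())

    def test_profile_without_total_is_a_usage_error(self):
        record = VesselDayRecord("x", "CON", 0, vfa_profile={"acetate": 52.1})
        with pytest.raises(ValueError, match="without total VFA"):
            build_flux_table(record)

    def test_gas_moles_override_record_volumes(self, mean_records, reference_gas):
        fluxes = build_flux_table(mean_records["CON"], gas_mmol=reference_gas["CON"])
        assert fluxes.fluxes["ch4"] == pytest.approx(4.54 / 4)

    def test_branched_chain_carried_but_excluded(self, mean_records):
        fluxes = build_flux_table(mean_records["CON"])
        assert "isovalerate" in fluxes.fluxes
        assert "isovalerate" not in fluxes.ledger_fluxes()

    def test_negative_flux_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            FluxTable("bad", {"acetate": -1.0})


class TestLedgerTotals:
    def test_control_production_both_scenarios(self, mean_records):
        fluxes = build_flux_table(mean_records["CON"])
        _, sc1 = h2_production(fluxes, "SC1")
        _, sc2 = h2_production(fluxes, "SC2")
        assert sc1 == pytest.approx(55.2, abs=0.1)   # acetate + butyrate
        assert sc2 == pytest.approx(59.1, abs=0.1)   # + caproate via acetyl-CoA

    def test_control_consumption_both_scenarios(self, mean_records, reference_gas):
        fluxes = build_flux_table(mean_records["CON"], gas_mmol=reference_gas["CON"])
        _, sc1 = h2_consumption(fluxes, "SC1")
        _, sc2 = h2_consumption(fluxes, "SC2")
        assert sc1 == pytest.approx(23.5, abs=0.1)
        assert sc2 == pytest.approx(15.8, abs=0.1)   # caproate no longer a sink

    def test_all_zero_fluxes_give_zero_totals(self):
        fluxes = FluxTable("zero", {p: 0.0 for p in LEDGER_PRODUCTS})
        for scenario in SCENARIOS:
            assert h2_production(fluxes, scenario)[1] == 0.0
            assert h2_consumption(fluxes, scenario)[1] == 0.0


class TestBalance:
    def test_printed_totals_give_printed_balances(self):
        balance, recovery = h2_balance(55.2, 23.5)
        assert round(balance, 1) == 31.7
        assert recovery == pytest.approx(42.57, abs=5e-3)
        assert round(h2_balance(59.1, 15.8)[0], 1) == 43.3

    def test_equal_totals_give_zero_balance_full_recovery(self):
        assert h2_balance(12.0, 12.0) == (0.0, 100.0)

    def test_zero_production_flags_recovery_undefined(self):
        balance, recovery = h2_balance(0.0, 5.0)
        assert balance == -5.0 and recovery is None

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            h2_balance(-1.0, 0.0)


class TestLedgerProperties:
    def test_scenario_identity_on_1000_random_tables(self):
        # balance(SC2) - balance(SC1) = 6 x caproate flux: SC2 adds +2/mol
        # to production while SC1 had charged 4/mol to consumption
        for fluxes in random_flux_tables(1000, seed=42):
            d = ledger(fluxes, "SC2").balance - ledger(fluxes, "SC1").balance
            assert d == pytest.approx(6 * fluxes.fluxes["caproate"], rel=1e-9)

    def test_totals_match_brute_force_oracle(self):
        for fluxes in random_flux_tables(200, seed=7):
            for scenario in SCENARIOS:
                led = ledger(fluxes, scenario)
                produced, consumed = brute_force_totals(fluxes, scenario)
                assert led.produced_total == pytest.approx(produced, rel=1e-12)
                assert led.consumed_total == pytest.approx(consumed, rel=1e-12)

    def test_each_product_contributes_to_exactly_one_side(self):
        for fluxes in random_flux_tables(50, seed=3):
            for scenario in SCENARIOS:
                led = ledger(fluxes, scenario)
                assert not set(led.produced) & set(led.consumed)
                assert set(led.produced) | set(led.consumed) == set(LEDGER_PRODUCTS)

    def test_linearity_under_flux_scaling(self):
        for fluxes in random_flux_tables(50, seed=11):
            led = ledger(fluxes, "SC1")
            scaled = ledger(fluxes.scaled(3.0), "SC1")
            assert scaled.produced_total == pytest.approx(3 * led.produced_total)
            assert scaled.consumed_total == pytest.approx(3 * led.consumed_total)
            assert scaled.balance == pytest.approx(3 * led.balance)
            if led.recovery is not None:
                assert scaled.recovery == pytest.approx(led.recovery)
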