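"""Auxiliary sink calculations: GHG, nitrate, microbial biomass, Sf."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rumenh2 import (
    GwpCoefficients,
    HenryConfig,
    MicrobialH2Config,
    co2_equivalents,
    concentration_to_daily_flux,
    mass_to_mmol,
    microbial_h2_sink,
    nitrate_h2_sink,
    nitrate_reduction_extent,
    supersaturation_factor,
)
from rumenh2.fixtures import NITRATE_DOSE_MG, NITRATE_MOLAR_MASS, fixture
from rumenh2.sinks import LITERATURE_MICROBIAL_CONFIG


class TestCo2Equivalents:
    @pytest.mark.parametrize("volumes, expected", [
        ({"co2": 1000.0}, 1000.0),             # CO2 identity
        ({"ch4": 1.0}, 28.0),                  # 100-year GWP of methane
        ({"ch4": 30.0, "co2": 141.0, "h2": 3.5}, 1000.6),  # ~control mix -> ~1 L
    ])
    def test_examples(self, volumes, expected):
        assert co2_equivalents(volumes) == pytest.approx(expected)

    def test_gas_without_gwp_rejected(self):
        with pytest.raises(KeyError, match="radon"):
            co2_equivalents({"radon": 1.0})

    def test_co2_gwp_fixed_at_one(self):
        with pytest.raises(ValueError):
            GwpCoefficients({"co2": 2.0})

    @given(st.dictionaries(st.sampled_from(["co2", "ch4", "h2", "n2o"]),
                           st.floats(0.0, 1e3), min_size=1))
    @settings(max_examples=100, deadline=None)
    def test_never_below_raw_volume(self, volumes):
        # all GWPs >= 1, so CO2-eq >= raw volume; the excess is exactly
        # the non-CO2 volumes weighted by (GWP - 1)
        total = sum(volumes.values())
        eq = co2_equivalents(volumes)
        gwp = GwpCoefficients().gwp
        excess = sum(v * (gwp[g] - 1.0) for g, v in volumes.items())
        assert eq >= total - 1e-9
        assert eq - total == pytest.approx(excess, rel=1e-9, abs=1e-9)
        if set(volumes) == {"co2"}:
            assert eq == pytest.approx(total)


def nitrate_intake_mmol() -> float:
    """Daily nitrate dose of the nitrate treatment, mmol/d."""
    return mass_to_mmol(NITRATE_DOSE_MG, NITRATE_MOLAR_MASS)


class TestNitrateSink:
    def test_reference_inputs_give_51_1(self):
        # 803 mg/d dose, 0.27 mM nitrate outflow x 0.626 L/d; 4 [2H]/mol.
        # (The source text prints 51.6; the gap is a documented
        # reconstruction limit, not a tolerance to absorb.)
        intake = nitrate_intake_mmol()
        out = concentration_to_daily_flux(0.27, 0.626)
        sink = nitrate_h2_sink(intake, out, nitrite_out=0.019)
        assert sink == pytest.approx(51.1, abs=0.05)

    def test_zero_intake_gives_zero(self):
        assert nitrate_h2_sink(0.0, 0.0) == 0.0

    def test_full_outflow_gives_zero(self):
        assert nitrate_h2_sink(5.0, 5.0) == 0.0

    def test_outflow_exceeding_intake_rejected(self):
        with pytest.raises(ValueError, match="exceeds intake"):
            nitrate_h2_sink(1.0, 2.0)

    def test_monotone_decreasing_in_nitrate_out(self):
        sinks = [nitrate_h2_sink(10.0, out) for out in (0.0, 1.0, 5.0, 10.0)]
        assert sinks == sorted(sinks, reverse=True)

    def test_partial_credit_charges_outflowing_nitrite_one_h2(self):
        from rumenh2 import NitratePathwayConfig
        cfg = NitratePathwayConfig(nitrite_rule="partial_credit")
        default = nitrate_h2_sink(10.0, 1.0, nitrite_out=2.0)
        credited = nitrate_h2_sink(10.0, 1.0, nitrite_out=2.0, config=cfg)
        assert default - credited == pytest.approx(3.0 * 2.0)


class TestReductionExtent:
    def test_zero_outflows_mean_complete_reduction(self):
        assert nitrate_reduction_extent(12.95, 0.0, 0.0) == 100.0

    def test_reference_outflows_give_98_5(self):
        extent = nitrate_reduction_extent(nitrate_intake_mmol(), 0.169, 0.019)
        assert extent == pytest.approx(98.5, abs=0.1)

    def test_full_nitrate_outflow_means_no_reduction(self):
        assert nitrate_reduction_extent(5.0, 5.0, 0.0) == 0.0

    def test_zero_intake_flagged(self):
        with pytest.raises(ValueError, match="intake"):
            nitrate_reduction_extent(0.0, 0.0, 0.0)


class TestMicrobialSink:
    def test_calibrated_preset_reproduces_reference_quadruple(self):
        t5 = fixture("T5")
        printed = {"CON": 1.62, "NIT": 1.89, "NOP": 1.48, "AQ": 1.41}
        for trt, expected in printed.items():
            got = microbial_h2_sink(t5.value("microbial_n_total", trt))
            tol = 1e-9 if trt == "CON" else 0.012  # preset calibrated on CON
            assert got == pytest.approx(expected, abs=max(tol, 1e-9))

    def test_literature_chain_is_orders_of_magnitude_larger(self):
        # 0.41 mol/g cells with 0.545 g CP/g and 16 % N gives ~281 mmol/d
        # for 59.8 mg N/d — the chain and the calibrated scale disagree by
        # design; both are exposed, the config records which was used.
        got = microbial_h2_sink(59.8, LITERATURE_MICROBIAL_CONFIG)
        assert got == pytest.approx(281.0, rel=0.01)

    def test_zero_nitrogen_gives_zero(self):
        assert microbial_h2_sink(0.0) == 0.0

    @given(st.floats(1e-3, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_treatment_ratios_independent_of_coefficient(self, coeff):
        cfg = MicrobialH2Config(coefficient=coeff)
        n = {"CON": 59.8, "NIT": 69.7, "NOP": 54.2, "AQ": 51.7}
        sinks = {t: microbial_h2_sink(v, cfg) for t, v in n.items()}
        for trt in ("NIT", "NOP", "AQ"):
            assert sinks[trt] / sinks["CON"] == pytest.approx(
                n[trt] / n["CON"], rel=1e-12)

    def test_unknown_basis_rejected(self):
        with pytest.raises(ValueError, match="basis"):
            MicrobialH2Config(basis="per_cow")


class TestSupersaturation:
    def test_equilibrium_gives_one(self):
        cfg = HenryConfig(henry_constant=780.0, reference="literature value")
        assert supersaturation_factor(780.0 * 0.02, 0.02, cfg) == pytest.approx(1.0)

    def test_worked_example(self):
        cfg = HenryConfig(henry_constant=780.0)
        sf = supersaturation_factor(40.8, 0.02, cfg)
        assert sf == pytest.approx(2.6, abs=0.05)

    def test_zero_dissolved_h2_gives_zero(self):
        assert supersaturation_factor(0.0, 0.1, HenryConfig(780.0)) == 0.0

    def test_zero_partial_pressure_flagged(self):
        with pytest.raises(ValueError, match="partial pressure"):
            supersaturation_factor(10.0, 0.0, HenryConfig(780.0))

    def test_no_default_henry_constant(self):
        with pytest.raises(TypeError):
            HenryConfig()  # type: ignore[call-arg]
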