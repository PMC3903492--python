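"""Transport free-energy ledger: quotients, conventions, extended reals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sc2flux.constants import ThermoConstants
from sc2flux.datasets import table6_keq_overrides
from sc2flux.errors import (
    IndeterminateSumError,
    InfeasibleBalanceError,
    UndefinedQuotientError,
    ValidationError,
)
from sc2flux.thermo import (
    FreeEnergyLedger,
    TransportState,
    complexation_balance,
    coverage_fmol_per_cell,
    free_energy,
    molar_from_mass_conc,
    overall_free_energy,
    particles_per_cell,
    partition_at_peak,
    step_keq,
)

RT = 8.314 * 310.0


class TestConversions:
    def test_carrier_dose_molarity(self):
        assert molar_from_mass_conc(1.0, 841.0) == pytest.approx(1.1891e-3, abs=5e-8)

    def test_zero_mass_gives_zero(self):
        assert molar_from_mass_conc(0.0, 841.0) == 0.0

    def test_linearity(self):
        assert molar_from_mass_conc(2.0, 841.0) == pytest.approx(2.3781e-3, abs=1e-7)

    def test_nonpositive_mw_rejected(self):
        with pytest.raises(ValidationError):
            molar_from_mass_conc(1.0, 0.0)

    @pytest.mark.parametrize(
        "conc,expected",
        [(0.0025, 2.97e-5), (6.25, 7.43e-2)],
    )
    def test_coverage_per_cell(self, conc, expected):
        got = coverage_fmol_per_cell(conc, 2.0, 2e5, 841.0)
        assert got == pytest.approx(expected, rel=2e-3)

    def test_coverage_zero_dose(self):
        assert coverage_fmol_per_cell(0.0, 2.0, 2e5, 841.0) == 0.0

    @pytest.mark.parametrize(
        "fmol,expected",
        [(3.0e-5, 1.81e4), (7.5e-2, 4.52e7), (0.0, 0.0)],
    )
    def test_particles_per_cell(self, fmol, expected):
        assert particles_per_cell(fmol) == pytest.approx(expected, rel=5e-3)

    def test_particles_rejects_negative(self):
        with pytest.raises(ValidationError):
            particles_per_cell(-1.0)

    @given(x=st.floats(0.001, 100.0), a=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_conversions_are_linear(self, x, a):
        assert molar_from_mass_conc(a * x, 841.0) == pytest.approx(
            a * molar_from_mass_conc(x, 841.0), rel=1e-12
        )
        assert particles_per_cell(a * x) == pytest.approx(
            a * particles_per_cell(x), rel=1e-12
        )


class TestMassBalances:
    def test_complexation_reference_value(self):
        got = complexation_balance(1e-3, 1.1891e-6)
        assert got == pytest.approx(9.988e-4, abs=5e-8)

    def test_no_carrier_leaves_total(self):
        assert complexation_balance(1e-3, 0.0) == 1e-3

    def test_full_consumption(self):
        assert complexation_balance(1e-3, 1e-3) == 0.0

    def test_infeasible_balance_rejected(self):
        with pytest.raises(InfeasibleBalanceError):
            complexation_balance(1e-6, 1e-3)

    @pytest.mark.parametrize(
        "c0,peak,expected",
        [(0.1, 0.093, (0.007, 0.093)), (0.1, 0.019, (0.081, 0.019)), (0.1, 0.0, (0.1, 0.0))],
    )
    def test_partition_at_peak(self, c0, peak, expected):
        c_om, c_mA = partition_at_peak(c0, peak)
        assert c_om == pytest.approx(expected[0], abs=1e-12)
        assert c_mA == expected[1]

    def test_partition_infeasible_rejected(self):
        with pytest.raises(InfeasibleBalanceError):
            partition_at_peak(0.1, 0.2)

    @given(
        c0=st.floats(1e-6, 10.0),
        frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_partition_conserves_mass(self, c0, frac):
        c_om, c_mA = partition_at_peak(c0, frac * c0)
        assert c_om + c_mA == pytest.approx(c0, rel=1e-12)


class TestStepQuotients:
    def test_fully_bound_carrier_gives_infinite_step1(self, transport_states):
        assert step_keq(transport_states["SB"], 1) == math.inf

    def test_unit_concentrations_give_unit_quotient(self):
        state = TransportState(
            sc2_free=1.0, sc2_mouter=1.0, sc2_mouter_ls=1.0, ls_free=1.0
        )
        assert step_keq(state, 1) == 1.0
        assert step_keq(state, 2) == 1.0

    def test_random_state_matches_hand_computed_quotient(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.uniform(0.01, 2.0, size=4)
            state = TransportState(
                sc2_free=v[0], sc2_mouter=v[1], sc2_mouter_ls=v[2], ls_free=v[3]
            )
            assert step_keq(state, 1) == pytest.approx(v[1] / v[0], rel=1e-12)
            assert step_keq(state, 2) == pytest.approx(
                v[2] / (v[1] * v[3]), rel=1e-12
            )

    def test_translocation_quotient(self, transport_states):
        state = transport_states["SA"]
        assert step_keq(state, 3) == pytest.approx(0.015 / 0.085, rel=1e-6)

    def test_irreversible_degradation_is_infinite(self, transport_states):
        assert step_keq(transport_states["SB"], 4) == math.inf

    def test_negative_numerator_over_zero_gives_minus_inf(self):
        # degraded amount is negative when the final pool exceeds the
        # delivered amount; with a zero reverse pool that is the -inf branch
        state = TransportState(ls_in=1e-6, c_mE=5e-6)
        assert step_keq(state, 4) == -math.inf

    def test_all_zero_species_undefined(self):
        state = TransportState()
        with pytest.raises(UndefinedQuotientError):
            step_keq(state, 1)

    def test_custom_stoichiometry(self, transport_states):
        table = {9: (("c_mA_prime", "c_mA_prime"), ("c_om",))}
        state = transport_states["SB"]
        got = step_keq(state, 9, stoichiometry=table)
        assert got == pytest.approx(0.093e-3**2 / 0.007e-3, rel=1e-9)


class TestFreeEnergy:
    def test_product_convention_reference_value(self):
        got = free_energy(0.9980, mode="table6")
        assert got / 1000.0 == pytest.approx(-2.572, abs=5e-4)

    def test_ln_equilibrium_is_zero(self):
        assert free_energy(1.0, mode="ln") == 0.0

    def test_ln_closed_form(self):
        assert free_energy(math.e, mode="ln") == pytest.approx(-RT, rel=1e-12)

    def test_ln_antisymmetry_and_monotonicity(self):
        for k in (0.1, 0.5, 2.0, 100.0):
            assert free_energy(1 / k, mode="ln") == pytest.approx(
                -free_energy(k, mode="ln"), rel=1e-12
            )
        ks = [0.01, 0.1, 1.0, 10.0, 1e4]
        gs = [free_energy(k, mode="ln") for k in ks]
        assert all(a > b for a, b in zip(gs, gs[1:]))

    def test_ln_extended_limits(self):
        assert free_energy(math.inf, mode="ln") == -math.inf
        assert free_energy(0.0, mode="ln") == math.inf

    def test_ln_rejects_negative_keq(self):
        with pytest.raises(ValidationError, match="table6"):
            free_energy(-0.0189, mode="ln")

    def test_product_convention_handles_negative_and_infinite(self):
        assert free_energy(-0.0189, mode="table6") == pytest.approx(
            RT * 0.0189, rel=1e-12
        )
        assert free_energy(math.inf, mode="table6") == -math.inf
        assert free_energy(-math.inf, mode="table6") == math.inf

    def test_temperature_dependence(self):
        cold = ThermoConstants(T=280.0)
        assert free_energy(2.0, cold, "ln") == pytest.approx(
            -8.314 * 280.0 * math.log(2.0), rel=1e-12
        )


class TestOverallFreeEnergy:
    def test_absorbing_negative_infinity(self):
        assert overall_free_energy([-math.inf, -2572.0, 59.0, -math.inf]) == -math.inf

    def test_null_ledger(self):
        assert overall_free_energy([0.0, 0.0, 0.0, 0.0]) == 0.0

    def test_finite_sum(self):
        assert overall_free_energy([1.0, -3.0, 2.0]) == pytest.approx(0.0)

    def test_mixed_infinities_raise(self):
        with pytest.raises(IndeterminateSumError):
            overall_free_energy([math.inf, -math.inf, 0.0, 0.0])


class TestLedger:
    @pytest.mark.parametrize("lignan", ["SB", "GmC", "SA"])
    def test_unidirectional_transport_theorem(self, transport_states, lignan):
        """Complete carrier binding (step 1) and irreversible degradation
        (step 4) drive the overall path free energy to -inf regardless of
        the finite middle steps: the carrier acts as a one-way pump."""
        ledger = FreeEnergyLedger.from_state(transport_states[lignan], mode="ln")
        by_step = {s.step: s for s in ledger.steps}
        assert by_step[1].delta_g_J == -math.inf
        assert by_step[4].delta_g_J == -math.inf
        assert math.isfinite(by_step[2].delta_g_J)
        assert math.isfinite(by_step[3].delta_g_J)
        assert ledger.overall_J == -math.inf

    def test_reproduction_mode_sign_pattern(self, transport_states):
        """With the published step-2/3 constants the ledger reproduces the
        printed pattern: -inf, negative, small positive, -inf."""
        ledger = FreeEnergyLedger.from_state(
            transport_states["SA"], mode="table6", keq_overrides=table6_keq_overrides()
        )
        dgs = [s.delta_g_J for s in ledger.steps]
        assert dgs[0] == -math.inf
        assert dgs[1] == pytest.approx(-2572.2, abs=0.5)
        assert 0 < dgs[2] < 100
        assert dgs[3] == -math.inf
        assert ledger.overall_J == -math.inf

    def test_to_dict_serialises_infinities_as_strings(self, transport_states):
        ledger = FreeEnergyLedger.from_state(transport_states["SB"], mode="ln")
        d = ledger.to_dict()
        assert d["overall_J"] == "-inf"
        assert d["steps"][0]["keq"] == "+inf"
        assert isinstance(d["steps"][2]["keq"], float)

    def test_summary_renders(self, transport_states):
        text = FreeEnergyLedger.from_state(transport_states["GmC"], mode="ln").summary()
        assert "GmC" in text and "-inf" in text


class TestTransportState:
    def test_mass_balance_enforced_at_construction(self):
        with pytest.raises(ValidationError, match="mass balance"):
            TransportState(c0=1e-4, c_om=5e-5, c_mA_prime=1e-5)

    def test_c_mA_defaults_to_c_mA_prime(self):
        state = TransportState(c0=1e-4, c_om=7e-6, c_mA_prime=93e-6)
        assert state.c_mA == 93e-6

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            TransportState(sc2_free=-1.0)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValidationError):
            TransportState().species("plutonium")
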