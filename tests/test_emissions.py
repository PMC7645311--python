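"""Manure emission chain: stoichiometry, pool bookkeeping, ledger closure."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from piglca.balance import NutrientVector
from piglca.emissions import (EmissionFactorSet, ManureState, GasEmissions,
                              enteric_ch4, housing_emissions, storage_emissions,
                              spreading_emissions, fertilizer_credit,
                              manure_chain, EmissionConfigError, N_TO_NH3)

EXC = NutrientVector(DM=180.0, OM=150.0, N=4.3, P=0.85, K=1.8, Cu=3.5, Zn=22.0)


def zero_factors():
    return EmissionFactorSet(
        enteric_ch4_per_kg_dig_fibre=0.0, housing_nh3_n_frac_tan=0.0,
        housing_n2o_n_frac=0.0, housing_no_n_frac=0.0, storage_mcf=0.0,
        storage_nh3_n_frac=0.0, storage_n2o_n_frac=0.0,
        spreading_nh3_n_frac_tan=0.0, spreading_n2o_n_direct_frac=0.0,
        n2o_n_indirect_volat_frac=0.0, n2o_n_indirect_leach_frac=0.0,
        leaching_frac=0.0, p_runoff_frac=0.0)


class TestEnteric:
    def test_zero_intake(self, fx):
        assert enteric_ch4(0.0, fx.emission_factors).CH4 == 0.0

    def test_linearity(self, fx):
        ef = fx.emission_factors
        assert enteric_ch4(60.0, ef).CH4 == pytest.approx(
            2 * enteric_ch4(30.0, ef).CH4)

    def test_fixture_product(self, fx):
        ef = fx.emission_factors
        assert enteric_ch4(30.0, ef).CH4 == pytest.approx(
            30.0 * ef.enteric_ch4_per_kg_dig_fibre)


class TestHousing:
    def test_zero_factors_pass_all_nitrogen_through(self):
        gases, state = housing_emissions(EXC, zero_factors())
        assert gases.NH3 == gases.N2O == gases.NO == 0.0
        assert state.N == pytest.approx(EXC.N)

    def test_ammonia_stoichiometry(self):
        # 1 kg NH3-N emitted -> 17/14 kg NH3
        ef = EmissionFactorSet(tan_fraction_excreted_n=1.0,
                               housing_nh3_n_frac_tan=1.0 / EXC.N,
                               housing_n2o_n_frac=0.0, housing_no_n_frac=0.0)
        gases, _ = housing_emissions(EXC, ef)
        assert gases.NH3 == pytest.approx(N_TO_NH3)
        assert gases.NH3 == pytest.approx(1.2142857142857142)

    def test_nitrogen_bookkeeping(self, fx):
        gases, state = housing_emissions(EXC, fx.emission_factors)
        assert state.N + gases.n_mass() == pytest.approx(EXC.N, abs=1e-12)

    def test_excess_losses_rejected(self):
        ef = EmissionFactorSet(tan_fraction_excreted_n=1.0,
                               housing_nh3_n_frac_tan=1.0,
                               housing_n2o_n_frac=0.5)
        with pytest.raises(EmissionConfigError):
            housing_emissions(EXC, ef)


class TestStorageSpreading:
    def test_mcf_zero_no_methane(self, fx):
        _, state = housing_emissions(EXC, fx.emission_factors)
        ef = dataclasses.replace(fx.emission_factors, storage_mcf=0.0)
        gases, _ = storage_emissions(state, ef)
        assert gases.CH4 == 0.0

    def test_storage_ch4_tier2_product(self, fx):
        ef = fx.emission_factors
        _, state = housing_emissions(EXC, ef)
        gases, _ = storage_emissions(state, ef)
        assert gases.CH4 == pytest.approx(
            state.VS * ef.storage_b0_m3_per_kg_vs * ef.storage_mcf
            * ef.ch4_density_kg_per_m3)

    def test_p_k_conserved_to_field(self, fx):
        ef = fx.emission_factors
        chain = manure_chain(EXC, ef)
        field = chain["field"]
        assert field["P_applied"] == pytest.approx(EXC.P)
        assert field["K_applied"] == pytest.approx(EXC.K)
        assert field["P_field_net"] == pytest.approx(
            EXC.P * (1 - ef.p_runoff_frac))

    def test_zero_factors_deliver_everything_to_field(self):
        chain = manure_chain(EXC, zero_factors())
        assert chain["field"]["N_field_net"] == pytest.approx(EXC.N)
        assert chain["field"]["N_leached"] == 0.0
        assert chain["field"]["P_to_freshwater"] == 0.0

    def test_indirect_n2o_zero_without_volatilization_or_leaching(self, fx):
        ef = dataclasses.replace(fx.emission_factors,
                                 spreading_nh3_n_frac_tan=0.0,
                                 leaching_frac=0.0)
        _, state = housing_emissions(EXC, ef)
        _, state2 = storage_emissions(state, ef)
        _, field = spreading_emissions(state2, ef)
        assert field["N2O_N_indirect"] == 0.0

    def test_phase_tags_enforced(self, fx):
        state = ManureState(phase="spreading_ready", N=1.0, tan_fraction=0.5,
                            P=0.1, K=0.1, VS=10.0)
        with pytest.raises(ValueError):
            storage_emissions(state, fx.emission_factors)


class TestLedgerClosure:
    def test_nitrogen_ledger_closes(self, fx):
        # excreted N = gaseous N (direct) + leached + net field N, exactly
        chain = manure_chain(EXC, fx.emission_factors)
        field = chain["field"]
        direct_spreading_n = (chain["spreading"].NH3 / N_TO_NH3
                              + field["N2O_N_direct"])
        ledger = (chain["housing"].n_mass() + chain["storage"].n_mass()
                  + direct_spreading_n + field["N_leached"]
                  + field["N_field_net"])
        assert ledger == pytest.approx(EXC.N, abs=1e-9)

    @given(st.floats(0.5, 10.0), st.floats(0.1, 2.0), st.floats(50.0, 300.0))
    @settings(max_examples=40, deadline=None)
    def test_ledger_closure_property(self, fx, n, p, om):
        exc = NutrientVector(DM=om * 1.1, OM=om, N=n, P=p, K=p, Cu=1.0, Zn=5.0)
        chain = manure_chain(exc, fx.emission_factors)
        field = chain["field"]
        ledger = (chain["housing"].n_mass() + chain["storage"].n_mass()
                  + chain["spreading"].NH3 / N_TO_NH3 + field["N2O_N_direct"]
                  + field["N_leached"] + field["N_field_net"])
        assert ledger == pytest.approx(exc.N, abs=1e-9)

    def test_gases_monotone_in_excretion(self, fx):
        small = manure_chain(EXC, fx.emission_factors)
        big = manure_chain(EXC.scale(1.5), fx.emission_factors)
        for phase in ("housing", "storage", "spreading"):
            for g in ("CH4", "NH3", "N2O", "NO"):
                assert getattr(big[phase], g) >= getattr(small[phase], g)


class TestFertilizerCredit:
    def test_printed_equivalencies(self, fx):
        field = {"N_applied": 10.0, "P_applied": 2.0, "K_applied": 5.0}
        credit = fertilizer_credit(field, fx.emission_factors)
        assert credit["N"] == pytest.approx(7.5)   # 75% equivalency for N
        assert credit["P"] == pytest.approx(2.0)   # 100% for P
        assert credit["K"] == pytest.approx(5.0)   # 100% for K

    def test_zero_field_nitrogen(self, fx):
        credit = fertilizer_credit(
            {"N_applied": 0.0, "P_applied": 0.0, "K_applied": 0.0},
            fx.emission_factors)
        assert credit == {"N": 0.0, "P": 0.0, "K": 0.0}


class TestFactorValidation:
    def test_fractions_outside_unit_interval_rejected(self):
        with pytest.raises(EmissionConfigError):
            EmissionFactorSet(storage_mcf=1.2)
        with pytest.raises(EmissionConfigError):
            EmissionFactorSet(leaching_frac=-0.1)

    def test_gas_masses_never_negative(self):
        with pytest.raises(ValueError):
            GasEmissions(phase="housing", NH3=-1.0)
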