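"""Manure emission chain: housing, outside storage and field spreading.

Excreted nutrients (from :mod:`piglca.balance`) move through three phases.
In each phase nitrogen species are emitted as fractions of the relevant N
pool -- ammonia from the volatilizable TAN pool, N2O and NO from total N --
and the manure N pool is netted down accordingly, so that the farm-level N
ledger closes exactly:

    excreted N = NH3-N + N2O-N + NO-N (all phases) + leached N + net field N.

Methane from stored slurry follows the classic Tier-2 structure
``CH4 = VS * B0 * MCF * rho_CH4``; enteric methane scales with digestible
fibre intake.  Gas masses are reported as the gas species (stoichiometric
conversion from N: NH3 = N*17/14, N2O = N*44/28, NO = N*30/14) because
characterization factors are per kg gas.  Indirect N2O (from re-deposited
volatilized N and leached N) is emitted off-site from N already counted as
NH3/NOx or leaching losses, so it appears as a gas flow but is excluded from
the on-farm N ledger to avoid double counting.

Manure nutrients delivered to the field displace mineral fertilizer at the
equivalency 75% for N and 100% for P and K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace, fields
from pathlib import Path

from .balance import NutrientVector

N_TO_NH3 = 17.0 / 14.0
N_TO_N2O = 44.0 / 28.0
N_TO_NO = 30.0 / 14.0

GASES = ("CH4", "NH3", "N2O", "NO", "CO2")


class EmissionConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GasEmissions:
    """Gas masses (kg) for one phase of the chain."""

    phase: str                 # enteric | housing | storage | spreading
    CH4: float = 0.0
    NH3: float = 0.0
    N2O: float = 0.0
    NO: float = 0.0
    CO2: float = 0.0

    def __post_init__(self):
        for g in GASES:
            if getattr(self, g) < 0:
                raise ValueError(f"negative {g} mass")

    def __add__(self, other: "GasEmissions") -> "GasEmissions":
        phase = self.phase if self.phase == other.phase else "combined"
        return GasEmissions(phase=phase, **{
            g: getattr(self, g) + getattr(other, g) for g in GASES})

    def n_mass(self) -> float:
        """Total N (kg) contained in the phase's N gases."""
        return self.NH3 / N_TO_NH3 + self.N2O / N_TO_N2O + self.NO / N_TO_NO


@dataclass(frozen=True)
class ManureState:
    """Manure nutrient pools between phases."""

    phase: str                 # storage_start | spreading_ready
    N: float
    tan_fraction: float
    P: float
    K: float
    VS: float                  # volatile solids, kg

    def __post_init__(self):
        if not 0.0 <= self.tan_fraction <= 1.0 + 1e-12:
            raise ValueError("TAN fraction must be in [0, 1]")
        if min(self.N, self.P, self.K, self.VS) < -1e-12:
            raise ValueError("manure masses must be >= 0")

    @property
    def tan(self) -> float:
        return self.tan_fraction * self.N


@dataclass(frozen=True)
class EmissionFactorSet:
    """All factors of the chain; fractions are of the named N pool.

    The values shipped by :func:`piglca.synthetic.default_fixtures` are
    documented fixture defaults in the style of slurry-system inventories,
    not measured values.
    """

    enteric_ch4_per_kg_dig_fibre: float = 0.06
    tan_fraction_excreted_n: float = 0.70
    # housing
    housing_nh3_n_frac_tan: float = 0.25
    housing_n2o_n_frac: float = 0.002
    housing_no_n_frac: float = 0.002
    housing_co2_per_kg_excreted_n: float = 0.0
    # storage
    storage_b0_m3_per_kg_vs: float = 0.45
    storage_mcf: float = 0.10
    ch4_density_kg_per_m3: float = 0.67
    storage_nh3_n_frac: float = 0.05
    storage_n2o_n_frac: float = 0.005
    vs_from_om: float = 0.25        # faecal VS as a share of balance OM
    # spreading
    spreading_nh3_n_frac_tan: float = 0.25
    spreading_n2o_n_direct_frac: float = 0.010
    n2o_n_indirect_volat_frac: float = 0.010
    n2o_n_indirect_leach_frac: float = 0.0075
    leaching_frac: float = 0.15
    p_runoff_frac: float = 0.20
    # mineral fertilizer equivalency
    fert_equiv_n: float = 0.75
    fert_equiv_p: float = 1.0
    fert_equiv_k: float = 1.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("enteric_ch4_per_kg_dig_fibre", "ch4_density_kg_per_m3",
                          "storage_b0_m3_per_kg_vs",
                          "housing_co2_per_kg_excreted_n"):
                if v < 0:
                    raise EmissionConfigError(f"{f.name} must be >= 0")
            elif not 0.0 <= v <= 1.0:
                raise EmissionConfigError(f"{f.name}={v} must be in [0, 1]")

    def scaled(self, multipliers: dict) -> "EmissionFactorSet":
        """Return a copy with named factors multiplied (for Monte Carlo);
        fractional factors are capped at 1."""
        frac_fields = {f.name for f in fields(self)} - {
            "enteric_ch4_per_kg_dig_fibre", "ch4_density_kg_per_m3",
            "storage_b0_m3_per_kg_vs", "housing_co2_per_kg_excreted_n"}
        updates = {}
        for name, m in multipliers.items():
            v = getattr(self, name) * m
            if name in frac_fields:
                v = min(v, 1.0)
            updates[name] = v
        return replace(self, **updates)

    def to_json(self, path) -> None:
        payload = {"_provenance": "piglca fixture emission factors", **asdict(self)}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "EmissionFactorSet":
        payload = json.loads(Path(path).read_text())
        payload.pop("_provenance", None)
        return cls(**payload)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def enteric_ch4(dig_fibre_intake_kg: float, ef: EmissionFactorSet) -> GasEmissions:
    """Enteric methane, linear in digestible fibre intake."""
    if dig_fibre_intake_kg < 0:
        raise ValueError("fibre intake must be >= 0")
    return GasEmissions(phase="enteric",
                        CH4=ef.enteric_ch4_per_kg_dig_fibre * dig_fibre_intake_kg)


def housing_emissions(excreted: NutrientVector,
                      ef: EmissionFactorSet) -> tuple:
    """Housing-phase gases and the manure state entering storage.

    NH3-N is a fraction of the TAN pool; N2O-N and NO-N are fractions of the
    total excreted N.  The state's N is excreted N net of all gaseous N.
    """
    n_exc = excreted.N
    tan0 = ef.tan_fraction_excreted_n * n_exc
    nh3_n = ef.housing_nh3_n_frac_tan * tan0
    n2o_n = ef.housing_n2o_n_frac * n_exc
    no_n = ef.housing_no_n_frac * n_exc
    n_out = n_exc - nh3_n - n2o_n - no_n
    if n_out < 0:
        raise EmissionConfigError("housing N losses exceed excreted N")
    tan_out = max(tan0 - nh3_n - n2o_n - no_n, 0.0)
    gases = GasEmissions(phase="housing",
                         NH3=nh3_n * N_TO_NH3, N2O=n2o_n * N_TO_N2O,
                         NO=no_n * N_TO_NO,
                         CO2=ef.housing_co2_per_kg_excreted_n * n_exc)
    state = ManureState(phase="storage_start", N=n_out,
                        tan_fraction=(tan_out / n_out if n_out > 0 else 0.0),
                        P=excreted.P, K=excreted.K,
                        VS=ef.vs_from_om * excreted.OM)
    return gases, state


def storage_emissions(state: ManureState, ef: EmissionFactorSet) -> tuple:
    """Outside-storage gases and the spreading-ready manure state.

    CH4 = VS * B0 * MCF * rho_CH4; NH3-N and N2O-N are fractions of the
    stored N; P and K pass through unchanged.
    """
    if state.phase != "storage_start":
        raise ValueError(f"expected storage_start state, got {state.phase!r}")
    ch4 = state.VS * ef.storage_b0_m3_per_kg_vs * ef.storage_mcf \
        * ef.ch4_density_kg_per_m3
    nh3_n = ef.storage_nh3_n_frac * state.N
    n2o_n = ef.storage_n2o_n_frac * state.N
    n_out = state.N - nh3_n - n2o_n
    if n_out < 0:
        raise EmissionConfigError("storage N losses exceed stored N")
    tan_out = max(state.tan - nh3_n - n2o_n, 0.0)
    gases = GasEmissions(phase="storage", CH4=ch4,
                         NH3=nh3_n * N_TO_NH3, N2O=n2o_n * N_TO_N2O)
    out = ManureState(phase="spreading_ready", N=n_out,
                      tan_fraction=(tan_out / n_out if n_out > 0 else 0.0),
                      P=state.P, K=state.K, VS=state.VS)
    return gases, out


def spreading_emissions(state: ManureState, ef: EmissionFactorSet) -> tuple:
    """Field-spreading gases and the field input dict.

    Direct N2O-N is a fraction of the applied N; indirect N2O covers
    volatilized (NH3-N) and leached N; leaching and P runoff are fractions of
    the applied N and P.  The returned dict carries both the applied amounts
    (basis of the fertilizer credit) and the net amounts left in the field
    soil (basis of the N ledger).
    """
    if state.phase != "spreading_ready":
        raise ValueError(f"expected spreading_ready state, got {state.phase!r}")
    n_app = state.N
    nh3_n = ef.spreading_nh3_n_frac_tan * state.tan
    n2o_n_direct = ef.spreading_n2o_n_direct_frac * n_app
    n_leached = ef.leaching_frac * n_app
    n2o_n_indirect = (ef.n2o_n_indirect_volat_frac * nh3_n
                      + ef.n2o_n_indirect_leach_frac * n_leached)
    n_field_net = n_app - nh3_n - n2o_n_direct - n_leached
    if n_field_net < 0:
        raise EmissionConfigError("spreading N losses exceed applied N")
    p_runoff = ef.p_runoff_frac * state.P
    gases = GasEmissions(phase="spreading",
                         NH3=nh3_n * N_TO_NH3,
                         N2O=(n2o_n_direct + n2o_n_indirect) * N_TO_N2O)
    field = {
        "N_applied": n_app,
        "P_applied": state.P,
        "K_applied": state.K,
        "N_leached": n_leached,
        "P_to_freshwater": p_runoff,
        "N_field_net": n_field_net,
        "P_field_net": state.P - p_runoff,
        "K_field_net": state.K,
        "N2O_N_direct": n2o_n_direct,
        "N2O_N_indirect": n2o_n_indirect,
    }
    return gases, field


def fertilizer_credit(field: dict, ef: EmissionFactorSet) -> dict:
    """Avoided mineral fertilizer (kg elemental N, P, K)."""
    if min(field["N_applied"], field["P_applied"], field["K_applied"]) < 0:
        raise ValueError("field inputs must be >= 0")
    return {
        "N": ef.fert_equiv_n * field["N_applied"],
        "P": ef.fert_equiv_p * field["P_applied"],
        "K": ef.fert_equiv_k * field["K_applied"],
    }


def manure_chain(excreted: NutrientVector, ef: EmissionFactorSet) -> dict:
    """Run housing -> storage -> spreading and collect everything.

    Returns a dict with per-phase :class:`GasEmissions`, the field inputs and
    the fertilizer credit.
    """
    g_house, st = housing_emissions(excreted, ef)
    g_store, st2 = storage_emissions(st, ef)
    g_spread, field = spreading_emissions(st2, ef)
    return {
        "housing": g_house,
        "storage": g_store,
        "spreading": g_spread,
        "field": field,
        "credit": fertilizer_credit(field, ef),
    }
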