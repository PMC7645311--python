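"""Model constants and configuration.

All biological and farm-level constants used by the growth simulator, the
nutrient mass balance and the on-farm input modules live here, so that every
assumption is visible and overridable in one place.  Values fall into two
groups:

* energetic and allometric constants of the pig growth closure (net energy of
  maintenance, tissue energy densities, body-water and ash allometry).  These
  follow the conventions of net-energy growth models for fattening pigs and
  are defaults, not measured values;
* bookkeeping coefficients for nutrient retention and on-farm inputs (water to
  feed ratios, cleaning water, energy use per kg live weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ModelConfig:
    """Constants of the net-energy growth and mass-balance model.

    Energy units are MJ, tissue masses kg, daily depositions g/day.
    """

    # --- maintenance: NEm = nem_coeff * BW**nem_exp  [MJ/day] ---
    nem_coeff: float = 0.75
    nem_exp: float = 0.60

    # --- tissue energy densities [kJ/g] ---
    kj_per_g_protein: float = 23.6
    kj_per_g_lipid: float = 39.7

    # --- body composition closure ---
    # empty BW = BP + BL + water + ash, water = water_coeff * BP**water_exp,
    # ash = ash_per_protein * BP, live BW = empty BW / (1 - gut_fill)
    water_coeff: float = 4.88
    water_exp: float = 0.855
    ash_per_protein: float = 0.20
    gut_fill: float = 0.05

    # --- intake curve defaults (Gamma in age): NEI(t) = A * t**k * exp(-t/theta) ---
    intake_shape: float = 2.0   # k, dimensionless
    intake_rate: float = 80.0   # theta, days

    # --- integration ---
    max_days: float = 400.0

    # --- nutrient retention per kg live BW gain (fattening) ---
    protein_n_fraction: float = 0.16       # kg N per kg body protein (6.25 rule)
    p_retention_g_per_kg_gain: float = 5.3
    k_retention_g_per_kg_gain: float = 2.2
    cu_retention_mg_per_kg_gain: float = 2.5
    zn_retention_mg_per_kg_gain: float = 25.0

    # --- post-weaning body composition (fractions of live BW gain) ---
    pw_protein_fraction: float = 0.16
    pw_lipid_fraction: float = 0.12

    # --- on-farm inputs ---
    water_to_feed: dict = field(default_factory=lambda: {
        "lactating": 4.5,
        "gestating": 4.0,
        "post_weaning": 2.5,
        "fattening": 2.7,
    })
    cleaning_water_per_sow_l: float = 2300.0
    cleaning_water_per_fattening_pig_l: float = 30.0
    energy_kwh_per_kg_lw: float = 0.42
    energy_split: dict = field(default_factory=lambda: {
        "electricity": 0.70, "oil": 0.20, "gas": 0.10,
    })
    transport_tkm_per_kg_feed: float = 0.10

    def with_overrides(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = ModelConfig()
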