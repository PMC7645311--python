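"""On-farm water, energy and feed-transport inputs.

All inputs are linear in their drivers (feed mass or live weight), which
keeps the inventory per kg live weight invariant to herd size and makes it
sensitive to feed efficiency: a pig that eats less drinks less, needs less
feed hauled, and its manure chain shrinks with it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ModelConfig, DEFAULT_CONFIG


@dataclass(frozen=True)
class FarmInputs:
    drinking_water_l: float = 0.0
    cleaning_water_l: float = 0.0
    electricity_kwh: float = 0.0
    oil_kwh: float = 0.0
    gas_kwh: float = 0.0
    transport_tkm: float = 0.0

    def __post_init__(self):
        for f in ("drinking_water_l", "cleaning_water_l", "electricity_kwh",
                  "oil_kwh", "gas_kwh", "transport_tkm"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def __add__(self, other: "FarmInputs") -> "FarmInputs":
        return FarmInputs(
            drinking_water_l=self.drinking_water_l + other.drinking_water_l,
            cleaning_water_l=self.cleaning_water_l + other.cleaning_water_l,
            electricity_kwh=self.electricity_kwh + other.electricity_kwh,
            oil_kwh=self.oil_kwh + other.oil_kwh,
            gas_kwh=self.gas_kwh + other.gas_kwh,
            transport_tkm=self.transport_tkm + other.transport_tkm)

    def scale(self, c: float) -> "FarmInputs":
        return FarmInputs(
            drinking_water_l=c * self.drinking_water_l,
            cleaning_water_l=c * self.cleaning_water_l,
            electricity_kwh=c * self.electricity_kwh,
            oil_kwh=c * self.oil_kwh,
            gas_kwh=c * self.gas_kwh,
            transport_tkm=c * self.transport_tkm)


def drinking_water(stage: str, feed_kg: float,
                   cfg: ModelConfig = DEFAULT_CONFIG) -> float:
    """Drinking water (L) as a stage-specific multiple of feed intake.

    Ratios default to 4.5, 4.0, 2.5 and 2.7 L/kg feed for lactating,
    gestating, post-weaning and fattening animals.
    """
    if stage not in cfg.water_to_feed:
        raise ValueError(f"unknown stage {stage!r}; expected one of "
                         f"{sorted(cfg.water_to_feed)}")
    if feed_kg < 0:
        raise ValueError("feed_kg must be >= 0")
    return cfg.water_to_feed[stage] * feed_kg


def cleaning_water(n_sows: float, n_fattening: float,
                   cfg: ModelConfig = DEFAULT_CONFIG) -> float:
    """Cleaning water (L): 2300 L per sow plus 30 L per fattening pig."""
    if n_sows < 0 or n_fattening < 0:
        raise ValueError("animal counts must be >= 0")
    return (cfg.cleaning_water_per_sow_l * n_sows
            + cfg.cleaning_water_per_fattening_pig_l * n_fattening)


def farm_energy(live_weight_kg: float, split: dict | None = None,
                cfg: ModelConfig = DEFAULT_CONFIG) -> tuple:
    """(electricity, oil, gas) kWh for the produced live weight.

    Total is 0.42 kWh per kg LW, split across carriers (default 70/20/10).
    """
    if live_weight_kg < 0:
        raise ValueError("live weight must be >= 0")
    split = cfg.energy_split if split is None else split
    if abs(sum(split.values()) - 1.0) > 1e-9:
        raise ValueError(f"energy split fractions sum to {sum(split.values())}, not 1")
    total = cfg.energy_kwh_per_kg_lw * live_weight_kg
    return (total * split["electricity"], total * split["oil"], total * split["gas"])


def feed_transport(feed_kg: float, coefficient: float | None = None,
                   cfg: ModelConfig = DEFAULT_CONFIG) -> float:
    """Feed transport (tkm), linear in feed mass."""
    if feed_kg < 0:
        raise ValueError("feed_kg must be >= 0")
    coef = cfg.transport_tkm_per_kg_feed if coefficient is None else coefficient
    return coef * feed_kg
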