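"""Nutrient mass balance: intake - retained = excreted, per life stage.

The excreta composition (DM, OM, N, P, K, Cu, Zn) is computed stage by stage
as the difference between nutrients taken up with the feed and nutrients
retained in the body; the identity is enforced exactly.  For the elements
(N, P, K, Cu, Zn) this is the usual excretion estimate.  For DM and OM the
"excreted" term is a closure that also contains respired carbon -- the
emission chain therefore derives storage volatile solids from its own
fraction of this OM rather than using it directly (see ``emissions``).

Three stages are covered: the fattening pig (individual), the post-weaning
pig (line average) and the sow-litter stage (line-average reproductive cycle
whose burdens are allocated equally across weaned piglets).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ModelConfig, DEFAULT_CONFIG
from .diet import DietSpec, NUTRIENTS


class MassBalanceError(ValueError):
    pass


@dataclass(frozen=True)
class NutrientVector:
    """Componentwise nutrient amounts: kg for DM/OM/N/P/K, g for Cu/Zn."""

    DM: float = 0.0
    OM: float = 0.0
    N: float = 0.0
    P: float = 0.0
    K: float = 0.0
    Cu: float = 0.0
    Zn: float = 0.0

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(**{n: getattr(self, n) + getattr(other, n)
                                 for n in NUTRIENTS})

    def __sub__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(**{n: getattr(self, n) - getattr(other, n)
                                 for n in NUTRIENTS})

    def scale(self, c: float) -> "NutrientVector":
        return NutrientVector(**{n: c * getattr(self, n) for n in NUTRIENTS})

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in NUTRIENTS}

    def min_component(self) -> float:
        return min(getattr(self, n) for n in NUTRIENTS)


ZERO = NutrientVector()


@dataclass(frozen=True)
class StageBalance:
    """intake - retained = excreted for one life stage."""

    stage: str                      # sow_litter | post_weaning | fattening
    feed_kg: float
    intake: NutrientVector
    retained: NutrientVector
    excreted: NutrientVector


@dataclass(frozen=True)
class SowLitterProfile:
    """Average reproductive-cycle performance of one line's sows.

    Feed is the total over one gestation + lactation cycle (ME basis --
    sow feed enters only as mass and nutrients; no sow growth is modelled).
    ``retained`` is the cycle's nutrient export in sow tissue change and
    weaned piglets.
    """

    line: str
    litters_per_year: float
    feed_gestation_kg: float
    feed_lactation_kg: float
    weaned_piglets: float
    piglet_weaning_weight: float
    retained: NutrientVector
    provenance: str = "synthetic fixture"

    def __post_init__(self):
        if self.weaned_piglets < 1:
            raise ValueError("weaned piglets must be >= 1")
        if self.feed_cycle_kg <= 0:
            raise ValueError("cycle feed must be positive")

    @property
    def feed_cycle_kg(self) -> float:
        return self.feed_gestation_kg + self.feed_lactation_kg


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def intake_nutrients(feed_kg: float, diet: DietSpec) -> NutrientVector:
    """Nutrients taken up with ``feed_kg`` of the diet (linear in feed)."""
    if feed_kg < 0:
        raise ValueError("feed_kg must be >= 0")
    missing = [n for n in NUTRIENTS if n not in diet.nutrient_content]
    if missing:
        raise MassBalanceError(f"diet missing content for: {', '.join(missing)}")
    # g/kg (or mg/kg for Cu, Zn) -> kg (or g): one factor of 1/1000 either way
    return NutrientVector(**{n: feed_kg * diet.nutrient_content[n] / 1000.0
                             for n in NUTRIENTS})


def retained_nutrients(bp_gain: float, bl_gain: float, bw_gain: float,
                       cfg: ModelConfig = DEFAULT_CONFIG) -> NutrientVector:
    """Nutrients fixed in the body over a growth interval.

    N follows the 6.25 protein convention (protein is 16% N); P, K, Cu and Zn
    use per-kg-live-gain retention coefficients; DM and OM retention are the
    body solids (protein + lipid + ash, ash counted in DM only).
    """
    if min(bp_gain, bl_gain, bw_gain) < 0:
        raise ValueError("gains must be >= 0")
    ash = cfg.ash_per_protein * bp_gain
    return NutrientVector(
        DM=bp_gain + bl_gain + ash,
        OM=bp_gain + bl_gain,
        N=cfg.protein_n_fraction * bp_gain,
        P=cfg.p_retention_g_per_kg_gain * bw_gain / 1000.0,
        K=cfg.k_retention_g_per_kg_gain * bw_gain / 1000.0,
        Cu=cfg.cu_retention_mg_per_kg_gain * bw_gain / 1000.0,
        Zn=cfg.zn_retention_mg_per_kg_gain * bw_gain / 1000.0,
    )


def stage_balance(stage: str, feed_kg: float, diet: DietSpec,
                  retained: NutrientVector) -> StageBalance:
    """Assemble a stage's balance, enforcing non-negative excretion."""
    intake = intake_nutrients(feed_kg, diet)
    excreted = intake - retained
    for n in NUTRIENTS:
        if getattr(excreted, n) < -1e-12:
            raise MassBalanceError(
                f"mass balance violation in stage {stage!r}: retained "
                f"{n} ({getattr(retained, n):.4g}) exceeds intake "
                f"({getattr(intake, n):.4g})")
    return StageBalance(stage=stage, feed_kg=feed_kg, intake=intake,
                        retained=retained, excreted=excreted)


def postweaning_balance(avg_feed_kg: float, avg_gain_kg: float, diet: DietSpec,
                        cfg: ModelConfig = DEFAULT_CONFIG) -> StageBalance:
    """Line-average post-weaning balance (28 days to 10 weeks of age).

    Individual feed records are unavailable before fattening, so the stage
    uses line averages and a fixed post-weaning body composition.
    """
    bp_gain = cfg.pw_protein_fraction * avg_gain_kg
    bl_gain = cfg.pw_lipid_fraction * avg_gain_kg
    retained = retained_nutrients(bp_gain, bl_gain, avg_gain_kg, cfg)
    return stage_balance("post_weaning", avg_feed_kg, diet, retained)


def sow_litter_share(profile: SowLitterProfile, diet_sow: DietSpec) -> tuple:
    """One reproductive cycle's balance and the per-weaned-piglet share.

    Burdens are divided by weaned (not born) piglets: only weaned piglets
    enter the fattening stage that carries the functional unit.
    """
    bal = stage_balance("sow_litter", profile.feed_cycle_kg, diet_sow,
                        profile.retained)
    return bal, 1.0 / profile.weaned_piglets
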