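"""Per-pig cradle-to-farm-gate pipeline.

For each fattening pig the chain is: growth trajectory -> fattening nutrient
balance -> (plus its own post-weaning stage and its allocated share of the
sow-litter cycle) -> manure emission chain on the summed excretion ->
on-farm water/energy/transport -> inventory per kg live weight ->
characterized impacts.

The manure chain is linear in the excretion vector, so running it once on
the summed (fattening + post-weaning + sow share) excretion equals summing
per-stage chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .balance import (StageBalance, retained_nutrients, stage_balance,
                      postweaning_balance, sow_litter_share)
from .emissions import enteric_ch4, manure_chain
from .farm_inputs import FarmInputs, drinking_water, cleaning_water, farm_energy, feed_transport
from .growth import GrowthTrajectory, PerformanceTraits
from .lcia import (LifeCycleInventory, ImpactVector, assemble_inventory,
                   characterize)
from .synthetic import FixtureSet


class PipelineError(RuntimeError):
    pass


@dataclass
class PigLCAResult:
    """One pig's traits, inventory and characterized impacts."""

    traits: PerformanceTraits
    inventory: LifeCycleInventory
    impacts: ImpactVector
    balances: dict                     # stage -> StageBalance


def fattening_balance(traj: GrowthTrajectory, traits: PerformanceTraits,
                      fx: FixtureSet) -> StageBalance:
    """Individual fattening-stage balance from the simulated trajectory."""
    bp_gain = traj.slaughter_bp - traj.start_bp
    bl_gain = traj.slaughter_bl - traj.start_bl
    bw_gain = traj.target_bw - traj.start_bw
    retained = retained_nutrients(bp_gain, bl_gain, bw_gain, fx.config)
    return stage_balance("fattening", traits.total_fi, fx.diet, retained)


def pig_lca(traj: GrowthTrajectory, traits: PerformanceTraits,
            fx: FixtureSet) -> PigLCAResult:
    """Full LCA of one fattening pig including its allocated shares."""
    line = traits.line
    if line not in fx.sow_profiles:
        raise PipelineError(f"no sow profile for line {line!r}")
    if line not in fx.postweaning:
        raise PipelineError(f"no post-weaning averages for line {line!r}")

    bal_fat = fattening_balance(traj, traits, fx)
    pw = fx.postweaning[line]
    bal_pw = postweaning_balance(pw["feed_kg"], pw["gain_kg"], fx.diet, fx.config)
    sow = fx.sow_profiles[line]
    bal_sow, share = sow_litter_share(sow, fx.diet)

    excreted = (bal_fat.excreted + bal_pw.excreted
                + bal_sow.excreted.scale(share))
    total_feed = bal_fat.feed_kg + bal_pw.feed_kg + share * bal_sow.feed_kg

    ef = fx.emission_factors
    fibre_kg = total_feed * fx.diet.dig_fibre / 1000.0
    g_enteric = enteric_ch4(fibre_kg, ef)
    chain = manure_chain(excreted, ef)

    farm = FarmInputs(
        drinking_water_l=(drinking_water("fattening", bal_fat.feed_kg, fx.config)
                          + drinking_water("post_weaning", bal_pw.feed_kg, fx.config)
                          + share * (drinking_water("gestating", sow.feed_gestation_kg, fx.config)
                                     + drinking_water("lactating", sow.feed_lactation_kg, fx.config))),
        cleaning_water_l=(cleaning_water(0, 1, fx.config)
                          + share * cleaning_water(1, 0, fx.config) / sow.litters_per_year),
        electricity_kwh=0.0, oil_kwh=0.0, gas_kwh=0.0,
        transport_tkm=feed_transport(total_feed, cfg=fx.config))
    elec, oil, gas = farm_energy(traits.target_bw, cfg=fx.config)
    farm = farm + FarmInputs(electricity_kwh=elec, oil_kwh=oil, gas_kwh=gas)

    feed_by_ing = {ing: frac * total_feed for ing, frac in fx.diet.ingredients}
    lci = assemble_inventory(
        feed_kg_by_ingredient=feed_by_ing,
        gas_emissions=[g_enteric, chain["housing"], chain["storage"],
                       chain["spreading"]],
        field=chain["field"], credit=chain["credit"], farm=farm,
        slaughter_lw=traits.target_bw)
    impacts = characterize(lci, fx.characterization, fx.feed_impacts)
    return PigLCAResult(traits=traits, inventory=lci, impacts=impacts,
                        balances={"fattening": bal_fat, "post_weaning": bal_pw,
                                  "sow_litter": bal_sow})


def run_cohort_lca(cohort: list, fx: FixtureSet) -> pd.DataFrame:
    """Individual LCA for every pig of a calibrated cohort.

    ``cohort`` is a list of (profile, trajectory, traits) triples as produced
    by :func:`piglca.synthetic.generate_cohort`.  Returns a tidy DataFrame
    (one row per pig: traits + the five impact categories per kg LW); the
    computation is per-pig deterministic and order-independent.
    """
    rows, failed = [], []
    for profile, traj, traits in cohort:
        try:
            res = pig_lca(traj, traits, fx)
        except Exception as err:   # noqa: BLE001 - report all failing ids at once
            failed.append((profile.id, str(err)))
            continue
        row = traits.as_dict()
        row.update(res.impacts.as_dict())
        rows.append(row)
    if failed:
        ids = "; ".join(f"{i}: {m}" for i, m in failed[:5])
        raise PipelineError(f"{len(failed)} pig(s) failed the LCA pipeline ({ids})")
    return pd.DataFrame(rows)
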