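"""Plain-text I/O: cohort tables, trajectories, ledgers and fixture files.

Everything is CSV or JSON so results can be inspected and versioned.
Trajectory files carry their scalar metadata (slaughter values, total NE)
as ``# key=value`` comment lines above the CSV header, which makes the
trajectory -> traits computation round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .balance import SowLitterProfile, NutrientVector
from .diet import DietSpec
from .emissions import EmissionFactorSet
from .growth import GrowthTrajectory
from .lcia import FeedImpactTable, CharacterizationTable
from .synthetic import FixtureSet
from .config import ModelConfig, DEFAULT_CONFIG

COHORT_COLUMNS = ("id", "line", "start_age", "start_bw", "target_bw", "bft",
                  "adfi", "total_fi", "adg")

_TRAJ_META = ("start_age", "slaughter_age", "slaughter_bp", "slaughter_bl",
              "total_nei", "start_bp", "start_bl", "start_bw", "target_bw",
              "step")


def write_cohort_csv(traits_list, path) -> None:
    """Cohort performance table (one row per pig)."""
    rows = []
    for t in traits_list:
        rows.append({"id": t.id, "line": t.line, "start_age": t.slaughter_age - t.duration,
                     "start_bw": t.start_bw, "target_bw": t.target_bw,
                     "bft": t.bft, "adfi": t.adfi, "total_fi": t.total_fi,
                     "adg": t.adg})
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {', '.join(missing)}")
    return df


def write_trajectory_csv(traj: GrowthTrajectory, path) -> None:
    lines = [f"# {k}={getattr(traj, k)!r}" for k in _TRAJ_META]
    body = traj.records.to_csv(index=False)
    Path(path).write_text("\n".join(lines) + "\n" + body)


def read_trajectory_csv(path) -> GrowthTrajectory:
    text = Path(path).read_text().splitlines()
    meta = {}
    n_meta = 0
    for line in text:
        if not line.startswith("#"):
            break
        n_meta += 1
        k, v = line[1:].strip().split("=", 1)
        meta[k] = float(v)
    from io import StringIO
    records = pd.read_csv(StringIO("\n".join(text[n_meta:])))
    return GrowthTrajectory(records=records, **meta)


def write_impacts_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_stage_balances_csv(balances: dict, path) -> None:
    """Tidy ledger: stage, nutrient, intake, retained, excreted."""
    rows = []
    for stage, bal in balances.items():
        for n in bal.intake.as_dict():
            rows.append({"stage": stage, "nutrient": n,
                         "intake": getattr(bal.intake, n),
                         "retained": getattr(bal.retained, n),
                         "excreted": getattr(bal.excreted, n)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_emission_ledger_csv(gas_list, path) -> None:
    """Tidy ledger: phase, gas, kg."""
    rows = []
    for g in gas_list:
        for species in ("CH4", "NH3", "N2O", "NO", "CO2"):
            rows.append({"phase": g.phase, "gas": species,
                         "kg": getattr(g, species)})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

def write_fixtures(fx: FixtureSet, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fx.diet.to_json(d / "diet.json")
    fx.emission_factors.to_json(d / "emission_factors.json")
    fx.feed_impacts.to_json(d / "feed_impacts.json")
    fx.characterization.to_json(d / "characterization.json")
    sows = {line: {
        "line": p.line, "litters_per_year": p.litters_per_year,
        "feed_gestation_kg": p.feed_gestation_kg,
        "feed_lactation_kg": p.feed_lactation_kg,
        "weaned_piglets": p.weaned_piglets,
        "piglet_weaning_weight": p.piglet_weaning_weight,
        "retained": p.retained.as_dict(), "provenance": p.provenance,
    } for line, p in fx.sow_profiles.items()}
    (d / "herd.json").write_text(json.dumps(
        {"sow_profiles": sows, "postweaning": fx.postweaning}, indent=2))


def load_fixtures(directory, config: ModelConfig = DEFAULT_CONFIG) -> FixtureSet:
    d = Path(directory)
    herd = json.loads((d / "herd.json").read_text())
    sow_profiles = {}
    for line, p in herd["sow_profiles"].items():
        p = dict(p)
        p["retained"] = NutrientVector(**p["retained"])
        sow_profiles[line] = SowLitterProfile(**p)
    return FixtureSet(
        diet=DietSpec.from_json(d / "diet.json"),
        emission_factors=EmissionFactorSet.from_json(d / "emission_factors.json"),
        feed_impacts=FeedImpactTable.from_json(d / "feed_impacts.json"),
        characterization=CharacterizationTable.from_json(d / "characterization.json"),
        sow_profiles=sow_profiles, postweaning=herd["postweaning"],
        config=config)
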