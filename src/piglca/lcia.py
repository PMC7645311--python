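"""Life cycle inventory assembly and midpoint impact characterization.

The functional unit is 1 kg of live pig at the farm gate.  A
:class:`LifeCycleInventory` lists every elementary flow of one pig's cradle-
to-farm-gate system (feed mass per ingredient, gases per phase, nutrient
losses to water, on-farm water/energy, transport, and avoided mineral
fertilizer as credit flows), normalized by slaughter live weight.

Characterization is strictly linear: each flow is multiplied by its factor
into the five midpoint categories

* CC -- climate change, kg CO2-eq
* AP -- terrestrial acidification, kg SO2-eq
* EP -- freshwater eutrophication, kg P-eq
* LO -- land occupation, m2.a
* WD -- water depletion, m3

Credit flows (prefix ``credit:``) subtract the production-phase impacts of
the mineral fertilizer they displace.  Biogenic CO2 from animals and manure
is excluded from CC by convention; CH4 and N2O are included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .emissions import GASES
from .farm_inputs import FarmInputs

CATEGORIES = ("CC", "AP", "EP", "LO", "WD")

#: impact-category display units per kg live weight
CATEGORY_UNITS = {"CC": "kg CO2-eq", "AP": "kg SO2-eq", "EP": "kg P-eq",
                  "LO": "m2.a", "WD": "m3"}

CREDIT_PREFIX = "credit:"
FEED_PREFIX = "feed:"

#: segment labels for contribution analysis
SEGMENTS = ("feed", "housing_and_manure", "on_farm_water_energy")


class CharacterizationError(ValueError):
    pass


@dataclass
class ImpactVector:
    """Five characterized midpoint impacts per kg live weight."""

    CC: float = 0.0
    AP: float = 0.0
    EP: float = 0.0
    LO: float = 0.0
    WD: float = 0.0

    def __add__(self, other: "ImpactVector") -> "ImpactVector":
        return ImpactVector(**{c: getattr(self, c) + getattr(other, c)
                               for c in CATEGORIES})

    def scale(self, a: float) -> "ImpactVector":
        return ImpactVector(**{c: a * getattr(self, c) for c in CATEGORIES})

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in CATEGORIES}


@dataclass
class LifeCycleInventory:
    """Flows per kg live weight at farm gate: name -> (amount, unit)."""

    flows: dict = field(default_factory=dict)
    normalization: str = "per kg live weight at farm gate"

    def add(self, name: str, amount: float, unit: str) -> None:
        if name in self.flows:
            old_amount, old_unit = self.flows[name]
            if old_unit != unit:
                raise ValueError(f"unit clash for flow {name!r}")
            self.flows[name] = (old_amount + amount, unit)
        else:
            self.flows[name] = (amount, unit)

    def amount(self, name: str) -> float:
        return self.flows.get(name, (0.0, ""))[0]


def _table_from_json(path, key):
    payload = json.loads(Path(path).read_text())
    return payload[key], payload.get("_provenance", "")


@dataclass
class FeedImpactTable:
    """Per-kg ingredient impact factors for the five categories."""

    factors: dict                       # ingredient -> {category: factor}
    provenance: str = "synthetic fixture"

    def __post_init__(self):
        for ing, row in self.factors.items():
            if row.get("LO", 0.0) < 0 or row.get("WD", 0.0) < 0:
                raise ValueError(f"LO/WD factors must be >= 0 ({ing})")

    def covers(self, ingredients) -> bool:
        return all(i in self.factors for i in ingredients)

    def scaled(self, multipliers: dict) -> "FeedImpactTable":
        """Multiply each (ingredient, category) cell (for Monte Carlo)."""
        new = {ing: {c: v * multipliers.get((ing, c), 1.0)
                     for c, v in row.items()}
               for ing, row in self.factors.items()}
        return FeedImpactTable(factors=new, provenance=self.provenance)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"_provenance": self.provenance, "factors": self.factors}, indent=2))

    @classmethod
    def from_json(cls, path) -> "FeedImpactTable":
        factors, prov = _table_from_json(path, "factors")
        return cls(factors=factors, provenance=prov or "file")


@dataclass
class CharacterizationTable:
    """Factor per (elementary flow, category); empty row = explicit zero."""

    factors: dict                       # flow base name -> {category: factor}
    method: str = "fixture midpoint method"

    def row(self, flow_base: str) -> dict | None:
        return self.factors.get(flow_base)

    def scaled(self, multipliers: dict) -> "CharacterizationTable":
        new = {f: {c: v * multipliers.get((f, c), 1.0) for c, v in row.items()}
               for f, row in self.factors.items()}
        return CharacterizationTable(factors=new, method=self.method)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"_provenance": self.method, "factors": self.factors}, indent=2))

    @classmethod
    def from_json(cls, path) -> "CharacterizationTable":
        factors, prov = _table_from_json(path, "factors")
        return cls(factors=factors, method=prov or "file")


@dataclass
class ContributionBreakdown:
    """Per category, percentage shares of the three process segments."""

    shares: dict                        # category -> {segment: %}


# ---------------------------------------------------------------------------
# inventory assembly
# ---------------------------------------------------------------------------

def assemble_inventory(*, feed_kg_by_ingredient: dict,
                       gas_emissions: list,
                       field: dict,
                       credit: dict,
                       farm: FarmInputs,
                       slaughter_lw: float) -> LifeCycleInventory:
    """Collect one pig's absolute flows and normalize per kg live weight.

    Parameters mirror the pipeline stages: total feed use per ingredient
    (all stages, kg), the per-phase gas emissions, the spreading field dict
    (for N leached and P to freshwater), the fertilizer credit and the
    on-farm inputs.  Doubling every absolute flow together with the live
    weight leaves the result unchanged.
    """
    if slaughter_lw <= 0:
        raise ValueError("slaughter live weight must be positive")
    for name, arg in (("feed", feed_kg_by_ingredient), ("gases", gas_emissions),
                      ("field", field), ("credit", credit), ("farm", farm)):
        if arg is None:
            raise ValueError(f"missing stage result: {name}")
    inv = LifeCycleInventory()
    s = 1.0 / slaughter_lw
    for ing, kg in feed_kg_by_ingredient.items():
        inv.add(f"{FEED_PREFIX}{ing}", kg * s, "kg")
    for gas in gas_emissions:
        for species in GASES:
            m = getattr(gas, species)
            if m != 0.0:
                inv.add(f"{species.lower()}@{gas.phase}", m * s, "kg")
    inv.add("n_leached", field["N_leached"] * s, "kg")
    inv.add("p_freshwater", field["P_to_freshwater"] * s, "kg")
    inv.add("water", (farm.drinking_water_l + farm.cleaning_water_l) * s, "L")
    inv.add("electricity", farm.electricity_kwh * s, "kWh")
    inv.add("oil", farm.oil_kwh * s, "kWh")
    inv.add("gas_energy", farm.gas_kwh * s, "kWh")
    inv.add("transport", farm.transport_tkm * s, "tkm")
    for elem in ("N", "P", "K"):
        inv.add(f"{CREDIT_PREFIX}fert_{elem.lower()}", credit[elem] * s, "kg")
    return inv


# ---------------------------------------------------------------------------
# characterization
# ---------------------------------------------------------------------------

def _flow_base(name: str) -> str:
    """'ch4@storage' -> 'ch4'; 'feed:wheat' and credits keep their names."""
    return name.split("@", 1)[0]


def _flow_impacts(name: str, amount: float, cf: CharacterizationTable,
                  feed_cf: FeedImpactTable) -> dict | None:
    """Characterized impacts of a single flow, or None if unmapped."""
    if name.startswith(FEED_PREFIX):
        row = feed_cf.factors.get(name[len(FEED_PREFIX):])
        sign = 1.0
    else:
        sign = 1.0
        base = _flow_base(name)
        if name.startswith(CREDIT_PREFIX):
            sign = -1.0
            base = name[len(CREDIT_PREFIX):]
        row = cf.row(base)
    if row is None:
        return None
    return {c: sign * amount * row.get(c, 0.0) for c in CATEGORIES}


def characterize(lci: LifeCycleInventory, cf: CharacterizationTable,
                 feed_cf: FeedImpactTable) -> ImpactVector:
    """Linear characterization of an inventory into the five categories.

    Every flow must be covered by the characterization table (an empty row is
    an explicit zero) or, for ``feed:`` flows, by the feed impact table;
    ``credit:`` flows enter with a negative sign.
    """
    totals = dict.fromkeys(CATEGORIES, 0.0)
    unmapped = []
    for name, (amount, _unit) in lci.flows.items():
        impacts = _flow_impacts(name, amount, cf, feed_cf)
        if impacts is None:
            unmapped.append(name)
            continue
        for c in CATEGORIES:
            totals[c] += impacts[c]
    if unmapped:
        raise CharacterizationError(
            "no characterization factor for flows: " + ", ".join(sorted(unmapped)))
    return ImpactVector(**totals)


def _segment_of(name: str) -> str:
    if name.startswith(FEED_PREFIX) or name == "transport":
        return "feed"
    if name in ("water", "electricity", "oil", "gas_energy"):
        return "on_farm_water_energy"
    # gases, nutrient losses and fertilizer credits originate from the animal
    # and its manure
    return "housing_and_manure"


def contribution(lci: LifeCycleInventory, cf: CharacterizationTable,
                 feed_cf: FeedImpactTable) -> ContributionBreakdown:
    """Percentage contribution of each process segment per category.

    Segments partition the flow set (feed incl. its transport; housing and
    manure incl. fertilizer credits; on-farm water and energy); shares sum
    to 100 per category.
    """
    seg_tot = {seg: dict.fromkeys(CATEGORIES, 0.0) for seg in SEGMENTS}
    for name, (amount, _unit) in lci.flows.items():
        impacts = _flow_impacts(name, amount, cf, feed_cf)
        if impacts is None:
            raise CharacterizationError(f"no characterization factor for {name!r}")
        seg = _segment_of(name)
        for c in CATEGORIES:
            seg_tot[seg][c] += impacts[c]
    shares = {}
    for c in CATEGORIES:
        total = sum(seg_tot[seg][c] for seg in SEGMENTS)
        if total == 0.0:
            raise CharacterizationError(
                f"total impact in category {c} is zero; shares undefined")
        shares[c] = {seg: 100.0 * seg_tot[seg][c] / total for seg in SEGMENTS}
    return ContributionBreakdown(shares=shares)
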