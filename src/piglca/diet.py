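"""Diet specification: ingredient incorporation and chemical composition.

A :class:`DietSpec` carries what the rest of the model needs from a feed:
its net and metabolisable energy, its nutrient contents for the mass balance
(DM, OM, N, P, K, Cu, Zn) and its digestible fibre content for enteric
methane.  Contents are g/kg feed except Cu and Zn which are mg/kg feed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

NUTRIENTS = ("DM", "OM", "N", "P", "K", "Cu", "Zn")


class DietError(ValueError):
    pass


@dataclass(frozen=True)
class DietSpec:
    """One feed: ingredient fractions plus chemical/nutritional composition.

    Parameters
    ----------
    ingredients : list of (name, fraction)
        Incorporation fractions of feed mass; must sum to 1.
    ne_content, me_content : float
        Net / metabolisable energy, MJ per kg feed; ``ne <= me``.
    crude_protein : float
        g crude protein per kg feed; N content must equal CP/6.25 within 1%.
    dig_fibre : float
        g digestible fibre per kg feed (drives enteric CH4).
    nutrient_content : dict
        {DM, OM, N, P, K in g/kg; Cu, Zn in mg/kg}.
    digestibility : dict
        Apparent digestibility fractions for N and P.
    """

    ingredients: tuple
    ne_content: float
    me_content: float
    crude_protein: float
    dig_fibre: float
    nutrient_content: dict
    digestibility: dict = field(default_factory=lambda: {"N": 0.85, "P": 0.55})
    name: str = "diet"

    def __post_init__(self):
        object.__setattr__(self, "ingredients", tuple(
            (str(n), float(f)) for n, f in self.ingredients))
        total = sum(f for _, f in self.ingredients)
        if abs(total - 1.0) > 1e-6:
            raise DietError(f"incorporation fractions sum to {total!r}, not 1")
        if self.ne_content > self.me_content:
            raise DietError("ne_content exceeds me_content")
        if self.ne_content <= 0:
            raise DietError("ne_content must be positive")
        missing = [n for n in NUTRIENTS if n not in self.nutrient_content]
        if missing:
            raise DietError(f"missing nutrient content for: {', '.join(missing)}")
        if any(v < 0 for v in self.nutrient_content.values()):
            raise DietError("nutrient contents must be non-negative")
        if self.dig_fibre < 0 or self.crude_protein < 0:
            raise DietError("contents must be non-negative")
        n_from_cp = self.crude_protein / 6.25
        n = self.nutrient_content["N"]
        if n_from_cp > 0 and abs(n - n_from_cp) / n_from_cp > 0.01:
            raise DietError(
                f"N content {n} g/kg inconsistent with crude protein "
                f"{self.crude_protein} g/kg (expected {n_from_cp:.2f})")

    @property
    def ingredient_names(self) -> tuple:
        return tuple(n for n, _ in self.ingredients)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["ingredients"] = [list(t) for t in self.ingredients]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "DietSpec":
        payload = json.loads(Path(path).read_text())
        payload["ingredients"] = tuple(tuple(t) for t in payload["ingredients"])
        return cls(**payload)
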