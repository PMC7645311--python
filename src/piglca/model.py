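"""Model/Results interface over the cohort pipeline.

:class:`CohortLCA` is built from data (a cohort performance table or a pair
of line specifications); ``fit()`` calibrates every pig, runs the individual
LCAs and the within-line RFI regressions, and returns a
:class:`CohortLCAResults` carrying the per-pig impacts, line comparison with
uncertainty, correlation tables and a ``summary()``.  The uncertainty and
sensitivity analyses hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import (compare_lines, trait_impact_correlations, oat_sensitivity,
                       parallel_monte_carlo, LineComparison, SensitivityReport,
                       MonteCarloReport, UncertaintySpec)
from .growth import fit_rfi
from .lcia import CATEGORIES, CATEGORY_UNITS
from .pipeline import run_cohort_lca
from .synthetic import (FixtureSet, LineSpec, default_fixtures,
                        default_line_specs, generate_cohort, calibrate_pig)


class CohortLCA:
    """Individual-pig LCA model for a two-line cohort.

    Parameters
    ----------
    cohort : list of (profile, trajectory, traits)
        Calibrated pigs, e.g. from :func:`piglca.synthetic.generate_cohort`.
    fixtures : FixtureSet, optional
        Diet, factor tables and herd profiles; defaults to the packaged
        fixture set.
    """

    def __init__(self, cohort: list, fixtures: FixtureSet | None = None,
                 low: str = "LRFI", high: str = "HRFI"):
        self.cohort = cohort
        self.fixtures = default_fixtures() if fixtures is None else fixtures
        self.low, self.high = low, high
        self._specs: dict | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_specs(cls, specs: dict | None = None, seed: int = 0,
                   fixtures: FixtureSet | None = None) -> "CohortLCA":
        """Generate and calibrate synthetic cohorts from line specs.

        ``specs`` maps line label to :class:`LineSpec`; defaults to the
        packaged two-line study conditions.  Each line's cohort gets a
        sub-seed derived from ``seed``.
        """
        fx = default_fixtures() if fixtures is None else fixtures
        if specs is None:
            lrfi, hrfi = default_line_specs()
            specs = {lrfi.label: lrfi, hrfi.label: hrfi}
        cohort = []
        ss = np.random.SeedSequence(seed)
        for (label, spec), child in zip(sorted(specs.items()),
                                        ss.spawn(len(specs))):
            sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
            cohort.extend(generate_cohort(spec, seed=sub_seed, diet=fx.diet,
                                          cfg=fx.config))
        model = cls(cohort, fixtures=fx)
        model._specs = specs
        return model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fixtures: FixtureSet | None = None,
                       bp_bl_default: float = 0.90) -> "CohortLCA":
        """Calibrate pigs from a cohort performance table.

        Expects the cohort CSV columns (id, line, start_age, start_bw,
        target_bw, bft, adfi, total_fi, adg) and optionally ``bp_bl``; the
        slaughter BP/BL target falls back to ``bp_bl_default`` when absent.
        """
        fx = default_fixtures() if fixtures is None else fixtures
        cohort = []
        for _, row in df.iterrows():
            gain = row["target_bw"] - row["start_bw"]
            fcr = row["total_fi"] / gain
            cohort.append(calibrate_pig(
                str(row["id"]), str(row["line"]), adfi=float(row["adfi"]),
                fcr=float(fcr), bft=float(row["bft"]),
                bp_bl=float(row.get("bp_bl", bp_bl_default)),
                start_bw=float(row["start_bw"]),
                start_age=float(row["start_age"]),
                target_bw=float(row["target_bw"]),
                diet=fx.diet, cfg=fx.config))
        return cls(cohort, fixtures=fx)

    # -- estimation ---------------------------------------------------------

    def fit(self, rfi_pooled: bool = False) -> "CohortLCAResults":
        """Run the individual LCAs and the within-line RFI regressions."""
        df = run_cohort_lca(self.cohort, self.fixtures)
        traits_by_id = {t.id: t for _, _, t in self.cohort}
        if rfi_pooled:
            groups = [list(traits_by_id.values())]
        else:
            groups = [[t for t in traits_by_id.values() if t.line == line]
                      for line in sorted(df["line"].unique())]
        for group in groups:
            if len(group) >= 10:
                fit_rfi(group, self.fixtures.config)
        df["rfi"] = [traits_by_id[i].rfi for i in df["id"]]
        return CohortLCAResults(model=self, impacts=df)


@dataclass
class CohortLCAResults:
    """Per-pig impacts and the study-level analyses over them."""

    model: CohortLCA
    impacts: pd.DataFrame

    def line_comparison(self) -> LineComparison:
        return compare_lines(self.impacts, low=self.model.low,
                             high=self.model.high)

    def correlations(self, traits: list | None = None) -> pd.DataFrame:
        return trait_impact_correlations(self.impacts, traits=traits)

    def oat(self, line: str | None = None, **kwargs) -> SensitivityReport:
        specs = self._specs()
        label = self.model.high if line is None else line
        return oat_sensitivity(specs[label], self.model.fixtures, **kwargs)

    def monte_carlo(self, n_draws: int = 1000, seed: int = 0,
                    unc: UncertaintySpec | None = None) -> MonteCarloReport:
        return parallel_monte_carlo(self._specs(), self.model.fixtures,
                                    n_draws=n_draws, seed=seed, unc=unc,
                                    low=self.model.low, high=self.model.high)

    def _specs(self) -> dict:
        if self.model._specs is None:
            raise ValueError(
                "line specs unavailable (model built from raw cohort); "
                "pass LineSpec objects via CohortLCA.from_specs")
        return self.model._specs

    def mean_pct_reduction(self) -> float:
        """Mean percent reduction (low vs high line) over the 5 categories."""
        cmp_ = self.line_comparison()
        return float(cmp_.table["pct_diff"].mean())

    def summary(self) -> str:
        cmp_ = self.line_comparison()
        n_by_line = self.impacts["line"].value_counts().to_dict()
        lines = [
            "Individual-pig life cycle assessment",
            "=" * 60,
            f"Functional unit: 1 kg live weight at farm gate",
            f"Pigs: " + ", ".join(f"{k} n={v}" for k, v in sorted(n_by_line.items())),
            "",
            f"{'category':<10}{'unit':<12}{cmp_.low_label:>10}{cmp_.high_label:>10}"
            f"{'diff %':>9}{'p':>12}",
            "-" * 63,
        ]
        for c in CATEGORIES:
            row = cmp_.table.loc[c]
            lines.append(
                f"{c:<10}{CATEGORY_UNITS[c]:<12}"
                f"{row[f'mean_{cmp_.low_label}']:>10.4f}"
                f"{row[f'mean_{cmp_.high_label}']:>10.4f}"
                f"{row['pct_diff']:>9.2f}{row['p']:>12.3g}")
        lines.append("-" * 63)
        lines.append(f"mean reduction over categories: "
                     f"{cmp_.table['pct_diff'].mean():.2f}%")
        return "\n".join(lines)
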