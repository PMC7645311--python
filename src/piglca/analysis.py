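"""Analysis layer: line comparison, correlations, sensitivity, uncertainty.

* :func:`compare_lines` -- Welch two-sample t-tests per impact category and
  percent differences relative to the HRFI (less efficient) line.
* :func:`trait_impact_correlations` -- within-line Pearson correlations with
  Fisher-z 95% confidence intervals.
* :func:`oat_sensitivity` -- one-at-a-time perturbation of the production
  traits by +/- 2 SD around a line's mean pig, rebuilding the pig and
  re-running the LCA; a trait is flagged sensitive when any category moves
  by more than 5%.
* :func:`parallel_monte_carlo` -- uncertainty propagation where both lines'
  mean pigs receive the *same* draw of all uncertain background factors each
  iteration, so shared uncertainty cancels in the comparison and the
  reported number is the fraction of draws in which the LRFI pig has the
  strictly lower impact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .emissions import EmissionFactorSet
from .growth import PigProfile, simulate_growth, compute_traits, GrowthError
from .lcia import CATEGORIES
from .pipeline import pig_lca, PipelineError
from .synthetic import (FixtureSet, LineSpec, mean_pig, calibrate_pig,
                        GenerationError)


# ---------------------------------------------------------------------------
# line comparison
# ---------------------------------------------------------------------------

@dataclass
class LineComparison:
    """Per-category line means, Welch t statistics and percent differences."""

    table: pd.DataFrame        # index: category
    low_label: str
    high_label: str


def compare_lines(impacts: pd.DataFrame, low: str = "LRFI",
                  high: str = "HRFI", alpha: float = 0.05) -> LineComparison:
    """Welch t-test per category; percent difference is 100*(H - L)/H."""
    lines = set(impacts["line"])
    if not {low, high} <= lines:
        raise ValueError(f"need both lines {low!r} and {high!r}, got {sorted(lines)}")
    lo = impacts[impacts["line"] == low]
    hi = impacts[impacts["line"] == high]
    if len(lo) < 2 or len(hi) < 2:
        raise ValueError("each line needs at least 2 pigs")
    rows = {}
    for c in CATEGORIES:
        t, p = stats.ttest_ind(lo[c], hi[c], equal_var=False)
        m_lo, m_hi = lo[c].mean(), hi[c].mean()
        rows[c] = {
            f"mean_{low}": m_lo, f"mean_{high}": m_hi,
            "t": float(t), "p": float(p),
            "pct_diff": 100.0 * (m_hi - m_lo) / m_hi,
            "significant": bool(p < alpha),
        }
    return LineComparison(table=pd.DataFrame(rows).T, low_label=low,
                          high_label=high)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple:
    """Fisher-z confidence interval for a Pearson correlation.

    A perfect correlation (|r| = 1) degenerates to the point interval.
    """
    if abs(r) >= 1.0:
        return r, r
    z = math.atanh(r)
    half = stats.norm.ppf(0.5 + conf / 2.0) / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def trait_impact_correlations(df: pd.DataFrame, traits: list | None = None,
                              by: str = "line") -> pd.DataFrame:
    """Within-line Pearson correlations of traits with impact categories.

    Returns a tidy frame (line, trait, category, n, r, ci_low, ci_high).
    """
    if traits is None:
        traits = ["adg", "adfi", "fcr", "rfi", "bp_bl_ratio", "bft", "mean_pd",
                  "bl", "bp"]
    rows = []
    for line, sub in df.groupby(by):
        n = len(sub)
        if n < 4:
            raise ValueError(f"line {line!r} has n={n} < 4")
        for trait in traits:
            if trait not in sub or sub[trait].isna().all():
                continue
            x = sub[trait].to_numpy(dtype=float)
            if np.std(x) == 0:
                raise ValueError(f"zero-variance trait {trait!r} in line {line!r}")
            for c in CATEGORIES:
                r = float(np.corrcoef(x, sub[c].to_numpy(dtype=float))[0, 1])
                lo, hi = fisher_ci(r, n)
                rows.append({"line": line, "trait": trait, "category": c,
                             "n": n, "r": r, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-at-a-time sensitivity
# ---------------------------------------------------------------------------

OAT_TRAITS = ("adfi", "adg", "fcr", "bp", "pd", "bl", "bp_bl", "bft")


def default_oat_sds(spec: LineSpec) -> dict:
    """Trait standard deviations for the OAT analysis.

    ADFI, FCR, BFT and BP/BL come from the line spec; the body-composition
    trait SDs (ADG, BP, PD, BL) are documented assumptions on the same scale
    as the generated cohorts.
    """
    return {"adfi": spec.sds["adfi"], "fcr": spec.sds["fcr"],
            "bft": spec.sds["bft"], "bp_bl": spec.sds["bp_bl"],
            "adg": 55.0, "bp": 1.0, "pd": 10.0, "bl": 1.5}


@dataclass
class SensitivityReport:
    table: pd.DataFrame        # trait, direction, category, pct_change, ...
    threshold_pct: float = 5.0

    def sensitive_traits(self) -> list:
        ok = self.table[~self.table["failed"]]
        flags = ok.groupby("trait")["sensitive"].any()
        return sorted(flags[flags].index)


def _rebuild_perturbed(trait: str, value: float, base_profile: PigProfile,
                       base_traits, fx: FixtureSet, spec: LineSpec):
    """Rebuild the representative pig with one trait moved, others at means."""
    diet, cfg = fx.diet, fx.config
    gain = spec.target_bw - spec.start_bw_mean

    if trait == "bft":
        # back fat has no lever in the deterministic growth model
        # (impact-inert; it enters only the RFI regression)
        return simulate_growth(base_profile, diet, cfg=cfg)

    if trait in ("adfi", "adg", "fcr"):
        # one trait moves, the others stay at their means: perturbing ADFI at
        # fixed ADG scales the intake amplitude over an unchanged fattening
        # window (all the extra feed is surplus, not growth); perturbing ADG
        # at fixed ADFI shortens or stretches the window
        if trait == "adfi":
            adfi = value
            fcr = value / (base_traits.adg / 1000.0)
        elif trait == "adg":
            adfi = base_traits.adfi
            fcr = adfi / (value / 1000.0)
        else:
            fcr = value
            adfi = fcr * (base_traits.adg / 1000.0)
        _, traj, _ = calibrate_pig(
            "oat", spec.label, adfi=adfi, fcr=fcr, bft=spec.means["bft"],
            bp_bl=spec.means["bp_bl"], start_bw=spec.start_bw_mean,
            start_age=spec.start_age, target_bw=spec.target_bw,
            diet=diet, cfg=cfg)
        return traj

    # composition traits: keep the intake curve and initial composition,
    # move the partition parameter until the slaughter target is met
    def target_residual(rho):
        prof = replace(base_profile, partition_rho=rho)
        traj = simulate_growth(prof, diet, cfg=cfg)   # may raise GrowthError
        if trait == "bp":
            got = traj.slaughter_bp
        elif trait == "bl":
            got = traj.slaughter_bl
        elif trait == "bp_bl":
            got = traj.slaughter_bp / traj.slaughter_bl
        elif trait == "pd":
            got = (traj.slaughter_bp - traj.start_bp) * 1000.0 / traj.duration
        else:
            raise ValueError(f"unknown OAT trait {trait!r}")
        return got - value

    # shrink the bracket to partition values at which the pig still finishes
    lo, hi = 0.03, 0.97
    f_lo = f_hi = None
    for _ in range(24):
        try:
            f_lo = target_residual(lo)
            break
        except GrowthError:
            lo += 0.04
    for _ in range(24):
        if hi <= lo:
            break
        try:
            f_hi = target_residual(hi)
            break
        except GrowthError:
            hi -= 0.04
    if f_lo is None or f_hi is None or hi <= lo or f_lo * f_hi > 0:
        raise GenerationError(
            f"OAT target {trait}={value:.3f} outside reachable range")
    rho = brentq(target_residual, lo, hi, xtol=1e-8)
    return simulate_growth(replace(base_profile, partition_rho=rho), diet, cfg=cfg)


def oat_sensitivity(spec: LineSpec, fx: FixtureSet,
                    trait_sds: dict | None = None,
                    n_sd: float = 2.0, threshold_pct: float = 5.0) -> SensitivityReport:
    """One-at-a-time +/- ``n_sd`` SD sensitivity around the line's mean pig.

    Each perturbed pig is rebuilt (growth re-simulated / recalibrated) and
    pushed through the full LCA; reported values are percent changes of each
    impact category against the baseline mean pig.  Perturbations that are
    biologically infeasible are reported as failed cells rather than raised.
    """
    sds = default_oat_sds(spec) if trait_sds is None else trait_sds
    base_profile, base_traj, base_traits = mean_pig(spec, fx.diet, cfg=fx.config)
    base = pig_lca(base_traj, base_traits, fx).impacts.as_dict()

    baseline_values = {
        "adfi": base_traits.adfi, "adg": base_traits.adg, "fcr": base_traits.fcr,
        "bp": base_traits.bp, "pd": base_traits.mean_pd, "bl": base_traits.bl,
        "bp_bl": base_traits.bp_bl_ratio, "bft": base_traits.bft,
    }
    rows = []
    for trait in OAT_TRAITS:
        sd = sds.get(trait, 0.0)
        for direction, sign in (("+", 1.0), ("-", -1.0)):
            value = baseline_values[trait] + sign * n_sd * sd
            if value == baseline_values[trait]:
                # unperturbed cell: exactly zero by definition
                for c in CATEGORIES:
                    rows.append({"trait": trait, "direction": direction,
                                 "category": c, "value": value,
                                 "pct_change": 0.0, "sensitive": False,
                                 "failed": False})
                continue
            try:
                traj = _rebuild_perturbed(trait, value, base_profile,
                                          base_traits, fx, spec)
                traits = compute_traits(traj, fx.diet, pig_id="oat",
                                        line=spec.label, bft=base_traits.bft)
                impacts = pig_lca(traj, traits, fx).impacts.as_dict()
                for c in CATEGORIES:
                    pct = 100.0 * (impacts[c] - base[c]) / base[c]
                    rows.append({"trait": trait, "direction": direction,
                                 "category": c, "value": value,
                                 "pct_change": pct,
                                 "sensitive": abs(pct) > threshold_pct,
                                 "failed": False})
            except (GenerationError, GrowthError, PipelineError, ValueError) as err:
                for c in CATEGORIES:
                    rows.append({"trait": trait, "direction": direction,
                                 "category": c, "value": value,
                                 "pct_change": float("nan"),
                                 "sensitive": False, "failed": True,
                                 "error": str(err)})
    return SensitivityReport(table=pd.DataFrame(rows), threshold_pct=threshold_pct)


# ---------------------------------------------------------------------------
# parallel Monte Carlo
# ---------------------------------------------------------------------------

#: emission factors treated as certain (printed equivalencies, gas density)
_CERTAIN_EF = {"fert_equiv_n", "fert_equiv_p", "fert_equiv_k",
               "ch4_density_kg_per_m3"}


@dataclass(frozen=True)
class UncertaintySpec:
    """Log-normal geometric SDs (median 1) for background parameter groups."""

    gsd_emission_factors: float = 1.3
    gsd_feed_impacts: float = 1.2
    gsd_characterization: float = 1.1
    overrides: dict = field(default_factory=dict)   # name -> gsd

    def __post_init__(self):
        for g in (self.gsd_emission_factors, self.gsd_feed_impacts,
                  self.gsd_characterization, *self.overrides.values()):
            if g < 1.0:
                raise ValueError("geometric SD must be >= 1")

    def gsd_for(self, name, default: float) -> float:
        return self.overrides.get(name, default)


@dataclass
class MonteCarloReport:
    n_draws: int
    win_pct: dict              # category -> % of draws with LRFI < HRFI
    quantiles: pd.DataFrame    # per (line, category): 2.5/50/97.5 percentiles
    low_label: str = "LRFI"
    high_label: str = "HRFI"


def _lognormal(rng, gsd: float) -> float:
    if gsd <= 1.0:
        return 1.0
    return float(rng.lognormal(mean=0.0, sigma=math.log(gsd)))


def parallel_monte_carlo(specs: dict, fx: FixtureSet, n_draws: int = 1000,
                         seed: int = 0,
                         unc: UncertaintySpec | None = None,
                         low: str = "LRFI", high: str = "HRFI") -> MonteCarloReport:
    """Shared-draw Monte Carlo on both lines' mean pigs.

    Per draw, one sample of every uncertain background parameter (emission
    factors, per-ingredient feed impact factors, characterization factors)
    is applied to *both* lines, the LCAs are recomputed, and the draw is a
    win for the efficient line in a category when its impact is strictly
    lower.  Animal traits are not resampled: the uncertainty quantified here
    is that of the background model parameters.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    unc = UncertaintySpec() if unc is None else unc
    rng = np.random.default_rng(seed)

    pigs = {}
    for label in (low, high):
        if label not in specs:
            raise ValueError(f"missing line spec {label!r}")
        _, traj, traits = mean_pig(specs[label], fx.diet, cfg=fx.config)
        pigs[label] = (traj, traits)

    ef_names = [f.name for f in fields(EmissionFactorSet)
                if f.name not in _CERTAIN_EF]
    feed_cells = [(ing, c) for ing, row in fx.feed_impacts.factors.items()
                  for c in row]
    cf_cells = [(flow, c) for flow, row in fx.characterization.factors.items()
                for c in row]

    wins = dict.fromkeys(CATEGORIES, 0)
    samples = {label: {c: np.empty(n_draws) for c in CATEGORIES}
               for label in (low, high)}
    for i in range(n_draws):
        ef_mult = {n: _lognormal(rng, unc.gsd_for(n, unc.gsd_emission_factors))
                   for n in ef_names}
        feed_mult = {cell: _lognormal(rng, unc.gsd_for(cell, unc.gsd_feed_impacts))
                     for cell in feed_cells}
        cf_mult = {cell: _lognormal(rng, unc.gsd_for(cell, unc.gsd_characterization))
                   for cell in cf_cells}
        fx_draw = replace(
            fx,
            emission_factors=fx.emission_factors.scaled(ef_mult),
            feed_impacts=fx.feed_impacts.scaled(feed_mult),
            characterization=fx.characterization.scaled(cf_mult))
        vals = {}
        for label in (low, high):
            traj, traits = pigs[label]
            vals[label] = pig_lca(traj, traits, fx_draw).impacts.as_dict()
            for c in CATEGORIES:
                samples[label][c][i] = vals[label][c]
        for c in CATEGORIES:
            if vals[low][c] < vals[high][c]:
                wins[c] += 1

    win_pct = {c: 100.0 * wins[c] / n_draws for c in CATEGORIES}
    qrows = []
    for label in (low, high):
        for c in CATEGORIES:
            q = np.percentile(samples[label][c], [2.5, 50.0, 97.5])
            qrows.append({"line": label, "category": c,
                          "q2.5": q[0], "median": q[1], "q97.5": q[2]})
    return MonteCarloReport(n_draws=n_draws, win_pct=win_pct,
                            quantiles=pd.DataFrame(qrows),
                            low_label=low, high_label=high)
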