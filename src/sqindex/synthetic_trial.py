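"""Synthetic multi-site fertilization-trial generator.

Emulates a six-site randomized complete block wheat–maize trial: four
treatment arms (control, NPK, and 15% / 30% manure substitution of chemical
N), three replicates, three years, two seasons per year.  Each soil indicator
is generated multiplicatively around its site baseline:

    value = baseline * (1 + delta_site,treatment) * (1 + b_i * f_plot + eps)

where ``delta`` is a site-specific treatment effect drawn once per
(site, treatment) from a configured range, ``f_plot`` is a standard-normal
latent fertility factor shared by all indicators of a plot (creating the
cross-indicator correlation that drives redundancy pruning downstream), and
``eps`` is residual noise with coefficient of variation ``cv``.  A second
plot-level factor with loadings ``contrast_loadings`` models the compaction
axis of such trials — denser plots holding less exchangeable K — giving bulk
density and available K their own correlation structure independent of the
fertility cluster.

The treatment-effect draw shares one uniform quantile per (site, indicator)
across treatments, so the treatment ordering encoded in the effect ranges is
site-consistent — field trials of this kind report consistent orderings
across sites, not arm-by-arm reshuffles.

Grain yield follows the same scheme with its own baseline interval per crop
and a per-treatment residual cv (unfertilized plots are the least stable), so
that yield-stability indices respond to fertilization.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    BD_RANGE,
    PH_RANGE,
    SEASONS,
    SOIL_INDICATORS,
    TREATMENTS,
    SiteProfile,
    SoilSample,
    samples_to_frame,
)
from .reference import DEFAULT_SITES

__all__ = [
    "EffectConfig",
    "TrialDesign",
    "default_effects",
    "default_design",
    "generate_trial",
    "recover_effects",
]

logger = logging.getLogger(__name__)

#: Default RNG seed: the trial start month (October 2021).
DEFAULT_SEED = 20211001

_YIELD = "yield"


@dataclass(frozen=True)
class EffectConfig:
    """Treatment-effect ranges and noise structure for the generator.

    ``deltas[treatment][indicator] = (low, high)`` are relative changes versus
    the unfertilized control; an absent indicator means no effect.  The
    ``"yield"`` pseudo-indicator configures the grain-yield effect.
    """

    deltas: Mapping[str, Mapping[str, tuple[float, float]]]
    cv: float = 0.05
    latent_loadings: Mapping[str, float] = field(default_factory=dict)
    contrast_loadings: Mapping[str, float] = field(default_factory=dict)
    yield_cv: Mapping[str, float] = field(default_factory=dict)
    yield_baseline: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"wheat": (2.4, 2.5), "maize": (2.8, 3.2)}
    )

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for tr, table in self.deltas.items():
            for ind, (lo, hi) in table.items():
                if lo > hi:
                    raise ValueError(f"{tr}/{ind}: range low {lo} > high {hi}")
                if 1.0 + lo <= 0:
                    raise ValueError(f"{tr}/{ind}: 1 + delta must stay positive (low={lo})")
        for tr, cv in self.yield_cv.items():
            if cv < 0:
                raise ValueError(f"yield_cv[{tr}] must be >= 0")
        for season, (lo, hi) in self.yield_baseline.items():
            if not 0 < lo <= hi:
                raise ValueError(f"yield_baseline[{season}] must satisfy 0 < low <= high")

    def delta_range(self, treatment: str, indicator: str) -> tuple[float, float]:
        return tuple(self.deltas.get(treatment, {}).get(indicator, (0.0, 0.0)))

    def without_latent(self) -> "EffectConfig":
        """Copy with both latent plot factors switched off."""
        return replace(self, latent_loadings={}, contrast_loadings={})


@dataclass(frozen=True)
class TrialDesign:
    sites: Sequence[SiteProfile]
    treatments: Sequence[str] = TREATMENTS
    n_replicates: int = 3
    years: Sequence[int] = (2021, 2022, 2023)
    seasons: Sequence[str] = SEASONS
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.sites:
            raise ValueError("at least one site is required")
        if not self.treatments:
            raise ValueError("at least one treatment is required")
        unknown = [t for t in self.treatments if t not in TREATMENTS]
        if unknown:
            raise ValueError(f"unknown treatment(s): {unknown}")
        bad = [s for s in self.seasons if s not in SEASONS]
        if bad:
            raise ValueError(f"unknown season(s): {bad}")

    @property
    def n_samples(self) -> int:
        return (len(self.sites) * len(self.treatments) * self.n_replicates
                * len(self.years) * len(self.seasons))


def default_effects() -> EffectConfig:
    """Effect configuration anchored to the reported multi-site response ranges.

    Bulk density falls under manure substitution (up to -17.1% at 30%M) and
    organic matter rises most at 30%M; total N and P rise most under pure NPK;
    total K is unresponsive; available N/P/K respond more strongly than the
    totals; pH is stable.  Yield gains are large because the unfertilized
    control is severely nutrient-limited.
    """
    deltas = {
        "control": {},
        "NPK": {
            "bd": (-0.020, 0.000),
            "som": (0.015, 0.137),
            "tn": (0.120, 0.237),
            "tp": (0.120, 0.237),
            "an": (0.050, 0.200),
            "ap": (0.050, 0.150),
            "ak": (0.004, 0.100),
            _YIELD: (0.50, 1.20),
        },
        "15%M": {
            "bd": (-0.063, -0.015),
            "som": (0.046, 0.175),
            "tn": (0.090, 0.180),
            "tp": (0.090, 0.180),
            "an": (0.077, 0.350),
            "ap": (0.071, 0.300),
            "ak": (0.050, 0.250),
            _YIELD: (0.70, 1.80),
        },
        "30%M": {
            "bd": (-0.171, -0.013),
            "som": (0.046, 0.225),
            "tn": (0.061, 0.150),
            "tp": (0.061, 0.150),
            "an": (0.100, 0.425),
            "ap": (0.150, 0.459),
            "ak": (0.100, 0.332),
            _YIELD: (0.90, 2.50),
        },
    }
    return EffectConfig(
        deltas=deltas,
        cv=0.05,
        # organic matter carries the fertility factor most strongly; N and P
        # pools follow it (the fertility cluster seen in field data)
        latent_loadings={"som": 0.15, "ap": 0.12, "tn": 0.10, "an": 0.10, _YIELD: 0.08},
        # compaction axis: denser plots hold less exchangeable K
        contrast_loadings={"bd": 0.09, "ak": -0.09},
        yield_cv={"control": 0.10, "NPK": 0.07, "15%M": 0.07, "30%M": 0.05},
    )


def default_design(seed: int = DEFAULT_SEED, **overrides) -> TrialDesign:
    """The full six-site, four-treatment, three-replicate, three-year design."""
    return TrialDesign(sites=DEFAULT_SITES, seed=seed, **overrides)


def _realize_deltas(design: TrialDesign, effects: EffectConfig,
                    rng: np.random.Generator) -> dict:
    """Draw site-specific treatment deltas, one shared quantile per (site, indicator)."""
    indicators = (*SOIL_INDICATORS, _YIELD)
    deltas: dict[tuple, float] = {}
    for site in design.sites:
        for ind in indicators:
            u = rng.uniform()
            for tr in design.treatments:
                lo, hi = effects.delta_range(tr, ind)
                deltas[(site.site_id, tr, ind)] = lo + u * (hi - lo)
    return deltas


def generate_trial(design: TrialDesign, effects: EffectConfig,
                   *, with_truth: bool = False):
    """Generate one full trial dataset.

    Returns the list of :class:`SoilSample`; with ``with_truth=True`` also
    returns a tidy DataFrame of the realized (site, treatment, indicator)
    deltas, for parameter-recovery validation.  Identical design + effects +
    seed give bit-identical output.  Out-of-range draws are clipped into the
    valid domain; the clip count is logged.
    """
    rng = np.random.default_rng(design.seed)
    deltas = _realize_deltas(design, effects, rng)

    yield_base = {
        (site.site_id, season): rng.uniform(*effects.yield_baseline[season])
        for site in design.sites for season in design.seasons
    }
    f_plot = {}
    g_plot = {}
    for site in design.sites:
        for tr in design.treatments:
            for rep in range(1, design.n_replicates + 1):
                f_plot[(site.site_id, tr, rep)] = rng.standard_normal()
                g_plot[(site.site_id, tr, rep)] = rng.standard_normal()

    b = {ind: float(effects.latent_loadings.get(ind, 0.0))
         for ind in (*SOIL_INDICATORS, _YIELD)}
    c = {ind: float(effects.contrast_loadings.get(ind, 0.0))
         for ind in (*SOIL_INDICATORS, _YIELD)}
    n_clipped = 0
    samples: list[SoilSample] = []
    for site in design.sites:
        base = site.baselines
        for tr in design.treatments:
            for rep in range(1, design.n_replicates + 1):
                f = f_plot[(site.site_id, tr, rep)]
                g = g_plot[(site.site_id, tr, rep)]
                for year in design.years:
                    for season in design.seasons:
                        eps = rng.normal(0.0, effects.cv, size=len(SOIL_INDICATORS))
                        values = {}
                        for j, ind in enumerate(SOIL_INDICATORS):
                            d = deltas[(site.site_id, tr, ind)]
                            noise = 1.0 + b[ind] * f + c[ind] * g + eps[j]
                            v = base[ind] * (1.0 + d) * max(noise, 1e-6)
                            values[ind] = v
                        clipped = _clip_values(values)
                        n_clipped += clipped
                        ycv = effects.yield_cv.get(tr, effects.cv)
                        ynoise = 1.0 + b[_YIELD] * f + rng.normal(0.0, ycv)
                        y = (yield_base[(site.site_id, season)]
                             * (1.0 + deltas[(site.site_id, tr, _YIELD)])
                             * max(ynoise, 1e-6))
                        samples.append(SoilSample(
                            site_id=site.site_id, year=year, season=season,
                            treatment=tr, replicate=rep,
                            yield_mg_ha=y, **values,
                        ))
    if n_clipped:
        logger.info("generate_trial: clipped %d out-of-range values", n_clipped)
    if with_truth:
        truth = pd.DataFrame(
            [{"site_id": s, "treatment": t, "indicator": i, "delta": d}
             for (s, t, i), d in deltas.items()]
        )
        return samples, truth
    return samples


def _clip_values(values: dict) -> int:
    """Clip indicator values into their valid domain in place; return clip count."""
    n = 0
    margin = 1e-3
    for name, (lo, hi) in (("bd", BD_RANGE), ("ph", PH_RANGE)):
        v = values[name]
        c = min(max(v, lo + margin), hi - margin)
        if c != v:
            values[name] = c
            n += 1
    # available pools cannot exceed totals (mg/kg vs g/kg)
    for avail, total in (("an", "tn"), ("ap", "tp"), ("ak", "tk")):
        cap = values[total] * 1000.0
        if values[avail] > cap:
            values[avail] = cap
            n += 1
    return n


def recover_effects(samples, *, include_yield: bool = True) -> pd.DataFrame:
    """Estimate per site x season x indicator treatment deltas from data.

    ``delta_hat = mean(treatment) / mean(control) - 1`` within each cell.
    Requires a control arm; raises ``ValueError`` without one.
    """
    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    if "control" not in set(df["treatment"]):
        raise ValueError("recover_effects requires a control arm")
    indicators = list(SOIL_INDICATORS)
    if include_yield and df["yield_mg_ha"].notna().all():
        df = df.rename(columns={"yield_mg_ha": _YIELD})
        indicators.append(_YIELD)
    means = df.groupby(["site_id", "season", "treatment"], sort=False)[indicators].mean()
    rows = []
    for (site, season), cell in means.groupby(level=["site_id", "season"], sort=False):
        cell = cell.droplevel(["site_id", "season"])
        control = cell.loc["control"]
        for tr in cell.index:
            for ind in indicators:
                rows.append({
                    "site_id": site, "season": season, "treatment": tr,
                    "indicator": ind,
                    "delta_hat": cell.loc[tr, ind] / control[ind] - 1.0,
                })
    return pd.DataFrame(rows)
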