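"""Sustainability yield index and treatment percent-change summaries.

The sustainability yield index SYI = (mean - sd) / max summarizes how stable
and close to its observed ceiling a group of yields is: 1 for perfectly
constant yields, lower for variable or under-performing groups.  The sample
(n-1) standard deviation is used throughout.

Percent-change summaries report each treatment arm's group-mean change versus
a baseline arm (control or NPK) per site, plus the min-max range across sites
— the way multi-site trials report treatment effects.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import samples_to_frame

__all__ = [
    "SYIResult",
    "EffectSummary",
    "syi",
    "syi_table",
    "percent_change",
    "effect_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SYIResult:
    mean_yield: float
    sd_yield: float
    max_yield: float
    syi: float
    key: Optional[tuple] = None


@dataclass(frozen=True)
class EffectSummary:
    indicator: str
    treatment: str
    baseline: str
    per_site: dict          # site_id -> percent change of group means
    range: tuple            # (min, max) across sites


def syi(yields: Sequence[float], key: Optional[tuple] = None) -> SYIResult:
    """SYI = (mean - sd) / max for a group of at least two yields."""
    y = np.asarray(list(yields), dtype=float)
    if y.size < 2:
        raise ValueError(f"need at least 2 yield values, got {y.size}")
    y_max = float(y.max())
    if y_max <= 0:
        raise ValueError("maximum yield must be positive")
    mean = float(y.mean())
    sd = float(y.std(ddof=1))
    return SYIResult(mean_yield=mean, sd_yield=sd, max_yield=y_max,
                     syi=(mean - sd) / y_max, key=key)


def syi_table(samples, grouping: str = "within_year_reps") -> pd.DataFrame:
    """One SYI per site x treatment x season cell.

    ``within_year_reps`` pools replicates within each year (one value per
    year); ``across_years`` pools all years and replicates of a cell, the
    across-season reading of the formula.  Cells with fewer than two yield
    observations are skipped with a warning.
    """
    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    if grouping == "within_year_reps":
        keys = ["site_id", "treatment", "season", "year"]
    elif grouping == "across_years":
        keys = ["site_id", "treatment", "season"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for gkey, block in df.groupby(keys, sort=False):
        y = block["yield_mg_ha"].dropna()
        if len(y) < 2:
            logger.warning("syi_table: skipping cell %s with %d yield value(s)",
                           gkey, len(y))
            continue
        res = syi(y, key=gkey)
        rows.append({**dict(zip(keys, gkey)),
                     "mean_yield": res.mean_yield, "sd_yield": res.sd_yield,
                     "max_yield": res.max_yield, "syi": res.syi})
    return pd.DataFrame(rows, columns=[*keys, "mean_yield", "sd_yield",
                                       "max_yield", "syi"])


def percent_change(value_t: float, value_baseline: float) -> float:
    """Relative change of ``value_t`` versus a positive baseline, in percent."""
    if value_baseline <= 0:
        raise ValueError(f"baseline must be positive, got {value_baseline}")
    return (value_t - value_baseline) / value_baseline * 100.0


def effect_summary(data, indicator: str, treatment: str,
                   baseline: str = "control") -> EffectSummary:
    """Per-site percent change of group means, with the cross-site range.

    ``data`` is a sample table (or any table with ``site_id``, ``treatment``
    and the indicator column, e.g. an SQI group table).  Sites missing either
    arm are skipped with a warning.
    """
    df = data if isinstance(data, pd.DataFrame) else samples_to_frame(data)
    if indicator not in df.columns:
        raise ValueError(f"column {indicator!r} not present")
    per_site: dict[str, float] = {}
    for site, block in df.groupby("site_id", sort=False):
        arms = block.groupby("treatment")[indicator].mean()
        if baseline not in arms.index or treatment not in arms.index:
            logger.warning("effect_summary: site %s missing arm (%s or %s); skipped",
                           site, baseline, treatment)
            continue
        per_site[site] = percent_change(arms[treatment], arms[baseline])
    if not per_site:
        raise ValueError(f"baseline arm {baseline!r} present at no site")
    values = list(per_site.values())
    return EffectSummary(indicator=indicator, treatment=treatment,
                         baseline=baseline, per_site=per_site,
                         range=(min(values), max(values)))
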