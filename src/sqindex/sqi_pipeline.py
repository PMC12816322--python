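"""Minimum-data-set Soil Quality Index pipeline.

The SQI condenses a panel of soil indicators into one number per sample:

1. standardize indicators (z-scores, n-1 sd) and form their Pearson
   correlation matrix;
2. eigendecompose the correlation matrix (correlation PCA); loadings are
   eigenvector * sqrt(eigenvalue);
3. retain components with eigenvalue > 1 (Kaiser rule);
4. per retained component, indicators with |loading| >= 0.5 and within 10% of
   that component's maximum |loading| are candidates;
5. within each component's candidate set, while any pair correlates beyond
   |r| > 0.6, the lower-weight member is dropped (redundancy pruning); the
   union of survivors is the minimum data set (MDS);
6. indicator weights come from the PCA — by default proportional to the
   eigenvalue-weighted communality (sum over retained components of
   variance-share * squared loading), normalized to sum to 1;
7. each MDS indicator is scored to [0, 1] by a min-max transform, increasing
   ("more is better") or decreasing ("less is better");
8. SQI = sum of weight * score, in [0, 1].

Every pruning decision is recorded in an audit log on the selection object,
because the redundancy step is the least self-explanatory part of the method.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import SOIL_INDICATORS

__all__ = [
    "DEFAULT_DIRECTIONS",
    "MORE_IS_BETTER",
    "LESS_IS_BETTER",
    "PCAResult",
    "MDSSelection",
    "ScoreConfig",
    "SQIResult",
    "PipelineResult",
    "zscore_matrix",
    "correlation_matrix",
    "pca_correlation",
    "retain_components",
    "candidate_indicators",
    "indicator_weights",
    "prune_redundant",
    "score_indicator",
    "compute_sqi",
    "sqi_from_samples",
]

logger = logging.getLogger(__name__)

MORE_IS_BETTER = "more_is_better"
LESS_IS_BETTER = "less_is_better"

#: Default scoring directions: compaction and (acid-to-neutral context) pH are
#: scored decreasing, fertility stocks and available pools increasing.
DEFAULT_DIRECTIONS = {
    "bd": LESS_IS_BETTER,
    "ph": LESS_IS_BETTER,
    "som": MORE_IS_BETTER,
    "tn": MORE_IS_BETTER,
    "tp": MORE_IS_BETTER,
    "tk": MORE_IS_BETTER,
    "an": MORE_IS_BETTER,
    "ap": MORE_IS_BETTER,
    "ak": MORE_IS_BETTER,
}

NORMALIZATION_SCOPES = ("global", "per_site_season", "per_season_year")

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of a standardized-indicator correlation matrix.

    ``loadings`` is indicators x components, on the correlation scale
    (column squared norms equal the eigenvalues).
    """

    indicators: tuple[str, ...]
    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame


@dataclass
class MDSSelection:
    """Outcome of candidate selection and redundancy pruning."""

    candidates: dict[int, list[str]]
    mds: list[str]
    weights: pd.Series           # over the MDS, sums to 1
    audit: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ScoreConfig:
    directions: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    normalization_scope: str = "global"

    def __post_init__(self) -> None:
        if self.normalization_scope not in NORMALIZATION_SCOPES:
            raise ValueError(
                f"normalization_scope={self.normalization_scope!r} "
                f"not in {NORMALIZATION_SCOPES}"
            )
        bad = {k: v for k, v in self.directions.items()
               if v not in (MORE_IS_BETTER, LESS_IS_BETTER)}
        if bad:
            raise ValueError(f"invalid scoring direction(s): {bad}")


@dataclass(frozen=True)
class SQIResult:
    scores: pd.DataFrame         # per-sample indicator scores S_i in [0, 1]
    sqi: pd.Series               # per-sample weighted index
    group_means: pd.DataFrame    # by site x treatment x year x season


@dataclass(frozen=True)
class PipelineResult:
    pca: PCAResult
    retained: list[int]
    selection: MDSSelection
    sqi: SQIResult


def zscore_matrix(data: pd.DataFrame, indicators: Sequence[str]):
    """Standardize each indicator column to mean 0, sd 1 (n-1 denominator).

    Returns ``(Z, means, sds)``.  Raises on fewer than 3 rows or on any
    zero-variance indicator (named in the message).
    """
    if len(data) < 3:
        raise ValueError(f"need at least 3 samples, got {len(data)}")
    X = data[list(indicators)].astype(float)
    means = X.mean()
    sds = X.std(ddof=1)
    dead = sds.index[sds == 0.0].tolist()
    if dead:
        raise ValueError(f"zero-variance indicator(s): {', '.join(dead)}")
    Z = (X - means) / sds
    return Z, means, sds


def correlation_matrix(Z: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of a (standardized) indicator matrix."""
    if len(Z) < 2:
        raise ValueError("need at least 2 rows to correlate")
    if len(Z) <= Z.shape[1]:
        warnings.warn(
            f"n={len(Z)} <= p={Z.shape[1]}: correlation matrix is singular",
            stacklevel=2,
        )
    R = Z.corr()
    return R.clip(-1.0, 1.0)


def pca_correlation(R: pd.DataFrame) -> PCAResult:
    """Correlation PCA: eigenvalues, variance percentages, loadings.

    ``R`` is symmetrized to (R + R^T)/2 first.  Eigenvalues below -1e-10 are
    an error (not a correlation matrix); tiny negatives are clipped to 0.
    Loading columns are sign-fixed so their largest-magnitude element is
    positive.  Variance percentages are eigenvalue / p * 100.
    """
    names = tuple(R.index)
    A = np.asarray(R, dtype=float)
    A = (A + A.T) / 2.0
    evals, evecs = np.linalg.eigh(A)
    if evals.min() < -_PSD_TOL:
        raise ValueError(
            f"matrix is not positive semi-definite (min eigenvalue {evals.min():.3e})"
        )
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    loadings = evecs * np.sqrt(evals)
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if np.abs(col).max() > 0 and col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    p = len(names)
    variance_pct = evals / p * 100.0
    return PCAResult(
        indicators=names,
        eigenvalues=evals,
        variance_pct=variance_pct,
        cumulative_pct=np.cumsum(variance_pct),
        loadings=pd.DataFrame(loadings, index=list(names), columns=range(p)),
    )


def retain_components(eigenvalues: np.ndarray, threshold: float = 1.0) -> list[int]:
    """Indices of components with eigenvalue strictly above ``threshold``."""
    retained = [k for k, ev in enumerate(eigenvalues) if ev > threshold]
    if not retained:
        warnings.warn("no component exceeds the eigenvalue threshold", stacklevel=2)
    return retained


def candidate_indicators(loadings: pd.DataFrame, retained: Sequence[int],
                         min_loading: float = 0.5,
                         within_frac: float = 0.10) -> dict[int, list[str]]:
    """Per-component candidate sets for the MDS.

    For each retained component, an indicator qualifies when its absolute
    loading is at least ``min_loading`` *and* within ``within_frac`` of that
    component's maximum absolute loading.  Candidacy is assessed over all
    indicators per component, so one indicator may be a candidate on several
    components.
    """
    if not retained:
        raise ValueError("retained component list is empty")
    out: dict[int, list[str]] = {}
    for k in retained:
        col = loadings[k].abs()
        cutoff = (1.0 - within_frac) * col.max()
        out[k] = [ind for ind in loadings.index
                  if col[ind] >= min_loading and col[ind] >= cutoff]
    return out


def indicator_weights(loadings: pd.DataFrame, eigenvalues: np.ndarray,
                      retained: Sequence[int],
                      indicators: Optional[Sequence[str]] = None,
                      mode: str = "communality") -> pd.Series:
    """PCA-derived indicator weights, normalized to sum to 1.

    ``communality`` (default): raw weight is the sum over retained components
    of (eigenvalue share among retained) * squared loading — proportional to
    the eigenvalue-weighted communality, hence non-negative.  ``as_printed``
    instead sums (eigenvalue / total eigenvalue sum) * |loading|, the published
    formula taken at absolute value.
    """
    if indicators is None:
        indicators = list(loadings.index)
    if not retained:
        raise ValueError("retained component list is empty")
    ev = np.asarray(eigenvalues, dtype=float)
    if mode == "communality":
        shares = {k: ev[k] / ev[list(retained)].sum() for k in retained}
        raw = sum(shares[k] * loadings[k] ** 2 for k in retained)
    elif mode == "as_printed":
        shares = {k: ev[k] / ev.sum() for k in retained}
        raw = sum(shares[k] * loadings[k].abs() for k in retained)
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    raw = raw.loc[list(indicators)]
    total = raw.sum()
    if total <= 0:
        raise ValueError("all raw weights are zero")
    return raw / total


def prune_redundant(candidates: Mapping[int, Sequence[str]], R: pd.DataFrame,
                    weights: pd.Series, loadings: Optional[pd.DataFrame] = None,
                    r_threshold: float = 0.6) -> MDSSelection:
    """Drop redundant candidates and assemble the minimum data set.

    Within each component's candidate set, while any pair has |r| above
    ``r_threshold``, the lower-weight member is dropped.  Weight ties break by
    larger |loading| on that component (when loadings are supplied), then by
    input order.  Survivors from all components are unioned; final weights are
    renormalized over the MDS.
    """
    audit: list[str] = []
    mds: list[str] = []
    for k, cands in candidates.items():
        cands = list(cands)

        def rank(ind: str) -> tuple:
            load = abs(loadings.loc[ind, k]) if loadings is not None else 0.0
            return (-weights[ind], -load, cands.index(ind))

        kept: list[str] = []
        for ind in sorted(cands, key=rank):
            clash = [o for o in kept if abs(R.loc[ind, o]) > r_threshold]
            if clash:
                audit.append(
                    f"component {k}: dropped {ind} (weight {weights[ind]:.4f}) — "
                    f"|r| > {r_threshold} with " +
                    ", ".join(f"{o} (r={R.loc[ind, o]:+.2f})" for o in clash)
                )
            else:
                kept.append(ind)
                audit.append(f"component {k}: kept {ind} (weight {weights[ind]:.4f})")
        for ind in kept:
            if ind not in mds:
                mds.append(ind)
    if not mds:
        raise ValueError("pruning produced an empty minimum data set")
    w = weights.loc[mds]
    w = w / w.sum()
    for line in audit:
        logger.info("MDS pruning | %s", line)
    return MDSSelection(candidates={k: list(v) for k, v in candidates.items()},
                        mds=mds, weights=w, audit=audit)


def score_indicator(x, x_min: float, x_max: float, direction: str):
    """Min-max score in [0, 1]; decreasing indicators score 1 at the minimum."""
    if x_max <= x_min:
        raise ValueError(f"degenerate score range [{x_min}, {x_max}]")
    if direction not in (MORE_IS_BETTER, LESS_IS_BETTER):
        raise ValueError(f"unknown direction {direction!r}")
    s = (np.clip(x, x_min, x_max) - x_min) / (x_max - x_min)
    return 1.0 - s if direction == LESS_IS_BETTER else s


_SCOPE_KEYS = {
    "global": None,
    "per_site_season": ["site_id", "season"],
    "per_season_year": ["season", "year"],
}


def compute_sqi(data: pd.DataFrame, selection: MDSSelection,
                score_config: ScoreConfig = ScoreConfig()) -> SQIResult:
    """Score the MDS indicators and form the weighted index per sample.

    Min/max for the scoring transform are taken within the configured
    normalization scope (whole dataset by default).  Group means are reported
    by site x treatment x year x season.
    """
    missing = [i for i in selection.mds if i not in data.columns]
    if missing:
        raise ValueError(f"MDS indicator(s) absent from data: {', '.join(missing)}")
    nodir = [i for i in selection.mds if i not in score_config.directions]
    if nodir:
        raise ValueError(f"no scoring direction for: {', '.join(nodir)}")

    scores = pd.DataFrame(index=data.index, columns=list(selection.mds), dtype=float)
    keys = _SCOPE_KEYS[score_config.normalization_scope]
    groups = [(None, data)] if keys is None else data.groupby(keys, sort=False)
    for gname, block in groups:
        for ind in selection.mds:
            lo, hi = block[ind].min(), block[ind].max()
            if hi <= lo:
                raise ValueError(
                    f"degenerate range for {ind!r} within scope {gname!r}")
            scores.loc[block.index, ind] = score_indicator(
                block[ind].to_numpy(), lo, hi, score_config.directions[ind])
    sqi = scores.mul(selection.weights, axis=1).sum(axis=1).rename("sqi")
    grouped = (
        data[["site_id", "treatment", "year", "season"]]
        .assign(sqi=sqi)
        .groupby(["site_id", "treatment", "year", "season"], sort=False)["sqi"]
        .mean()
        .reset_index()
    )
    return SQIResult(scores=scores, sqi=sqi, group_means=grouped)


def sqi_from_samples(data: pd.DataFrame, *,
                     indicators: Sequence[str] = SOIL_INDICATORS,
                     eigenvalue_threshold: float = 1.0,
                     min_loading: float = 0.5,
                     within_frac: float = 0.10,
                     r_threshold: float = 0.6,
                     weight_mode: str = "communality",
                     score_config: ScoreConfig = ScoreConfig()) -> PipelineResult:
    """End-to-end SQI: standardize, PCA, select, prune, weight, score."""
    Z, _, _ = zscore_matrix(data, indicators)
    R = correlation_matrix(Z)
    pca = pca_correlation(R)
    retained = retain_components(pca.eigenvalues, eigenvalue_threshold)
    cands = candidate_indicators(pca.loadings, retained, min_loading, within_frac)
    weights = indicator_weights(pca.loadings, pca.eigenvalues, retained, mode=weight_mode)
    selection = prune_redundant(cands, R, weights, pca.loadings, r_threshold)
    sqi = compute_sqi(data, selection, score_config)
    return PipelineResult(pca=pca, retained=retained, selection=selection, sqi=sqi)
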