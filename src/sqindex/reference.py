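"""Preset study parameters: site baselines, fertilizer treatments, and a
worked-example PCA loading matrix.

The presets describe a six-site wheat–maize rotation network on Vertisols
(Shajiang Black Soil, southern North China Plain): four treatment arms
(unfertilized control, full chemical NPK, and NPK with 15% / 30% of its
nitrogen replaced by composted pig manure at nitrogen equivalence), a
randomized complete block with three replicates, run over three years and two
seasons per year.

Baseline total N/P/K are not part of the published initial-property table;
they are derived here from each site's baseline organic matter and its
unfertilized-control molar C:N / C:P / C:K ratios, which keeps generated data
stoichiometrically realistic and consistent with the available<=total
invariant.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import SiteProfile, TreatmentSpec, chemical_n_rate
from .stoichiometry import MOLAR_MASS

__all__ = [
    "DEFAULT_SITES",
    "DEFAULT_TREATMENT_SPECS",
    "MANURE_COMPOSITION",
    "EXAMPLE_INDICATORS",
    "EXAMPLE_LOADINGS",
    "EXAMPLE_EIGENVALUES",
    "EXAMPLE_VARIANCE_PCT",
    "EXAMPLE_MDS",
    "example_redundancy_correlations",
]

# site_id -> (lat, lon, elev m, MAT degC, MAP mm, ph, som, bd, an, ap, ak,
#             sand %, silt %, clay %)
_SITE_TABLE = {
    "FN": (33.750, 116.567, 20.0, 15.2, 985.2, 5.70, 18.3, 1.26, 63.26, 30.55, 140.78, 18.5, 45.4, 36.1),
    "YX": (33.350, 117.133, 29.0, 15.2, 823.9, 5.07, 23.6, 1.25, 106.67, 42.97, 117.76, 54.7, 15.9, 29.4),
    "KT": (33.450, 116.883, 27.0, 14.9, 826.0, 5.20, 16.3, 1.31, 83.51, 23.61, 116.17, 52.1, 16.3, 31.6),
    "GY": (33.900, 117.400, 29.5, 15.1, 851.6, 5.60, 21.8, 1.35, 111.35, 40.68, 108.19, 10.4, 56.8, 32.8),
    "MC": (32.667, 115.700, 21.0, 16.5, 872.0, 7.50, 19.4, 1.34, 119.33, 34.23, 100.06, 8.2, 54.1, 37.7),
    "WH": (34.017, 118.450, 16.0, 15.7, 896.0, 7.40, 19.2, 1.29, 78.80, 18.21, 99.66, 64.7, 18.9, 16.4),
}

# Unfertilized-control molar C:N, C:P, C:K per site (wheat season), used to
# back out baseline total N/P/K from baseline SOM.
_CONTROL_RATIOS = {
    "FN": (10.8, 17.9, 0.74),
    "YX": (11.0, 26.8, 0.92),
    "KT": (9.81, 20.2, 0.47),
    "GY": (9.50, 20.1, 0.88),
    "MC": (8.98, 17.2, 1.10),
    "WH": (10.7, 26.8, 0.95),
}

_VAN_BEMMELEN = 1.724


def _totals_from_som(som: float, cn: float, cp: float, ck: float) -> tuple[float, float, float]:
    soc = som / _VAN_BEMMELEN
    moles_c = soc / MOLAR_MASS["C"]
    tn = moles_c / cn * MOLAR_MASS["N"]
    tp = moles_c / cp * MOLAR_MASS["P"]
    tk = moles_c / ck * MOLAR_MASS["K"]
    return tn, tp, tk


def _build_sites() -> tuple[SiteProfile, ...]:
    sites = []
    for sid, (lat, lon, elev, mat, mapmm, ph, som, bd, an, ap, ak, sa, si, cl) in _SITE_TABLE.items():
        tn, tp, tk = _totals_from_som(som, *_CONTROL_RATIOS[sid])
        sites.append(SiteProfile(
            site_id=sid, latitude=lat, longitude=lon, elevation_m=elev,
            mat_c=mat, map_mm=mapmm, ph=ph, som=som, bd=bd,
            an=an, ap=ap, ak=ak, tn=tn, tp=tp, tk=tk,
            sand_pct=sa, silt_pct=si, clay_pct=cl,
        ))
    return tuple(sites)


DEFAULT_SITES: tuple[SiteProfile, ...] = _build_sites()

#: Composted pig manure composition by year: organic C and total N mass fractions.
MANURE_COMPOSITION = {
    2021: {"oc_frac": 0.199, "tn_frac": 0.014},
    2022: {"oc_frac": 0.239, "tn_frac": 0.021},
    2023: {"oc_frac": 0.211, "tn_frac": 0.017},
}

_MEAN_OC = sum(v["oc_frac"] for v in MANURE_COMPOSITION.values()) / 3
_MEAN_TN = sum(v["tn_frac"] for v in MANURE_COMPOSITION.values()) / 3

_FULL_N = 225.0

# name -> (f, manure kg/ha, wheat (P2O5, K2O), maize (P2O5, K2O))
_TREATMENT_TABLE = {
    "control": (0.00, 0.0, (0.0, 0.0), (0.0, 0.0)),
    "NPK":     (0.00, 0.0, (90.0, 75.0), (75.0, 90.0)),
    "15%M":    (0.15, 1950.0, (52.0, 42.0), (42.0, 52.0)),
    "30%M":    (0.30, 3900.0, (25.0, 20.0), (20.0, 25.0)),
}


def _build_treatments() -> dict:
    specs: dict[str, dict[str, TreatmentSpec]] = {}
    for name, (f, manure, wheat_pk, maize_pk) in _TREATMENT_TABLE.items():
        full_n = 0.0 if name == "control" else _FULL_N
        chem_n = 0 if name == "control" else chemical_n_rate(full_n, f)
        specs[name] = {}
        for season, (p2o5, k2o) in (("wheat", wheat_pk), ("maize", maize_pk)):
            specs[name][season] = TreatmentSpec(
                name=name, substitution_fraction=f, full_chemical_n=full_n,
                chemical_n=chem_n, p2o5=p2o5, k2o=k2o, manure_rate=manure,
                manure_oc_frac=_MEAN_OC if manure else 0.0,
                manure_tn_frac=_MEAN_TN if manure else 0.0,
            )
    return specs


#: treatment name -> season -> TreatmentSpec
DEFAULT_TREATMENT_SPECS = _build_treatments()


# ---------------------------------------------------------------------------
# Worked example: loading matrix of a pooled correlation PCA over the nine
# indicators, with five components of eigenvalue > 1.  Used as a frozen
# end-to-end fixture for minimum-data-set selection.

EXAMPLE_INDICATORS = ("som", "ap", "tn", "an", "ph", "bd", "tp", "ak", "tk")

EXAMPLE_LOADINGS = pd.DataFrame(
    np.array([
        # PC1     PC2     PC3     PC4     PC5
        [0.841, -0.020,  0.208, -0.240,  0.431],   # som
        [0.817, -0.165,  0.133,  0.320, -0.170],   # ap
        [0.803,  0.252,  0.273, -0.017,  0.240],   # tn
        [0.707,  0.461,  0.278, -0.200, -0.262],   # an
        [-0.424, 0.828, -0.018, -0.113,  0.201],   # ph
        [-0.243, -0.297, 0.754,  0.167,  0.086],   # bd
        [0.456,  0.375, -0.190,  0.711, -0.139],   # tp
        [0.266, -0.461, -0.661,  0.241,  0.658],   # ak
        [0.336, -0.808,  0.041, -0.288, -0.194],   # tk
    ]),
    index=list(EXAMPLE_INDICATORS),
    columns=[0, 1, 2, 3, 4],
)

EXAMPLE_EIGENVALUES = np.array([3.391, 2.137, 1.579, 1.075, 1.074])

#: Printed per-component variance percentages (their sum is the cumulative
#: variance explained by the five retained components, 92.55%).
EXAMPLE_VARIANCE_PCT = np.array([33.912, 21.367, 15.789, 10.746, 10.738])

#: The five-indicator minimum data set the worked example resolves to.
EXAMPLE_MDS = frozenset({"som", "ph", "bd", "tp", "ak"})


def example_redundancy_correlations() -> pd.DataFrame:
    """Indicator correlation matrix encoding the worked example's redundancies.

    The pairs that exceed the |r| > 0.6 pruning threshold are SOM–AP, SOM–TN,
    AP–TN (the organic-fertility cluster) and pH–TK; all other pairs sit below
    threshold.
    """
    names = list(EXAMPLE_INDICATORS)
    R = pd.DataFrame(0.30, index=names, columns=names)
    np.fill_diagonal(R.values, 1.0)
    strong = {("som", "ap"): 0.84, ("som", "tn"): 0.89, ("ap", "tn"): 0.72,
              ("ph", "tk"): -0.81}
    for (a, b), r in strong.items():
        R.loc[a, b] = r
        R.loc[b, a] = r
    return R
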