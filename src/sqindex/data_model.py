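"""Domain types, validation, and delimited-table I/O for fertilization-trial data.

The central record is :class:`SoilSample` — one plot-season observation from a
wheat–maize rotation trial: nine topsoil indicators (bulk density, pH, organic
matter, total and available N/P/K) plus grain yield.  Collections of samples
are exchanged as UTF-8 comma-delimited tables with a fixed header; all
validation happens at construction time so that downstream analysis modules
can assume clean inputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "SEASONS",
    "TREATMENTS",
    "SOIL_INDICATORS",
    "CSV_COLUMNS",
    "KEY_COLUMNS",
    "SchemaError",
    "RowError",
    "DuplicateKeyError",
    "SoilSample",
    "SiteProfile",
    "TreatmentSpec",
    "chemical_n_rate",
    "read_samples",
    "write_samples",
    "samples_to_frame",
    "frame_to_samples",
]

SEASONS = ("wheat", "maize")
TREATMENTS = ("control", "NPK", "15%M", "30%M")

#: The nine soil-quality indicators, in canonical column order.
#: bd g cm^-3; ph unitless; som/tn/tp/tk g kg^-1; an/ap/ak mg kg^-1.
SOIL_INDICATORS = ("bd", "ph", "som", "tn", "tp", "tk", "an", "ap", "ak")

CSV_COLUMNS = (
    "site_id", "year", "season", "treatment", "replicate",
    *SOIL_INDICATORS, "yield_mg_ha",
)
KEY_COLUMNS = ("site_id", "year", "season", "treatment", "replicate")

#: Physically plausible (open) ranges enforced at validation time.
BD_RANGE = (0.5, 2.2)
PH_RANGE = (3.0, 10.0)

# slack for the available<=total check, in g kg^-1, to tolerate rounding
_AVAIL_EPS = 1e-9


class SchemaError(ValueError):
    """A table is missing required columns or is not parseable at all."""


class RowError(ValueError):
    """A single row failed validation; carries the zero-based row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class DuplicateKeyError(ValueError):
    """Two rows share the same (site, year, season, treatment, replicate) key."""


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo < value < hi):
        raise ValueError(f"{name}={value!r} outside ({lo}, {hi})")


def _check_finite(name: str, value: float) -> None:
    if value is None or not math.isfinite(value):
        raise ValueError(f"{name} is missing or non-finite ({value!r})")


@dataclass(frozen=True)
class SoilSample:
    """One plot-season observation.

    Units: ``bd`` g cm^-3, ``ph`` unitless, ``som``/``tn``/``tp``/``tk``
    g kg^-1, ``an``/``ap``/``ak`` mg kg^-1, ``yield_mg_ha`` Mg ha^-1
    (optional — soil-only datasets are allowed).
    """

    site_id: str
    year: int
    season: str
    treatment: str
    replicate: int
    bd: float
    ph: float
    som: float
    tn: float
    tp: float
    tk: float
    an: float
    ap: float
    ak: float
    yield_mg_ha: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be non-empty")
        if self.season not in SEASONS:
            raise ValueError(f"season={self.season!r} not in {SEASONS}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment={self.treatment!r} not in {TREATMENTS}")
        if int(self.replicate) != self.replicate or self.replicate < 1:
            raise ValueError(f"replicate={self.replicate!r} must be a positive integer")
        for name in SOIL_INDICATORS:
            _check_finite(name, getattr(self, name))
        _check_range("bd", self.bd, *BD_RANGE)
        _check_range("ph", self.ph, *PH_RANGE)
        for name in ("som", "tn", "tp", "tk", "an", "ap", "ak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}={getattr(self, name)!r} must be >= 0")
        # available pools (mg kg^-1) cannot exceed totals (g kg^-1)
        for avail, total in (("an", "tn"), ("ap", "tp"), ("ak", "tk")):
            if getattr(self, avail) / 1000.0 > getattr(self, total) + _AVAIL_EPS:
                raise ValueError(
                    f"available {avail}={getattr(self, avail)} mg/kg exceeds "
                    f"total {total}={getattr(self, total)} g/kg"
                )
        if self.yield_mg_ha is not None:
            _check_finite("yield_mg_ha", self.yield_mg_ha)
            if self.yield_mg_ha < 0:
                raise ValueError(f"yield_mg_ha={self.yield_mg_ha!r} must be >= 0")

    @property
    def key(self) -> tuple:
        return (self.site_id, self.year, self.season, self.treatment, self.replicate)


@dataclass(frozen=True)
class SiteProfile:
    """Site location, climate, and baseline (pre-trial) topsoil properties.

    ``tn``/``tp``/``tk`` baselines are part of the profile so that generated
    samples can honour the available<=total invariant and produce realistic
    stoichiometric ratios.
    """

    site_id: str
    latitude: float
    longitude: float
    elevation_m: float
    mat_c: float          # mean annual air temperature
    map_mm: float         # mean annual precipitation
    ph: float
    som: float
    bd: float
    an: float
    ap: float
    ak: float
    tn: float
    tp: float
    tk: float
    sand_pct: float
    silt_pct: float
    clay_pct: float

    def __post_init__(self) -> None:
        total = self.sand_pct + self.silt_pct + self.clay_pct
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"texture fractions sum to {total}, not 100 +/- 0.5")
        _check_range("bd", self.bd, *BD_RANGE)
        _check_range("ph", self.ph, *PH_RANGE)
        for name in ("som", "tn", "tp", "tk", "an", "ap", "ak"):
            if getattr(self, name) < 0:
                raise ValueError(f"baseline {name} must be >= 0")

    @property
    def baselines(self) -> dict:
        """Baseline value for each of the nine soil indicators."""
        return {name: getattr(self, name) for name in SOIL_INDICATORS}


@dataclass(frozen=True)
class TreatmentSpec:
    """Fertilizer inputs for one treatment arm in one season (kg ha^-1).

    ``substitution_fraction`` is the share of the full chemical N rate replaced
    by manure N; the remaining chemical N rate follows nitrogen equivalence
    (see :func:`chemical_n_rate`).
    """

    name: str
    substitution_fraction: float
    full_chemical_n: float
    chemical_n: float
    p2o5: float
    k2o: float
    manure_rate: float
    manure_oc_frac: float = 0.0
    manure_tn_frac: float = 0.0

    def __post_init__(self) -> None:
        f = self.substitution_fraction
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"substitution_fraction={f} outside [0, 1]")
        for name in ("full_chemical_n", "chemical_n", "p2o5", "k2o", "manure_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.manure_rate == 0 and f != 0.0:
            raise ValueError("substitution_fraction must be 0 when no manure is applied")
        if self.full_chemical_n > 0:
            expected = chemical_n_rate(self.full_chemical_n, f)
            if self.chemical_n != expected:
                raise ValueError(
                    f"chemical_n={self.chemical_n} inconsistent with nitrogen "
                    f"equivalence: expected {expected}"
                )


def chemical_n_rate(full_n: float, f: float) -> int:
    """Chemical N rate (kg ha^-1) after substituting fraction ``f`` with manure N.

    Nitrogen equivalence: the chemical share is ``full_n * (1 - f)``, rounded to
    the nearest integer; an exact half rounds *down* (225 * 0.70 = 157.5 -> 157),
    matching the convention of published per-treatment rate tables.
    """
    if full_n < 0:
        raise ValueError(f"full_n={full_n} must be >= 0")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f={f} outside [0, 1]")
    raw = full_n * (1.0 - f)
    floor = math.floor(raw)
    frac = raw - floor
    if abs(frac - 0.5) <= 1e-9:
        return int(floor)
    return int(math.floor(raw + 0.5))


# ---------------------------------------------------------------------------
# Tabular I/O


def samples_to_frame(samples: Iterable[SoilSample]) -> pd.DataFrame:
    """Represent samples as a DataFrame in canonical column order."""
    rows = [
        {col: getattr(s, col) for col in CSV_COLUMNS}
        for s in samples
    ]
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    return df


def frame_to_samples(df: pd.DataFrame) -> list[SoilSample]:
    """Validate a DataFrame row-by-row into :class:`SoilSample` records.

    Raises :class:`SchemaError` for missing columns, :class:`RowError` for the
    first invalid row, and :class:`DuplicateKeyError` for repeated keys.
    """
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    samples: list[SoilSample] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            y = getattr(row, "yield_mg_ha")
            sample = SoilSample(
                site_id=str(getattr(row, "site_id")),
                year=int(getattr(row, "year")),
                season=str(getattr(row, "season")),
                treatment=str(getattr(row, "treatment")),
                replicate=int(getattr(row, "replicate")),
                **{k: float(getattr(row, k)) for k in SOIL_INDICATORS},
                yield_mg_ha=None if y is None or (isinstance(y, float) and math.isnan(y)) else float(y),
            )
        except (ValueError, TypeError) as exc:
            raise RowError(i, str(exc)) from exc
        if sample.key in seen:
            raise DuplicateKeyError(f"duplicate sample key {sample.key} at row {i}")
        seen.add(sample.key)
        samples.append(sample)
    return samples


def read_samples(path) -> list[SoilSample]:
    """Read and validate a sample table from a comma-delimited UTF-8 file."""
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty (not even a header)") from exc
    return frame_to_samples(df)


def write_samples(samples: Sequence[SoilSample], path) -> None:
    """Write samples as a comma-delimited UTF-8 table (deterministic columns)."""
    df = samples_to_frame(samples)
    df.to_csv(path, index=False, encoding="utf-8")
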