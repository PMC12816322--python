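"""Molar elemental stoichiometry of soil carbon, nitrogen, phosphorus, potassium.

Ratios (C:N, C:P, C:K, N:P, N:K, P:K) are computed on a molar basis from mass
contents in g kg^-1: ``(mass_a / M_a) / (mass_b / M_b)``.  Carbon is taken as
soil organic carbon, by default derived from measured soil organic matter via
the Van Bemmelen factor (SOC = SOM / 1.724); labs that report SOC directly can
set ``use_som_directly_as_carbon``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .data_model import KEY_COLUMNS, SoilSample, samples_to_frame

__all__ = [
    "MOLAR_MASS",
    "RATIO_COLUMNS",
    "StoichConfig",
    "StoichRecord",
    "som_to_soc",
    "molar_ratio",
    "stoich_record",
    "stoich_table",
]

#: Standard atomic masses, g mol^-1.
MOLAR_MASS = {"C": 12.011, "N": 14.007, "P": 30.974, "K": 39.098}

RATIO_COLUMNS = ("c_n", "c_p", "c_k", "n_p", "n_k", "p_k")


@dataclass(frozen=True)
class StoichConfig:
    som_to_soc_divisor: float = 1.724
    molar_masses: Mapping[str, float] = field(default_factory=lambda: dict(MOLAR_MASS))
    use_som_directly_as_carbon: bool = False

    def __post_init__(self) -> None:
        if self.som_to_soc_divisor <= 1.0:
            raise ValueError("som_to_soc_divisor must be > 1")
        for el, m in self.molar_masses.items():
            if m <= 0:
                raise ValueError(f"molar mass of {el} must be positive")


@dataclass(frozen=True)
class StoichRecord:
    """Six dimensionless molar ratios for one sample."""

    key: tuple
    c_n: float
    c_p: float
    c_k: float
    n_p: float
    n_k: float
    p_k: float


def som_to_soc(som: float, config: StoichConfig = StoichConfig()) -> float:
    """Organic carbon (g kg^-1) from organic matter via the configured divisor."""
    if som < 0:
        raise ValueError(f"som={som} must be >= 0")
    return som / config.som_to_soc_divisor


def molar_ratio(mass_a: float, mass_b: float, molar_mass_a: float, molar_mass_b: float) -> float:
    """Molar ratio a:b of two elements given mass contents in the same unit."""
    if mass_b <= 0:
        raise ValueError(f"denominator mass must be positive, got {mass_b}")
    return (mass_a / molar_mass_a) / (mass_b / molar_mass_b)


def stoich_record(sample: SoilSample, config: StoichConfig = StoichConfig()) -> StoichRecord:
    """Compute the six molar ratios for one sample (totals in g kg^-1)."""
    if sample.tn <= 0 or sample.tp <= 0 or sample.tk <= 0:
        raise ValueError(
            f"total N/P/K must all be positive for {sample.key}: "
            f"tn={sample.tn}, tp={sample.tp}, tk={sample.tk}"
        )
    mm = config.molar_masses
    carbon = sample.som if config.use_som_directly_as_carbon else som_to_soc(sample.som, config)
    return StoichRecord(
        key=sample.key,
        c_n=molar_ratio(carbon, sample.tn, mm["C"], mm["N"]),
        c_p=molar_ratio(carbon, sample.tp, mm["C"], mm["P"]),
        c_k=molar_ratio(carbon, sample.tk, mm["C"], mm["K"]),
        n_p=molar_ratio(sample.tn, sample.tp, mm["N"], mm["P"]),
        n_k=molar_ratio(sample.tn, sample.tk, mm["N"], mm["K"]),
        p_k=molar_ratio(sample.tp, sample.tk, mm["P"], mm["K"]),
    )


def stoich_table(samples: Iterable[SoilSample], config: StoichConfig = StoichConfig()) -> pd.DataFrame:
    """Sample table with the six molar-ratio columns appended."""
    samples = list(samples)
    df = samples_to_frame(samples)[list(KEY_COLUMNS)].copy()
    records = [stoich_record(s, config) for s in samples]
    for col in RATIO_COLUMNS:
        df[col] = [getattr(r, col) for r in records]
    return df
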