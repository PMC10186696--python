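"""Descriptive summaries of capture records: injury prevalence, survey
effort per population, and the sex difference in body size."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "ViperRecord",
    "Prevalence",
    "PopulationSummary",
    "SexSizeComparison",
    "prevalence",
    "per_population_summary",
    "sex_size_comparison",
]


@dataclass(frozen=True)
class ViperRecord:
    """One captured individual."""

    population: str
    sex: str  # male | female | unknown
    svl_mm: float
    injured: bool

    def __post_init__(self):
        if not self.svl_mm > 0:
            raise InputError(f"svl_mm must be positive (got {self.svl_mm})")
        if self.sex not in ("male", "female", "unknown"):
            raise InputError(f"sex must be male/female/unknown (got {self.sex!r})")


class Prevalence(NamedTuple):
    n_total: int
    n_injured: int
    percent: float  # half-up rounded to one decimal


class PopulationSummary(NamedTuple):
    n_populations: int
    mean_count: float
    se_count: float  # NaN for a single population


class SexSizeComparison(NamedTuple):
    statistic: float  # rank-sum W (Mann-Whitney U of the female sample)
    pvalue: float
    medians: dict


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        if rows and isinstance(rows[0], ViperRecord):
            df = pd.DataFrame([r.__dict__ for r in rows])
        else:
            df = pd.DataFrame(rows)
    if len(df) == 0:
        raise InputError("no capture records supplied")
    missing = {"population", "sex", "svl_mm", "injured"} - set(df.columns)
    if missing:
        raise InputError(f"capture records missing columns: {sorted(missing)}")
    return df


def prevalence(records) -> Prevalence:
    """Share of individuals carrying predator-type injuries.

    The percentage is rounded half-up to one decimal, the precision survey
    papers print (e.g. 40 of 319 -> 12.5).
    """
    df = _as_frame(records)
    n = len(df)
    n_inj = int(df["injured"].astype(bool).sum())
    pct = float((Decimal(100) * Decimal(n_inj) / Decimal(n)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))
    return Prevalence(n_total=n, n_injured=n_inj, percent=pct)


def per_population_summary(records) -> PopulationSummary:
    """Mean and standard error of the per-population capture counts."""
    df = _as_frame(records)
    counts = df.groupby("population").size().to_numpy()
    k = counts.size
    se = float(counts.std(ddof=1) / np.sqrt(k)) if k > 1 else float("nan")
    return PopulationSummary(
        n_populations=int(k), mean_count=float(counts.mean()), se_count=se
    )


def sex_size_comparison(records) -> SexSizeComparison:
    """Two-sided rank-sum test of snout-vent length, females vs males."""
    df = _as_frame(records)
    females = df.loc[df["sex"] == "female", "svl_mm"].to_numpy(dtype=float)
    males = df.loc[df["sex"] == "male", "svl_mm"].to_numpy(dtype=float)
    if females.size < 2 or males.size < 2:
        raise InputError("need at least two records of each sex")
    if np.all(np.concatenate([females, males]) == females[0]):
        return SexSizeComparison(
            statistic=females.size * males.size / 2.0,
            pvalue=1.0,
            medians={"female": float(females[0]), "male": float(males[0])},
        )
    res = stats.mannwhitneyu(females, males, alternative="two-sided",
                             method="asymptotic")
    return SexSizeComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        medians={"female": float(np.median(females)),
                 "male": float(np.median(males))},
    )
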