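"""National, per-capita, smoothed, growth-rate and share series.

The National Scientific Product at a focal year y is the sum of the
productivity scores of all individuals who reached their peak age
(default 35) between y - 25 and y + 25, both endpoints inclusive, in a
given country.  Per-capita series divide by the population linearly
interpolated to the grid and are smoothed by loess (local-linear,
tricube weights) with a bandwidth expressed in years.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import InvalidConfigError

__all__ = [
    "AggregationConfig",
    "prepare_birth_years",
    "national_product",
    "product_series",
    "interpolate_population",
    "loess_smooth",
    "per_capita_series",
    "growth_rate",
    "country_shares",
    "subset_and_pool",
]

logger = logging.getLogger(__name__)


@dataclass
class AggregationConfig:
    peak_age: int = 35
    half_window: int = 25
    grid_step: int = 10
    loess_window: int = 50
    log_offset: float | None = None  # default: half the smallest positive value

    def __post_init__(self):
        if min(self.peak_age, self.half_window, self.grid_step, self.loess_window) <= 0:
            raise InvalidConfigError("all aggregation parameters must be positive")
        if self.loess_window < self.grid_step:
            raise InvalidConfigError("loess_window must be at least grid_step")


def prepare_birth_years(bios: pd.DataFrame, fallback_lifespan: int = 60) -> pd.DataFrame:
    """Fill unknown birth years from death_year - 60; drop the rest.

    The number of imputed and dropped rows is logged.
    """
    bios = bios.copy()
    missing = bios["birth_year"].isna()
    if missing.any() and "death_year" in bios.columns:
        fillable = missing & bios["death_year"].notna()
        bios.loc[fillable, "birth_year"] = bios.loc[fillable, "death_year"] - fallback_lifespan
        if fillable.any():
            logger.warning("imputed %d birth years from death_year - %d",
                           int(fillable.sum()), fallback_lifespan)
    still = bios["birth_year"].isna()
    if still.any():
        logger.warning("dropping %d individuals with unknown birth year", int(still.sum()))
        bios = bios[~still]
    return bios


def national_product(bios: pd.DataFrame, country: str, y: int,
                     cfg: AggregationConfig | None = None) -> float:
    """Sum of scores of individuals peaking within the window around y.

    An individual peaks at ``birth_year + peak_age``; the window
    ``[y - half_window, y + half_window]`` is inclusive on both sides.
    """
    cfg = cfg or AggregationConfig()
    sub = bios[bios["country"] == country]
    if sub.empty:
        warnings.warn(f"no individuals for country {country!r}; product is 0")
        return 0.0
    peak = sub["birth_year"] + cfg.peak_age
    mask = (peak >= y - cfg.half_window) & (peak <= y + cfg.half_window)
    return float(sub.loc[mask, "score"].sum())


def product_series(bios: pd.DataFrame, grid_years,
                   cfg: AggregationConfig | None = None,
                   countries=None) -> pd.DataFrame:
    """Long-format (country, year, production) table over a year grid."""
    cfg = cfg or AggregationConfig()
    if countries is None:
        countries = sorted(bios["country"].unique())
    rows = []
    for c in countries:
        sub = bios[bios["country"] == c]
        peak = (sub["birth_year"] + cfg.peak_age).to_numpy()
        scores = sub["score"].to_numpy()
        for y in grid_years:
            mask = (peak >= y - cfg.half_window) & (peak <= y + cfg.half_window)
            rows.append((c, int(y), float(scores[mask].sum())))
    return pd.DataFrame(rows, columns=["country", "year", "production"])


def interpolate_population(anchors, grid_years) -> np.ndarray:
    """Populations at the grid years: linear interpolation between
    anchors, linear extrapolation from the two nearest anchors outside.

    ``anchors`` is a sequence of (year, population) pairs or a DataFrame
    with year/population columns.
    """
    if isinstance(anchors, pd.DataFrame):
        years = anchors["year"].to_numpy(dtype=float)
        pops = anchors["population"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(anchors), dtype=float)
        years, pops = arr[:, 0], arr[:, 1]
    if len(np.unique(years)) != len(years):
        raise InvalidConfigError("duplicate anchor years")
    if np.any(np.diff(years) <= 0):
        order = np.argsort(years)
        years, pops = years[order], pops[order]
    if np.any(pops <= 0):
        raise InvalidConfigError("populations must be positive")
    grid = np.asarray(grid_years, dtype=float)
    if len(years) == 1:
        warnings.warn("single population anchor; returning a constant series")
        return np.full(grid.shape, pops[0])
    out = np.interp(grid, years, pops)
    # linear extrapolation beyond the anchor range
    lo = grid < years[0]
    if lo.any():
        slope = (pops[1] - pops[0]) / (years[1] - years[0])
        out[lo] = pops[0] + slope * (grid[lo] - years[0])
    hi = grid > years[-1]
    if hi.any():
        slope = (pops[-1] - pops[-2]) / (years[-1] - years[-2])
        out[hi] = pops[-1] + slope * (grid[hi] - years[-1])
    return out


def loess_smooth(years, values, window: int, it: int = 0) -> np.ndarray:
    """Local-linear loess with tricube weights; bandwidth in years."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    span = years.max() - years.min()
    frac = 1.0 if span <= 0 else min(1.0, window / span)
    out = lowess(values, years, frac=frac, it=it, return_sorted=False)
    return np.asarray(out, dtype=float)


def per_capita_series(products, populations, years,
                      cfg: AggregationConfig | None = None) -> pd.DataFrame:
    """Per-capita production on the grid, with a loess-smoothed column and
    a log view ``log(x + log_offset)``.

    The default log offset is half the smallest positive per-capita value,
    so zero-production cells stay finite in log space.
    """
    cfg = cfg or AggregationConfig()
    products = np.asarray(products, dtype=float)
    populations = np.asarray(populations, dtype=float)
    years = np.asarray(years, dtype=int)
    if not (len(products) == len(populations) == len(years)):
        raise InvalidConfigError("products, populations and years must be aligned")
    if np.any(populations <= 0):
        raise InvalidConfigError("zero or negative population")
    percap = products / populations
    smooth = loess_smooth(years, percap, cfg.loess_window)
    offset = cfg.log_offset
    if offset is None:
        positive = percap[percap > 0]
        offset = float(positive.min() / 2) if positive.size else 1.0
    return pd.DataFrame(
        {
            "year": years,
            "production_pc": percap,
            "production_pc_smooth": smooth,
            "log_production_pc": np.log(percap + offset),
        }
    )


def growth_rate(values, step: float) -> np.ndarray:
    """Per-year log growth: (log x[t+1] - log x[t]) / step."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise InvalidConfigError("growth rate requires strictly positive values")
    if step <= 0:
        raise InvalidConfigError("step must be positive")
    return np.diff(np.log(v)) / step


def country_shares(products) -> pd.Series:
    """Share of each country in the total; sums to one."""
    s = pd.Series(products, dtype=float)
    total = s.sum()
    if total <= 0:
        raise InvalidConfigError("total production is zero; shares undefined")
    return s / total


def subset_and_pool(bios: pd.DataFrame, rule) -> pd.DataFrame:
    """Robustness splits: decile filters and country pooling.

    ``rule`` is either the string ``"top10"`` / ``"bottom90"`` (split at
    the empirical 90th percentile of scores) or a country -> region
    mapping (countries absent from the mapping keep their own label).
    """
    if isinstance(rule, str):
        thr = float(np.quantile(bios["score"].to_numpy(dtype=float), 0.9))
        if rule == "top10":
            out = bios[bios["score"] >= thr]
        elif rule == "bottom90":
            out = bios[bios["score"] < thr]
        else:
            raise InvalidConfigError(f"unknown split rule {rule!r}")
    elif isinstance(rule, dict):
        out = bios.copy()
        out["country"] = out["country"].map(lambda c: rule.get(c, c))
    else:
        raise InvalidConfigError("rule must be a split name or a country->region map")
    if out.empty:
        warnings.warn("subset rule selected no individuals")
    return out.reset_index(drop=True)
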