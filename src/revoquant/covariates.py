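"""Spatial-diffusion and environment covariates for the panel models.

Three transmission covariates are built from the production panel:

* ``diff`` — horizontal diffusion: the sum of the other countries'
  production weighted by the inverse squared great-circle distance
  between capital cities;
* ``cum`` — vertical diffusion: a country's own cumulative production
  strictly before the focal year;
* ``cumdiff`` — cumulative horizontal diffusion.

"Neighbouring countries" means every other country in the panel: the
inverse-square distance weighting already discounts remote ones, and no
adjacency list exists for the historical setting.  By default the
horizontal-diffusion covariate is lagged by one grid step — a country
cannot be influenced by strictly contemporaneous output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, NoVarianceError, UnmappedCountryError

__all__ = [
    "horizontal_diffusion",
    "cumulative_production",
    "cumulative_diffusion",
    "add_diffusion_covariates",
    "scale_covariates",
    "unscale_covariates",
    "religion_group",
    "PROTESTANT_COUNTRIES",
    "CATHOLIC_COUNTRIES",
]

#: Majority-religion groups after the Wars of Religion settled the borders.
PROTESTANT_COUNTRIES = frozenset(
    {"england", "scotland", "germany", "netherlands", "switzerland", "scandinavia"}
)
CATHOLIC_COUNTRIES = frozenset({"france", "italy", "portugal", "spain", "belgium"})


def _wide(panel: pd.DataFrame, value: str) -> pd.DataFrame:
    wide = panel.pivot(index="country", columns="year", values=value)
    if wide.isna().any().any():
        raise InvalidConfigError(f"panel grid not rectangular in column {value!r}")
    return wide


def _inverse_square_weights(dmat: pd.DataFrame, countries) -> np.ndarray:
    d = dmat.loc[countries, countries].to_numpy(dtype=float)
    off = ~np.eye(len(countries), dtype=bool)
    if np.any(d[off] <= 0):
        raise InvalidConfigError("zero or negative distance between distinct countries")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off] ** 2
    return w


def horizontal_diffusion(panel: pd.DataFrame, dmat: pd.DataFrame,
                         country: str, t: int) -> float:
    """Sum of the other countries' production at year ``t`` divided by the
    squared capital-to-capital distance."""
    wide = _wide(panel, "production")
    if t not in wide.columns:
        raise InvalidConfigError(f"year {t} not on the panel grid")
    w = _inverse_square_weights(dmat, wide.index)
    i = list(wide.index).index(country)
    return float(w[i] @ wide[t].to_numpy(dtype=float))


def cumulative_production(panel: pd.DataFrame, country: str, t: int) -> float:
    """A country's summed production strictly before year ``t``."""
    rows = panel[(panel["country"] == country) & (panel["year"] < t)]
    return float(rows["production"].sum())


def cumulative_diffusion(panel: pd.DataFrame, dmat: pd.DataFrame,
                         country: str, t: int) -> float:
    """Cumulative horizontal diffusion strictly before year ``t``."""
    wide = _wide(panel, "production")
    years = [y for y in wide.columns if y < t]
    w = _inverse_square_weights(dmat, wide.index)
    i = list(wide.index).index(country)
    return float(sum(w[i] @ wide[y].to_numpy(dtype=float) for y in years))


def add_diffusion_covariates(panel: pd.DataFrame, dmat: pd.DataFrame,
                             lag: int = 1) -> pd.DataFrame:
    """Attach diff/cum/cumdiff (raw and z-scored) plus a z-scored date.

    ``lag`` shifts the horizontal-diffusion covariate by that many grid
    steps (default 1).  Cells with no defined lagged value (the first
    ``lag`` grid years) are zero after z-scoring; they never enter the
    likelihood, which conditions on each country's first observation.
    """
    panel = panel.sort_values(["country", "year"]).reset_index(drop=True)
    wide = _wide(panel, "production")
    countries, years = list(wide.index), list(wide.columns)
    P = wide.to_numpy(dtype=float)  # (C, T)
    w = _inverse_square_weights(dmat, countries)

    diff = w @ P  # (C, T) contemporaneous
    cum = np.concatenate([np.zeros((len(countries), 1)), np.cumsum(P, axis=1)[:, :-1]], axis=1)
    cumdiff = np.concatenate([np.zeros((len(countries), 1)), np.cumsum(diff, axis=1)[:, :-1]],
                             axis=1)
    if lag > 0:
        lagged = np.full_like(diff, np.nan)
        lagged[:, lag:] = diff[:, :-lag]
    else:
        lagged = diff

    key = pd.MultiIndex.from_product([countries, years], names=["country", "year"])
    extra = pd.DataFrame(
        {"diff": lagged.ravel(), "cum": cum.ravel(), "cumdiff": cumdiff.ravel()},
        index=key,
    ).reset_index()
    panel = panel.merge(extra, on=["country", "year"], how="left",
                        suffixes=("", "_new"))
    for col in ("diff", "cum", "cumdiff"):
        if f"{col}_new" in panel.columns:
            panel[col] = panel[f"{col}_new"]
            panel = panel.drop(columns=[f"{col}_new"])
        try:
            z = _zscore_ignore_nan(panel[col].to_numpy(dtype=float))
        except NoVarianceError:
            # e.g. a single-country panel: diffusion is identically zero
            z = np.zeros(len(panel))
        panel[f"{col}_z"] = np.nan_to_num(z)
    panel["date_z"] = _zscore_ignore_nan(panel["year"].to_numpy(dtype=float))
    if "gdp_pc" in panel.columns and "gdp_z" not in panel.columns:
        panel["gdp_z"] = _zscore_ignore_nan(np.log(panel["gdp_pc"].to_numpy(dtype=float)))
    return panel


def _zscore_ignore_nan(a: np.ndarray) -> np.ndarray:
    m = np.nanmean(a)
    s = np.nanstd(a)
    if not np.isfinite(s) or s == 0:
        raise NoVarianceError("column has zero variance; cannot z-score")
    return (a - m) / s


def scale_covariates(panel: pd.DataFrame, columns) -> tuple[pd.DataFrame, dict]:
    """Z-score the named columns over all non-missing country-years.

    Returns the panel plus a mapping column -> (mean, sd) so the scaling
    can be undone exactly.
    """
    panel = panel.copy()
    scales: dict[str, tuple[float, float]] = {}
    for col in columns:
        vals = panel[col].to_numpy(dtype=float)
        m, s = float(np.nanmean(vals)), float(np.nanstd(vals))
        if not np.isfinite(s) or s == 0:
            raise NoVarianceError(f"column {col!r} has zero variance")
        panel[col] = (vals - m) / s
        scales[col] = (m, s)
    return panel, scales


def unscale_covariates(panel: pd.DataFrame, scales: dict) -> pd.DataFrame:
    panel = panel.copy()
    for col, (m, s) in scales.items():
        panel[col] = panel[col].to_numpy(dtype=float) * s + m
    return panel


def religion_group(country: str) -> int:
    """1 for the Protestant group, 0 for the Catholic group.

    Unlisted countries raise rather than silently defaulting: religion is
    a historical assignment, not something to guess.
    """
    c = country.strip().lower()
    if c in PROTESTANT_COUNTRIES:
        return 1
    if c in CATHOLIC_COUNTRIES:
        return 0
    raise UnmappedCountryError(
        f"country {country!r} is in neither religion group; "
        "extend the mapping explicitly"
    )
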