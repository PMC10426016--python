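"""Composite productivity index and power-law tail characterisation.

Nine per-person notability indicators (page length, language count,
inbound links, each in three language editions) are combined into a
single Individual Scientific Productivity score: the projection on the
first principal component of the correlation matrix.  The correlation
(not covariance) matrix is used because the indicators have
incommensurate units (bytes vs counts).  The tail of the resulting
scores is summarised with the continuous maximum-likelihood (Hill)
estimate of the CCDF exponent, for which Zipf-like data give alpha
around 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import NoVarianceError

__all__ = ["compute_index", "fit_power_law", "PowerLawFit", "INDICATOR_COLUMNS"]

logger = logging.getLogger(__name__)

INDICATOR_COLUMNS = tuple(
    f"ind_{proxy}_{lang}" for lang in ("en", "fr", "de") for proxy in ("len", "lang", "link")
)


@dataclass(frozen=True)
class PowerLawFit:
    """Continuous-MLE fit of a power-law tail (CCDF convention)."""

    alpha_hat: float
    xmin: float
    n_tail: int


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, pd.DataFrame):
        cols = [c for c in INDICATOR_COLUMNS if c in m.columns]
        m = m[cols] if cols else m.select_dtypes("number")
    return np.asarray(m, dtype=float)


def compute_index(m, positivize: bool = False, scale: float = 1.0,
                  standardize: bool = True) -> np.ndarray:
    """First-principal-component score per individual.

    Missing entries are imputed as the column minimum (an individual
    absent from a language edition is at the notability floor there);
    constant columns are dropped with a logged warning.  Columns are
    standardized, the first eigenvector of their correlation matrix
    defines the score, and the sign is fixed so the score correlates
    positively with the mean indicator.

    With ``positivize=True`` the z-scored PC1 coordinate ``s`` is mapped
    to ``exp(scale * s)``, a positive heavy-tailed magnitude that can be
    summed into national totals.
    """
    X = _as_matrix(m)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two individuals (rows)")
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        logger.warning("imputing %d missing indicator cells as column minima", n_missing)
        col_min = np.nanmin(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = col_min[idx[1]]
    sd = X.std(axis=0)
    # a constant column's sd is only zero up to rounding in the mean
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    if not keep.any():
        raise NoVarianceError("all indicator columns are constant")
    if not keep.all():
        logger.warning("dropping %d constant indicator column(s)", int((~keep).sum()))
        X = X[:, keep]
        sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd if standardize else X - X.mean(axis=0)
    corr = (Z.T @ Z) / Z.shape[0]
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]  # leading component
    scores = Z @ v
    if np.corrcoef(scores, Z.mean(axis=1))[0, 1] < 0:
        scores = -scores
    if positivize:
        s = scores.std()
        if s == 0:
            raise NoVarianceError("scores are constant; cannot positivize")
        scores = np.exp(scale * scores / s)
    return scores


def fit_power_law(values, xmin: float) -> PowerLawFit:
    """Hill estimator of the CCDF exponent over the tail ``x >= xmin``.

    alpha_hat = n / sum(log(x_i / xmin)); this equals the density
    exponent minus one.
    """
    if xmin <= 0:
        raise ValueError("xmin must be positive")
    x = np.asarray(values, dtype=float)
    tail = x[x >= xmin]
    if (x > xmin).sum() < 2:
        raise ValueError("need at least two values strictly above xmin")
    s = float(np.sum(np.log(tail / xmin)))
    if s <= 0:
        raise NoVarianceError("all tail values equal xmin; estimate diverges")
    return PowerLawFit(alpha_hat=len(tail) / s, xmin=float(xmin), n_tail=int(len(tail)))
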