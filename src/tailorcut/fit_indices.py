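"""Fit indices: chi-square (raw/scaled), CFI, RMSEA, SRMR.

Directions: CFI variants are higher-is-better; chi-square, RMSEA and SRMR
are lower-is-better.  The RMSEA denominator uses the same multiplier (n by
default) as the test statistic, for internal consistency.  SRMR is the
covariance version including diagonal residuals (no mean residuals; the
mean structure is out of scope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

from .estimate import FitResult

__all__ = ["FitIndexSet", "INDEX_DIRECTIONS", "cfi", "rmsea", "srmr", "compute_all"]

#: higher_is_better flag per index name
INDEX_DIRECTIONS: dict[str, bool] = {
    "chisq": False,
    "chisq_scaled": False,
    "cfi": True,
    "cfi_scaled": True,
    "rmsea": False,
    "rmsea_scaled": False,
    "srmr": False,
}


@dataclass
class FitIndexSet:
    """Values of all in-scope fit indices for one model-data fit."""

    chisq: float
    chisq_scaled: float
    cfi: float
    cfi_scaled: float
    rmsea: float
    rmsea_scaled: float
    srmr: float
    df: int
    converged: bool = True
    proper: bool = True

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def cfi(T: float, df: int, T_b: float, df_b: int) -> float:
    """Comparative fit index vs. the all-items-uncorrelated baseline.

    ``1 - max(T - df, 0) / max(T_b - df_b, T - df, 0)``; a degenerate
    baseline (no excess misfit anywhere) returns 1, a baseline beaten by the
    target model clamps at the obvious bound.
    """
    if df_b < df:
        raise ValueError("baseline df must be >= model df")
    num = max(T - df, 0.0)
    den = max(T_b - df_b, T - df, 0.0)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def rmsea(T: float, df: int, n: float) -> float:
    """Root-mean-square error of approximation, sqrt(max(T - df, 0)/(df n)).

    ``n`` is the test-statistic multiplier (sample size by default).  For a
    saturated model (df = 0) the index is undefined: returns NaN with a
    warning.
    """
    if df == 0:
        warnings.warn("RMSEA undefined for df = 0; returning NaN")
        return float("nan")
    if n <= 1:
        raise ValueError("n must exceed 1")
    return float(np.sqrt(max(T - df, 0.0) / (df * n)))


def srmr(S: np.ndarray, Sigma_hat: np.ndarray) -> float:
    """Standardized root-mean-square residual (covariance version).

    Root of the mean squared standardized residual
    ``(s_ij - sigma_ij) / sqrt(s_ii s_jj)`` over the p(p+1)/2 unique
    elements, diagonal included.
    """
    S = np.asarray(S, dtype=float)
    Sigma_hat = np.asarray(Sigma_hat, dtype=float)
    if S.shape != Sigma_hat.shape:
        raise ValueError("dimension mismatch between S and Sigma_hat")
    d = np.diag(S)
    if np.any(d <= 0):
        raise ValueError("nonpositive variance on the diagonal of S")
    scale = np.sqrt(np.outer(d, d))
    resid = (S - Sigma_hat) / scale
    rows, cols = np.tril_indices(S.shape[0])
    return float(np.sqrt(np.mean(resid[rows, cols] ** 2)))


def compute_all(fit: FitResult, S: np.ndarray, n: int) -> FitIndexSet:
    """All in-scope indices for one fit.

    Non-converged fits yield a NaN sentinel record (flagged, excluded from
    distributions downstream and counted there).
    """
    if not fit.converged:
        return FitIndexSet(*([float("nan")] * 7), df=fit.df,
                           converged=False, proper=fit.proper)
    mult = float(n) if fit.multiplier == "n" else float(n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # df = 0 RMSEA NaN is expected here
        return FitIndexSet(
            chisq=fit.T,
            chisq_scaled=fit.T_scaled,
            cfi=cfi(fit.T, fit.df, fit.baseline_T, fit.baseline_df),
            cfi_scaled=cfi(fit.T_scaled, fit.df, fit.baseline_T_scaled,
                           fit.baseline_df),
            rmsea=rmsea(fit.T, fit.df, mult) if fit.df > 0 else float("nan"),
            rmsea_scaled=rmsea(fit.T_scaled, fit.df, mult) if fit.df > 0
            else float("nan"),
            srmr=srmr(S, fit.implied),
            df=fit.df,
            converged=True,
            proper=fit.proper,
        )
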