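"""Frequentist per-factor pooling.

Inverse-variance fixed-effect pooling, DerSimonian-Laird random-effects
pooling, Cochran's Q, the I-squared heterogeneity percentage, Wald tests,
and forest-plot data export.

Notation: study i contributes an estimate :math:`y_i` with standard error
:math:`s_i`.  Fixed-effect weights are :math:`W_i = 1/s_i^2`; the
DerSimonian-Laird moment estimator of the between-study variance is

.. math:: \\hat\\tau^2 = \\max\\!\\left(0,\\;
    \\frac{Q - (k-1)}{\\sum W_i - \\sum W_i^2 / \\sum W_i}\\right)

with random-effects weights :math:`1/(s_i^2 + \\hat\\tau^2)`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect_table import EffectEstimate, EffectTable

__all__ = [
    "UnivariatePoolResult",
    "pool_fixed",
    "pool_dersimonian_laird",
    "pool_table",
    "i_squared",
    "z_from_or_ci",
    "forest_data",
]

_Z975 = 1.959963984540054  # standard normal 97.5th percentile


@dataclass(frozen=True)
class UnivariatePoolResult:
    """Pooled summary for one factor.

    ``mu_hat`` and the CI are on the log-OR scale; ``I2`` is a percentage
    in [0, 100); ``per_study_weights`` are normalized (sum to 1) pooling
    weights in study order.
    """

    factor_id: str
    n_studies: int
    mu_hat: float
    se_mu: float
    ci95: tuple[float, float]
    tau2: float
    Q: float
    df: int
    I2: float
    z: float
    p: float
    per_study_weights: tuple[float, ...]
    method: str  # "fixed" or "dersimonian-laird"

    @property
    def or_point(self) -> float:
        return float(np.exp(self.mu_hat))

    @property
    def or_ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.ci95[0])), float(np.exp(self.ci95[1])))


def _as_arrays(estimates: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) == 0:
        raise ValueError("at least one estimate is required")
    y = np.array([e.log_or for e in estimates], dtype=float)
    s = np.array([e.se for e in estimates], dtype=float)
    if np.any(s <= 0):
        raise ValueError("all standard errors must be > 0")
    return y, s


def _wald(factor_id, y, weights, tau2, Q, df, method) -> UnivariatePoolResult:
    wsum = weights.sum()
    mu = float(np.sum(weights * y) / wsum)
    se = float(1.0 / np.sqrt(wsum))
    z = mu / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return UnivariatePoolResult(
        factor_id=factor_id,
        n_studies=len(y),
        mu_hat=mu,
        se_mu=se,
        ci95=(mu - _Z975 * se, mu + _Z975 * se),
        tau2=float(tau2),
        Q=float(Q),
        df=int(df),
        I2=i_squared(Q, df),
        z=float(z),
        p=p,
        per_study_weights=tuple(weights / wsum),
        method=method,
    )


def _q_statistic(y: np.ndarray, w_fixed: np.ndarray) -> float:
    mu_fe = np.sum(w_fixed * y) / w_fixed.sum()
    return float(np.sum(w_fixed * (y - mu_fe) ** 2))


def pool_fixed(
    estimates: Sequence[EffectEstimate], factor_id: str = ""
) -> UnivariatePoolResult:
    """Inverse-variance fixed-effect pooling of one factor's estimates."""
    y, s = _as_arrays(estimates)
    w = 1.0 / s**2
    Q = _q_statistic(y, w)
    return _wald(factor_id, y, w, 0.0, Q, len(y) - 1, "fixed")


def pool_dersimonian_laird(
    estimates: Sequence[EffectEstimate], factor_id: str = ""
) -> UnivariatePoolResult:
    """DerSimonian-Laird random-effects pooling of one factor's estimates.

    With a single study (or whenever Q <= df) the between-study variance
    truncates to zero and the result coincides with :func:`pool_fixed`.
    """
    y, s = _as_arrays(estimates)
    w = 1.0 / s**2
    Q = _q_statistic(y, w)
    df = len(y) - 1
    if df > 0:
        c = w.sum() - np.sum(w**2) / w.sum()
        tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
    else:
        tau2 = 0.0
    w_re = 1.0 / (s**2 + tau2)
    return _wald(factor_id, y, w_re, tau2, Q, df, "dersimonian-laird")


def pool_table(table: EffectTable, method: str = "dersimonian-laird") -> pd.DataFrame:
    """Pool every factor of a table; one row per factor, in table order."""
    pool = {"fixed": pool_fixed, "dersimonian-laird": pool_dersimonian_laird}[method]
    rows = []
    for fid in table.factor_ids:
        col = table.column(fid)
        if not col:
            continue
        r = pool([e for _, e in col], factor_id=fid)
        rows.append(
            {
                "factor": fid,
                "n_studies": r.n_studies,
                "mu_hat": r.mu_hat,
                "se_mu": r.se_mu,
                "ci_lo": r.ci95[0],
                "ci_hi": r.ci95[1],
                "tau2": r.tau2,
                "Q": r.Q,
                "df": r.df,
                "I2": r.I2,
                "z": r.z,
                "p": r.p,
            }
        )
    return pd.DataFrame(rows).set_index("factor")


def i_squared(Q: float, df: int) -> float:
    """Percentage of total variability attributed to heterogeneity.

    ``I2 = max(0, (Q - df)/Q) * 100``; by convention 0 when Q == 0.
    Values above 50% are conventionally read as substantial heterogeneity,
    and the Q test itself is read at the 0.10 significance level.
    """
    if Q < 0:
        raise ValueError(f"Q must be >= 0, got {Q}")
    if df < 0:
        raise ValueError(f"df must be >= 0, got {df}")
    if Q == 0:
        return 0.0
    return float(max(0.0, (Q - df) / Q) * 100.0)


def q_test_pvalue(Q: float, df: int) -> float:
    """Chi-square upper-tail p of Cochran's Q (significant at p < 0.10)."""
    if df <= 0:
        return float("nan")
    return float(stats.chi2.sf(Q, df))


def z_from_or_ci(or_point: float, ci: tuple[float, float]) -> float:
    """Back out a Wald z from a published OR and its 95% CI.

    A consistency check for published summaries, not an estimator: the SE
    is reconstructed as ``(ln hi - ln lo) / (2 * 1.96)`` and z is
    ``ln(OR) / SE``.  Rounding of the printed CI propagates into z.
    """
    lo, hi = ci
    if not (0 < lo < or_point < hi):
        raise ValueError(f"require 0 < lo < OR < hi, got OR={or_point}, CI={ci}")
    se = (np.log(hi) - np.log(lo)) / (2.0 * _Z975)
    return float(np.log(or_point) / se)


def forest_data(table: EffectTable, factor_id: str) -> pd.DataFrame:
    """Per-study rows plus a pooled DerSimonian-Laird row for one factor.

    Columns: study, log_or, se, ci_lo, ci_hi, weight_pct (random-effects
    weights, summing to 100 across studies), is_pooled.
    """
    col = table.column(factor_id)
    if not col:
        raise KeyError(f"factor {factor_id!r} is not reported by any study")
    pooled = pool_dersimonian_laird([e for _, e in col], factor_id=factor_id)
    rows = []
    for (sid, e), w in zip(col, pooled.per_study_weights):
        rows.append(
            {
                "study": sid,
                "log_or": e.log_or,
                "se": e.se,
                "ci_lo": e.log_or - _Z975 * e.se,
                "ci_hi": e.log_or + _Z975 * e.se,
                "weight_pct": 100.0 * w,
                "is_pooled": False,
            }
        )
    rows.append(
        {
            "study": "pooled (DL)",
            "log_or": pooled.mu_hat,
            "se": pooled.se_mu,
            "ci_lo": pooled.ci95[0],
            "ci_hi": pooled.ci95[1],
            "weight_pct": 100.0,
            "is_pooled": True,
        }
    )
    return pd.DataFrame(rows)
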