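"""Funnel-plot asymmetry tests: Begg's rank correlation and Egger's regression.

Begg's test (Begg-Mazumdar form) correlates variance-adjusted standardized
deviates with the study variances. With fixed-effect mean
:math:`\\bar y` and variances :math:`v_i`, the deviates are

.. math:: t_i = (y_i - \\bar y) / \\sqrt{v_i - 1/\\sum v_j^{-1}},

and Kendall's S between :math:`t_i` and :math:`v_i` is referred to the
normal approximation with tie correction and a continuity correction of 1.
The two-sided p is reported uncapped.

Egger's test regresses the standardized effect :math:`y_i/s_i` on precision
:math:`1/s_i` by ordinary (unweighted) least squares; a nonzero intercept
indicates small-study asymmetry and is tested with ``k - 2`` df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError
from .records import EffectEstimate


@dataclass(frozen=True)
class BiasTestResult:
    begg_z: float
    begg_p: float
    egger_intercept: float
    egger_t: float
    egger_df: int
    egger_p: float


def _kendall_s_and_var(x: np.ndarray, y: np.ndarray) -> Tuple[int, float]:
    """Kendall's S statistic and its tie-corrected null variance."""
    n = len(x)
    s = 0
    for i, j in combinations(range(n), 2):
        s += int(np.sign(x[i] - x[j]) * np.sign(y[i] - y[j]))

    def tie_sizes(v: np.ndarray) -> np.ndarray:
        _, counts = np.unique(v, return_counts=True)
        return counts[counts > 1].astype(float)

    t = tie_sizes(x)
    u = tie_sizes(y)
    var = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(t * (t - 1) * (2 * t + 5))
        - np.sum(u * (u - 1) * (2 * u + 5))
    ) / 18.0
    if n > 2:
        var += (np.sum(t * (t - 1) * (t - 2)) * np.sum(u * (u - 1) * (u - 2))) / (
            9.0 * n * (n - 1) * (n - 2)
        )
    var += (np.sum(t * (t - 1)) * np.sum(u * (u - 1))) / (2.0 * n * (n - 1))
    return s, float(var)


def begg_test(effects: Sequence[EffectEstimate]) -> Tuple[float, float]:
    """Begg's rank-correlation asymmetry test; returns (z, two-sided p)."""
    if len(effects) < 3:
        raise DomainError(f"Begg's test needs at least 3 studies, got {len(effects)}")
    y = np.array([e.log_effect for e in effects])
    v = np.array([e.se**2 for e in effects])
    w = 1.0 / v
    y_bar = float(np.dot(w, y) / w.sum())
    # v_i - 1/sum(w) is the variance of y_i - y_bar; strictly positive for k >= 2
    deviates = (y - y_bar) / np.sqrt(v - 1.0 / w.sum())
    s, var = _kendall_s_and_var(deviates, v)
    if var <= 0:
        raise DomainError("Begg's test: degenerate variance (all studies tied)")
    z = 0.0 if s == 0 else (s - math.copysign(1, s)) / math.sqrt(var)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def egger_test(effects: Sequence[EffectEstimate]) -> Tuple[float, float, int, float]:
    """Egger's regression asymmetry test.

    Returns (intercept, t, df, two-sided p) from the unweighted OLS of
    standardized effect on precision.
    """
    if len(effects) < 3:
        raise DomainError(f"Egger's test needs at least 3 studies, got {len(effects)}")
    se = np.array([e.se for e in effects])
    if np.ptp(se) == 0:
        raise DomainError(
            "Egger's test: all standard errors equal — precision is collinear "
            "with the intercept and the regression is unidentifiable"
        )
    y = np.array([e.log_effect for e in effects])
    fit = sm.OLS(y / se, sm.add_constant(1.0 / se)).fit()
    df = len(effects) - 2
    return (
        float(fit.params[0]),
        float(fit.tvalues[0]),
        df,
        float(fit.pvalues[0]),
    )


def bias_tests(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Run both asymmetry tests on one study set."""
    bz, bp = begg_test(effects)
    intercept, t, df, p = egger_test(effects)
    return BiasTestResult(
        begg_z=bz, begg_p=bp,
        egger_intercept=intercept, egger_t=t, egger_df=df, egger_p=p,
    )


def funnel_table(effects: Sequence[EffectEstimate]) -> pd.DataFrame:
    """Data needed to replot the funnel: effect, se, and the precision axis."""
    return pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "log_effect": [e.log_effect for e in effects],
            "se": [e.se for e in effects],
            "precision": [1.0 / e.se for e in effects],
        }
    )
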