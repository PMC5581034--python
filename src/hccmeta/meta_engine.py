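"""Inverse-variance meta-analysis: fixed-effect and DerSimonian-Laird pooling.

Given per-study log effects :math:`y_i` with standard errors :math:`s_i`,
the fixed-effect model weights each study by :math:`w_i = 1/s_i^2` and pools

.. math:: \\hat\\mu = \\frac{\\sum w_i y_i}{\\sum w_i}, \\qquad
          \\mathrm{SE}(\\hat\\mu) = \\Big(\\sum w_i\\Big)^{-1/2}.

Heterogeneity is measured by Cochran's
:math:`Q = \\sum w_i (y_i - \\hat\\mu)^2` (chi-square with ``k-1`` df under
homogeneity) and Higgins' :math:`I^2 = \\max(0, (Q - df)/Q) \\times 100`.
The random-effects model uses the DerSimonian-Laird moment estimator of the
between-study variance,

.. math:: \\tau^2 = \\max\\Big(0, \\frac{Q - (k-1)}
          {\\sum w_i - \\sum w_i^2 / \\sum w_i}\\Big),

and re-pools with weights :math:`w_i^* = 1/(s_i^2 + \\tau^2)`. When
:math:`\\tau^2 = 0` the two models coincide exactly.

Conventions fixed throughout: two-sided p from the normal distribution of
``z = estimate/se``; association significant at p < 0.05; heterogeneity
flagged only when both I^2 >= 50% and the Q-test p < 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DomainError, EmptyInputError
from .records import EffectEstimate, Scale, Z95

#: Heterogeneity is called significant only when both hold.
I2_THRESHOLD = 50.0
Q_P_THRESHOLD = 0.1


@dataclass(frozen=True)
class PooledResult:
    """A pooled effect with its heterogeneity statistics (log scale)."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q: float
    df: int
    i_squared: float  # percent in [0, 100]
    tau_squared: float
    model: str  # "fixed" | "random_dl"
    weights: tuple  # normalized, sum to 1, input order
    study_ids: tuple
    scale: Scale

    @property
    def ratio(self) -> float:
        """Back-transformed pooled effect (HR or OR)."""
        return math.exp(self.estimate)

    @property
    def ratio_ci(self) -> Tuple[float, float]:
        return (math.exp(self.ci_low), math.exp(self.ci_high))


@dataclass(frozen=True)
class Heterogeneity:
    q: float
    df: int
    p: float
    i_squared: float
    significant: bool


@dataclass(frozen=True)
class SubgroupComparison:
    """Per-subgroup pools plus the between-subgroup chi-square test."""

    results: tuple  # one PooledResult per group
    q_between: float
    df_between: int
    p_between: float


def _check_effects(effects: Sequence[EffectEstimate], min_k: int = 1) -> Scale:
    if not effects:
        raise EmptyInputError("no effect estimates supplied")
    if len(effects) < min_k:
        raise DomainError(f"need at least {min_k} effect estimates, got {len(effects)}")
    scales = {e.scale for e in effects}
    if len(scales) > 1:
        raise DomainError(f"cannot pool mixed scales: {sorted(s.value for s in scales)}")
    return scales.pop()


def _q_statistic(y: np.ndarray, w: np.ndarray) -> Tuple[float, float]:
    mean = float(np.dot(w, y) / w.sum())
    return float(np.dot(w, (y - mean) ** 2)), mean


def _i_squared(q: float, df: int) -> float:
    return 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0


def _assemble(
    y: np.ndarray,
    w_pool: np.ndarray,
    q: float,
    df: int,
    tau2: float,
    model: str,
    effects: Sequence[EffectEstimate],
    scale: Scale,
) -> PooledResult:
    sw = w_pool.sum()
    est = float(np.dot(w_pool, y) / sw)
    se = float(1.0 / math.sqrt(sw))
    z = est / se
    return PooledResult(
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        z=z,
        p=float(2.0 * stats.norm.sf(abs(z))),
        q=q,
        df=df,
        i_squared=_i_squared(q, df),
        tau_squared=tau2,
        model=model,
        weights=tuple(w_pool / sw),
        study_ids=tuple(e.study_id for e in effects),
        scale=scale,
    )


def pool_fixed(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Fixed-effect inverse-variance pool."""
    scale = _check_effects(effects)
    y = np.array([e.log_effect for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    q, _ = _q_statistic(y, w)
    return _assemble(y, w, q, len(effects) - 1, 0.0, "fixed", effects, scale)


def pool_random_dl(effects: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pool.

    Q, I^2 and tau^2 are computed at the fixed-effect stage and reported
    alongside the random-effects estimate. A homogeneous set (Q <= df)
    yields tau^2 = 0 and reproduces :func:`pool_fixed` exactly.
    """
    scale = _check_effects(effects)
    y = np.array([e.log_effect for e in effects])
    v = np.array([e.se**2 for e in effects])
    w = 1.0 / v
    q, _ = _q_statistic(y, w)
    df = len(effects) - 1
    if df > 0:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    return _assemble(y, w_star, q, df, tau2, "random_dl", effects, scale)


def pool(effects: Sequence[EffectEstimate], model: str = "random_dl") -> PooledResult:
    if model == "fixed":
        return pool_fixed(effects)
    if model in ("random", "random_dl"):
        return pool_random_dl(effects)
    raise DomainError(f"unknown model {model!r} (use 'fixed' or 'random_dl')")


def heterogeneity(effects: Sequence[EffectEstimate]) -> Heterogeneity:
    """Cochran's Q, its chi-square p, and Higgins' I^2, with the joint flag."""
    _check_effects(effects, min_k=2)
    y = np.array([e.log_effect for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    q, _ = _q_statistic(y, w)
    df = len(effects) - 1
    p = float(stats.chi2.sf(q, df))
    i2 = _i_squared(q, df)
    return Heterogeneity(q=q, df=df, p=p, i_squared=i2,
                         significant=(i2 >= I2_THRESHOLD and p < Q_P_THRESHOLD))


def subgroup_difference(
    groups: Sequence[Sequence[EffectEstimate]],
    model: str = "random_dl",
) -> SubgroupComparison:
    """Pool each subgroup, then chi-square test for between-group difference.

    Each subgroup summary enters with weight ``1/se_g^2``; the between-group
    statistic is the weighted dispersion of subgroup estimates around their
    fixed-effect combination, chi-square with ``G-1`` df.
    """
    if len(groups) < 2:
        raise DomainError("need at least 2 subgroups")
    if any(len(g) == 0 for g in groups):
        raise DomainError("every subgroup must be nonempty")
    results = tuple(pool(g, model) for g in groups)
    est = np.array([r.estimate for r in results])
    w = np.array([1.0 / r.se**2 for r in results])
    q_between, _ = _q_statistic(est, w)
    df_between = len(groups) - 1
    return SubgroupComparison(
        results=results,
        q_between=float(q_between),
        df_between=df_between,
        p_between=float(stats.chi2.sf(q_between, df_between)),
    )


def leave_one_out(
    effects: Sequence[EffectEstimate],
    model: str = "random_dl",
) -> List[Tuple[str, PooledResult]]:
    """Sensitivity analysis: re-pool omitting one study at a time.

    Returns ``k`` pairs (omitted study_id, pool of the remaining ``k-1``)
    in input order; each reduced pool carries its own Q and I^2.
    """
    if len(effects) < 2:
        raise DomainError("leave-one-out needs at least 2 studies")
    out = []
    for i, e in enumerate(effects):
        rest = [x for j, x in enumerate(effects) if j != i]
        out.append((e.study_id, pool(rest, model)))
    return out
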