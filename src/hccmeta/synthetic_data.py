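"""Synthetic study-set generators with the structure the analysis assumes.

The survival generator emulates the shape of the source literature: ``k``
retrospective cohorts of 70-300 Asian HCC patients, a dichotomized marker
(about half the patients marker-high), exponential event times under
proportional hazards (per-study true log HR drawn around a global effect
with between-study SD ``tau``), independent exponential censoring truncated
at the study's follow-up, and a digitized-looking Kaplan-Meier curve per arm
on a monthly grid. Because event times are exponential, the per-study
hazard ratio has a closed-form maximum-likelihood estimate (the event
rate ratio) that serves as the "reported HR + 95% CI" of each synthetic
study; the emitted curves let the KM-reconstruction path be tested against
the same truth.

The contingency generator draws per-study 2x2 tables from the multinomial
implied by an exposure probability, a baseline outcome probability and a
true odds ratio via the logistic relation.

All generators are pure functions of their config (including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from lifelines import KaplanMeierFitter

from .errors import ConfigError
from .records import (
    Adjustment,
    ContingencyTable,
    EffectSource,
    KMCurve,
    Method,
    Outcome,
    StudyRecord,
    Z95,
)


@dataclass(frozen=True)
class MetaSimConfig:
    """Survival meta-analysis scenario (defaults mirror the source cohorts)."""

    k_studies: int = 8
    true_log_hr: float = math.log(1.8)
    tau: float = 0.1
    n_per_study: Tuple[int, int] = (70, 300)
    p_high: float = 0.54
    baseline_hazard: float = 0.01  # events per month, marker-low arm
    censoring_rate: float = 0.003  # censorings per month
    max_follow_up: float = 120.0  # months
    seed: int = 0
    emit_curves: bool = True

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ConfigError("k_studies must be positive")
        if not (0 < self.p_high < 1):
            raise ConfigError("p_high must be in (0, 1)")
        if self.baseline_hazard <= 0 or self.censoring_rate < 0:
            raise ConfigError("rates must be positive (censoring may be 0)")
        if self.tau < 0:
            raise ConfigError("tau must be nonnegative")
        if self.max_follow_up <= 0:
            raise ConfigError("max_follow_up must be positive")
        lo, hi = self.n_per_study
        if not (2 <= lo <= hi):
            raise ConfigError("n_per_study must satisfy 2 <= lo <= hi")
        # a study must be expected to produce events in both arms
        expected_events = lo * min(self.p_high, 1 - self.p_high) * (
            1 - math.exp(-self.baseline_hazard * self.max_follow_up)
        )
        if expected_events < 1:
            raise ConfigError(
                "degenerate config: fewer than one event expected per arm "
                f"(~{expected_events:.2f})"
            )


@dataclass(frozen=True)
class ContingencySimConfig:
    """Clinicopathologic 2x2 scenario (defaults mirror the TNM analysis)."""

    k_studies: int = 8
    true_or: float = 1.7
    p_exposure: float = 0.54
    p_outcome_baseline: float = 0.30
    n_per_study: Tuple[int, int] = (70, 300)
    feature: str = "TNM_stage"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ConfigError("k_studies must be positive")
        if self.true_or <= 0:
            raise ConfigError("true_or must be positive")
        for name in ("p_exposure", "p_outcome_baseline"):
            if not (0 < getattr(self, name) < 1):
                raise ConfigError(f"{name} must be in (0, 1)")
        if any(not (0 < p < 1) for p in self.cell_probabilities()):
            raise ConfigError("implied cell probabilities fall outside (0, 1)")

    def cell_probabilities(self) -> np.ndarray:
        """Multinomial cell probabilities (a, b, c, d) implied by the config."""
        p0 = self.p_outcome_baseline
        odds1 = self.true_or * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        pe = self.p_exposure
        return np.array([pe * p1, pe * (1 - p1), (1 - pe) * p0, (1 - pe) * (1 - p0)])


def exponential_hr_fit(
    time: np.ndarray, event: np.ndarray, high: np.ndarray
) -> Tuple[float, float]:
    """Closed-form proportional-hazards fit for exponential event times.

    The MLE of the log hazard ratio is the log event-rate ratio
    ``ln((d1/T1)/(d0/T0))`` with variance ``1/d1 + 1/d0`` (d = events,
    T = person-time at risk per arm).
    """
    high = np.asarray(high, dtype=bool)
    d1 = float(np.sum(event[high]))
    d0 = float(np.sum(event[~high]))
    if d1 == 0 or d0 == 0:
        raise ConfigError("no events in one arm; hazard ratio undefined")
    t1 = float(np.sum(time[high]))
    t0 = float(np.sum(time[~high]))
    return math.log((d1 / t1) / (d0 / t0)), math.sqrt(1.0 / d1 + 1.0 / d0)


def _km_curve(
    arm_label: str, time: np.ndarray, event: np.ndarray, grid: np.ndarray
) -> KMCurve:
    """Product-limit curve evaluated on a monthly grid (digitizer-like)."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    surv = np.clip(surv, 0.0, 1.0)
    points = tuple(zip(grid.tolist(), surv.tolist()))
    return KMCurve(arm_label=arm_label, points=points, n_at_risk_initial=int(len(time)))


def simulate_meta_studies(
    config: MetaSimConfig,
) -> Tuple[List[StudyRecord], Dict[str, float]]:
    """Generate ``k`` survival studies; returns (records, true log HR per study).

    Each record carries two effect sources for OS: the closed-form
    "reported" HR + 95% CI, and the digitized KM curve pair (when
    ``emit_curves``), so both extraction paths see the same patients.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.n_per_study
    grid = np.arange(0.0, config.max_follow_up + 1.0)
    studies: List[StudyRecord] = []
    truths: Dict[str, float] = {}
    for i in range(config.k_studies):
        study_id = f"sim{i + 1:02d}"
        n = int(rng.integers(lo, hi + 1))
        theta = float(rng.normal(config.true_log_hr, config.tau))
        high = rng.random(n) < config.p_high
        if high.all() or (~high).all():  # tiny studies: force both arms occupied
            high[int(rng.integers(n))] = not high[0]
        hazard = config.baseline_hazard * np.exp(theta * high)
        t_event = rng.exponential(1.0 / hazard)
        if config.censoring_rate > 0:
            t_cens = rng.exponential(1.0 / config.censoring_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        t_cens = np.minimum(t_cens, config.max_follow_up)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

        log_hr, se = exponential_hr_fit(time, event, high)
        sources = [
            EffectSource(
                outcome=Outcome.OS,
                adjustment=Adjustment.UNIVARIATE,
                hr=math.exp(log_hr),
                ci_low=math.exp(log_hr - Z95 * se),
                ci_high=math.exp(log_hr + Z95 * se),
            )
        ]
        if config.emit_curves:
            curve_high = _km_curve("high", time[high], event[high], grid)
            curve_low = _km_curve("low", time[~high], event[~high], grid)
            sources.append(
                EffectSource(
                    outcome=Outcome.OS,
                    adjustment=Adjustment.CURVE_DERIVED,
                    km_curves=(curve_high, curve_low),
                )
            )
        n_high = int(high.sum())
        n_male = int(rng.binomial(n, 0.85))
        studies.append(
            StudyRecord(
                study_id=study_id,
                first_author=f"Synth{i + 1}",
                year=int(2011 + (i % 6)),
                n_total=n,
                n_male=n_male,
                n_female=n - n_male,
                n_high=n_high,
                n_low=n - n_high,
                method=Method.IHC,
                follow_up_months=config.max_follow_up,
                outcomes=frozenset({Outcome.OS}),
                nos_score=int(rng.integers(4, 10)),
                effect_sources=tuple(sources),
            )
        )
        truths[study_id] = theta
    return studies, truths


def simulate_contingency_studies(config: ContingencySimConfig) -> List[ContingencyTable]:
    """Generate ``k`` 2x2 tables from the configured multinomial."""
    rng = np.random.default_rng(config.seed)
    probs = config.cell_probabilities()
    lo, hi = config.n_per_study
    tables: List[ContingencyTable] = []
    for i in range(config.k_studies):
        n = int(rng.integers(lo, hi + 1))
        cells = rng.multinomial(n, probs)
        tables.append(
            ContingencyTable(
                study_id=f"sim{i + 1:02d}",
                feature=config.feature,
                a=int(cells[0]),
                b=int(cells[1]),
                c=int(cells[2]),
                d=int(cells[3]),
            )
        )
    return tables
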