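"""Domain record types shared across the pipeline.

The records mirror what a reviewer extracts from published studies of a
dichotomized tumor marker: per-study patient counts and assay metadata
(:class:`StudyRecord`), every reported form of survival evidence
(:class:`EffectSource`, :class:`KMCurve`), per-feature 2x2 tables
(:class:`ContingencyTable`), and the common log-scale currency all evidence
is converted into before pooling (:class:`EffectEstimate`).

All types are frozen dataclasses validated on construction; invalid records
raise :class:`~hccmeta.errors.ValidationError` naming the study and field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .errors import ValidationError

#: Two-sided 95% normal quantile, kept at full precision so that
#: CI -> SE -> CI round-trips reproduce the input to display precision.
Z95 = 1.959964


class Method(str, Enum):
    """Assay used to dichotomize marker expression."""

    IHC = "IHC"
    WESTERN_BLOT = "western_blot"
    OTHER = "other"


class Outcome(str, Enum):
    """Time-to-event endpoint reported by a study.

    ``NONE`` marks a study whose survival data were not reported ("NR");
    such studies still contribute to counting and clinicopathologic
    analyses but never to survival pooling.
    """

    OS = "OS"
    DFS = "DFS"
    NONE = "none"


class Adjustment(str, Enum):
    """Provenance of a reported hazard ratio.

    Multivariate estimates adjust for confounders and take precedence over
    univariate ones; ``CURVE_DERIVED`` marks ratios reconstructed from
    digitized survival curves and ranks last.
    """

    MULTIVARIATE = "multivariate"
    UNIVARIATE = "univariate"
    CURVE_DERIVED = "curve_derived"


class Scale(str, Enum):
    """Log scale of an effect estimate."""

    LOG_HR = "log_hr"
    LOG_OR = "log_or"


class EffectOrigin(str, Enum):
    """How an :class:`EffectEstimate` was obtained."""

    REPORTED_CI = "reported_ci"
    CONTINGENCY = "contingency"
    KM_CURVE = "km_curve"


@dataclass(frozen=True)
class KMCurve:
    """A digitized Kaplan-Meier curve for one study arm.

    ``points`` are (time in months, survival probability) pairs as read off
    the published figure; times must strictly increase from 0 where the
    survival is 1.0, and survival must be non-increasing within [0, 1].
    ``at_risk_times`` optionally carries the numbers-at-risk row printed
    under the figure.
    """

    arm_label: str
    points: tuple
    n_at_risk_initial: int
    at_risk_times: Optional[tuple] = None

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(s)) for t, s in self.points)
        object.__setattr__(self, "points", pts)
        if self.at_risk_times is not None:
            object.__setattr__(
                self,
                "at_risk_times",
                tuple((float(t), float(n)) for t, n in self.at_risk_times),
            )
        if not pts:
            raise ValidationError(f"KM curve {self.arm_label!r}: no points")
        times = [t for t, _ in pts]
        survs = [s for _, s in pts]
        if times[0] != 0.0 or survs[0] != 1.0:
            raise ValidationError(
                f"KM curve {self.arm_label!r}: must start at (0, 1.0), got "
                f"({times[0]}, {survs[0]})"
            )
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"KM curve {self.arm_label!r}: times not strictly increasing"
            )
        if any(not (0.0 <= s <= 1.0) for s in survs):
            raise ValidationError(
                f"KM curve {self.arm_label!r}: survival outside [0, 1]"
            )
        if any(s1 < s2 - 1e-12 for s1, s2 in zip(survs, survs[1:])):
            raise ValidationError(
                f"KM curve {self.arm_label!r}: survival increases"
            )
        if self.n_at_risk_initial <= 0:
            raise ValidationError(
                f"KM curve {self.arm_label!r}: n_at_risk_initial must be positive"
            )

    @property
    def times(self) -> tuple:
        return tuple(t for t, _ in self.points)

    @property
    def survival(self) -> tuple:
        return tuple(s for _, s in self.points)


@dataclass(frozen=True)
class EffectSource:
    """One reported piece of survival evidence for one endpoint.

    Either a hazard ratio with its 95% CI, or a pair of digitized KM curves
    (marker-high arm, marker-low arm) from which one can be reconstructed.
    """

    outcome: Outcome
    adjustment: Adjustment
    hr: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    km_curves: Optional[tuple] = None  # (high: KMCurve, low: KMCurve)

    def __post_init__(self) -> None:
        if self.outcome not in (Outcome.OS, Outcome.DFS):
            raise ValidationError(f"effect source outcome must be OS or DFS, got {self.outcome}")
        has_hr = self.hr is not None
        if has_hr:
            if self.ci_low is None or self.ci_high is None:
                raise ValidationError("effect source with hr must carry both CI bounds")
            if not (0 < self.ci_low <= self.hr <= self.ci_high):
                raise ValidationError(
                    f"effect source CI disordered: {self.ci_low} <= {self.hr} <= {self.ci_high} fails"
                )
        if not has_hr and self.km_curves is None:
            raise ValidationError("effect source needs a reported HR+CI or KM curves")
        if self.km_curves is not None and len(self.km_curves) != 2:
            raise ValidationError("km_curves must be a (high, low) pair")


@dataclass(frozen=True)
class StudyRecord:
    """One source study of the marker, as transcribed from its publication."""

    study_id: str
    first_author: str
    year: int
    n_total: int
    n_high: int
    n_low: int
    method: Method
    outcomes: frozenset
    n_male: Optional[int] = None
    n_female: Optional[int] = None
    follow_up_months: Optional[float] = None
    nos_score: Optional[int] = None
    effect_sources: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", frozenset(Outcome(o) for o in self.outcomes))
        object.__setattr__(self, "effect_sources", tuple(self.effect_sources))
        sid = self.study_id

        def bad(fieldname: str, msg: str) -> ValidationError:
            return ValidationError(f"study {sid!r}, field {fieldname!r}: {msg}")

        if not sid:
            raise ValidationError("study_id must be nonempty")
        for name in ("n_total", "n_high", "n_low"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise bad(name, f"must be a nonnegative integer, got {v!r}")
        # Equality holds when expression status is known for every patient;
        # strict inequality is accepted (one study reports 153+98=251 of 252).
        if self.n_high + self.n_low > self.n_total:
            raise bad("n_high", f"n_high + n_low = {self.n_high + self.n_low} exceeds n_total = {self.n_total}")
        if not (1900 <= self.year <= 2100):
            raise bad("year", f"{self.year} outside [1900, 2100]")
        if self.nos_score is not None and not (0 <= self.nos_score <= 9):
            raise bad("nos_score", f"{self.nos_score} outside [0, 9]")
        if self.follow_up_months is not None and self.follow_up_months <= 0:
            raise bad("follow_up_months", "must be positive when present")
        for name in ("n_male", "n_female"):
            v = getattr(self, name)
            if v is not None and (not isinstance(v, int) or v < 0):
                raise bad(name, f"must be a nonnegative integer or missing, got {v!r}")
        if not self.outcomes:
            raise bad("outcomes", "must be nonempty (use {none} for unreported survival data)")
        if Outcome.NONE in self.outcomes and len(self.outcomes) > 1:
            raise bad("outcomes", "'none' cannot be combined with real endpoints")

    def has_survival(self, outcome: Outcome) -> bool:
        return outcome in self.outcomes


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure (marker-high) x outcome counts for one study and feature.

    Cell layout: ``a`` exposed-with-outcome, ``b`` exposed-without,
    ``c`` unexposed-with, ``d`` unexposed-without. The outcome convention is
    feature-specific (e.g. for TNM stage, "outcome" = stage III-IV) and is
    declared in the source file's header.
    """

    study_id: str
    feature: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(
                    f"study {self.study_id!r}, feature {self.feature!r}, cell {name!r}: "
                    f"must be a nonnegative integer, got {v!r}"
                )
        if self.total == 0:
            raise ValidationError(
                f"study {self.study_id!r}, feature {self.feature!r}: all four cells are zero"
            )

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EffectEstimate:
    """A log-scale effect (log HR or log OR) with its standard error."""

    study_id: str
    outcome_or_feature: str
    log_effect: float
    se: float
    scale: Scale
    source: EffectOrigin

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_effect):
            raise ValidationError(f"study {self.study_id!r}: log_effect not finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValidationError(f"study {self.study_id!r}: se must be positive and finite, got {self.se}")

    @property
    def ratio(self) -> float:
        """Back-transformed effect (HR or OR)."""
        return math.exp(self.log_effect)

    def ci(self, z: float = Z95) -> tuple:
        """95% CI on the ratio scale."""
        return (math.exp(self.log_effect - z * self.se), math.exp(self.log_effect + z * self.se))
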