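"""Declarative subgroup rules over study records.

A rule is a conjunction of range predicates on declared study fields plus a
required endpoint. All ``*_min`` bounds are inclusive and ``*_max`` bounds
exclusive, so complementary pairs like "subjects < 150" / "subjects >= 150"
partition a study set exactly. Studies missing a tested field (e.g. no
follow-up reported) never satisfy a rule that tests it, and studies with no
survival data never satisfy a rule requiring an endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import List, Optional, Sequence, Tuple

from .errors import RuleError
from .records import Outcome, StudyRecord


@dataclass(frozen=True)
class SubgroupRule:
    """Conjunctive filter; ``None`` bounds are inactive."""

    name: str
    outcome: Optional[Outcome] = None  # study must report this endpoint
    year_min: Optional[int] = None
    year_max: Optional[int] = None  # exclusive
    n_total_min: Optional[int] = None
    n_total_max: Optional[int] = None  # exclusive
    follow_up_min: Optional[float] = None
    follow_up_max: Optional[float] = None  # exclusive
    nos_min: Optional[int] = None
    nos_max: Optional[int] = None  # exclusive

    def __post_init__(self) -> None:
        if self.outcome is not None:
            object.__setattr__(self, "outcome", Outcome(self.outcome))

    @classmethod
    def from_dict(cls, d: dict) -> "SubgroupRule":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise RuleError(
                f"rule {d.get('name', '?')!r} references unknown fields: {sorted(unknown)}"
            )
        if "name" not in d:
            raise RuleError("rule needs a 'name'")
        return cls(**d)

    def matches(self, study: StudyRecord) -> bool:
        if self.outcome is not None and self.outcome not in study.outcomes:
            return False
        checks = [
            (self.year_min, self.year_max, study.year),
            (self.n_total_min, self.n_total_max, study.n_total),
            (self.follow_up_min, self.follow_up_max, study.follow_up_months),
            (self.nos_min, self.nos_max, study.nos_score),
        ]
        for lo, hi, value in checks:
            if lo is None and hi is None:
                continue
            if value is None:
                return False  # field tested but not reported
            if lo is not None and value < lo:
                return False
            if hi is not None and value >= hi:
                return False
        return True


def filter_studies(
    studies: Sequence[StudyRecord], rule: SubgroupRule
) -> Tuple[List[StudyRecord], int]:
    """Apply a rule; returns (selected studies in order, their patient total)."""
    selected = [s for s in studies if rule.matches(s)]
    return selected, sum(s.n_total for s in selected)


def standard_subgroup_comparisons() -> List[Tuple[str, List[SubgroupRule]]]:
    """The canonical OS subgroup pairs: publication year, cohort size,
    follow-up length, and study quality (NOS > 6 = high quality)."""
    os = Outcome.OS
    return [
        ("publication_year", [
            SubgroupRule("before_2015", outcome=os, year_max=2015),
            SubgroupRule("2015_2016", outcome=os, year_min=2015, year_max=2017),
        ]),
        ("subjects", [
            SubgroupRule("subjects_lt150", outcome=os, n_total_max=150),
            SubgroupRule("subjects_ge150", outcome=os, n_total_min=150),
        ]),
        ("follow_up", [
            SubgroupRule("follow_up_lt100", outcome=os, follow_up_max=100),
            SubgroupRule("follow_up_ge100", outcome=os, follow_up_min=100),
        ]),
        ("quality", [
            SubgroupRule("high_quality", outcome=os, nos_min=7),
            SubgroupRule("other_quality", outcome=os, nos_max=7),
        ]),
    ]
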