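"""Bootstrap re-sampling of pooled 2x2 tables.

The procedure validates a marker/feature association by (1) expanding the
per-study contingency tables into patient-level (exposure, outcome) pairs,
(2) drawing ``n_groups`` resample groups of ``group_size`` patients each
with replacement from the pooled patient pool, (3) computing the odds ratio
of every group (the spread of this distribution shows the robustness of the
association), and (4) tabulating one combined 2x2 over all
``n_groups x group_size`` draws whose Woolf CI gives the headline combined
odds ratio. With the default 1000 x 5000 configuration the combined table
holds five million samples and its CI is razor-thin around the plug-in OR
of the input tables.

Each group is drawn as a multinomial over the four cell probabilities,
which is exactly a with-replacement draw of ``group_size`` patient pairs;
per-group RNG streams are spawned deterministically from the root seed, so
results do not depend on execution order or parallelization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .errors import DomainError
from .meta_engine import PooledResult, pool_fixed
from .records import (
    ContingencyTable,
    EffectEstimate,
    EffectOrigin,
    Scale,
    Z95,
)

# patient-pair cell order: a=(1,1) b=(1,0) c=(0,1) d=(0,0)
_CELL_PAIRS = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int64)


@dataclass(frozen=True)
class ResampleConfig:
    """Configuration of the re-sampling run (defaults: 1000 x 5000 = 5M)."""

    n_groups: int = 1000
    group_size: int = 5000
    seed: int = 0
    correction: float = 0.5
    stratified: bool = False  # resample within study instead of the pooled pool

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.group_size < 1:
            raise DomainError("n_groups and group_size must be positive")
        if self.correction < 0:
            raise DomainError("correction must be nonnegative")

    @property
    def total_samples(self) -> int:
        return self.n_groups * self.group_size


@dataclass(frozen=True)
class ResampleResult:
    """Per-group OR distribution plus the combined-sample OR."""

    group_ors: tuple
    group_log_ses: tuple  # Woolf SE of each group's log OR
    or_min: float
    or_max: float
    combined_table: tuple  # (a, b, c, d) over all draws
    combined_or: float
    combined_ci_low: float
    combined_ci_high: float
    combined_p: float
    n_degenerate_groups: int  # groups with an undefined OR (zero cell, correction 0)
    config: ResampleConfig

    @property
    def ci_width(self) -> float:
        return self.combined_ci_high - self.combined_ci_low


def reconstruct_patients(tables: Sequence[ContingencyTable]) -> np.ndarray:
    """Expand 2x2 tables into patient-level (exposure, outcome) pairs.

    Order is deterministic: studies in input order, cells a, b, c, d within
    each study. Returns an integer array of shape (sum of cell totals, 2).
    """
    if not tables:
        raise DomainError("reconstruct_patients: no tables supplied")
    features = {t.feature for t in tables}
    if len(features) > 1:
        raise DomainError(f"tables mix features: {sorted(features)}")
    blocks = [np.repeat(_CELL_PAIRS, t.cells, axis=0) for t in tables]
    return np.concatenate(blocks, axis=0)


def tabulate_pairs(pairs: np.ndarray) -> Tuple[int, int, int, int]:
    """Count pairs back into (a, b, c, d)."""
    pairs = np.asarray(pairs)
    a = int(np.sum((pairs[:, 0] == 1) & (pairs[:, 1] == 1)))
    b = int(np.sum((pairs[:, 0] == 1) & (pairs[:, 1] == 0)))
    c = int(np.sum((pairs[:, 0] == 0) & (pairs[:, 1] == 1)))
    d = int(np.sum((pairs[:, 0] == 0) & (pairs[:, 1] == 0)))
    return a, b, c, d


def _or_and_se(cells: Sequence[float], correction: float) -> Tuple[Optional[float], Optional[float]]:
    """(OR, Woolf SE of log OR), or (None, None) if undefined."""
    vals = [float(x) for x in cells]
    if any(x == 0 for x in vals):
        if correction == 0:
            return None, None
        vals = [x + correction for x in vals]
    a, b, c, d = vals
    return (a * d) / (b * c), math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def _check_pairs_nondegenerate(counts: Tuple[int, int, int, int]) -> None:
    a, b, c, d = counts
    if a + b == 0 or c + d == 0:
        raise DomainError("patient pool contains a single exposure level")
    if a + c == 0 or b + d == 0:
        raise DomainError("patient pool contains a single outcome level")


def bootstrap_or(
    pairs: Union[np.ndarray, Sequence[np.ndarray]],
    config: ResampleConfig,
) -> ResampleResult:
    """Run the seeded re-sampling procedure over a patient pool.

    ``pairs`` is the array from :func:`reconstruct_patients`; with
    ``config.stratified`` it is a sequence of per-study arrays and each
    group allocates its draws across studies proportionally to study size.
    """
    if config.stratified:
        strata = [np.asarray(p) for p in pairs]
        counts_per_stratum = [np.array(tabulate_pairs(p), dtype=float) for p in strata]
        pooled_counts = tuple(int(x) for x in np.sum(counts_per_stratum, axis=0))
        sizes = np.array([p.shape[0] for p in strata], dtype=float)
        alloc = np.floor(config.group_size * sizes / sizes.sum()).astype(int)
        # hand leftover draws to the largest strata, deterministically
        for i in np.argsort(-sizes)[: config.group_size - alloc.sum()]:
            alloc[i] += 1
        probs_list = [c / c.sum() for c in counts_per_stratum]
    else:
        pooled_counts = tabulate_pairs(np.asarray(pairs))
        probs_list = [np.array(pooled_counts, dtype=float) / sum(pooled_counts)]
        alloc = np.array([config.group_size])
    _check_pairs_nondegenerate(pooled_counts)

    streams = np.random.SeedSequence(config.seed).spawn(config.n_groups)
    group_ors: List[float] = []
    group_ses: List[float] = []
    combined = np.zeros(4, dtype=np.int64)
    n_degenerate = 0
    for ss in streams:
        rng = np.random.Generator(np.random.PCG64(ss))
        table = np.zeros(4, dtype=np.int64)
        for n_draw, probs in zip(alloc, probs_list):
            if n_draw:
                table += rng.multinomial(int(n_draw), probs)
        combined += table
        or_g, se_g = _or_and_se(table, config.correction)
        if or_g is None:
            n_degenerate += 1
        else:
            group_ors.append(or_g)
            group_ses.append(se_g)
    if not group_ors:
        raise DomainError("every resample group had an undefined OR")

    or_c, se_c = _or_and_se(combined, config.correction)
    if or_c is None:
        raise DomainError("combined table has a zero cell with correction 0")
    log_or = math.log(or_c)
    z = log_or / se_c
    return ResampleResult(
        group_ors=tuple(group_ors),
        group_log_ses=tuple(group_ses),
        or_min=min(group_ors),
        or_max=max(group_ors),
        combined_table=tuple(int(x) for x in combined),
        combined_or=or_c,
        combined_ci_low=math.exp(log_or - Z95 * se_c),
        combined_ci_high=math.exp(log_or + Z95 * se_c),
        combined_p=float(2.0 * stats.norm.sf(abs(z))),
        n_degenerate_groups=n_degenerate,
        config=config,
    )


def resample_meta(result: ResampleResult) -> PooledResult:
    """Pool the group ORs as pseudo-studies (fixed model, Woolf SEs).

    Mirrors presenting the resample groups as a forest plot: each group is
    one line, and the fixed-effect summary should agree with the
    combined-table OR to within Monte-Carlo error.
    """
    effects = [
        EffectEstimate(
            study_id=f"group_{i:04d}",
            outcome_or_feature="resample",
            log_effect=math.log(or_g),
            se=se_g,
            scale=Scale.LOG_OR,
            source=EffectOrigin.CONTINGENCY,
        )
        for i, (or_g, se_g) in enumerate(zip(result.group_ors, result.group_log_ses))
    ]
    if len(effects) < 2:
        raise DomainError("resample_meta needs at least 2 usable groups")
    return pool_fixed(effects)


def write_group_ors(result: ResampleResult, path) -> None:
    """Group-OR distribution as TSV (group index, OR)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\tor\n")
        for i, or_g in enumerate(result.group_ors):
            fh.write(f"{i}\t{or_g:.6g}\n")


def summary_dict(result: ResampleResult) -> dict:
    """JSON-ready summary: distribution extremes/quantiles, combined OR, config."""
    ors = np.array(result.group_ors)
    q = np.quantile(ors, [0.025, 0.25, 0.5, 0.75, 0.975])
    return {
        "n_groups": result.config.n_groups,
        "group_size": result.config.group_size,
        "total_samples": result.config.total_samples,
        "seed": result.config.seed,
        "correction": result.config.correction,
        "stratified": result.config.stratified,
        "or_min": result.or_min,
        "or_max": result.or_max,
        "or_quantiles": {"2.5%": q[0], "25%": q[1], "50%": q[2], "75%": q[3], "97.5%": q[4]},
        "combined_or": result.combined_or,
        "combined_ci_low": result.combined_ci_low,
        "combined_ci_high": result.combined_ci_high,
        "combined_p": result.combined_p,
        "n_degenerate_groups": result.n_degenerate_groups,
    }


def write_summary(result: ResampleResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary_dict(result), fh, indent=1, default=float)
        fh.write("\n")
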