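"""End-to-end report pipeline: extract -> pool -> subgroups -> sensitivity ->
publication bias -> resampling, with every output row carrying provenance
(model, evidence source, seed).

The pipeline consumes a YAML/JSON config naming the input files and writes
TSV tables (overall pools, subgroup comparisons, leave-one-out, bias tests,
funnel data, group-OR distribution) plus one machine-readable
``summary.json`` into the output directory. Reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import yaml

from . import meta_engine, publication_bias, resampling
from .effect_extraction import effect_from_source, select_effect
from .errors import ConfigError, EffectLookupError
from .records import EffectEstimate, Outcome, StudyRecord
from .study_io import format_sig4, load_contingency_tables, load_studies
from .subgroups import SubgroupRule, filter_studies, standard_subgroup_comparisons

_POOL_HEADER = (
    "label\tn_studies\tn_patients\tratio\tci_low\tci_high\tp\tz\tq\tdf\t"
    "i_squared\ttau_squared\tmodel\tseed\n"
)


def _pool_row(
    label: str,
    result: meta_engine.PooledResult,
    n_patients: int,
    seed: int,
) -> str:
    lo, hi = result.ratio_ci
    cols = [
        label,
        str(len(result.study_ids)),
        str(n_patients),
        format_sig4(result.ratio),
        format_sig4(lo),
        format_sig4(hi),
        format_sig4(result.p),
        format_sig4(result.z),
        format_sig4(result.q),
        str(result.df),
        format_sig4(result.i_squared),
        format_sig4(result.tau_squared),
        result.model,
        str(seed),
    ]
    return "\t".join(cols) + "\n"


def study_effects(
    studies: Sequence[StudyRecord],
    outcome: Outcome,
    n_intervals: int = 5,
) -> List[EffectEstimate]:
    """Best available effect per study for one endpoint, precedence applied.

    Studies not reporting the endpoint (including 'NR' studies) are skipped.
    """
    effects = []
    for s in studies:
        if outcome not in s.outcomes:
            continue
        try:
            src = select_effect(s.effect_sources, outcome)
        except EffectLookupError:
            continue  # endpoint listed but no usable evidence
        effects.append(effect_from_source(src, study_id=s.study_id, n_intervals=n_intervals))
    return effects


def _pooled_to_dict(r: meta_engine.PooledResult) -> dict:
    lo, hi = r.ratio_ci
    return {
        "ratio": r.ratio, "ci_low": lo, "ci_high": hi,
        "log_estimate": r.estimate, "se": r.se, "z": r.z, "p": r.p,
        "q": r.q, "df": r.df, "i_squared": r.i_squared,
        "tau_squared": r.tau_squared, "model": r.model, "k": len(r.study_ids),
    }


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def run_pipeline(config, out_dir=None) -> dict:
    """Run the full analysis described by ``config`` (mapping or file path).

    Config keys: ``studies`` (path, required); ``contingency`` (path,
    optional); ``model`` (fixed | random_dl, default random_dl); ``seed``
    (default 0); ``n_intervals`` (KM reconstruction, default 5);
    ``subgroups`` (list of {name, rules: [...]}; default: the standard
    year/size/follow-up/quality pairs); ``resample`` ({n_groups,
    group_size, correction}, optional); ``out_dir`` (required unless passed
    as argument). Returns the summary dict it also writes as JSON.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir or config.get("out_dir") or _missing(config, "out_dir"))
    out_dir.mkdir(parents=True, exist_ok=True)

    studies_path = config.get("studies") or _missing(config, "studies")
    if not Path(studies_path).exists():
        raise ConfigError(f"missing input file: {studies_path}")
    studies = load_studies(studies_path)
    model = config.get("model", "random_dl")
    seed = int(config.get("seed", 0))
    n_intervals = int(config.get("n_intervals", 5))

    summary: dict = {
        "provenance": {
            "model": model,
            "tau_estimator": "DerSimonian-Laird",
            "seed": seed,
            "n_intervals": n_intervals,
            "studies": str(studies_path),
        },
        "outcomes": {},
        "subgroups": {},
        "leave_one_out": [],
        "publication_bias": {},
        "notes": [],
    }

    excluded = [s.study_id for s in studies if Outcome.NONE in s.outcomes]
    if excluded:
        summary["notes"].append(
            "excluded from survival pooling (no survival data reported): "
            + ", ".join(excluded)
        )

    # ---- overall pools, per endpoint, both models emitted -------------------
    effects_by_outcome: Dict[Outcome, List[EffectEstimate]] = {}
    with open(out_dir / "overall.tsv", "w", encoding="utf-8") as fh:
        fh.write(_POOL_HEADER)
        for outcome in (Outcome.OS, Outcome.DFS):
            effects = study_effects(studies, outcome, n_intervals)
            if not effects:
                continue
            effects_by_outcome[outcome] = effects
            ids = {e.study_id for e in effects}
            n_patients = sum(s.n_total for s in studies if s.study_id in ids)
            entry = {"n_patients": n_patients}
            for m in ("fixed", "random_dl"):
                result = meta_engine.pool(effects, m)
                fh.write(_pool_row(f"{outcome.value}_overall", result, n_patients, seed))
                entry[m] = _pooled_to_dict(result)
            summary["outcomes"][outcome.value] = entry

    # ---- subgroup comparisons ----------------------------------------------
    if "subgroups" in config:
        comparisons = [
            (c["name"], [SubgroupRule.from_dict(r) for r in c["rules"]])
            for c in config["subgroups"]
        ]
    else:
        comparisons = standard_subgroup_comparisons()
    with open(out_dir / "subgroups.tsv", "w", encoding="utf-8") as fh:
        fh.write("comparison\t" + _POOL_HEADER.replace("label", "subgroup", 1))
        for comp_name, rules in comparisons:
            groups, totals, labels = [], [], []
            for rule in rules:
                sel, n_pat = filter_studies(studies, rule)
                eff = study_effects(sel, rule.outcome or Outcome.OS, n_intervals)
                if eff:
                    groups.append(eff)
                    totals.append(n_pat)
                    labels.append(rule.name)
            if len(groups) < 2:
                summary["notes"].append(
                    f"subgroup comparison {comp_name!r} skipped: fewer than 2 nonempty groups"
                )
                continue
            comp = meta_engine.subgroup_difference(groups, model)
            entry = {"groups": {}, "q_between": comp.q_between,
                     "df_between": comp.df_between, "p_between": comp.p_between}
            for label, result, n_pat in zip(labels, comp.results, totals):
                fh.write(comp_name + "\t" + _pool_row(label, result, n_pat, seed))
                entry["groups"][label] = dict(_pooled_to_dict(result), n_patients=n_pat)
            summary["subgroups"][comp_name] = entry

    # ---- leave-one-out sensitivity (primary endpoint) -----------------------
    os_effects = effects_by_outcome.get(Outcome.OS, [])
    if len(os_effects) >= 2:
        with open(out_dir / "leave_one_out.tsv", "w", encoding="utf-8") as fh:
            fh.write(_POOL_HEADER.replace("label", "omitted", 1))
            for omitted, result in meta_engine.leave_one_out(os_effects, model):
                fh.write(_pool_row(omitted, result, 0, seed))
                summary["leave_one_out"].append(
                    dict(_pooled_to_dict(result), omitted=omitted)
                )

    # ---- publication bias (k >= 3 only) -------------------------------------
    with open(out_dir / "publication_bias.tsv", "w", encoding="utf-8") as fh:
        fh.write("outcome\tk\tbegg_z\tbegg_p\tegger_intercept\tegger_t\tegger_df\tegger_p\n")
        for outcome, effects in effects_by_outcome.items():
            if len(effects) < 3:
                summary["notes"].append(
                    f"publication bias for {outcome.value} skipped: k < 3"
                )
                continue
            r = publication_bias.bias_tests(effects)
            fh.write(
                f"{outcome.value}\t{len(effects)}\t{format_sig4(r.begg_z)}\t"
                f"{format_sig4(r.begg_p)}\t{format_sig4(r.egger_intercept)}\t"
                f"{format_sig4(r.egger_t)}\t{r.egger_df}\t{format_sig4(r.egger_p)}\n"
            )
            summary["publication_bias"][outcome.value] = r.__dict__.copy()
            publication_bias.funnel_table(effects).to_csv(
                out_dir / f"funnel_{outcome.value}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )

    # ---- resampling ----------------------------------------------------------
    if config.get("contingency"):
        cpath = Path(config["contingency"])
        if not cpath.exists():
            raise ConfigError(f"missing input file: {cpath}")
        tables = load_contingency_tables(cpath)
        rs_cfg_raw = config.get("resample", {})
        rs_cfg = resampling.ResampleConfig(
            n_groups=int(rs_cfg_raw.get("n_groups", 1000)),
            group_size=int(rs_cfg_raw.get("group_size", 5000)),
            seed=seed,
            correction=float(rs_cfg_raw.get("correction", 0.5)),
            stratified=bool(rs_cfg_raw.get("stratified", False)),
        )
        pairs = resampling.reconstruct_patients(tables)
        result = resampling.bootstrap_or(pairs, rs_cfg)
        resampling.write_group_ors(result, out_dir / "resample_groups.tsv")
        resampling.write_summary(result, out_dir / "resample_summary.json")
        summary["resample"] = resampling.summary_dict(result)

    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, default=float, sort_keys=True)
        fh.write("\n")
    return summary


def _missing(config: dict, key: str):
    raise ConfigError(f"config is missing required key {key!r}")
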