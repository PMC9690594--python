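"""End-to-end orchestration of the two-study design.

Study 1: Hardy-Weinberg screen, case-control association grid, data-driven
score-model construction, per-group TGS summaries with the >= 50-point
proportion, and (when individual-level data are present) performance
analyses.  Study 2: apply a *fixed* score model to an independent case
group; no re-fitting.

Every report table is regenerated deterministically from the inputs; TSV
output rounds p-values to 3 decimals and TGS to 2 (JSON keeps full
precision).
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._errors import EmptyGroupError, EmptyModelError, PanelMismatchError, TgskitError
from .association import (
    ALPHA,
    AssociationResult,
    HweResult,
    SCREEN_MODELS,
    bonferroni,
    hwe_screen,
    run_case_control_screen,
    screen_frame,
)
from .genotype_data import (
    Cohort,
    CountTable,
    count_table_from_cohort,
    derive_national,
    load_fixture_table2,
    read_cohort,
)
from .group_comparison import (
    GroupComparison,
    anova_with_trend,
    genotype_performance_compare,
    regress_performance_on_tgs,
    two_group_t,
)
from .synthetic_cohort import SimulationConfig, simulate_study
from .tgs import (
    ScoreTable,
    TgsSummary,
    WrmSelection,
    build_wrm,
    compare_threshold_proportions,
    empirical_proportion_at_least,
    load_score_tables,
    proportion_at_least,
    tgs_cohort,
    tgs_summaries,
)

CONTROL_GROUP = "control"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a pipeline run; exactly one input mode is active."""

    mode: str  # "fixture" | "cohort" | "simulate"
    cohort_path: str | None = None
    simulation: SimulationConfig | None = None
    alpha: float = ALPHA
    models: Sequence[str] = SCREEN_MODELS
    bonferroni_m: int | None = None
    threshold: float = 50.0
    out_dir: str | None = None
    formats: Sequence[str] = ("tsv", "json")

    def __post_init__(self) -> None:
        if self.mode not in ("fixture", "cohort", "simulate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "cohort" and not self.cohort_path:
            raise ValueError("cohort mode needs cohort_path")
        if self.mode == "simulate" and self.simulation is None:
            raise ValueError("simulate mode needs a SimulationConfig")


@dataclass
class Study1Report:
    config: RunConfig
    count_tables: Mapping[str, CountTable]
    hwe: list[HweResult]
    screen: list[AssociationResult]
    wrm: ScoreTable | None
    wrm_audit: list[WrmSelection]
    pwm_summaries: Mapping[str, TgsSummary]
    wrm_summaries: Mapping[str, TgsSummary]
    proportions: Mapping[str, float]
    performance: list[GroupComparison] = field(default_factory=list)
    tgs_tests: list[GroupComparison] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def association_frame(self) -> pd.DataFrame:
        frame = screen_frame(self.screen)
        m = self.config.bonferroni_m or len({r.locus.rs_id for r in self.screen})
        frame["p_bonferroni"] = [min(1.0, p * m) for p in frame["p"]]
        frame["bonferroni_m"] = m
        return frame

    def hwe_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": r.group,
                "gene": r.locus.gene,
                "rs_id": r.locus.rs_id,
                "chi2": r.chi2,
                "p": r.p,
                "in_hwe": r.in_hwe,
                "monomorphic": r.monomorphic,
            }
            for r in self.hwe
        )

    def tgs_frame(self) -> pd.DataFrame:
        rows = []
        for model_summaries in (self.pwm_summaries, self.wrm_summaries):
            for s in model_summaries.values():
                rows.append(
                    {
                        "model": s.model_name,
                        "group": s.group,
                        "n": s.n,
                        "mean_tgs": s.mean,
                        "sd_tgs_independence": s.sd,
                    }
                )
        return pd.DataFrame(rows)

    def write(self) -> Path:
        return _write_study1(self)


def _case_tables_from_cohort(cohort: Cohort) -> tuple[CountTable, dict[str, CountTable]]:
    groups = list(cohort.groups)
    if CONTROL_GROUP not in groups:
        raise TgskitError(f"cohort has no {CONTROL_GROUP!r} group")
    control = count_table_from_cohort(cohort, CONTROL_GROUP)
    athletes = [g for g in groups if g != CONTROL_GROUP]
    case_tables: dict[str, CountTable] = {}
    if len(athletes) > 1:
        merged = cohort.subset(athletes)
        merged_data = merged.data.assign(group="all_weightlifters")
        case_tables["all_weightlifters"] = count_table_from_cohort(
            Cohort(merged_data, cohort.panel), "all_weightlifters"
        )
    if "international" in athletes:
        case_tables["international"] = count_table_from_cohort(cohort, "international")
    for g in athletes:
        if g not in ("international",) and len(athletes) == 1:
            case_tables[g] = count_table_from_cohort(cohort, g)
    return control, case_tables


def run_study1(config: RunConfig) -> Study1Report:
    """Execute the full study-1 analysis for the configured input mode."""
    notes: list[str] = []
    cohort: Cohort | None = None

    if config.mode == "fixture":
        fixture = load_fixture_table2()
        control = fixture.controls
        national = derive_national(fixture.all_weightlifters, fixture.international)
        case_tables = {
            "all_weightlifters": fixture.all_weightlifters,
            "international": fixture.international,
        }
        summary_tables = {
            "controls": control,
            "national": national,
            "international": fixture.international,
            "all_weightlifters": fixture.all_weightlifters,
        }
    else:
        if config.mode == "cohort":
            cohort = read_cohort(config.cohort_path)
        else:
            cohort = simulate_study(config.simulation)
        control, case_tables = _case_tables_from_cohort(cohort)
        summary_tables = {CONTROL_GROUP: control, **case_tables}

    hwe = hwe_screen({"controls": control, **case_tables}, alpha=config.alpha)
    screen = run_case_control_screen(case_tables, control, models=config.models)

    wrm = None
    audit: list[WrmSelection] = []
    try:
        wrm, audit = build_wrm(screen, case_tables, control, alpha=config.alpha)
    except (EmptyModelError, TgskitError) as exc:
        notes.append(f"WRM not built: {exc}")

    pwm, _packaged_wrm = load_score_tables()
    pwm_summaries = tgs_summaries(pwm, summary_tables)
    wrm_summaries = tgs_summaries(wrm, summary_tables) if wrm else {}

    proportions = {
        name: proportion_at_least(summary, config.threshold)
        for name, summary in wrm_summaries.items()
    }

    performance: list[GroupComparison] = []
    tgs_tests: list[GroupComparison] = []
    if cohort is not None and wrm is not None:
        athlete_groups = [g for g in cohort.groups if g != CONTROL_GROUP]
        scores_by_group = {}
        for g in [CONTROL_GROUP] + athlete_groups:
            scores, n_excluded = tgs_cohort(wrm, cohort.subset(g))
            if n_excluded:
                notes.append(f"{g}: {n_excluded} individuals excluded from TGS (missing genotypes)")
            scores_by_group[g] = scores.to_numpy()
        athletes_scores = [s for g in athlete_groups for s in scores_by_group[g]]
        tgs_tests.append(
            two_group_t(
                athletes_scores,
                scores_by_group[CONTROL_GROUP],
                labels=("weightlifters", CONTROL_GROUP),
            )
        )
        if len(athlete_groups) >= 2:
            omnibus, trend = anova_with_trend(
                {g: scores_by_group[g] for g in [CONTROL_GROUP] + athlete_groups}
            )
            tgs_tests.extend([omnibus, trend])
        frac_ctrl, frac_case, p = compare_threshold_proportions(
            scores_by_group[CONTROL_GROUP], athletes_scores, config.threshold
        )
        proportions = dict(proportions)
        proportions.update(
            {
                "empirical_control": frac_ctrl,
                "empirical_athletes": frac_case,
                "empirical_comparison_p": p,
            }
        )

        athletes = cohort.subset(athlete_groups)
        if athletes.data["wilks"].notna().sum() >= 3:
            for rs_id in wrm.loci:
                try:
                    performance.append(
                        genotype_performance_compare(athletes, cohort.panel[rs_id], "dominant")
                    )
                except EmptyGroupError as exc:
                    notes.append(f"performance contrast skipped: {exc}")
            try:
                performance.append(regress_performance_on_tgs(athletes, wrm))
            except EmptyGroupError as exc:
                notes.append(f"TGS regression skipped: {exc}")

    report = Study1Report(
        config=config,
        count_tables=summary_tables,
        hwe=hwe,
        screen=screen,
        wrm=wrm,
        wrm_audit=audit,
        pwm_summaries=pwm_summaries,
        wrm_summaries=wrm_summaries,
        proportions=proportions,
        performance=performance,
        tgs_tests=tgs_tests,
        notes=notes,
    )
    if config.out_dir:
        report.write()
    return report


@dataclass
class Study2Report:
    wrm: ScoreTable
    screen: list[AssociationResult]
    summaries: Mapping[str, TgsSummary]
    tgs_test: GroupComparison | None
    notes: list[str] = field(default_factory=list)


def run_study2(
    wrm: ScoreTable,
    cohort: Cohort | None = None,
    control_table: CountTable | None = None,
    case_table: CountTable | None = None,
    alpha: float = ALPHA,
    models: Sequence[str] = SCREEN_MODELS,
) -> Study2Report:
    """Apply a fixed score model to an independent case group (no re-fitting).

    Accepts either an individual-level cohort (control group plus one or
    more athlete groups) or a pair of count tables.  The score model's loci
    must all be present, otherwise :class:`PanelMismatchError`.
    """
    notes: list[str] = []
    tgs_test = None
    if cohort is not None:
        missing = [rs for rs in wrm.loci if rs not in cohort.data.columns]
        if missing:
            raise PanelMismatchError(f"cohort lacks score-model loci {missing}")
        control_table, case_tables = _case_tables_from_cohort(cohort)
        case_name = next(iter(case_tables))
        case_table = case_tables[case_name]
        case_groups = [g for g in cohort.groups if g != CONTROL_GROUP]
        ctrl_scores, _ = tgs_cohort(wrm, cohort.subset(CONTROL_GROUP))
        case_scores, _ = tgs_cohort(wrm, cohort.subset(case_groups))
        tgs_test = two_group_t(
            case_scores.to_numpy(), ctrl_scores.to_numpy(), labels=("athletes", CONTROL_GROUP)
        )
    elif control_table is None or case_table is None:
        raise ValueError("run_study2 needs a cohort or both count tables")
    for table in (control_table, case_table):
        missing = [rs for rs in wrm.loci if rs not in table.loci]
        if missing:
            raise PanelMismatchError(f"{table.group} counts lack score-model loci {missing}")

    restricted_control = CountTable(
        control_table.group, {rs: control_table[rs] for rs in wrm.loci},
        allow_ragged=True,
    )
    restricted_case = CountTable(
        case_table.group, {rs: case_table[rs] for rs in wrm.loci}, allow_ragged=True
    )
    case_key = case_table.group
    if case_key == control_table.group:  # e.g. controls compared against themselves
        case_key = f"{case_key} (case)"
    screen = run_case_control_screen(
        {case_key: restricted_case}, restricted_control, models=models
    )
    summaries = tgs_summaries(
        wrm, {control_table.group: restricted_control, case_key: restricted_case}
    )
    return Study2Report(wrm, screen, summaries, tgs_test, notes)


# ---------------------------------------------------------------------------
# Report rendering


def _round_frame(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if col.startswith("p") or col in ("p",):
            out[col] = out[col].map(lambda v: round(v, 3) if isinstance(v, float) else v)
        elif col.startswith("mean_tgs") or col.startswith("sd_tgs"):
            out[col] = out[col].map(lambda v: round(v, 2) if isinstance(v, float) else v)
    return out


def _write_study1(report: Study1Report) -> Path:
    out = Path(report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    formats = report.config.formats

    frames = {
        "hwe": report.hwe_frame(),
        "association": report.association_frame(),
        "tgs_summary": report.tgs_frame(),
    }
    if "tsv" in formats:
        for name, frame in frames.items():
            _round_frame(frame).to_csv(out / f"{name}.tsv", sep="\t", index=False)
        pd.concat([t.to_frame() for t in report.count_tables.values()]).to_csv(
            out / "counts.tsv", sep="\t", index=False
        )
    if "json" in formats:
        payload = {
            "hwe": frames["hwe"].to_dict(orient="records"),
            "association": frames["association"].to_dict(orient="records"),
            "tgs_summary": frames["tgs_summary"].to_dict(orient="records"),
            "proportions_ge_threshold": dict(report.proportions),
            "threshold": report.config.threshold,
            "tgs_tests": [t.__dict__ | {"effect": dict(t.effect)} for t in report.tgs_tests],
            "performance": [t.__dict__ | {"effect": dict(t.effect)} for t in report.performance],
            "notes": report.notes,
        }
        (out / "study1.json").write_text(json.dumps(payload, indent=2, default=str) + "\n")
    if report.wrm is not None:
        report.wrm.to_json(out / "wrm.json")
        audit_rows = [
            {
                "rs_id": sel.locus.rs_id,
                "gene": sel.locus.gene,
                "trigger_group": sel.trigger_group,
                "optimal_allele": sel.optimal_allele,
                "case_allele_freq": sel.case_freq,
                "control_allele_freq": sel.control_freq,
                "significant_results": [
                    {"case_group": r.case_group, "model": r.model, "p": r.p}
                    for r in sel.triggering
                ],
            }
            for sel in report.wrm_audit
        ]
        (out / "wrm_audit.json").write_text(json.dumps(audit_rows, indent=2) + "\n")
    manifest = {
        "mode": report.config.mode,
        "alpha": report.config.alpha,
        "models": list(report.config.models),
        "wrm_built": report.wrm is not None,
        "wrm_loci": list(report.wrm.loci) if report.wrm else [],
        "notes": report.notes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
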