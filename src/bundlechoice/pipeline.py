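"""End-to-end study runner: simulate, filter, analyze, predict, report.

The interchange format is a long-format trial CSV (one row per trial,
quality-control rows flagged) plus a per-participant sidecar with
ground truth and QC outcomes.  ``run_study`` drives the full battery:

    cohort simulation -> QC filter -> log transform -> mixed ANOVA
    + planned comparisons -> model predictions + difference scores
    -> one-sample t and TOST equivalence per condition and order group

and emits a machine-readable report.  The primary analysis excludes
participants failing any quality-control item; the sensitivity
analysis retains everyone — the two differ only by the filter step.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, CohortDataset, simulate_cohort
from .prediction import predict_for_participant
from .stats import (
    equivalence_test,
    log_transform,
    mixed_anova,
    one_sample_t,
    planned_comparisons,
)
from .task import DelayGrid, default_delay_grid

__all__ = [
    "RunConfig",
    "SCHEMA_VERSION",
    "apply_qc_filter",
    "indifference_table",
    "prediction_table",
    "run_study",
    "write_cohort_csv",
    "load_cohort_csv",
    "report_to_markdown",
]

log = logging.getLogger("bundlechoice")

SCHEMA_VERSION = "bundlechoice-trials-v1"


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    alpha: float = 0.05
    delta_factor: float = 0.1
    include_qc_failures: bool = False  # True = sensitivity analysis

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**{
            **raw.get("cohort", {}),
            **({"bundle_sizes": tuple(raw["cohort"]["bundle_sizes"])}
               if "bundle_sizes" in raw.get("cohort", {}) else {}),
        })
        return cls(
            cohort=cohort,
            alpha=raw.get("alpha", 0.05),
            delta_factor=raw.get("delta_factor", 0.1),
            include_qc_failures=raw.get("include_qc_failures", False),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["bundle_sizes"] = list(d["cohort"]["bundle_sizes"])
        return d


def write_cohort_csv(dataset: CohortDataset, trials_path: str | Path,
                     participants_path: str | Path | None = None) -> None:
    """Write the long trial table (and truth sidecar) with a schema header."""
    trials_path = Path(trials_path)
    with open(trials_path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        dataset.trials.to_csv(fh, index=False)
    if participants_path is not None:
        dataset.participants.to_csv(participants_path, index=False)
    log.info("wrote %d trial rows to %s", len(dataset.trials), trials_path)


def load_cohort_csv(trials_path: str | Path,
                    participants_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    trials = pd.read_csv(trials_path, comment="#")
    participants = pd.read_csv(participants_path)
    return trials, participants


def apply_qc_filter(
    dataset: CohortDataset, *, include_qc_failures: bool = False
) -> tuple[CohortDataset, dict]:
    """Drop participants failing the color item or any choice QC trial.

    Returns the filtered dataset plus an exclusion report with counts
    per order group.  With ``include_qc_failures=True`` (the
    sensitivity analysis) the dataset passes through unchanged but the
    report still counts failures.
    """
    parts = dataset.participants
    for col in ("qc_color_pass", "qc_pass_all"):
        if col not in parts.columns:
            raise KeyError(f"QC column missing from participant table: {col}")
    ok = parts["qc_color_pass"] & parts["qc_pass_all"]
    failed = parts.loc[~ok]
    report = {
        "n_total": int(len(parts)),
        "n_failed_qc": int(len(failed)),
        "n_retained": int(ok.sum()) if not include_qc_failures else int(len(parts)),
        "failed_by_group": failed.groupby("order_group").size().to_dict(),
        "include_qc_failures": bool(include_qc_failures),
    }
    if include_qc_failures:
        return dataset, report
    keep = parts.loc[ok, "participant_id"]
    filtered = CohortDataset(
        trials=dataset.trials[dataset.trials["participant_id"].isin(keep)].copy(),
        participants=parts.loc[ok].copy(),
        config=dataset.config,
        grid=dataset.grid,
    )
    log.info("QC filter: %d -> %d participants", report["n_total"], report["n_retained"])
    return filtered, report


def indifference_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x condition indifference delays, with log10 column."""
    final = trials[trials["is_final"] == True]  # noqa: E712 (CSV round-trip safe)
    tab = final[[
        "participant_id", "order_group", "bundle_size", "indifference_days"
    ]].copy()
    tab["log10_id"] = log_transform(tab["indifference_days"].to_numpy())
    return tab.reset_index(drop=True)


def prediction_table(ids: pd.DataFrame, grid: DelayGrid | None = None,
                     control_size: int = 1, *, log_space_snap: bool = False) -> pd.DataFrame:
    """Model predictions and difference scores for every bundled condition.

    ``ids`` is the output of :func:`indifference_table`.  Each
    participant's discount rate comes from the control condition
    (k = 1/ID at bundle size ``control_size``); predictions cover each
    larger bundle size present.
    """
    if grid is None:
        grid = default_delay_grid()
    wide = ids.pivot_table(index="participant_id", columns="bundle_size",
                           values="indifference_days")
    groups = ids.drop_duplicates("participant_id").set_index("participant_id")["order_group"]
    rows = []
    for pid, row in wide.iterrows():
        control = row[control_size]
        for bs in wide.columns:
            if bs == control_size:
                continue
            res = predict_for_participant(
                control, int(bs), observed_days=row[bs], grid=grid,
                log_space_snap=log_space_snap,
            )
            rows.append(dict(
                participant_id=pid, order_group=groups[pid], k=res.k,
                bundle_size=int(bs), D1_star_days=res.D1_star,
                snapped_days=res.snapped_days,
                predicted_log10=res.predicted_log10,
                observed_log10=res.observed_log10,
                diff_score=res.diff_score,
            ))
    return pd.DataFrame(rows)


def _tost_block(scores: np.ndarray, alpha: float, delta_factor: float) -> dict:
    t = one_sample_t(scores)
    eq = equivalence_test(scores, delta_factor=delta_factor, alpha=alpha)
    return {
        "n": t.n, "mean_diff": t.mean, "sd": t.sd,
        "t": t.t, "df": t.df, "p": t.p,
        "equivalence": {
            "delta": eq.delta, "t_lower": eq.t_lower, "p_lower": eq.p_lower,
            "t_upper": eq.t_upper, "p_upper": eq.p_upper,
            "ci95": list(eq.ci95), "equivalent": eq.equivalent,
            "ci_within_interval": eq.ci_within_interval,
        },
    }


def run_study(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the complete synthetic study and return the report dict.

    Stages are logged with row counts so the exclusion accounting is
    auditable.  Identical config (seed included) produces an identical
    report.  When ``out_dir`` is given, the trial CSV, truth sidecar,
    JSON report and markdown summary are written there.
    """
    stage = "simulate"
    try:
        dataset = simulate_cohort(config.cohort)
        log.info("simulated %d participants", config.cohort.n_participants)

        stage = "qc_filter"
        analyzed, qc_report = apply_qc_filter(
            dataset, include_qc_failures=config.include_qc_failures
        )

        stage = "log_transform"
        ids = indifference_table(analyzed.trials)

        stage = "anova"
        anova = mixed_anova(ids)
        comparisons = planned_comparisons(ids)

        stage = "prediction"
        control_size = min(config.cohort.bundle_sizes)
        preds = prediction_table(ids, analyzed.grid, control_size=control_size)

        stage = "model_comparison"
        model_tests: dict[str, dict] = {}
        for bs, sub in preds.groupby("bundle_size"):
            block: dict[str, Any] = {}
            block["combined"] = _tost_block(
                sub["diff_score"].to_numpy(), config.alpha, config.delta_factor)
            for grp, gsub in sub.groupby("order_group"):
                block[grp] = _tost_block(
                    gsub["diff_score"].to_numpy(), config.alpha, config.delta_factor)
            model_tests[f"BS{bs}"] = block

        stage = "summarize"
        summary = (
            ids.groupby("bundle_size")["log10_id"]
            .agg(["mean", "std", "count"]).reset_index()
        )
        summary["mean_days"] = 10 ** summary["mean"]
        by_group = (
            ids.groupby(["order_group", "bundle_size"])["log10_id"]
            .agg(["mean", "std", "count"]).reset_index()
        )

        report = {
            "config": config.to_dict(),
            "qc": qc_report,
            "n_analyzed": anova.n_analyzed,
            "anova": {k: asdict(v) for k, v in anova.effects().items()},
            "planned_comparisons": [asdict(c) for c in comparisons],
            "condition_means": summary.to_dict(orient="records"),
            "condition_means_by_group": by_group.to_dict(orient="records"),
            "model_comparison": model_tests,
        }
    except Exception:
        log.error("run_study failed at stage %r", stage)
        raise

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(dataset, out_dir / "trials.csv", out_dir / "participants.csv")
        preds.to_csv(out_dir / "predictions.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out_dir / "report.md").write_text(report_to_markdown(report))
    return report


def _fmt_p(p: float) -> str:
    return "< .001" if p < 0.001 else f"= {p:.3f}"


def report_to_markdown(report: dict) -> str:
    """Human-readable summary of a study report."""
    lines = ["# Choice-bundling study report", ""]
    qc = report["qc"]
    lines += [
        f"Participants: {qc['n_total']} simulated, {qc['n_failed_qc']} failed QC, "
        f"{qc['n_retained']} analyzed"
        + (" (sensitivity analysis: QC failures retained)" if qc["include_qc_failures"] else ""),
        "",
        "## Mixed ANOVA (log10 indifference delay)",
        "",
        "| effect | F | df | p | partial eta^2 |",
        "|---|---|---|---|---|",
    ]
    for name, e in report["anova"].items():
        lines.append(
            f"| {name} | {e['F']:.3f} | ({e['df1']:.0f}, {e['df2']:.0f}) "
            f"| {_fmt_p(e['p'])} | {e['partial_eta_sq']:.3f} |"
        )
    lines += ["", "## Planned comparisons (Bonferroni within family)", ""]
    for c in report["planned_comparisons"]:
        lines.append(
            f"- {c['label']}: mean diff = {c['mean_diff']:.3f} log10 d, "
            f"t({c['df']:.0f}) = {c['t']:.3f}, p {_fmt_p(c['p_bonferroni'])}"
        )
    lines += ["", "## Condition means", ""]
    for row in report["condition_means"]:
        lines.append(
            f"- BS{row['bundle_size']}: mean log10 ID = {row['mean']:.3f} "
            f"({row['mean_days']:.2f} days), n = {row['count']}"
        )
    lines += ["", "## Observed vs model-predicted (difference scores)", ""]
    for cond, block in report["model_comparison"].items():
        for grp, r in block.items():
            eq = r["equivalence"]
            verdict = "equivalent" if eq["equivalent"] else "not equivalent"
            lines.append(
                f"- {cond} ({grp}): mean diff = {r['mean_diff']:.3f} (SD {r['sd']:.3f}), "
                f"t({r['df']:.0f}) = {r['t']:.3f}, p {_fmt_p(r['p'])}; TOST: {verdict} "
                f"(95% CI [{eq['ci95'][0]:.3f}, {eq['ci95'][1]:.3f}], "
                f"delta = {eq['delta']:.3f})"
            )
    lines.append("")
    return "\n".join(lines)
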