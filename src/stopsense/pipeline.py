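"""End-to-end orchestration: simulate -> extract -> SSRT -> fit -> classify.

`run_pipeline` executes every stage on a (synthetic or loaded) cohort and
returns a JSON-serializable report embedding the configuration and seeds,
so a rerun with the same inputs reproduces the report bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .hrv import hrv_features
from .models import (
    GBTConfig,
    fit_gee,
    label_states,
    rmcorr,
    train_eval_loso,
    train_eval_mixed,
    vif_prune,
)
from .scales import bis_self_control
from .sensors import build_feature_table
from .sst import apply_exclusion, estimate_ssrt_integration
from .synth import Cohort, CohortConfig, make_cohort

__all__ = ["RunConfig", "run_pipeline", "extract_features", "estimate_sessions"]


@dataclass
class RunConfig:
    """Settings of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    features: list[str] | None = None     # default: planted effects + baseline
    vif_threshold: float = 5.0
    gee_cov_type: str = "bias_reduced"
    gbt: GBTConfig | None = None
    mixed_fractions: tuple[float, ...] = (0.10, 0.20, 0.30)
    run_classifiers: bool = True
    tz: str = "UTC"


def extract_features(cohort: Cohort, tz: str = "UTC") -> pd.DataFrame:
    """Per-participant feature tables for every answered prompt, plus HRV
    columns when the cohort carries RR series."""
    tables = []
    for pid, streams in cohort.streams.items():
        prompts = cohort.prompts.loc[
            cohort.prompts["participant_id"] == pid, "end_s"
        ].to_numpy()
        if not len(prompts):
            continue
        tab = build_feature_table(streams, prompts, cohort.poi, pid, tz)
        if cohort.rr:
            hrv_rows = [
                hrv_features(cohort.rr[(pid, t)])
                if (pid, t) in cohort.rr
                else {}
                for t in prompts
            ]
            tab = pd.concat(
                [tab.reset_index(drop=True), pd.DataFrame(hrv_rows)], axis=1
            )
        tables.append(tab)
    if not tables:
        return pd.DataFrame(columns=["participant_id", "end_s"])
    return pd.concat(tables, ignore_index=True)


def estimate_sessions(sessions: dict) -> pd.DataFrame:
    """Integration-method SSRT per session with exclusion bookkeeping."""
    rows = []
    ests = []
    for (pid, t), session in sessions.items():
        est = estimate_ssrt_integration(session)
        ests.append(est)
        rows.append({"participant_id": pid, "end_s": t})
    kept, dropped = apply_exclusion(ests)
    kept_ids = {id(e) for e in kept}
    for row, est in zip(rows, ests):
        row.update(
            ssrt_ms=est.ssrt_ms,
            p_respond=est.p_respond_overall,
            estimable=est.estimable,
            excluded=id(est) not in kept_ids,
            exclusion_reason=est.exclusion_reason,
        )
    out = pd.DataFrame(
        rows,
        columns=["participant_id", "end_s", "ssrt_ms", "p_respond",
                 "estimable", "excluded", "exclusion_reason"],
    )
    return out.astype({"estimable": bool, "excluded": bool})


def build_model_matrix(cohort: Cohort, tz: str = "UTC") -> pd.DataFrame:
    """Join features, SSRT estimates (retained sessions only), momentary
    scores and the trait baseline into the analysis table."""
    features = extract_features(cohort, tz)
    ssrt = estimate_sessions(cohort.sessions)
    baseline = {
        row["participant_id"]: bis_self_control(
            [row[f"item{i+1}"] for i in range(30)]
        )
        for _, row in cohort.bis.iterrows()
    }
    mm = features.merge(
        ssrt[~ssrt["excluded"]][["participant_id", "end_s", "ssrt_ms", "p_respond"]],
        on=["participant_id", "end_s"],
        how="inner",
    )
    if len(cohort.ema):
        mm = mm.merge(
            cohort.ema[["participant_id", "end_s", "ema_score"]],
            on=["participant_id", "end_s"],
            how="left",
        )
    mm["baseline"] = mm["participant_id"].map(baseline)
    return mm.sort_values(["participant_id", "end_s"]).reset_index(drop=True)


def run_pipeline(config: RunConfig | None = None, out_dir: str | Path | None = None) -> dict:
    """Run all stages and return (and optionally write) the report."""
    config = config or RunConfig()
    cohort = make_cohort(config.cohort)
    report: dict = {
        "config": {
            "cohort": dataclasses.asdict(cohort.config),
            "vif_threshold": config.vif_threshold,
            "gee_cov_type": config.gee_cov_type,
            "mixed_fractions": list(config.mixed_fractions),
            "seed": cohort.config.seed,
        }
    }
    mm = build_model_matrix(cohort, config.tz)
    ssrt_table = estimate_sessions(cohort.sessions)
    report["n_prompts"] = int(len(cohort.prompts))
    report["n_sessions"] = int(len(cohort.sessions))
    report["n_retained"] = int(len(mm))
    report["n_excluded"] = int(ssrt_table["excluded"].sum())

    feats = config.features or (list(cohort.config.effects) + ["baseline"])
    feats = [f for f in feats if f in mm.columns]
    results: dict = {}
    if len(mm) and feats:
        cc = mm[feats + ["ssrt_ms", "participant_id", "end_s"]].dropna()
        retained = vif_prune(cc[feats], config.vif_threshold) if len(cc) else feats
        results["vif_retained"] = retained
        if len(cc) and cc["participant_id"].nunique() >= 2:
            fit = fit_gee(cc, retained, cov_type=config.gee_cov_type)
            results["gee"] = {
                term: {
                    "coef": float(row["coef"]),
                    "ci_low": float(row["ci_low"]),
                    "ci_high": float(row["ci_high"]),
                    "p": float(row["p"]),
                }
                for term, row in fit.table.iterrows()
            }
            if "ema_score" in mm.columns:
                sub = mm[["ema_score", "ssrt_ms", "participant_id"]].dropna()
                if len(sub) > sub["participant_id"].nunique() + 2:
                    rm = rmcorr(sub["ema_score"], sub["ssrt_ms"], sub["participant_id"])
                    results["rmcorr_ema_ssrt"] = dataclasses.asdict(rm)
            if config.run_classifiers:
                labels = label_states(cc)
                gbt = config.gbt or GBTConfig(random_state=cohort.config.seed)
                evals = {"loso": train_eval_loso(cc, retained, labels, config=gbt)}
                for frac in config.mixed_fractions:
                    evals[f"mixed_{int(frac*100)}"] = train_eval_mixed(
                        cc, retained, labels, frac, config=gbt
                    )
                results["classification"] = {
                    name: {
                        "accuracy_pct": ev.accuracy_pct,
                        "auc_pct": ev.auc_pct,
                        "scheme": ev.scheme,
                        "fraction": ev.fraction,
                    }
                    for name, ev in evals.items()
                }
    report["results"] = results

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mm.to_csv(out / "model_matrix.csv", index=False)
        ssrt_table.to_csv(out / "ssrt_table.csv", index=False)
        cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        with open(out / "report.txt", "w") as fh:
            fh.write(format_report(report))
    return report


def format_report(report: dict) -> str:
    lines = [
        "stopsense pipeline report",
        f"prompts answered: {report.get('n_prompts')}",
        f"sessions retained after exclusion: {report.get('n_retained')} "
        f"(excluded {report.get('n_excluded')})",
        "",
    ]
    gee = report.get("results", {}).get("gee")
    if gee:
        lines.append("GEE (Gamma, log link, exchangeable):")
        lines.append(f"{'term':<28}{'coef':>12}{'95% CI':>26}{'p':>10}")
        for term, row in gee.items():
            ci = f"({row['ci_low']:.4g}, {row['ci_high']:.4g})"
            lines.append(
                f"{term:<28}{row['coef']:>12.4g}{ci:>26}{row['p']:>10.3g}"
            )
        lines.append("")
    rm = report.get("results", {}).get("rmcorr_ema_ssrt")
    if rm:
        lines.append(
            f"rmcorr(EMA score, SSRT): r={rm['r']:.3f} "
            f"(95% CI {rm['ci_low']:.3f} to {rm['ci_high']:.3f}), "
            f"p={rm['p']:.3g}, df={rm['df']}"
        )
        lines.append("")
    cls = report.get("results", {}).get("classification")
    if cls:
        lines.append("state classification (gradient-boosted trees):")
        for name, ev in cls.items():
            lines.append(
                f"  {name:<10} ACC {ev['accuracy_pct']:.1f}%  "
                f"AUC-ROC {ev['auc_pct']:.1f}%"
            )
    return "\n".join(lines) + "\n"
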