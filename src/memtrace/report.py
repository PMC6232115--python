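"""Pipeline orchestration: simulate -> analyze -> report, with a manifest.

Every stage writes plain-text tables into the output directory and registers
them in ``manifest.json`` (config hash, seeds, package version, per-stage
status, artifact list).  Given the same config and seed, all tables are
byte-identical across reruns; stages whose inputs are absent (e.g. the
eye-dependent stages on a study without fixation records) are skipped with an
explicit notice rather than failing the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .content import content_report, fixation_report
from .lagcurve import (
    conditional_curve,
    curve_table,
    fit_decay,
    fit_summary,
    test_order_curve,
)
from .memorability import FEATURE_GROUPS, ablate_groups, assemble_features
from .sdt import group_report
from .synthetic import GeneratorConfig, build_cohort, ground_truth
from .trial_io import StudyTable, read_study, validate_balance, write_study

log = logging.getLogger("memtrace")


def config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


class Manifest:
    def __init__(self, out_dir: Path, config: dict, seed):
        self.data = {
            "memtrace_version": __version__,
            "config_hash": config_hash(config),
            "config": config,
            "seed": seed,
            "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
            "stages": {},
            "artifacts": [],
        }
        self.out_dir = out_dir

    def artifact(self, path: Path):
        self.data["artifacts"].append(str(Path(path).relative_to(self.out_dir)))

    def stage(self, name: str, status: str, detail: str = ""):
        self.data["stages"][name] = {"status": status, "detail": detail}

    def write(self):
        path = self.out_dir / "manifest.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(self.data), fh, indent=2, sort_keys=True)
        return path


def _write_json(path: Path, obj, manifest: Manifest):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
    manifest.artifact(path)


def _write_csv(path: Path, df: pd.DataFrame, manifest: Manifest):
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.artifact(path)


def run_pipeline(
    out_dir,
    config: GeneratorConfig | None = None,
    in_dir=None,
    bin_width_s: float = 5.0,
    max_lag_s: float = 120.0,
    n_folds: int = 10,
    n_rounds: int = 100,
    predict: bool = True,
    render: bool = True,
) -> dict:
    """Run the full analysis pipeline and write a report bundle.

    Either ``config`` (simulate a cohort) or ``in_dir`` (read external tables)
    must be given.  Returns the in-memory bundle; exit-status handling for the
    command line lives in :mod:`memtrace.cli`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = ground_truth(config) if config is not None else {"input_dir": str(in_dir)}
    manifest = Manifest(out, cfg_dict, seed=getattr(config, "seed", None))
    bundle: dict = {}
    failed = []

    def run_stage(name, fn):
        try:
            fn()
            manifest.stage(name, "ok")
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            manifest.stage(name, "failed", str(exc))
            failed.append(name)

    # -- load or simulate ------------------------------------------------------
    def stage_data():
        if config is not None:
            study = build_cohort(config)
            data_dir = out / "data"
            paths = write_study(study, data_dir)
            for p in paths.values():
                manifest.artifact(Path(p))
            _write_json(data_dir / "ground_truth.json", ground_truth(config), manifest)
        else:
            study = read_study(in_dir)
        bundle["study"] = study
        bundle["balance"] = validate_balance(study)
        _write_csv(out / "balance.csv", bundle["balance"], manifest)

    run_stage("data", stage_data)
    if "study" not in bundle:
        manifest.write()
        return {"bundle": bundle, "failed": failed, "manifest": manifest.data}
    study: StudyTable = bundle["study"]

    def stage_sdt():
        rep = group_report(study)
        bundle["sdt"] = rep
        _write_csv(out / "subject_summaries.csv", rep["subject_summaries"], manifest)
        _write_json(
            out / "group_results.json",
            {k: v for k, v in rep.items() if k != "subject_summaries"},
            manifest,
        )

    def stage_lag():
        curve = conditional_curve(study, bin_width_s=bin_width_s, max_lag_s=max_lag_s)
        fit = fit_decay(curve)
        order = test_order_curve(study)
        bundle["lag_curve"], bundle["decay_fit"], bundle["order_curve"] = curve, fit, order
        _write_csv(out / "lag_curve.csv", curve_table(curve), manifest)
        _write_csv(out / "test_order_curve.csv", curve_table(order), manifest)
        _write_json(out / "decay_fit.json", fit_summary(fit, curve), manifest)

    def stage_content():
        cells, comps = content_report(study)
        bundle["content_splits"], bundle["content_tests"] = cells, comps
        _write_csv(out / "content_splits.csv", cells, manifest)
        if len(comps):
            _write_csv(out / "content_tests.csv", comps, manifest)
        if study.has_fixations():
            fcells, fcomps = fixation_report(study)
            bundle["fixation_splits"], bundle["fixation_tests"] = fcells, fcomps
            _write_csv(out / "fixation_splits.csv", fcells, manifest)
            _write_csv(out / "fixation_tests.csv", fcomps, manifest)
        else:
            manifest.stage("content.fixations", "skipped", "no fixation records")

    def stage_predict():
        groups = ["cv", "annot"]
        if study.has_fixations():
            groups += ["eye", "eye_annot"]
        else:
            manifest.stage(
                "predict.eye", "skipped", "no fixation records: eye groups excluded"
            )
        feats = assemble_features(study, groups)
        combos = [[g] for g in groups] + ([groups] if len(groups) > 1 else [])
        seed = getattr(config, "seed", 0) or 0
        results = ablate_groups(
            feats, combos, n_folds=n_folds, seed=seed, n_rounds=n_rounds
        )
        bundle["predictions"] = results
        table = pd.DataFrame(
            [
                {
                    "groups": name,
                    "mean_accuracy": r.mean_accuracy,
                    "sem_accuracy": r.sem_accuracy,
                    "t_statistic": r.t_statistic,
                    "p_value": r.p_value,
                    "n_subjects": r.n_subjects,
                }
                for name, r in results.items()
            ]
        )
        bundle["prediction_table"] = table
        _write_csv(out / "model_report.csv", table, manifest)
        full = results["+".join(groups)] if len(groups) > 1 else results[groups[0]]
        _write_csv(out / "predictions.csv", full.predictions, manifest)
        _write_json(
            out / "model_report.json",
            {"results": table, "config": full.config}, manifest,
        )

    run_stage("sdt", stage_sdt)
    run_stage("lag", stage_lag)
    run_stage("content", stage_content)
    if predict:
        run_stage("predict", stage_predict)
    if render:
        run_stage("report", lambda: render_report(bundle, out, manifest))

    manifest.write()
    return {"bundle": bundle, "failed": failed, "manifest": manifest.data}


def render_report(bundle: dict, out_dir, manifest: Manifest | None = None) -> Path:
    """Human-readable summary: text report plus deterministic figures.

    Panels whose inputs are missing from the bundle are omitted with a notice
    in the report text.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Study report", ""]

    if "sdt" in bundle:
        rep = bundle["sdt"]
        df = rep["subject_summaries"]
        pc = rep["percent_correct_vs_chance"]
        lines += [
            "## Recognition performance",
            "",
            f"- subjects: {pc.n_subjects}",
            f"- percent correct: {pc.mean:.1f} +/- {pc.dispersion:.1f} "
            f"({pc.dispersion_label}); t = {pc.t_statistic:.3f}, "
            f"p = {pc.p_value:.4g} vs {pc.chance:.0f}%",
            f"- mean d' = {rep['mean_d_prime']:.2f} +/- {rep['sd_d_prime']:.2f} (SD); "
            f"pooled d' = {rep['pooled_d_prime']:.2f}",
            f"- mean yes-rate = {100 * rep['mean_yes_rate']:.1f}%",
        ]
        cons = rep.get("self_consistency_vs_chance")
        if cons is not None:
            lines.append(
                f"- self-consistency: {cons.mean:.1f} +/- {cons.dispersion:.1f}% "
                f"({cons.dispersion_label}), p = {cons.p_value:.4g} vs 50%"
            )
        flagged = df[df["qc_flags"].astype(str) != ""]
        if len(flagged):
            lines.append(
                "- QC flags: "
                + "; ".join(f"{r.subject_id}: {r.qc_flags}" for r in flagged.itertuples())
            )
        lines.append("")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(df["p_fa"], df["p_cd"], s=18, color="k")
        ax.plot([0, 1], [0, 1], "--", color="gray", lw=1)
        ax.set_xlabel("P(false alarm)")
        ax.set_ylabel("P(correct detection)")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        fig.tight_layout()
        fig.savefig(out / "fig_sdt.png", dpi=110)
        plt.close(fig)
        if manifest:
            manifest.artifact(out / "fig_sdt.png")
    else:
        lines += ["## Recognition performance", "", "- panel omitted: no summaries", ""]

    if "lag_curve" in bundle and "decay_fit" in bundle:
        curve, fit = bundle["lag_curve"], bundle["decay_fit"]
        lines += [
            "## History dependence over encoding time",
            "",
            f"- fitted y = 1 + a*exp(-dt/tau): a = {fit.alpha:.3f}, "
            f"tau = {fit.tau_s:.1f} s (converged: {fit.converged}, "
            f"tau identifiable: {fit.tau_identifiable})",
            f"- bins: {fit.n_bins} of width {curve.bin_width_s:g} s up to "
            f"{curve.max_lag_s:g} s; scope {curve.scope}",
            "",
        ]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(curve.bin_centers_s, curve.y, "o", color="k", ms=4)
        tt = np.linspace(0, curve.max_lag_s, 200)
        ax.plot(tt, 1 + fit.alpha * np.exp(-tt / fit.tau_s), "-", color="tab:red", lw=1.5)
        ax.axhline(1.0, ls="--", color="gray", lw=1)
        ax.set_xlabel("lag between encoding times (s)")
        ax.set_ylabel("P(correct | previous correct) / P(correct)")
        fig.tight_layout()
        fig.savefig(out / "fig_lag.png", dpi=110)
        plt.close(fig)
        if manifest:
            manifest.artifact(out / "fig_lag.png")
    else:
        lines += ["## History dependence", "", "- panel omitted: no decay fit", ""]

    if "prediction_table" in bundle:
        table = bundle["prediction_table"]
        lines += ["## Single-trial memorability prediction", ""]
        for r in table.itertuples():
            star = " *" if r.p_value < 0.01 else ""
            lines.append(
                f"- {r.groups}: {r.mean_accuracy:.1f} +/- {r.sem_accuracy:.1f}% "
                f"(SEM), p = {r.p_value:.4g}{star}"
            )
        lines.append("")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar(table["groups"], table["mean_accuracy"], yerr=table["sem_accuracy"],
               color="lightgray", edgecolor="k")
        ax.axhline(50.0, ls="--", color="gray", lw=1)
        ax.set_ylabel("cross-validated accuracy (%)")
        ax.set_ylim(40, max(70, table["mean_accuracy"].max() + 5))
        plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
        fig.tight_layout()
        fig.savefig(out / "fig_predict.png", dpi=110)
        plt.close(fig)
        if manifest:
            manifest.artifact(out / "fig_predict.png")
    else:
        lines += ["## Memorability prediction", "", "- panel omitted: no model results", ""]

    path = out / "report.md"
    path.write_text("\n".join(lines), encoding="utf-8")
    if manifest:
        manifest.artifact(path)
    return path
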