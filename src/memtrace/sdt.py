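"""Per-subject and group signal-detection summaries for the old/new task.

Conventions
-----------
* Rates (hit rate ``p_cd``, false-alarm rate ``p_fa``, yes-rate,
  self-consistency) are fractions in [0, 1]; ``percent_correct`` is on the
  percent scale as it is usually reported.
* Accuracy statistics use first presentations only; self-consistency uses
  both presentations of each covert repeat pair.
* d' and criterion use the log-linear extreme-rate correction
  ``p* = (x + 0.5) / (n + 1)``, applied always (not only at 0/1 rates) so the
  estimator is continuous in the counts:
  ``d' = Phi^-1(p_cd*) - Phi^-1(p_fa*)``, ``c = -(Phi^-1(p_cd*) + Phi^-1(p_fa*)) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError
from .trial_io import StudyTable

QC_YES_BIAS = "yes_bias"
QC_ACCURACY_OUTLIER = "accuracy_outlier"


@dataclass
class SubjectSummary:
    subject_id: str
    n_trials: int
    n_target: int
    n_foil: int
    percent_correct: float          # % scale
    p_cd: float                     # hit rate, fraction
    p_fa: float                     # false-alarm rate, fraction
    d_prime: float
    criterion: float
    yes_rate: float                 # fraction
    self_consistency: Optional[float]  # fraction; None when no repeat pairs
    n_repeat_pairs: int
    qc_flags: tuple = field(default_factory=tuple)


def _corrected(x: int, n: int) -> float:
    return (x + 0.5) / (n + 1.0)


def dprime_criterion(n_hit: int, n_target: int, n_fa: int, n_foil: int) -> tuple[float, float]:
    """(d', criterion) from raw counts with the log-linear correction."""
    zh = stats.norm.ppf(_corrected(n_hit, n_target))
    zf = stats.norm.ppf(_corrected(n_fa, n_foil))
    return float(zh - zf), float(-(zh + zf) / 2.0)


def summarize_subject(trials: pd.DataFrame, study: Optional[StudyTable] = None) -> SubjectSummary:
    """Signal-detection and consistency summary for one subject's trials.

    ``trials`` holds every test trial of a single subject (repeat second
    presentations included; they are used only for self-consistency).
    """
    sid = trials["subject_id"].iloc[0]
    sub_study = StudyTable(trials=trials)
    first = sub_study.first_presentations()

    tgt = first[first["trial_type"] == "target"]
    foil = first[first["trial_type"] == "foil"]
    n_target, n_foil = len(tgt), len(foil)
    n_hit = int((tgt["response"] == "yes").sum())
    n_fa = int((foil["response"] == "yes").sum())

    p_cd = n_hit / n_target if n_target else float("nan")
    p_fa = n_fa / n_foil if n_foil else float("nan")
    n_correct = int(first["correct"].sum())
    percent_correct = 100.0 * n_correct / len(first)
    yes_rate = float((first["response"] == "yes").mean())
    d_prime, criterion = dprime_criterion(n_hit, n_target, n_fa, n_foil)

    pairs = sub_study.repeat_pairs()
    if len(pairs):
        self_consistency = float(pairs["agree"].mean())
    else:
        self_consistency = None  # absent, not 0

    return SubjectSummary(
        subject_id=sid,
        n_trials=len(first),
        n_target=n_target,
        n_foil=n_foil,
        percent_correct=percent_correct,
        p_cd=p_cd,
        p_fa=p_fa,
        d_prime=d_prime,
        criterion=criterion,
        yes_rate=yes_rate,
        self_consistency=self_consistency,
        n_repeat_pairs=len(pairs),
    )


def summarize_subjects(study: StudyTable, outlier_k: float = 5.0) -> pd.DataFrame:
    """One SubjectSummary row per subject, with cohort-level QC flags set."""
    summaries = [
        summarize_subject(g) for _, g in study.trials.groupby("subject_id", sort=True)
    ]
    df = pd.DataFrame([vars(s) for s in summaries])
    flags = qc_flags(df, outlier_k=outlier_k)
    df["qc_flags"] = df["subject_id"].map(flags).map(lambda f: ";".join(sorted(f)))
    return df


def qc_flags(
    summaries: pd.DataFrame,
    yes_bias_hi: float = 0.90,
    yes_bias_lo: float = 0.10,
    outlier_k: float = 5.0,
) -> dict:
    """Exclusion flags per subject.

    ``yes_bias``: yes-rate above ``yes_bias_hi`` or below ``yes_bias_lo``
    (one response key used almost exclusively).  ``accuracy_outlier``:
    percent correct exceeding the cohort median by more than
    ``outlier_k`` median absolute deviations — the pattern of a subject who
    can recognize their own clips from an incidental global cue rather than
    event memory.
    """
    pc = summaries["percent_correct"].to_numpy(dtype=float)
    med = float(np.median(pc))
    mad = float(np.median(np.abs(pc - med)))
    out = {}
    for _, row in summaries.iterrows():
        flags = set()
        if row["yes_rate"] > yes_bias_hi or row["yes_rate"] < yes_bias_lo:
            flags.add(QC_YES_BIAS)
        if mad > 0 and row["percent_correct"] > med + outlier_k * mad:
            flags.add(QC_ACCURACY_OUTLIER)
        out[row["subject_id"]] = flags
    return out


@dataclass
class GroupResult:
    mean: float
    dispersion: float
    dispersion_label: str  # "SD" or "SEM"
    t_statistic: float
    p_value: float
    n_subjects: int
    chance: float


def group_vs_chance(
    values: Sequence[float],
    chance: float = 50.0,
    dispersion: str = "SD",
) -> GroupResult:
    """Two-sided one-sample t-test of per-subject values against chance.

    ``values`` are usually per-subject percent-correct scores (percent scale,
    chance 50).  Dispersion is reported as SD or SEM, explicitly labeled.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise DegenerateInputError("need at least two subjects for a group test")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("zero variance across subjects: t-test undefined")
    t, p = stats.ttest_1samp(v, popmean=chance)
    disp = sd if dispersion == "SD" else sd / np.sqrt(len(v))
    return GroupResult(
        mean=float(np.mean(v)),
        dispersion=float(disp),
        dispersion_label=dispersion,
        t_statistic=float(t),
        p_value=float(p),
        n_subjects=len(v),
        chance=float(chance),
    )


def pooled_dprime(study: StudyTable) -> dict:
    """Cohort-pooled hit/false-alarm rates and the d' they imply.

    Distinct from the mean of per-subject d' values (the two conventions are
    not mutually consistent); both are worth reporting, labeled.
    """
    first = study.first_presentations()
    tgt = first[first["trial_type"] == "target"]
    foil = first[first["trial_type"] == "foil"]
    n_hit = int((tgt["response"] == "yes").sum())
    n_fa = int((foil["response"] == "yes").sum())
    d, c = dprime_criterion(n_hit, len(tgt), n_fa, len(foil))
    return {
        "pooled_p_cd": n_hit / len(tgt),
        "pooled_p_fa": n_fa / len(foil),
        "pooled_d_prime": d,
        "pooled_criterion": c,
    }


def group_report(study: StudyTable, outlier_k: float = 5.0) -> dict:
    """Cohort summary: group tests and pooled rates, with QC applied."""
    df = summarize_subjects(study, outlier_k=outlier_k)
    pc = group_vs_chance(df["percent_correct"], chance=50.0, dispersion="SD")
    cons_values = df.loc[df["self_consistency"].notna(), "self_consistency"] * 100.0
    cons = (
        group_vs_chance(cons_values, chance=50.0, dispersion="SEM")
        if len(cons_values) >= 2 and cons_values.std(ddof=1) > 0
        else None
    )
    return {
        "subject_summaries": df,
        "percent_correct_vs_chance": pc,
        "self_consistency_vs_chance": cons,
        "mean_d_prime": float(df["d_prime"].mean()),
        "sd_d_prime": float(df["d_prime"].std(ddof=1)) if len(df) > 1 else float("nan"),
        "mean_yes_rate": float(df["yes_rate"].mean()),
        **pooled_dprime(study),
    }
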