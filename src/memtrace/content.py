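"""Performance conditioned on clip content and on fixated content.

Two splits mirror the two ways gaze-independent and gaze-dependent content
can relate to memory:

* :func:`split_by_content` — percent correct per (feature level x
  target/foil) cell, over first presentations;
* :func:`split_by_fixation` — percent correct for target trials partitioned
  by whether any fixation landed on the named content (foil fixations belong
  to a different subject and are excluded upstream).

Significance between cells uses the two-sided Wilcoxon rank-sum test on
*per-subject* cell performance (the subject is the experimental unit):
exhaustive-permutation exact p for small groups, normal approximation with
tie correction otherwise.  No multiple-testing correction is applied by
default; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, VocabularyError
from .trial_io import StudyTable

EXACT_MAX_N = 10
SIGNIFICANCE_LEVEL = 0.01


def _check_feature(study: StudyTable, feature_name: str) -> None:
    vocab = study.vocabulary
    if vocab and feature_name not in vocab:
        raise VocabularyError(
            f"feature {feature_name!r} not in declared vocabulary "
            f"({', '.join(sorted(vocab))})"
        )
    if not vocab and feature_name not in set(study.annotations["feature_name"]):
        raise VocabularyError(f"feature {feature_name!r} absent from annotations")


def _first_with_levels(study: StudyTable, feature_name: str) -> pd.DataFrame:
    ann = study.annotations
    lut = ann[ann["feature_name"] == feature_name].set_index("clip_id")["feature_value"]
    first = study.first_presentations()
    first = first.assign(level=first["clip_id"].map(lut))
    return first[first["level"].notna()]


def split_by_content(
    study: StudyTable, feature_name: str, min_n: int = 5
) -> pd.DataFrame:
    """Percent correct per (level x trial_type) cell for one content feature.

    Cell performance pools trials; ``sem`` is the standard error of the mean
    of per-subject cell performances.  Cells with fewer than ``min_n`` trials
    are flagged ``low_n``.
    """
    _check_feature(study, feature_name)
    first = _first_with_levels(study, feature_name)
    levels = sorted(first["level"].unique())
    if len(levels) < 2:
        warnings.warn(
            f"feature {feature_name!r} takes a single level in this study"
        )
    rows = []
    for level in levels:
        for ttype in ("target", "foil"):
            cell = first[(first["level"] == level) & (first["trial_type"] == ttype)]
            per_subj = cell.groupby("subject_id")["correct"].mean() * 100.0
            rows.append(
                {
                    "feature_name": feature_name,
                    "level": level,
                    "trial_type": ttype,
                    "n_trials": len(cell),
                    "percent_correct": (
                        100.0 * cell["correct"].mean() if len(cell) else np.nan
                    ),
                    "sem": (
                        float(per_subj.std(ddof=1) / np.sqrt(len(per_subj)))
                        if len(per_subj) > 1
                        else np.nan
                    ),
                    "low_n": len(cell) < min_n,
                }
            )
    return pd.DataFrame(rows)


def per_subject_cell_values(
    study: StudyTable,
    feature_name: str,
    level: str,
    trial_type: str,
    fixated: "bool | None" = None,
) -> np.ndarray:
    """Per-subject percent correct in one cell (the rank-sum test unit)."""
    if fixated is None:
        first = _first_with_levels(study, feature_name)
        cell = first[(first["level"] == level) & (first["trial_type"] == trial_type)]
    else:
        first = _fixation_trials(study, feature_name)
        cell = first[first["fixated"] == fixated]
    return (cell.groupby("subject_id")["correct"].mean() * 100.0).to_numpy()


@dataclass
class CompareResult:
    p_value: float
    significant: bool
    statistic: float
    method: str
    n_a: int
    n_b: int


def compare_levels(
    values_a, values_b, significance_level: float = SIGNIFICANCE_LEVEL
) -> CompareResult:
    """Two-sided Wilcoxon rank-sum comparison of two per-subject value sets.

    Groups of at most ``EXACT_MAX_N`` use the exhaustive permutation
    distribution of the Mann-Whitney statistic (exact even under ties);
    larger groups use the normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("cannot compare against an empty group")
    if len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N:
        method_obj = stats.PermutationMethod(n_resamples=500_000, rng=0)
        method = "exact_permutation"
    else:
        method_obj = "asymptotic"
        method = "normal_tie_corrected"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method_obj)
    p = float(min(res.pvalue, 1.0))
    return CompareResult(
        p_value=p,
        significant=p < significance_level,
        statistic=float(res.statistic),
        method=method,
        n_a=len(a),
        n_b=len(b),
    )


def _fixation_trials(study: StudyTable, feature_name: str) -> pd.DataFrame:
    if not study.has_fixations():
        raise ConfigurationError("study has no fixation records")
    fix = study.fixations
    flag = (
        fix[fix["fixated_feature"] == feature_name]
        .groupby("clip_id")["fixated"]
        .any()
    )
    first = study.first_presentations()
    tgt = first[first["trial_type"] == "target"].copy()
    tgt["fixated"] = tgt["clip_id"].map(flag)
    return tgt[tgt["fixated"].notna()].astype({"fixated": bool})


def split_by_fixation(
    study: StudyTable, feature_name: str, min_n: int = 5
) -> pd.DataFrame:
    """Target-trial percent correct split by fixation on the named content."""
    _check_feature(study, feature_name)
    tgt = _fixation_trials(study, feature_name)
    present = sorted(tgt["fixated"].unique())
    if len(present) < 2:
        warnings.warn(
            f"content {feature_name!r} is {'always' if True in present else 'never'}"
            " fixated in this study"
        )
    rows = []
    for fixated in (True, False):
        cell = tgt[tgt["fixated"] == fixated]
        per_subj = cell.groupby("subject_id")["correct"].mean() * 100.0
        rows.append(
            {
                "feature_name": feature_name,
                "fixated": "Y" if fixated else "N",
                "n_trials": len(cell),
                "percent_correct": (
                    100.0 * cell["correct"].mean() if len(cell) else np.nan
                ),
                "sem": (
                    float(per_subj.std(ddof=1) / np.sqrt(len(per_subj)))
                    if len(per_subj) > 1
                    else np.nan
                ),
                "low_n": len(cell) < min_n,
            }
        )
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


def content_report(
    study: StudyTable,
    min_n: int = 5,
    significance_level: float = SIGNIFICANCE_LEVEL,
    adjust: bool = False,
) -> pd.DataFrame:
    """All features x both comparison families, with significance columns.

    For every feature level, the target-vs-foil comparison is emitted; for
    binary features, the level-vs-level comparison within each trial type is
    emitted as well (which family a study's figure stars is ambiguous without
    its analysis code, so both are labeled explicitly).
    """
    vocab = study.vocabulary or {
        f: sorted(study.annotations.loc[study.annotations["feature_name"] == f,
                                        "feature_value"].unique())
        for f in sorted(study.annotations["feature_name"].unique())
    }
    cells, comps = [], []
    for feature in sorted(vocab):
        split = split_by_content(study, feature, min_n=min_n)
        cells.append(split)
        for level in split["level"].unique():
            va = per_subject_cell_values(study, feature, level, "target")
            vb = per_subject_cell_values(study, feature, level, "foil")
            if len(va) and len(vb):
                r = compare_levels(va, vb, significance_level)
                comps.append(
                    {
                        "feature_name": feature,
                        "comparison": f"target_vs_foil@{level}",
                        "p_value": r.p_value,
                        "significant": r.significant,
                        "method": r.method,
                    }
                )
        levels = list(split["level"].unique())
        if len(levels) == 2:
            for ttype in ("target", "foil"):
                va = per_subject_cell_values(study, feature, levels[0], ttype)
                vb = per_subject_cell_values(study, feature, levels[1], ttype)
                if len(va) and len(vb):
                    r = compare_levels(va, vb, significance_level)
                    comps.append(
                        {
                            "feature_name": feature,
                            "comparison": f"{levels[0]}_vs_{levels[1]}@{ttype}",
                            "p_value": r.p_value,
                            "significant": r.significant,
                            "method": r.method,
                        }
                    )
    comp_df = pd.DataFrame(comps)
    if adjust and len(comp_df):
        comp_df["p_adjusted"] = benjamini_hochberg(comp_df["p_value"])
        comp_df["significant"] = comp_df["p_adjusted"] < significance_level
    return pd.concat(cells, ignore_index=True), comp_df if len(comp_df) else pd.DataFrame()


def fixation_report(study: StudyTable, min_n: int = 5,
                    significance_level: float = SIGNIFICANCE_LEVEL):
    """Fixation splits plus Y-vs-N rank-sum comparisons for every feature."""
    vocab = study.vocabulary or sorted(study.fixations["fixated_feature"].unique())
    cells, comps = [], []
    for feature in sorted(vocab):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            split = split_by_fixation(study, feature, min_n=min_n)
        cells.append(split)
        va = per_subject_cell_values(study, feature, "", "target", fixated=True)
        vb = per_subject_cell_values(study, feature, "", "target", fixated=False)
        if len(va) and len(vb):
            r = compare_levels(va, vb, significance_level)
            comps.append(
                {
                    "feature_name": feature,
                    "comparison": "fixated_vs_not",
                    "p_value": r.p_value,
                    "significant": r.significant,
                    "method": r.method,
                }
            )
    return pd.concat(cells, ignore_index=True), pd.DataFrame(comps)
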