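"""Single-trial memorability prediction.

Per subject, a boosted ensemble of depth-limited decision trees (AdaBoost
stumps by default; an RBF-kernel SVM is available behind a switch) is trained
to predict trial correctness from selectable feature groups:

* ``cv`` — per-clip numeric visual features (surrogate vectors by default; a
  real network-layer extraction can be plugged in through the same table);
* ``annot`` — one-hot clip content annotations;
* ``eye`` — saccade count and mean saccade duration within the clip;
* ``eye_annot`` — binary flags for fixated content.

Performance is stratified k-fold cross-validated within subject
(standardization is fit on training folds only, inside the fold pipeline),
then averaged across subjects with a one-sample t-test against chance (50%).
The reported metric is *balanced* accuracy (mean of the per-class hit rates):
correctness base rates sit above 50%, so raw accuracy has a majority-class
null at the base rate rather than at chance, while balanced accuracy has a
50% null under any label shuffle.  Raw accuracy is carried alongside.  Fold
assignments depend only on (seed, subject, labels), so ablations over feature
groups are paired trial-for-trial.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError
from .trial_io import StudyTable, cv_feature_matrix

FEATURE_GROUPS = ("cv", "annot", "eye", "eye_annot")

DEFAULT_N_FOLDS = 10
DEFAULT_N_ROUNDS = 100
DEFAULT_MAX_DEPTH = 1


@dataclass
class FeatureMatrix:
    """Trial-by-feature design matrix with column group labels."""

    X: np.ndarray
    y: np.ndarray                  # True = correct
    columns: list
    groups: list                   # group label per column
    subject_ids: np.ndarray
    clip_ids: np.ndarray
    requested_groups: tuple

    def select(self, groups: Iterable[str]) -> "FeatureMatrix":
        groups = tuple(groups)
        unknown = set(groups) - set(FEATURE_GROUPS)
        if unknown:
            raise ConfigurationError(f"unknown feature group(s): {sorted(unknown)}")
        missing = set(groups) - set(self.groups)
        if missing:
            raise ConfigurationError(
                f"feature group(s) not present in this matrix: {sorted(missing)}"
            )
        idx = [i for i, g in enumerate(self.groups) if g in groups]
        return FeatureMatrix(
            X=self.X[:, idx],
            y=self.y,
            columns=[self.columns[i] for i in idx],
            groups=[self.groups[i] for i in idx],
            subject_ids=self.subject_ids,
            clip_ids=self.clip_ids,
            requested_groups=groups,
        )


def assemble_features(
    study: StudyTable, groups: Sequence[str], trial_scope: str = "all"
) -> FeatureMatrix:
    """Build the design matrix for the requested feature groups.

    Rows are first-presentation trials (repeat second showings are excluded:
    they share the label-generating clip and would leak across folds).  Eye
    groups exist only for target trials of studies with fixation records;
    requesting them restricts rows to target trials, and requesting them on a
    study without eye data raises :class:`ConfigurationError` naming the
    group.  ``trial_scope`` may also be set to ``"targets"`` explicitly: when
    a content feature shifts familiarity symmetrically it raises hits but
    also false alarms, so its effect on pooled-correctness largely cancels —
    restricting to targets removes that cancellation.  Column order is
    deterministic; categorical annotations are one-hot encoded against a
    declared reference level (the last level of the vocabulary entry).
    """
    groups = tuple(groups)
    if trial_scope not in ("all", "targets"):
        raise ConfigurationError(f"unknown trial_scope: {trial_scope!r}")
    if not groups:
        raise ConfigurationError("at least one feature group is required")
    unknown = set(groups) - set(FEATURE_GROUPS)
    if unknown:
        raise ConfigurationError(f"unknown feature group(s): {sorted(unknown)}")
    eye_requested = bool({"eye", "eye_annot"} & set(groups))
    if eye_requested and not study.has_fixations():
        missing = sorted({"eye", "eye_annot"} & set(groups))
        raise ConfigurationError(
            f"feature group(s) {missing} need fixation records, which this "
            "study does not contain"
        )

    first = study.first_presentations()
    if eye_requested or trial_scope == "targets":
        first = first[first["trial_type"] == "target"]
    first = first.sort_values(["subject_id", "test_index"], kind="mergesort")

    blocks, columns, col_groups = [], [], []

    if "cv" in groups:
        if len(study.cv_features.columns) <= 1:
            raise ConfigurationError("feature group ['cv'] has no columns in this study")
        idx, mat = cv_feature_matrix(study)
        lut = {cid: row for cid, row in zip(idx, mat)}
        blocks.append(np.vstack([lut[c] for c in first["clip_id"]]))
        names = sorted(
            [c for c in study.cv_features.columns if c != "clip_id"],
            key=lambda c: (len(c), c),
        )
        columns += names
        col_groups += ["cv"] * len(names)

    if "annot" in groups:
        if study.annotations.empty:
            raise ConfigurationError("feature group ['annot'] has no data in this study")
        vocab = study.vocabulary or {
            f: sorted(
                study.annotations.loc[
                    study.annotations["feature_name"] == f, "feature_value"
                ].unique()
            )
            for f in sorted(study.annotations["feature_name"].unique())
        }
        wide = study.annotations.pivot_table(
            index="clip_id", columns="feature_name", values="feature_value",
            aggfunc="first",
        )
        sub = wide.reindex(first["clip_id"])
        for feat in sorted(vocab):
            levels = list(vocab[feat])
            for level in levels[:-1]:  # last level is the reference
                blocks.append(
                    (sub[feat].to_numpy() == level).astype(float)[:, None]
                )
                columns.append(f"{feat}={level}")
                col_groups.append("annot")

    if "eye" in groups:
        per_clip = study.fixations.groupby("clip_id").agg(
            n_saccades=("n_saccades", "first"),
            saccade_duration_ms=("saccade_duration_ms", "first"),
        )
        sub = per_clip.reindex(first["clip_id"])
        blocks.append(sub.to_numpy(dtype=float))
        columns += ["n_saccades", "saccade_duration_ms"]
        col_groups += ["eye", "eye"]

    if "eye_annot" in groups:
        flags = (
            study.fixations.pivot_table(
                index="clip_id", columns="fixated_feature", values="fixated",
                aggfunc="any",
            )
            .astype(float)
        )
        sub = flags.reindex(first["clip_id"]).fillna(0.0)
        for feat in sorted(flags.columns):
            blocks.append(sub[feat].to_numpy()[:, None])
            columns.append(f"fixated:{feat}")
            col_groups.append("eye_annot")

    X = np.hstack(blocks)
    return FeatureMatrix(
        X=X,
        y=first["correct"].to_numpy(dtype=bool),
        columns=columns,
        groups=col_groups,
        subject_ids=first["subject_id"].to_numpy(),
        clip_ids=first["clip_id"].to_numpy(),
        requested_groups=groups,
    )


@dataclass
class PredictionResult:
    per_subject: pd.DataFrame      # subject_id, accuracy, raw_accuracy (%), n_trials
    predictions: pd.DataFrame      # subject_id, clip_id, label, score, predicted
    mean_accuracy: float           # balanced accuracy, % across subjects
    sem_accuracy: float
    t_statistic: float
    p_value: float
    n_subjects: int
    groups: tuple
    config: dict = field(default_factory=dict)
    skipped_subjects: tuple = ()


def _make_learner(learner, n_rounds, max_depth, seed):
    if learner == "adaboost":
        clf = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=max_depth),
            n_estimators=n_rounds,
            random_state=seed,
        )
    elif learner == "svm_rbf":
        clf = SVC(kernel="rbf", random_state=seed)
    else:
        raise ConfigurationError(f"unknown learner: {learner!r}")
    return make_pipeline(StandardScaler(), clf)


def _subject_fold_seed(seed: int, subject_id: str) -> int:
    # independent of the feature columns so ablations share fold assignments;
    # crc32 keeps the derivation stable across processes
    sid_hash = zlib.crc32(subject_id.encode("utf-8"))
    return int(np.random.SeedSequence([seed, sid_hash])
               .generate_state(1)[0] % (2**31))


def train_predict_cv(
    features: FeatureMatrix,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    learner: str = "adaboost",
    n_rounds: int = DEFAULT_N_ROUNDS,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> PredictionResult:
    """Per-subject stratified cross-validation of the memorability classifier.

    Subjects whose labels are all-correct or all-incorrect (or too sparse to
    stratify) are skipped with a warning.  Per subject, held-out predictions
    are pooled over folds and scored as balanced accuracy; the group test is
    a two-sided one-sample t-test against 50%.
    """
    per_subject, rows, skipped = [], [], []
    for sid in np.unique(features.subject_ids):
        mask = features.subject_ids == sid
        Xs, ys = features.X[mask], features.y[mask]
        classes, counts = np.unique(ys, return_counts=True)
        if len(classes) < 2 or counts.min() < 2:
            warnings.warn(f"subject {sid}: labels degenerate, skipped")
            skipped.append(sid)
            continue
        k = int(min(n_folds, counts.min()))
        fold_seed = _subject_fold_seed(seed, str(sid))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        pred = np.zeros(len(ys), dtype=bool)
        score = np.zeros(len(ys))
        for train_idx, test_idx in skf.split(Xs, ys):
            model = _make_learner(learner, n_rounds, max_depth, fold_seed)
            try:
                model.fit(Xs[train_idx], ys[train_idx])
            except ValueError:
                # boosting cannot beat random on this fold (e.g. permuted
                # labels): fall back to the training majority class
                majority = bool(np.mean(ys[train_idx]) >= 0.5)
                pred[test_idx] = majority
                continue
            pred[test_idx] = model.predict(Xs[test_idx])
            if hasattr(model, "decision_function"):
                score[test_idx] = model.decision_function(Xs[test_idx])
        recall_pos = float(np.mean(pred[ys]))
        recall_neg = float(np.mean(~pred[~ys]))
        acc = 100.0 * 0.5 * (recall_pos + recall_neg)
        raw = 100.0 * float(np.mean(pred == ys))
        per_subject.append(
            {"subject_id": sid, "accuracy": acc, "raw_accuracy": raw,
             "n_trials": len(ys)}
        )
        clip_mask = features.clip_ids[mask]
        for c, yl, sc, pr in zip(clip_mask, ys, score, pred):
            rows.append(
                {"subject_id": sid, "clip_id": c, "label": bool(yl),
                 "score": float(sc), "predicted": bool(pr)}
            )

    ps = pd.DataFrame(per_subject)
    if len(ps) == 0:
        raise ConfigurationError("no subject had trainable labels")
    accs = ps["accuracy"].to_numpy()
    if len(accs) >= 2 and np.std(accs, ddof=1) > 0:
        t, p = stats.ttest_1samp(accs, popmean=50.0)
    else:
        t, p = float("nan"), float("nan")
    return PredictionResult(
        per_subject=ps,
        predictions=pd.DataFrame(rows),
        mean_accuracy=float(np.mean(accs)),
        sem_accuracy=(
            float(np.std(accs, ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else float("nan")
        ),
        t_statistic=float(t),
        p_value=float(p),
        n_subjects=len(ps),
        groups=features.requested_groups,
        config={
            "learner": learner, "n_folds": n_folds, "n_rounds": n_rounds,
            "max_depth": max_depth, "seed": seed,
        },
        skipped_subjects=tuple(skipped),
    )


def ablate_groups(
    features: FeatureMatrix,
    group_combinations: Sequence[Sequence[str]],
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    **learner_kwargs,
) -> dict:
    """Run the same CV protocol on several feature-group combinations.

    Fold assignments depend only on (seed, subject, labels), hence identical
    across combinations: comparisons are paired.  Returns
    ``{"cv+annot": PredictionResult, ...}`` keyed by the joined group names.
    """
    results = {}
    for combo in group_combinations:
        name = "+".join(combo)
        sub = features.select(combo)
        results[name] = train_predict_cv(
            sub, n_folds=n_folds, seed=seed, **learner_kwargs
        )
    return results
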