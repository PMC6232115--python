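"""Study data model and delimited-text I/O.

A study is a bundle of four tables plus metadata:

* ``trials`` — one row per old/new test trial (subject, test order, clip,
  target/foil, encoding time, yes/no response, correctness, covert-repeat
  linkage);
* ``annotations`` — long-format categorical content labels per clip;
* ``fixations`` — per-clip flags saying whether the subject fixated each
  content category, with saccade statistics (target clips only: foil clips
  come from a different subject's walk, whose gaze is irrelevant);
* ``cv_features`` — a fixed-dimension numeric feature vector per clip
  (surrogate or real visual-network activations).

All files are comma-separated UTF-8 with a mandatory header row.  Writing is
deterministic (fixed column order, rows sorted by subject and test order) so
that re-running a pipeline reproduces byte-identical artifacts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import IntegrityError, SchemaError

TRIAL_TYPES = ("target", "foil")
RESPONSES = ("yes", "no")

TRIAL_COLUMNS = [
    "subject_id",
    "test_index",
    "clip_id",
    "trial_type",
    "encode_time_s",
    "response",
    "correct",
    "repeat_group",
]
ANNOTATION_COLUMNS = ["clip_id", "feature_name", "feature_value"]
FIXATION_COLUMNS = [
    "clip_id",
    "fixation_index",
    "fixated_feature",
    "fixated",
    "n_saccades",
    "saccade_duration_ms",
]

FILE_NAMES = {
    "trials": "trials.csv",
    "annotations": "annotations.csv",
    "fixations": "fixations.csv",
    "cv_features": "cv_features.csv",
    "meta": "study.yaml",
}


def _empty_trials() -> pd.DataFrame:
    return pd.DataFrame(columns=TRIAL_COLUMNS)


@dataclass
class StudyTable:
    """In-memory container for one study (cohort) and its metadata.

    ``meta`` carries the experiment label, session duration, the declared
    content-feature vocabulary (``feature_vocabulary``: name -> list of
    levels) and free-form provenance notes.
    """

    trials: pd.DataFrame = field(default_factory=_empty_trials)
    annotations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=ANNOTATION_COLUMNS)
    )
    fixations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=FIXATION_COLUMNS)
    )
    cv_features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["clip_id"])
    )
    meta: dict = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------------

    @property
    def subjects(self) -> list:
        return sorted(self.trials["subject_id"].unique().tolist())

    @property
    def vocabulary(self) -> dict:
        return dict(self.meta.get("feature_vocabulary", {}))

    def has_fixations(self) -> bool:
        return len(self.fixations) > 0

    def first_presentations(self) -> pd.DataFrame:
        """Trials with second showings of covert repeats removed.

        Within each (subject, repeat_group) only the earliest test position is
        kept; trials without a repeat linkage are kept as they are.  All
        performance analyses run on this view so that repeated clips are not
        double counted and chance stays at 50%.
        """
        t = self.trials
        if t.empty:
            return t.copy()
        linked = t["repeat_group"].notna()
        if not linked.any():
            return t.copy()
        keep_idx = (
            t[linked]
            .groupby(["subject_id", "repeat_group"], sort=False)["test_index"]
            .idxmin()
        )
        mask = ~linked
        mask.loc[keep_idx] = True
        return t[mask].copy()

    def repeat_pairs(self) -> pd.DataFrame:
        """One row per covert repeat pair: both responses, agreement flag."""
        t = self.trials[self.trials["repeat_group"].notna()]
        rows = []
        for (sid, grp), g in t.groupby(["subject_id", "repeat_group"], sort=False):
            if len(g) != 2:
                continue
            g = g.sort_values("test_index")
            rows.append(
                {
                    "subject_id": sid,
                    "repeat_group": grp,
                    "clip_id": g["clip_id"].iloc[0],
                    "trial_type": g["trial_type"].iloc[0],
                    "response_1": g["response"].iloc[0],
                    "response_2": g["response"].iloc[1],
                    "agree": g["response"].iloc[0] == g["response"].iloc[1],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "subject_id",
                "repeat_group",
                "clip_id",
                "trial_type",
                "response_1",
                "response_2",
                "agree",
            ],
        )

    def validate(self) -> "StudyTable":
        _validate_study(self)
        return self


# -- validation ----------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} is missing required column(s): {', '.join(missing)}")


def _validate_study(study: StudyTable) -> None:
    t = study.trials
    _require_columns(t, TRIAL_COLUMNS, "trials")
    _require_columns(study.annotations, ANNOTATION_COLUMNS, "annotations")
    _require_columns(study.fixations, FIXATION_COLUMNS, "fixations")
    if "clip_id" not in study.cv_features.columns:
        raise SchemaError("cv_features is missing required column(s): clip_id")
    if t.empty:
        return

    bad_type = sorted(set(t["trial_type"]) - set(TRIAL_TYPES))
    if bad_type:
        raise SchemaError(f"unknown trial_type token(s): {bad_type}")
    bad_resp = sorted(set(t["response"]) - set(RESPONSES))
    if bad_resp:
        raise SchemaError(f"unknown response token(s): {bad_resp}")

    if (t["encode_time_s"] < 0).any():
        raise IntegrityError("encode_time_s must be non-negative")
    dup = t.duplicated(subset=["subject_id", "test_index"])
    if dup.any():
        pairs = t.loc[dup, ["subject_id", "test_index"]].drop_duplicates()
        raise IntegrityError(
            "test_index not unique within subject: "
            + ", ".join(f"{r.subject_id}@{r.test_index}" for r in pairs.itertuples())
        )

    expected = (t["response"] == "yes") == (t["trial_type"] == "target")
    if (t["correct"].astype(bool) != expected).any():
        n_bad = int((t["correct"].astype(bool) != expected).sum())
        raise IntegrityError(
            f"'correct' column inconsistent with response/trial_type on {n_bad} row(s)"
        )

    linked = t[t["repeat_group"].notna()]
    if not linked.empty:
        nun = linked.groupby(["subject_id", "repeat_group"])[
            ["clip_id", "trial_type"]
        ].nunique()
        bad = nun[(nun > 1).any(axis=1)]
        if not bad.empty:
            raise IntegrityError(
                "repeat groups with inconsistent clip_id/trial_type: "
                + ", ".join(map(str, bad.index.tolist()))
            )

    # cross references: every trial clip must resolve in annotations/cv_features
    for name, table in (("annotations", study.annotations), ("cv_features", study.cv_features)):
        if table.empty:
            continue
        known = set(table["clip_id"])
        missing = sorted(set(t["clip_id"]) - known)
        if missing:
            raise IntegrityError(
                f"clip_id(s) in trials unresolved in {name}: {', '.join(map(str, missing[:20]))}"
            )

    if not study.fixations.empty:
        target_clips = set(t.loc[t["trial_type"] == "target", "clip_id"])
        foil_clips = set(t.loc[t["trial_type"] == "foil", "clip_id"])
        bad_fix = sorted(set(study.fixations["clip_id"]) & (foil_clips - target_clips))
        if bad_fix:
            raise IntegrityError(
                f"fixation records attached to foil clips: {', '.join(map(str, bad_fix[:20]))}"
            )


def validate_balance(study: StudyTable) -> pd.DataFrame:
    """Per-subject target/foil counts over first presentations.

    ``balanced`` is true when the two counts are equal; chance performance on
    a balanced design is exactly 50%.
    """
    first = study.first_presentations()
    rows = []
    for sid, g in first.groupby("subject_id", sort=True):
        n_t = int((g["trial_type"] == "target").sum())
        n_f = int((g["trial_type"] == "foil").sum())
        rows.append(
            {"subject_id": sid, "n_target": n_t, "n_foil": n_f, "balanced": n_t == n_f}
        )
    return pd.DataFrame(rows, columns=["subject_id", "n_target", "n_foil", "balanced"])


# -- file I/O ------------------------------------------------------------------


def write_study(study: StudyTable, out_dir: str | os.PathLike) -> dict:
    """Write all study tables as CSV plus a ``study.yaml`` metadata file.

    Deterministic: fixed column order, trials sorted by (subject_id,
    test_index), the other tables by clip_id.  Returns the mapping of table
    name to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in FILE_NAMES.items()}

    trials = study.trials[TRIAL_COLUMNS].sort_values(
        ["subject_id", "test_index"], kind="mergesort"
    )
    trials.to_csv(paths["trials"], index=False)

    ann = study.annotations[ANNOTATION_COLUMNS].sort_values(
        ["clip_id", "feature_name"], kind="mergesort"
    )
    ann.to_csv(paths["annotations"], index=False)

    fix = study.fixations[FIXATION_COLUMNS].sort_values(
        ["clip_id", "fixation_index"], kind="mergesort"
    )
    fix.to_csv(paths["fixations"], index=False)

    cv_cols = ["clip_id"] + sorted(
        [c for c in study.cv_features.columns if c != "clip_id"],
        key=lambda c: (len(c), c),
    )
    cv = study.cv_features[cv_cols].sort_values("clip_id", kind="mergesort")
    cv.to_csv(paths["cv_features"], index=False, float_format="%.10g")

    with open(paths["meta"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(study.meta, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def read_study(in_dir: str | os.PathLike) -> StudyTable:
    """Read and validate a study written by :func:`write_study`.

    Raises :class:`SchemaError` for missing columns or unknown categorical
    tokens and :class:`IntegrityError` for broken cross references.
    """
    d = Path(in_dir)
    trials_path = d / FILE_NAMES["trials"]
    if not trials_path.exists():
        raise SchemaError(f"no trials table at {trials_path}")
    trials = pd.read_csv(
        trials_path,
        dtype={"subject_id": str, "clip_id": str, "repeat_group": str},
    )
    _require_columns(trials, TRIAL_COLUMNS, "trials")
    if not trials.empty:
        trials["test_index"] = trials["test_index"].astype(int)
        trials["encode_time_s"] = trials["encode_time_s"].astype(float)
        trials["correct"] = trials["correct"].astype(bool)
    trials["repeat_group"] = (
        trials["repeat_group"].astype(object).where(trials["repeat_group"].notna(), None)
    )

    def _read(name: str, columns: list) -> pd.DataFrame:
        p = d / FILE_NAMES[name]
        if not p.exists():
            return pd.DataFrame(columns=columns)
        df = pd.read_csv(p, dtype={"clip_id": str})
        if df.empty:
            df = pd.DataFrame(columns=columns if name != "cv_features" else df.columns)
        return df

    annotations = _read("annotations", ANNOTATION_COLUMNS)
    if not annotations.empty:
        annotations = annotations.astype(
            {"feature_name": str, "feature_value": str}
        )
    fixations = _read("fixations", FIXATION_COLUMNS)
    if not fixations.empty:
        fixations["fixated"] = fixations["fixated"].astype(bool)
        fixations["fixation_index"] = fixations["fixation_index"].astype(int)
    cv_features = _read("cv_features", ["clip_id"])

    meta_path = d / FILE_NAMES["meta"]
    meta = {}
    if meta_path.exists():
        with open(meta_path, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}

    study = StudyTable(
        trials=trials,
        annotations=annotations,
        fixations=fixations,
        cv_features=cv_features,
        meta=meta,
    )
    study.validate()
    return study


def cv_feature_matrix(study: StudyTable) -> tuple[pd.Index, np.ndarray]:
    """Return (clip index, dense array) for the per-clip numeric features."""
    cv = study.cv_features.set_index("clip_id")
    cols = sorted(cv.columns, key=lambda c: (len(c), c))
    return cv.index, cv[cols].to_numpy(dtype=float)
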