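"""Shared fixtures: hand-built micro studies and scaled-down synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import memtrace as mt
from memtrace.trial_io import StudyTable


def trial_row(subject, idx, clip, ttype, t, resp, grp=None):
    correct = (resp == "yes") == (ttype == "target")
    return {
        "subject_id": subject,
        "test_index": idx,
        "clip_id": clip,
        "trial_type": ttype,
        "encode_time_s": float(t),
        "response": resp,
        "correct": correct,
        "repeat_group": grp,
    }


def make_trials(rows) -> pd.DataFrame:
    return pd.DataFrame([trial_row(*r) for r in rows])


def make_study(trials: pd.DataFrame, annotations=None, fixations=None) -> StudyTable:
    study = StudyTable(trials=trials)
    if annotations is not None:
        study.annotations = pd.DataFrame(
            annotations, columns=["clip_id", "feature_name", "feature_value"]
        )
    if fixations is not None:
        study.fixations = pd.DataFrame(
            fixations,
            columns=[
                "clip_id", "fixation_index", "fixated_feature", "fixated",
                "n_saccades", "saccade_duration_ms",
            ],
        )
    return study


@pytest.fixture(scope="session")
def small_cohort() -> StudyTable:
    """4-subject outdoor-style cohort, ~100 clips per subject."""
    cfg = mt.experiment_i(
        n_subjects=4, session_duration_s=720.0, n_repeats=10, cv_dim=8, seed=42
    )
    return mt.build_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_fix() -> StudyTable:
    """4-subject indoor-style cohort with fixation records."""
    cfg = mt.experiment_ii(
        n_subjects=4, session_duration_s=760.0, n_repeats=8, cv_dim=8, seed=43
    )
    return mt.build_cohort(cfg)
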