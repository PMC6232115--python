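"""Study data model: round-trip I/O, validation, balance accounting."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import memtrace as mt
from memtrace.errors import IntegrityError, SchemaError
from memtrace.trial_io import StudyTable

from conftest import make_study, make_trials, trial_row


def _hash_dir(d: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(d.iterdir())
    }


class TestRoundTrip:
    def test_cohort_round_trips_field_for_field(self, small_cohort, tmp_path):
        mt.write_study(small_cohort, tmp_path)
        back = mt.read_study(tmp_path)
        orig = small_cohort.trials.sort_values(
            ["subject_id", "test_index"]
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            back.trials.reset_index(drop=True), orig, check_dtype=False
        )
        assert set(back.annotations["clip_id"]) == set(
            small_cohort.annotations["clip_id"]
        )
        assert back.meta["feature_vocabulary"] == small_cohort.vocabulary

    def test_double_write_is_byte_identical(self, small_cohort, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        mt.write_study(small_cohort, a)
        mt.write_study(small_cohort, b)
        assert _hash_dir(a) == _hash_dir(b)

    def test_empty_study_writes_headers_only(self, tmp_path):
        mt.write_study(StudyTable(), tmp_path)
        lines = (tmp_path / "trials.csv").read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("subject_id,")
        back = mt.read_study(tmp_path)
        assert back.trials.empty

    @settings(max_examples=25, deadline=None)
    @given(
        n_subjects=st.integers(1, 3),
        n_trials=st.integers(1, 8),
        data=st.data(),
    )
    def test_random_study_round_trip(self, n_subjects, n_trials, data, tmp_path_factory):
        rows = []
        for s in range(n_subjects):
            for i in range(n_trials):
                ttype = data.draw(st.sampled_from(["target", "foil"]))
                resp = data.draw(st.sampled_from(["yes", "no"]))
                t = data.draw(st.floats(0, 1000, allow_nan=False))
                rows.append((f"s{s}", i, f"c{s}_{i}", ttype, t, resp))
        study = make_study(make_trials(rows))
        out = tmp_path_factory.mktemp("rt")
        mt.write_study(study, out)
        back = mt.read_study(out)
        got = back.trials.sort_values(["subject_id", "test_index"]).reset_index(drop=True)
        want = study.trials.sort_values(["subject_id", "test_index"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want, check_dtype=False)


class TestValidation:
    def test_unknown_response_token_is_schema_error(self, tmp_path):
        study = make_study(make_trials([("s1", 0, "c1", "target", 1.0, "yes")]))
        mt.write_study(study, tmp_path)
        trials = pd.read_csv(tmp_path / "trials.csv")
        trials.loc[0, "response"] = "maybe"
        trials.to_csv(tmp_path / "trials.csv", index=False)
        with pytest.raises(SchemaError, match="maybe"):
            mt.read_study(tmp_path)

    def test_missing_column_names_the_column(self, tmp_path):
        study = make_study(make_trials([("s1", 0, "c1", "target", 1.0, "yes")]))
        mt.write_study(study, tmp_path)
        trials = pd.read_csv(tmp_path / "trials.csv").drop(columns=["encode_time_s"])
        trials.to_csv(tmp_path / "trials.csv", index=False)
        with pytest.raises(SchemaError, match="encode_time_s"):
            mt.read_study(tmp_path)

    def test_unresolved_clip_reference_lists_offender(self):
        trials = make_trials(
            [
                ("s1", 0, "c1", "target", 1.0, "yes"),
                ("s1", 1, "c2", "foil", 2.0, "no"),
                ("s1", 2, "c999", "target", 3.0, "no"),
            ]
        )
        ann = [("c1", "faces_present", "yes"), ("c2", "faces_present", "no")]
        study = make_study(trials, annotations=ann)
        with pytest.raises(IntegrityError, match="c999"):
            study.validate()

    def test_inconsistent_correct_column_rejected(self):
        trials = make_trials([("s1", 0, "c1", "target", 1.0, "yes")])
        trials.loc[0, "correct"] = False
        with pytest.raises(IntegrityError, match="correct"):
            make_study(trials).validate()

    def test_duplicate_test_index_rejected(self):
        trials = make_trials(
            [("s1", 0, "c1", "target", 1.0, "yes"), ("s1", 0, "c2", "foil", 2.0, "no")]
        )
        with pytest.raises(IntegrityError, match="test_index"):
            make_study(trials).validate()

    def test_repeat_group_must_share_clip(self):
        trials = make_trials(
            [
                ("s1", 0, "c1", "target", 1.0, "yes", "g1"),
                ("s1", 1, "c2", "target", 1.0, "yes", "g1"),
            ]
        )
        with pytest.raises(IntegrityError, match="repeat"):
            make_study(trials).validate()


class TestBalance:
    def _study(self, n_t, n_f, repeats=0):
        rows = []
        idx = 0
        for i in range(n_t):
            rows.append(("s1", idx, f"t{i}", "target", float(i), "yes")); idx += 1
        for i in range(n_f):
            rows.append(("s1", idx, f"f{i}", "foil", float(i), "no")); idx += 1
        trials = make_trials(rows)
        extra = []
        for k in range(repeats):
            for ttype, pref in (("target", "t"), ("foil", "f")):
                grp = f"g_{ttype}{k}"
                trials.loc[
                    (trials["clip_id"] == f"{pref}{k}"), "repeat_group"
                ] = grp
                extra.append(
                    trial_row("s1", idx, f"{pref}{k}", ttype, float(k), "yes", grp)
                )
                idx += 1
        if extra:
            trials = pd.concat([trials, pd.DataFrame(extra)], ignore_index=True)
        return make_study(trials)

    def test_equal_counts_balanced(self):
        rep = mt.validate_balance(self._study(10, 10))
        assert rep.loc[0, "balanced"] and rep.loc[0, "n_target"] == 10

    def test_unequal_counts_reported(self):
        rep = mt.validate_balance(self._study(10, 8))
        assert not rep.loc[0, "balanced"]
        assert (rep.loc[0, "n_target"], rep.loc[0, "n_foil"]) == (10, 8)

    def test_repeats_excluded_symmetrically(self):
        # 10+10 with 2 repeated targets and 2 repeated foils: still balanced,
        # second presentations do not enter the counts
        rep = mt.validate_balance(self._study(10, 10, repeats=2))
        assert rep.loc[0, "balanced"]
        assert rep.loc[0, "n_target"] == 10 and rep.loc[0, "n_foil"] == 10


def test_first_presentations_keep_earliest_showing():
    trials = make_trials(
        [
            ("s1", 5, "c1", "target", 1.0, "yes", "g1"),
            ("s1", 2, "c1", "target", 1.0, "no", "g1"),
            ("s1", 3, "c2", "foil", 4.0, "no"),
        ]
    )
    first = make_study(trials).first_presentations()
    assert len(first) == 2
    kept = first[first["clip_id"] == "c1"]
    assert kept["test_index"].tolist() == [2]
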