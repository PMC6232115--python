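"""Content/fixation splits and the rank-sum comparison vs enumeration."""

import itertools

import numpy as np
import pytest
from scipy import stats

import memtrace as mt
from memtrace.content import compare_levels, split_by_content, split_by_fixation
from memtrace.errors import ConfigurationError, VocabularyError

from conftest import make_study, make_trials


def rank_sum_exact_oracle(a, b):
    """Exhaustive-permutation two-sided rank-sum p-value (midrank ties).

    Independent of the implementation: enumerates every assignment of the
    pooled values to groups and doubles the smaller tail of the rank-sum
    statistic (capped at 1)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    sums = np.array(
        [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), n_a)]
    )
    p_le = np.mean(sums <= obs + 1e-9)
    p_ge = np.mean(sums >= obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def _content_study(corrects_with, corrects_without):
    rows, ann, idx = [], [], 0
    for i, c in enumerate(corrects_with):
        cid = f"w{i}"
        rows.append(("s1", idx, cid, "target", float(i), "yes" if c else "no"))
        ann.append((cid, "faces_present", "yes")); idx += 1
    for i, c in enumerate(corrects_without):
        cid = f"o{i}"
        rows.append(("s1", idx, cid, "target", 100.0 + i, "yes" if c else "no"))
        ann.append((cid, "faces_present", "no")); idx += 1
    return make_study(make_trials(rows), annotations=ann)


class TestContentSplit:
    def test_hand_counted_cells(self):
        study = _content_study([1, 1, 1, 0], [1, 0, 0, 0])
        cells = split_by_content(study, "faces_present", min_n=1)
        by = cells.set_index(["level", "trial_type"])["percent_correct"]
        assert by[("yes", "target")] == pytest.approx(75.0)
        assert by[("no", "target")] == pytest.approx(25.0)

    def test_all_correct_gives_100_everywhere(self):
        study = _content_study([1, 1, 1], [1, 1])
        cells = split_by_content(study, "faces_present", min_n=1)
        occupied = cells[cells["n_trials"] > 0]
        assert np.allclose(occupied["percent_correct"], 100.0)

    def test_unknown_feature_is_vocabulary_error(self):
        study = _content_study([1], [0])
        with pytest.raises(VocabularyError, match="nonexistent"):
            split_by_content(study, "nonexistent")

    def test_single_level_warns(self):
        study = _content_study([1, 0, 1], [])
        with pytest.warns(UserWarning, match="single level"):
            split_by_content(study, "faces_present", min_n=1)

    def test_cell_counts_sum_to_first_presentations(self, small_cohort):
        first = small_cohort.first_presentations()
        for feature in small_cohort.vocabulary:
            cells = split_by_content(small_cohort, feature)
            for ttype in ("target", "foil"):
                total = cells.loc[cells["trial_type"] == ttype, "n_trials"].sum()
                assert total == (first["trial_type"] == ttype).sum()


class TestRankSum:
    def test_identical_multisets_p_one(self):
        r = compare_levels([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_extreme_separation_exact_tail(self):
        # {1,2,3} vs {4,5,6}: statistic at its extreme, 2/C(6,3) = 0.1
        r = compare_levels([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert r.method == "exact_permutation"
        assert r.p_value == pytest.approx(0.1, abs=1e-9)

    def test_interleaved_groups_not_significant(self):
        a, b = [55.0, 57.0, 60.0, 62.0], [54.0, 56.0, 59.0, 61.0]
        r = compare_levels(a, b)
        assert r.p_value == pytest.approx(rank_sum_exact_oracle(a, b), abs=1e-9)
        assert not r.significant

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (3, 3), (4, 6), (5, 5), (8, 8)])
    def test_matches_enumeration_oracle(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for trial in range(3):
            a = rng.normal(0, 1, n_a)
            b = rng.normal(0.8, 1, n_b)
            if trial == 2:  # force ties
                a = np.round(a); b = np.round(b)
            r = compare_levels(a, b)
            assert r.p_value == pytest.approx(rank_sum_exact_oracle(a, b), abs=1e-9)

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        r = compare_levels(a, b)
        assert r.method == "normal_tie_corrected"
        want = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert r.p_value == pytest.approx(want.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_levels([], [1.0])


class TestFixationSplit:
    def _study(self):
        rows, ann, fix = [], [], []
        # 6 target trials: fixated-on-talking clips 0-2 (2 correct),
        # non-fixated clips 3-5 (1 correct)
        corr = [1, 1, 0, 1, 0, 0]
        fixd = [True, True, True, False, False, False]
        for i in range(6):
            cid = f"c{i}"
            rows.append(("s1", i, cid, "target", float(i),
                         "yes" if corr[i] else "no"))
            ann.append((cid, "talking", "yes"))
            fix.append((cid, 0, "talking", fixd[i], 3, 250.0))
        for i in range(6):
            rows.append(("s1", 6 + i, f"f{i}", "foil", float(i), "no"))
        return make_study(make_trials(rows), annotations=ann, fixations=fix)

    def test_hand_counted_fixation_cells(self):
        cells = split_by_fixation(self._study(), "talking", min_n=1)
        by = cells.set_index("fixated")["percent_correct"]
        assert by["Y"] == pytest.approx(100 * 2 / 3)
        assert by["N"] == pytest.approx(100 * 1 / 3)
        assert cells.set_index("fixated")["n_trials"].tolist() == [3, 3]

    def test_requires_fixation_records(self):
        study = _content_study([1], [0])
        with pytest.raises(ConfigurationError, match="fixation"):
            split_by_fixation(study, "faces_present")

    def test_planted_fixation_effect_direction(self):
        """A positive planted talking-fixation effect raises performance on
        fixated-talking targets relative to non-fixated ones."""
        diffs = []
        for r in range(3):
            cfg = mt.experiment_ii(
                n_subjects=4, session_duration_s=1200.0, n_repeats=8, cv_dim=4,
                seed=60 + r,
            )
            cfg.feature_spec["talking"] = mt.binary_feature(
                0.4, fixation_prob=0.6, fixation_effect=0.8
            )
            study = mt.build_cohort(cfg)
            cells = split_by_fixation(study, "talking").set_index("fixated")
            diffs.append(
                cells.loc["Y", "percent_correct"] - cells.loc["N", "percent_correct"]
            )
        assert np.mean(diffs) > 0

    def test_null_fixation_effect_small_difference(self):
        cfg = mt.experiment_ii(n_subjects=4, session_duration_s=1500.0,
                               n_repeats=8, cv_dim=4, seed=66)
        study = mt.build_cohort(cfg)
        cells = split_by_fixation(study, "talking").set_index("fixated")
        diff = cells.loc["Y", "percent_correct"] - cells.loc["N", "percent_correct"]
        assert abs(diff) < 8.0
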