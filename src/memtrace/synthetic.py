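"""Synthetic cohorts for the one-second real-life recognition-memory task.

Generates trial tables, content annotations, fixation flags and surrogate
visual feature vectors whose statistical structure matches a configurable set
of study conditions: per-subject sensitivity barely above chance, covert
repeats with calibrated response agreement, and a history dependence of
correctness over encoding time that follows ``y = 1 + alpha*exp(-dt/tau)``.

Generative model (all variances in familiarity-SD units, summing to 1):

    f = mu(trial_type) + sqrt(w_g) * g(t)  +  clip_persistent  +  sqrt(w_eps) * eps

* ``g(t)`` — stationary Gaussian (Ornstein-Uhlenbeck) with autocovariance
  ``exp(-dt/tau_gen_s)``, simulated exactly at the clip onset times via the
  conditional AR recursion (no discretization error).  Present for target
  clips (it lives on the subject's own encoding timeline); foil clips carry
  an iid clip-level stand-in of equal variance so marginals match.
* ``clip_persistent`` — content effects plus a clip-level trait ``eta``;
  never redrawn, so it is shared by the two presentations of a repeat.
* ``eps`` — trial-unique noise, the only component redrawn on a repeat.

``mu(target) - mu(foil) = d'`` (per subject, Gaussian between-subject spread)
and responses are ``yes`` iff ``f > criterion``.  ``w_g`` is set by the
dichotomized-Gaussian calibration so the binary correctness correlation at
zero lag induces the requested lag-curve amplitude; ``w_eps`` is set so the
cohort-mean repeat agreement hits the requested self-consistency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import (
    calibrate_consistency_cohort,
    calibrate_latent_correlation,
)
from .errors import CalibrationError
from .trial_io import StudyTable

__all__ = [
    "FeatureSpec",
    "GeneratorConfig",
    "Session",
    "experiment_i",
    "experiment_i_3month",
    "experiment_ii",
    "subject_seed",
    "draw_intervals",
    "generate_session",
    "simulate_responses",
    "build_cohort",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One annotated content feature of the clip vocabulary.

    ``levels``/``probs`` define the categorical distribution per clip;
    ``effects`` (familiarity-SD units) are added to clip familiarity according
    to the drawn level, centred so the cohort d' is unaffected.
    ``fixation_probs`` give P(subject fixates this content | clip level);
    ``fixation_effects`` are added to target-clip familiarity when fixated.
    """

    levels: tuple = ("yes", "no")
    probs: tuple = (0.5, 0.5)
    effects: tuple = (0.0, 0.0)
    fixation_probs: tuple = (0.0, 0.0)
    fixation_effects: tuple = (0.0, 0.0)

    def __post_init__(self):
        n = len(self.levels)
        for name in ("probs", "effects", "fixation_probs", "fixation_effects"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"FeatureSpec.{name} must have {n} entries")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("FeatureSpec.probs must sum to 1")

    @property
    def effect_mean(self) -> float:
        return float(np.dot(self.probs, self.effects))

    @property
    def effect_var(self) -> float:
        m = self.effect_mean
        return float(np.dot(self.probs, (np.asarray(self.effects) - m) ** 2))


def binary_feature(
    prevalence: float,
    effect: float = 0.0,
    fixation_prob: float = 0.0,
    fixation_effect: float = 0.0,
) -> FeatureSpec:
    """Yes/no feature present with probability ``prevalence``."""
    return FeatureSpec(
        levels=("yes", "no"),
        probs=(prevalence, 1.0 - prevalence),
        effects=(effect, 0.0),
        fixation_probs=(fixation_prob, 0.0),
        fixation_effects=(fixation_effect, 0.0),
    )


def _default_features_outdoor() -> dict:
    return {
        "faces_present": binary_feature(0.70),
        "gender": FeatureSpec(("female", "male"), (0.5, 0.5), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0)),
        "n_faces_bin": FeatureSpec(
            ("none", "one", "several"), (0.30, 0.35, 0.35), (0.0, 0.0, 0.0),
            (0.0, 0.0, 0.0), (0.0, 0.0, 0.0),
        ),
        "age_bin": FeatureSpec(("young", "old"), (0.7, 0.3), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0)),
        "action": binary_feature(0.40),
        "talking": binary_feature(0.30),
        "distinct_face": binary_feature(0.20),
        "distinct_object": binary_feature(0.25),
        "people_background": binary_feature(0.50),
    }


def _default_features_indoor() -> dict:
    # fixation probabilities: how often gaze lands on the content when present
    feats = {
        "faces_present": binary_feature(0.70, fixation_prob=0.65),
        "gender": FeatureSpec(
            ("female", "male"), (0.5, 0.5), (0.0, 0.0), (0.5, 0.5), (0.0, 0.0)
        ),
        "n_faces_bin": FeatureSpec(
            ("none", "one", "several"), (0.30, 0.35, 0.35), (0.0, 0.0, 0.0),
            (0.0, 0.6, 0.6), (0.0, 0.0, 0.0),
        ),
        "age_bin": FeatureSpec(
            ("young", "old"), (0.7, 0.3), (0.0, 0.0), (0.5, 0.5), (0.0, 0.0)
        ),
        "action": binary_feature(0.40, fixation_prob=0.55),
        "talking": binary_feature(0.30, fixation_prob=0.55),
        "distinct_face": binary_feature(0.20, fixation_prob=0.5),
        "distinct_object": binary_feature(0.25, fixation_prob=0.6),
        "painting": binary_feature(0.55, fixation_prob=0.7),
        "sculpture": binary_feature(0.25, fixation_prob=0.5),
    }
    return feats


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    Defaults reproduce the outdoor (Experiment-I-style, 1-day) study
    conditions; see :func:`experiment_i` and friends for named presets.
    """

    n_subjects: int = 16
    session_duration_s: float = 3540.0
    interval_mean_s: float = 7.07
    interval_sd_s: float = 0.89
    interval_min_s: float = 0.5
    n_repeats: int = 25  # repeat pairs per trial type

    # signal detection
    d_prime_gen: Optional[float] = 0.29
    criterion_gen: float = 0.065
    d_prime_sd: float = 0.19
    criterion_sd: float = 0.35
    p_overall: Optional[float] = None  # alternative to d_prime_gen (criterion 0)

    # history dependence of correctness over encoding time
    alpha_gen: float = 0.32
    tau_gen_s: float = 28.4

    # covert-repeat response agreement
    consistency_target: float = 0.781

    # content/fixation structure
    feature_spec: dict = field(default_factory=_default_features_outdoor)
    with_fixations: bool = False
    saccades_rate: float = 3.0
    saccade_duration_mean_ms: float = 250.0
    saccade_duration_sd_ms: float = 60.0

    # surrogate visual features
    cv_dim: int = 64
    cv_signal: float = 0.4

    seed: int = 0
    experiment: str = "experiment_I_1day"

    def __post_init__(self):
        if self.p_overall is not None:
            if not 0.0 < self.p_overall < 1.0:
                raise ValueError("p_overall must be in (0, 1)")
            if self.d_prime_gen is None:
                self.d_prime_gen = float(2.0 * stats.norm.ppf(self.p_overall))
        if self.d_prime_gen is None:
            raise ValueError("either d_prime_gen or p_overall must be given")
        if self.alpha_gen < 0:
            raise ValueError("alpha_gen must be non-negative")
        if self.tau_gen_s <= 0:
            raise ValueError("tau_gen_s must be positive")
        if not 0.5 <= self.consistency_target <= 1.0:
            raise ValueError("consistency_target must be in [0.5, 1]")

    # -- expected rates for the mean subject ----------------------------------

    @property
    def expected_hit_rate(self) -> float:
        return float(stats.norm.cdf(self.d_prime_gen / 2.0 - self.criterion_gen))

    @property
    def expected_cr_rate(self) -> float:
        return float(stats.norm.cdf(self.d_prime_gen / 2.0 + self.criterion_gen))

    @property
    def expected_percent_correct(self) -> float:
        return 50.0 * (self.expected_hit_rate + self.expected_cr_rate)

    def variance_budget(self) -> dict:
        """Calibrated variance shares {w_g, w_clip, w_eps, eta_var, feat_var}.

        Raises :class:`CalibrationError` when the requested amplitude and
        consistency jointly exceed the unit familiarity variance.
        """
        w_g = calibrate_latent_correlation(self.alpha_gen, self.expected_hit_rate)
        w_eps = calibrate_consistency_cohort(
            self.consistency_target,
            self.d_prime_gen,
            self.d_prime_sd,
            self.criterion_gen,
            self.criterion_sd,
        )
        w_clip = 1.0 - w_g - w_eps
        feat_var = sum(fs.effect_var for fs in self.feature_spec.values())
        eta_var = w_clip - feat_var
        if eta_var < -1e-9:
            raise CalibrationError(
                "infeasible configuration: temporal share "
                f"w_g={w_g:.3f} + trial-noise share w_eps={w_eps:.3f} + "
                f"content-effect variance {feat_var:.3f} exceeds the unit "
                "familiarity variance"
            )
        return {
            "w_g": w_g,
            "w_eps": w_eps,
            "w_clip": w_clip,
            "feat_var": feat_var,
            "eta_var": max(eta_var, 0.0),
        }

    def vocabulary(self) -> dict:
        return {name: list(fs.levels) for name, fs in self.feature_spec.items()}


def experiment_i(**overrides) -> GeneratorConfig:
    """Outdoor-walk cohort, 1-day retention (no usable eye tracking)."""
    cfg = dict(
        session_duration_s=3540.0,
        interval_mean_s=7.07,
        interval_sd_s=0.89,
        n_repeats=25,
        d_prime_gen=0.29,
        criterion_gen=0.065,
        d_prime_sd=0.19,
        criterion_sd=0.35,
        alpha_gen=0.32,
        tau_gen_s=28.4,
        consistency_target=0.781,
        feature_spec=_default_features_outdoor(),
        with_fixations=False,
        experiment="experiment_I_1day",
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def experiment_i_3month(**overrides) -> GeneratorConfig:
    """Outdoor-walk cohort retested three months after encoding."""
    cfg = dict(
        session_duration_s=3540.0,
        interval_mean_s=7.07,
        interval_sd_s=0.89,
        n_repeats=25,
        d_prime_gen=0.41,
        criterion_gen=0.18,
        d_prime_sd=0.38,
        criterion_sd=0.35,
        alpha_gen=0.375,
        tau_gen_s=37.6,
        consistency_target=0.781,
        feature_spec=_default_features_outdoor(),
        with_fixations=False,
        experiment="experiment_I_3month",
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def experiment_ii(**overrides) -> GeneratorConfig:
    """Indoor-museum cohort with usable eye tracking (fixation records)."""
    cfg = dict(
        session_duration_s=3324.0,
        interval_mean_s=7.50,
        interval_sd_s=0.32,
        n_repeats=18,
        d_prime_gen=0.67,
        criterion_gen=0.106,
        d_prime_sd=0.41,
        criterion_sd=0.27,
        alpha_gen=0.13,
        tau_gen_s=10.8,
        consistency_target=0.749,
        feature_spec=_default_features_indoor(),
        with_fixations=True,
        experiment="experiment_II",
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


# -- randomness plumbing -------------------------------------------------------


def subject_seed(master_seed: int, subject_index: int) -> np.random.SeedSequence:
    """Deterministic per-subject seed stream.

    Explicit derivation rule: ``SeedSequence(master_seed, spawn_key=(k,))`` for
    subject index ``k``, so any single subject can be regenerated in isolation.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(subject_index,))


# -- session generation --------------------------------------------------------


def draw_intervals(config: GeneratorConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Inter-onset intervals: normal truncated below at ``interval_min_s``."""
    a = (config.interval_min_s - config.interval_mean_s) / config.interval_sd_s
    return stats.truncnorm.rvs(
        a, np.inf, loc=config.interval_mean_s, scale=config.interval_sd_s,
        size=n, random_state=rng,
    )


def _ou_at_times(times: np.ndarray, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary exponential-autocovariance Gaussian sampled
    exactly at irregular times via the conditional AR(1) recursion."""
    n = len(times)
    g = np.empty(n)
    if n == 0:
        return g
    g[0] = rng.standard_normal()
    phi = np.exp(-np.diff(times) / tau)
    innov = rng.standard_normal(n - 1)
    for i in range(1, n):
        g[i] = phi[i - 1] * g[i - 1] + np.sqrt(1.0 - phi[i - 1] ** 2) * innov[i - 1]
    return g


@dataclass
class Session:
    """One encoding walk: clip onsets plus everything attached to the clips."""

    clip_ids: list
    onset_s: np.ndarray
    annotations: pd.DataFrame
    fixations: pd.DataFrame
    cv_features: pd.DataFrame
    persistent: np.ndarray      # content effects + eta (variance w_clip)
    fixation_effect: np.ndarray  # extra familiarity from fixated content
    g: np.ndarray               # unit-variance temporal process at onsets


def generate_session(
    config: GeneratorConfig,
    rng: np.random.Generator,
    clip_prefix: str,
) -> Session:
    """Generate one encoding session (clip times, annotations, fixations,
    surrogate visual features, and the latent familiarity components)."""
    budget = config.variance_budget()
    n_max = int(config.session_duration_s / config.interval_min_s) + 1
    n_guess = int(config.session_duration_s / config.interval_mean_s * 1.25) + 10
    intervals = draw_intervals(config, rng, min(n_guess, n_max))
    onsets = np.cumsum(intervals)
    onsets = onsets[onsets <= config.session_duration_s]
    n = len(onsets)
    clip_ids = [f"{clip_prefix}{i:04d}" for i in range(n)]

    ann_rows = []
    feat_effect = np.zeros(n)
    fix_effect = np.zeros(n)
    fix_rows = []
    for name, fs in config.feature_spec.items():
        idx = rng.choice(len(fs.levels), size=n, p=fs.probs)
        effects = np.asarray(fs.effects, dtype=float)
        feat_effect += effects[idx] - fs.effect_mean
        for i in range(n):
            ann_rows.append((clip_ids[i], name, fs.levels[idx[i]]))
        if config.with_fixations:
            fprob = np.asarray(fs.fixation_probs, dtype=float)[idx]
            fixated = rng.random(n) < fprob
            feff = np.asarray(fs.fixation_effects, dtype=float)
            mean_fix_eff = float(
                np.dot(fs.probs, np.asarray(fs.fixation_probs) * feff)
            )
            fix_effect += np.where(fixated, feff[idx], 0.0) - mean_fix_eff
            for i in range(n):
                fix_rows.append((clip_ids[i], name, bool(fixated[i])))

    annotations = pd.DataFrame(ann_rows, columns=["clip_id", "feature_name", "feature_value"])

    if config.with_fixations:
        n_sacc = 1 + rng.poisson(max(config.saccades_rate - 1.0, 0.0), size=n)
        sacc_dur = np.clip(
            rng.normal(config.saccade_duration_mean_ms, config.saccade_duration_sd_ms, size=n),
            20.0, None,
        )
        per_clip = {cid: (int(ns), float(sd)) for cid, ns, sd in zip(clip_ids, n_sacc, sacc_dur)}
        fixations = pd.DataFrame(fix_rows, columns=["clip_id", "fixated_feature", "fixated"])
        fixations["fixation_index"] = fixations.groupby("clip_id").cumcount()
        fixations["n_saccades"] = fixations["clip_id"].map(lambda c: per_clip[c][0])
        fixations["saccade_duration_ms"] = fixations["clip_id"].map(lambda c: per_clip[c][1])
        fixations = fixations[
            ["clip_id", "fixation_index", "fixated_feature", "fixated",
             "n_saccades", "saccade_duration_ms"]
        ]
    else:
        fixations = pd.DataFrame(
            columns=["clip_id", "fixation_index", "fixated_feature", "fixated",
                     "n_saccades", "saccade_duration_ms"]
        )

    eta = rng.normal(0.0, np.sqrt(budget["eta_var"]), size=n)
    persistent = feat_effect + eta

    cv = rng.standard_normal((n, config.cv_dim))
    if config.cv_dim > 0 and config.cv_signal != 0:
        s = float(np.clip(config.cv_signal, -1.0, 1.0))
        scale = np.sqrt(budget["w_clip"]) if budget["w_clip"] > 0 else 1.0
        cv[:, 0] = s * persistent / scale + np.sqrt(1.0 - s * s) * cv[:, 0]
    cv_features = pd.DataFrame(cv, columns=[f"f{j}" for j in range(config.cv_dim)])
    cv_features.insert(0, "clip_id", clip_ids)

    g = _ou_at_times(onsets, config.tau_gen_s, rng)

    return Session(
        clip_ids=clip_ids,
        onset_s=onsets,
        annotations=annotations,
        fixations=fixations,
        cv_features=cv_features,
        persistent=persistent,
        fixation_effect=fix_effect,
        g=g,
    )


# -- response simulation -------------------------------------------------------


def simulate_responses(
    session: Session,
    donor: Session,
    config: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str,
) -> pd.DataFrame:
    """Simulate one subject's full test: targets from the subject's own
    session, foils from an independently generated donor session, covert
    repeats of ``n_repeats`` clips per type, test order shuffled."""
    budget = config.variance_budget()
    w_g, w_eps = budget["w_g"], budget["w_eps"]

    d_prime = max(rng.normal(config.d_prime_gen, config.d_prime_sd), 0.0)
    criterion = rng.normal(config.criterion_gen, config.criterion_sd)

    n = min(len(session.clip_ids), len(donor.clip_ids))
    if n < 2 * config.n_repeats:
        raise CalibrationError("session too short for the requested repeat count")

    # persistent familiarity per clip (everything but the trial-unique noise)
    base_target = (
        d_prime / 2.0
        + np.sqrt(w_g) * session.g[:n]
        + session.persistent[:n]
        + session.fixation_effect[:n]
    )
    # foils: donor clips; the subject has no encoding-time process for them,
    # an iid clip-level term of variance w_g keeps the marginals matched
    base_foil = (
        -d_prime / 2.0
        + donor.persistent[:n]
        + np.sqrt(w_g) * rng.standard_normal(n)
    )

    rep_t = rng.choice(n, size=config.n_repeats, replace=False)
    rep_f = rng.choice(n, size=config.n_repeats, replace=False)
    grp_t = {int(i): f"{subject_id}_rt{k}" for k, i in enumerate(rep_t)}
    grp_f = {int(i): f"{subject_id}_rf{k}" for k, i in enumerate(rep_f)}

    rows = []  # (clip_id, trial_type, encode_time, base, repeat_group)
    for i in range(n):
        rows.append(
            (session.clip_ids[i], "target", session.onset_s[i], base_target[i], grp_t.get(i))
        )
    for i in range(n):
        rows.append(
            (donor.clip_ids[i], "foil", donor.onset_s[i], base_foil[i], grp_f.get(i))
        )
    # second presentations of the repeated clips
    for k, i in enumerate(rep_t):
        rows.append((session.clip_ids[i], "target", session.onset_s[i], base_target[i],
                     f"{subject_id}_rt{k}"))
    for k, i in enumerate(rep_f):
        rows.append((donor.clip_ids[i], "foil", donor.onset_s[i], base_foil[i],
                     f"{subject_id}_rf{k}"))

    m = len(rows)
    eps = rng.standard_normal(m)  # redrawn per presentation (repeats included)
    order = rng.permutation(m)

    out = []
    for test_index, j in enumerate(order):
        clip_id, ttype, t_enc, base, grp = rows[j]
        f = base + np.sqrt(w_eps) * eps[j]
        response = "yes" if f > criterion else "no"
        correct = (response == "yes") == (ttype == "target")
        out.append(
            {
                "subject_id": subject_id,
                "test_index": test_index,
                "clip_id": clip_id,
                "trial_type": ttype,
                "encode_time_s": float(t_enc),
                "response": response,
                "correct": bool(correct),
                "repeat_group": grp,
            }
        )
    return pd.DataFrame(out)


def build_cohort(config: GeneratorConfig) -> StudyTable:
    """Generate a full cohort StudyTable, deterministically from config.seed."""
    all_trials, all_ann, all_fix, all_cv = [], [], [], []
    for k in range(config.n_subjects):
        sid = f"s{k:02d}"
        ss = subject_seed(config.seed, k)
        enc_rng, donor_rng, resp_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
        session = generate_session(config, enc_rng, clip_prefix=f"{sid}t")
        donor = generate_session(config, donor_rng, clip_prefix=f"{sid}f")
        trials = simulate_responses(session, donor, config, resp_rng, sid)
        used = set(trials["clip_id"])
        all_trials.append(trials)
        for sess, target in ((session, True), (donor, False)):
            ann = sess.annotations[sess.annotations["clip_id"].isin(used)]
            cv = sess.cv_features[sess.cv_features["clip_id"].isin(used)]
            all_ann.append(ann)
            all_cv.append(cv)
            if target and config.with_fixations:
                all_fix.append(sess.fixations[sess.fixations["clip_id"].isin(used)])

    meta = {
        "experiment": config.experiment,
        "session_duration_s": config.session_duration_s,
        "feature_vocabulary": config.vocabulary(),
        "generator": ground_truth(config),
    }
    study = StudyTable(
        trials=pd.concat(all_trials, ignore_index=True),
        annotations=pd.concat(all_ann, ignore_index=True),
        fixations=(
            pd.concat(all_fix, ignore_index=True)
            if all_fix
            else StudyTable().fixations
        ),
        cv_features=pd.concat(all_cv, ignore_index=True),
        meta=meta,
    )
    return study.validate()


def ground_truth(config: GeneratorConfig) -> dict:
    """Generating parameters and derived calibrations, for provenance files."""
    budget = config.variance_budget()
    gt = {
        k: v
        for k, v in dataclasses.asdict(config).items()
        if k != "feature_spec"
    }
    gt["feature_spec"] = {
        name: dataclasses.asdict(fs) for name, fs in config.feature_spec.items()
    }
    gt.update({f"calibrated_{k}": float(v) for k, v in budget.items()})
    gt["expected_hit_rate"] = config.expected_hit_rate
    gt["expected_cr_rate"] = config.expected_cr_rate
    gt["expected_percent_correct"] = config.expected_percent_correct
    return gt
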