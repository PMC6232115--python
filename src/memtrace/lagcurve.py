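"""History dependence of recognition accuracy over encoding time.

The central statistic is the normalized conditional probability

    y(dt) = P(correct at t | correct at t - dt) / P(correct),

estimated over all ordered within-subject trial pairs whose encoding times
differ by a lag in a given bin (test positions are free to differ: the
dependence under study lives on the encoding timeline, not the test order).
Under independence y = 1 at every lag; event structure in memory shows up as
an excess at short lags, summarized by fitting ``y = 1 + alpha*exp(-dt/tau)``.

The same estimator applied to test-position lags (:func:`test_order_curve`)
is the negative control: a well-randomized test sequence must give a flat
curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .trial_io import StudyTable

DEFAULT_BIN_WIDTH_S = 5.0
DEFAULT_MAX_LAG_S = 120.0
DEFAULT_MIN_PAIRS = 30

TAU_STARTS = (5.0, 10.0, 20.0, 40.0, 80.0, 160.0)
ALPHA_BOUNDS = (0.0, 5.0)
TAU_BOUNDS = (1.0, 600.0)
ALPHA_IDENTIFIABLE_MIN = 0.02


@dataclass
class LagCurve:
    """Normalized conditional-probability curve over lag bins.

    ``bin_centers_s`` are pair-weighted mean lags of the occupied bins (with
    ~7 s clip spacing, pairs cluster far from nominal bin midpoints, so
    nominal centers would bias the fit).  Bins with fewer than ``min_pairs``
    conditioning pairs are dropped, not reported as zero.
    """

    bin_centers_s: np.ndarray
    y: np.ndarray                   # conditional / marginal, null level 1
    raw_conditional: np.ndarray     # P(correct | previous correct), un-normalized
    n_pairs: np.ndarray             # conditioning (predecessor-correct) pairs per bin
    p_overall: float
    bin_width_s: float
    max_lag_s: float
    scope: str
    lag_units: str = "seconds"
    min_pairs: int = DEFAULT_MIN_PAIRS


def _pair_accumulate(times, correct, bin_width, max_lag, n_bins):
    """Per-subject pair counts: (all, predecessor-correct, both-correct,
    lag mass of predecessor-correct pairs) per bin."""
    order = np.argsort(times, kind="mergesort")
    t = np.asarray(times, dtype=float)[order]
    c = np.asarray(correct, dtype=bool)[order]
    lag = t[None, :] - t[:, None]           # lag[i, j] = t_j - t_i
    iu, ju = np.nonzero((lag > 0) & (lag <= max_lag))
    lags = lag[iu, ju]
    bins = np.minimum((lags / bin_width).astype(int), n_bins - 1)
    pred = c[iu]
    joint = pred & c[ju]
    n_all = np.bincount(bins, minlength=n_bins)
    n_pred = np.bincount(bins[pred], minlength=n_bins)
    n_joint = np.bincount(bins[joint], minlength=n_bins)
    lag_sum = np.bincount(bins[pred], weights=lags[pred], minlength=n_bins)
    return n_all, n_pred, n_joint, lag_sum


def conditional_curve(
    study: StudyTable | pd.DataFrame,
    bin_width_s: float = DEFAULT_BIN_WIDTH_S,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    scope: str = "targets_only",
    min_pairs: int = DEFAULT_MIN_PAIRS,
    lag_column: str = "encode_time_s",
) -> LagCurve:
    """Pooled normalized conditional-probability curve over encoding-time lags.

    ``scope`` is ``"targets_only"`` (default: foil "encoding times" belong to
    a donor subject's timeline) or ``"all_trials"`` (sensitivity analysis that
    places foils on the donor timeline).  Pairs are accumulated within
    subject, each subject's conditional probability is normalized by that
    subject's own marginal probability correct, and subjects are pooled
    weighted by their conditioning-pair counts.
    """
    trials = study.first_presentations() if isinstance(study, StudyTable) else study
    if scope == "targets_only":
        trials = trials[trials["trial_type"] == "target"]
    elif scope != "all_trials":
        raise ValueError(f"unknown scope: {scope!r}")
    if len(trials) < 2:
        raise ValueError("need at least two trials in scope")

    n_bins = int(np.ceil(max_lag_s / bin_width_s))
    y_num = np.zeros(n_bins)        # sum over subjects of n_joint / p_subject
    n_pred_tot = np.zeros(n_bins, dtype=int)
    n_all_tot = np.zeros(n_bins, dtype=int)
    raw_num = np.zeros(n_bins)
    lag_sum_tot = np.zeros(n_bins)
    p_num = p_den = 0.0

    for _, g in trials.groupby("subject_id", sort=True):
        p_s = float(g["correct"].mean())
        n_all, n_pred, n_joint, lag_sum = _pair_accumulate(
            g[lag_column].to_numpy(), g["correct"].to_numpy(),
            bin_width_s, max_lag_s, n_bins,
        )
        if p_s > 0:
            y_num += n_joint / p_s
        raw_num += n_joint
        n_pred_tot += n_pred
        n_all_tot += n_all
        lag_sum_tot += lag_sum
        p_num += float(g["correct"].sum())
        p_den += len(g)

    occupied = n_pred_tot >= max(min_pairs, 1)
    if not occupied.any():
        warnings.warn("no lag bin reaches the minimum pair count")
    with np.errstate(invalid="ignore", divide="ignore"):
        y = y_num[occupied] / n_pred_tot[occupied]
        raw = raw_num[occupied] / n_pred_tot[occupied]
        centers = lag_sum_tot[occupied] / n_pred_tot[occupied]

    return LagCurve(
        bin_centers_s=centers,
        y=y,
        raw_conditional=raw,
        n_pairs=n_pred_tot[occupied],
        p_overall=p_num / p_den,
        bin_width_s=bin_width_s,
        max_lag_s=max_lag_s,
        scope=scope,
        lag_units="seconds" if lag_column == "encode_time_s" else "trials",
        min_pairs=min_pairs,
    )


def test_order_curve(
    study: StudyTable | pd.DataFrame,
    bin_width: float = 1.0,
    max_lag: float = 50.0,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> LagCurve:
    """Control curve with lag measured in test positions (units: trials).

    All first-presentation trials are in scope; with a properly shuffled test
    sequence the curve is flat at 1.
    """
    return conditional_curve(
        study,
        bin_width_s=bin_width,
        max_lag_s=max_lag,
        scope="all_trials",
        min_pairs=min_pairs,
        lag_column="test_index",
    )


@dataclass
class DecayFit:
    alpha: float
    tau_s: float
    rss: float
    converged: bool
    tau_identifiable: bool
    n_bins: int
    weighted: bool
    diagnostics: dict = field(default_factory=dict)


def fit_decay(curve: LagCurve, weights: str = "none") -> DecayFit:
    """Bounded least-squares fit of ``y = 1 + alpha*exp(-dt/tau)``.

    ``weights="pair_counts"`` weights residuals by sqrt of the conditioning
    pair counts.  Multi-start over a tau grid guards against the local minima
    of the separable exponential; ``tau_identifiable`` is false when the
    fitted amplitude is too small to constrain the timescale.
    """
    t = np.asarray(curve.bin_centers_s, dtype=float)
    y = np.asarray(curve.y, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least three occupied lag bins to fit")
    if weights == "pair_counts":
        w = np.sqrt(np.asarray(curve.n_pairs, dtype=float))
        w = w / w.mean()
    elif weights == "none":
        w = np.ones_like(t)
    else:
        raise ValueError(f"unknown weights mode: {weights!r}")

    def resid(params):
        a, tau = params
        return w * (1.0 + a * np.exp(-t / tau) - y)

    lo = np.array([ALPHA_BOUNDS[0], TAU_BOUNDS[0]])
    hi = np.array([ALPHA_BOUNDS[1], TAU_BOUNDS[1]])
    alpha0 = float(np.clip(np.max(y) - 1.0, 0.01, ALPHA_BOUNDS[1]))
    best, tried = None, []
    for tau0 in TAU_STARTS:
        x0 = np.clip([alpha0, tau0], lo, hi)
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception as exc:  # pragma: no cover - scipy failure path
            tried.append({"tau0": tau0, "error": str(exc)})
            continue
        rss = float(np.sum(sol.fun**2))
        tried.append({"tau0": tau0, "rss": rss, "success": bool(sol.success)})
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol)

    if best is None:
        return DecayFit(
            alpha=float("nan"), tau_s=float("nan"), rss=float("nan"),
            converged=False, tau_identifiable=False, n_bins=len(t),
            weighted=weights == "pair_counts", diagnostics={"starts": tried},
        )
    rss, sol = best
    alpha, tau = map(float, sol.x)
    return DecayFit(
        alpha=alpha,
        tau_s=tau,
        rss=rss,
        converged=True,
        tau_identifiable=alpha >= ALPHA_IDENTIFIABLE_MIN,
        n_bins=len(t),
        weighted=weights == "pair_counts",
        diagnostics={"starts": tried},
    )


def curve_table(curve: LagCurve) -> pd.DataFrame:
    """LagCurve as a tidy table for CSV output."""
    return pd.DataFrame(
        {
            "bin_center": curve.bin_centers_s,
            "y": curve.y,
            "raw_conditional": curve.raw_conditional,
            "n_pairs": curve.n_pairs,
        }
    )


def fit_summary(fit: DecayFit, curve: Optional[LagCurve] = None) -> dict:
    out = {
        "alpha": fit.alpha,
        "tau_s": fit.tau_s,
        "rss": fit.rss,
        "converged": fit.converged,
        "tau_identifiable": fit.tau_identifiable,
        "n_bins": fit.n_bins,
        "weighted": fit.weighted,
    }
    if curve is not None:
        out.update(
            {
                "bin_width": curve.bin_width_s,
                "max_lag": curve.max_lag_s,
                "scope": curve.scope,
                "lag_units": curve.lag_units,
                "min_pairs": curve.min_pairs,
                "p_overall": curve.p_overall,
            }
        )
    return out
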