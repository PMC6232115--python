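"""Latent-Gaussian calibrations for the synthetic cohort generator.

The generator produces yes/no responses by thresholding a Gaussian
familiarity variable, so every binary statistic it must reproduce (lag-zero
correctness correlation, covert-repeat agreement) reduces to a bivariate
normal orthant probability.  This module numerically inverts those orthant
identities:

* :func:`calibrate_latent_correlation` — given the target amplitude ``alpha``
  of the normalized conditional-probability curve ``y = 1 + alpha*exp(-t/tau)``
  and the marginal probability correct ``p``, find the zero-lag correlation
  of the latent Gaussian such that the dichotomized binary correlation equals
  ``rho_C = alpha * p / (1 - p)`` (from the identity
  ``P(C=1 | C'=1) = p + rho_C (1 - p)``).
* :func:`calibrate_consistency` — given a target repeat agreement and a
  yes-rate, find the share of trial-unique noise in the familiarity variance.
* :func:`calibrate_consistency_cohort` — same, but targeting the cohort-mean
  agreement pooled over trial types and the between-subject spread.

Orthant probabilities use Owen's T function (exact to machine precision);
Monte-Carlo cross-checks live in the test suite, not here.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize, special, stats

from .errors import CalibrationError

_RHO_MAX = 1.0 - 1e-9


def _orthant_diag(z, rho: float):
    """P(Z1 <= z, Z2 <= z) for standard bivariate normals with correlation rho.

    Owen (1956): for z != 0, ``Phi2(z,z;rho) = Phi(z) - 2*T(z, sqrt((1-rho)/(1+rho)))``;
    at z = 0 the limit is ``1/4 + arcsin(rho)/(2*pi)``.  Vectorized over z.
    """
    z = np.asarray(z, dtype=float)
    if rho >= _RHO_MAX:
        out = stats.norm.cdf(z)
    elif rho <= -_RHO_MAX:
        out = np.maximum(2.0 * stats.norm.cdf(z) - 1.0, 0.0)
    else:
        a = np.sqrt((1.0 - rho) / (1.0 + rho))
        out = stats.norm.cdf(z) - 2.0 * special.owens_t(z, a)
        out = np.where(
            np.abs(z) < 1e-14, 0.25 + np.arcsin(rho) / (2.0 * np.pi), out
        )
    return out if out.shape else float(out)


def bivariate_orthant(z1: float, z2: float, rho: float) -> float:
    """P(Z1 <= z1, Z2 <= z2) for standard bivariate normal with correlation rho."""
    if rho >= _RHO_MAX:
        return float(stats.norm.cdf(min(z1, z2)))
    if rho <= -_RHO_MAX:
        return float(max(stats.norm.cdf(z1) + stats.norm.cdf(z2) - 1.0, 0.0))
    if abs(z1 - z2) < 1e-14:
        return float(_orthant_diag(z1, rho))
    # Owen's general two-threshold formula; nudge off the removable z=0 poles
    h = z1 if abs(z1) > 1e-12 else 1e-12
    k = z2 if abs(z2) > 1e-12 else 1e-12
    r = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * r)
    ak = (h - rho * k) / (k * r)
    beta = 0.5 if h * k < 0 else 0.0
    val = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, ah)
        - special.owens_t(k, ak)
        - beta
    )
    return float(val)


def binary_correlation(rho_latent: float, p: float) -> float:
    """Pearson correlation of two Bernoulli(p) variables obtained by
    thresholding standard bivariate normals with correlation ``rho_latent``."""
    if not 0.0 < p < 1.0:
        raise CalibrationError(f"marginal probability must be in (0,1), got {p}")
    z = stats.norm.ppf(p)
    p11 = _orthant_diag(z, rho_latent)
    return float((p11 - p * p) / (p * (1.0 - p)))


def alpha_to_binary_correlation(alpha: float, p: float) -> float:
    """Amplitude of the normalized conditional curve -> binary correlation.

    From ``y(0) = 1 + alpha = P(C|C')/p`` and ``P(C|C') = p + rho_C (1-p)``.
    """
    return alpha * p / (1.0 - p)


@lru_cache(maxsize=512)
def calibrate_latent_correlation(alpha_target: float, p_overall: float) -> float:
    """Zero-lag latent Gaussian correlation inducing lag-curve amplitude
    ``alpha_target`` after dichotomization at marginal probability ``p_overall``.

    Raises :class:`CalibrationError` when the implied binary correlation is
    infeasible (>= 1), reporting the feasible maximum amplitude.
    """
    if alpha_target < 0:
        raise CalibrationError("alpha_target must be non-negative")
    if alpha_target == 0:
        return 0.0
    rho_c = alpha_to_binary_correlation(alpha_target, p_overall)
    if rho_c >= 1.0:
        alpha_max = (1.0 - p_overall) / p_overall
        raise CalibrationError(
            f"alpha_target={alpha_target} infeasible at p={p_overall}: "
            f"binary correlation {rho_c:.3f} >= 1 (feasible alpha < {alpha_max:.3f})"
        )
    f = lambda r: binary_correlation(r, p_overall) - rho_c
    return float(optimize.brentq(f, 0.0, _RHO_MAX, xtol=1e-12))


def repeat_agreement(rho: float, p_yes) -> float:
    """Probability that two thresholded draws with latent correlation ``rho``
    and marginal yes-probability ``p_yes`` give the same yes/no answer.

    Closed form: ``2*Phi2(z, z; rho) + 2*p_yes - 1`` with ``z = Phi^-1(1-p_yes)``.
    At rho=0 this is the independent-responder floor ``p^2 + (1-p)^2``; at
    rho=1 it is 1.  Vectorized over ``p_yes``.
    """
    p_yes = np.asarray(p_yes, dtype=float)
    z = stats.norm.ppf(1.0 - p_yes)
    out = 2.0 * _orthant_diag(z, rho) + 2.0 * p_yes - 1.0
    return out if out.shape else float(out)


def calibrate_consistency(consistency_target: float, p_yes: float) -> float:
    """Trial-noise variance share ``lambda`` achieving a target repeat agreement.

    The two presentations of a covertly repeated clip share every familiarity
    component except the trial-unique noise, so their latent correlation is
    ``1 - lambda``.  Solves ``repeat_agreement(1 - lambda, p_yes) = target``.
    """
    floor = p_yes**2 + (1.0 - p_yes) ** 2
    if consistency_target < floor - 1e-12:
        raise CalibrationError(
            f"consistency_target={consistency_target:.4f} below the independent-"
            f"responder floor {floor:.4f} at yes-rate {p_yes:.3f}"
        )
    if consistency_target >= 1.0:
        return 0.0
    if abs(consistency_target - floor) <= 1e-12:
        return 1.0
    f = lambda rho: repeat_agreement(rho, p_yes) - consistency_target
    rho = float(optimize.brentq(f, 0.0, _RHO_MAX, xtol=1e-12))
    return 1.0 - rho


def _subject_nodes(
    d_prime_mean: float,
    d_prime_sd: float,
    criterion_mean: float,
    criterion_sd: float,
    n_nodes: int,
):
    """Gauss-Hermite grid over the subject (d', criterion) distribution."""
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / w.sum()
    d = np.clip(d_prime_mean + d_prime_sd * x, 0.0, None)  # generator clips at 0
    c = criterion_mean + criterion_sd * x
    dd, cc = np.meshgrid(d, c, indexing="ij")
    ww = np.outer(w, w)
    return dd.ravel(), cc.ravel(), ww.ravel()


def cohort_repeat_agreement(
    rho: float,
    d_prime_mean: float,
    d_prime_sd: float,
    criterion_mean: float,
    criterion_sd: float,
    n_nodes: int = 15,
) -> float:
    """Expected repeat agreement pooled over trial types and subjects.

    Target and foil repeats have different yes-rates (``Phi(+d'/2 - c)`` and
    ``Phi(-d'/2 - c)``), and subjects vary in sensitivity and criterion.  The
    expectation averages the closed-form agreement over a Gauss-Hermite grid
    on the subject distribution and equally over the two trial types.
    """
    dd, cc, ww = _subject_nodes(
        d_prime_mean, d_prime_sd, criterion_mean, criterion_sd, n_nodes
    )
    total = 0.0
    for sign in (0.5, -0.5):
        p_yes = stats.norm.cdf(sign * dd - cc)
        total += 0.5 * float(np.dot(ww, repeat_agreement(rho, p_yes)))
    return total


@lru_cache(maxsize=512)
def calibrate_consistency_cohort(
    consistency_target: float,
    d_prime_mean: float,
    d_prime_sd: float,
    criterion_mean: float,
    criterion_sd: float,
    n_nodes: int = 15,
) -> float:
    """Trial-noise share ``lambda`` whose *cohort-average* repeat agreement
    equals the target, accounting for trial-type asymmetry and between-subject
    heterogeneity (see :func:`cohort_repeat_agreement`)."""
    args = (d_prime_mean, d_prime_sd, criterion_mean, criterion_sd, n_nodes)
    floor = cohort_repeat_agreement(0.0, *args)
    if consistency_target < floor - 1e-12:
        raise CalibrationError(
            f"consistency_target={consistency_target:.4f} below the cohort "
            f"independent-responder floor {floor:.4f}"
        )
    if consistency_target >= 1.0:
        return 0.0
    if consistency_target <= floor + 1e-12:
        return 1.0
    f = lambda rho: cohort_repeat_agreement(rho, *args) - consistency_target
    rho = float(optimize.brentq(f, 0.0, _RHO_MAX, xtol=1e-10))
    return 1.0 - rho


def conditional_given_correct(p: float, rho_c: float) -> float:
    """P(C_t = 1 | C_{t-dt} = 1) for Bernoulli(p) margins with correlation rho_c."""
    return p + rho_c * (1.0 - p)
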