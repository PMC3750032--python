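"""Random-intercept mixed model for normative FA and its prediction interval.

Each ROI group's repeated measurements are modelled as

    y_ij = mu + b_i + e_ij,   b_i ~ N(0, tau^2),  e_ij ~ N(0, sigma^2),

with subject i and ROI j. The population mean mu and the 95% prediction
interval for a new observation from a new subject,

    mu +/- z_0.975 * sqrt(tau^2 + sigma^2),

are the quantities the color look-up table is anchored to. Two estimation
routes are provided: restricted maximum likelihood (``reml``, the default,
via statsmodels MixedLM) and the classical one-way ANOVA method-of-moments
estimators (``moments``), which coincide with REML on balanced designs and
serve as a closed-form cross-check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .roi_data import MeasurementTable

__all__ = [
    "RandomInterceptFit",
    "fit_random_intercept",
    "prediction_interval",
    "fit_all_groups",
    "LUT_GROUPS",
]

#: ROI groups a LUT is anchored to, in ascending order of typical FA.
LUT_GROUPS = ("BG", "GM", "CC_FREEHAND", "CC_CROI")


class GroupLookupError(KeyError):
    """Requested ROI group has no records in the table."""


class DegenerateDesignError(ValueError):
    """Design cannot identify the between-subject variance (one subject)."""


@dataclass(frozen=True)
class RandomInterceptFit:
    """Fitted random-intercept model summary for one ROI group.

    ``pi_low``/``pi_high`` bound the 95% prediction interval for a new
    observation from a new subject; they are symmetric about ``mu_hat`` and
    are deliberately NOT clipped to [0, 1] (the LUT builder clips).
    """

    roi_group: str
    mu_hat: float
    tau2_hat: float
    sigma2_hat: float
    pi_low: float
    pi_high: float
    n_subjects: int
    n_obs: int
    method: str

    @property
    def total_variance(self) -> float:
        return self.tau2_hat + self.sigma2_hat

    def to_dict(self) -> dict:
        return asdict(self)


def _moments_estimates(y: np.ndarray, subjects: np.ndarray) -> tuple[float, float, float]:
    """One-way random-effects ANOVA estimators (unbalanced-safe).

    sigma^2 is the within-subject mean square; tau^2 is
    max(0, (MSB - MSE) / k~) with k~ = (N - sum n_i^2 / N) / (m - 1),
    the harmonic-mean-adjusted per-subject count.
    """
    uniq, inverse = np.unique(subjects, return_inverse=True)
    m = len(uniq)
    n = len(y)
    counts = np.bincount(inverse).astype(float)
    sums = np.bincount(inverse, weights=y)
    means_i = sums / counts
    grand = float(np.mean(y))
    ssw = float(np.sum((y - means_i[inverse]) ** 2))
    ssb = float(np.sum(counts * (means_i - grand) ** 2))
    mse = ssw / (n - m) if n > m else 0.0
    msb = ssb / (m - 1)
    k_tilde = (n - float(np.sum(counts**2)) / n) / (m - 1)
    tau2 = max(0.0, (msb - mse) / k_tilde) if k_tilde > 0 else 0.0
    return grand, tau2, mse


def _gls_mean(tau2: float, sigma2: float, counts: np.ndarray, means_i: np.ndarray) -> float:
    w = counts / (sigma2 + counts * tau2)
    return float(np.sum(w * means_i) / np.sum(w))


def _restricted_loglik(
    tau2: float, sigma2: float, counts: np.ndarray, means_i: np.ndarray, ssw: float
) -> float:
    """Restricted log-likelihood of the one-way random-intercept model.

    Uses the Woodbury form of V_i = sigma2 I + tau2 J per subject; constants
    not depending on (tau2, sigma2) are dropped.
    """
    if sigma2 <= 0:
        return -np.inf
    d = sigma2 + counts * tau2
    mu = _gls_mean(tau2, sigma2, counts, means_i)
    logdet = float(np.sum((counts - 1) * np.log(sigma2) + np.log(d)))
    quad = ssw / sigma2 + float(np.sum(counts * (means_i - mu) ** 2 / d))
    log_xvx = float(np.log(np.sum(counts / d)))
    return -0.5 * (logdet + log_xvx + quad)


def _reml_estimates(y: np.ndarray, subjects: np.ndarray) -> tuple[float, float, float]:
    import statsmodels.api as sm

    exog = np.ones((len(y), 1))
    model = sm.MixedLM(y, exog, groups=subjects)
    with warnings.catch_warnings():
        # boundary (tau^2 -> 0) fits emit convergence warnings by design
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    tau2 = max(0.0, float(np.asarray(result.cov_re)[0, 0]))
    sigma2 = max(0.0, float(result.scale))
    # Guard against a stalled optimizer: keep whichever of the statsmodels
    # solution and the closed-form moments solution has the higher restricted
    # likelihood (on balanced designs with tau2 > 0 they coincide).
    uniq, inverse = np.unique(subjects, return_inverse=True)
    counts = np.bincount(inverse).astype(float)
    means_i = np.bincount(inverse, weights=y) / counts
    ssw = float(np.sum((y - means_i[inverse]) ** 2))
    _, tau2_m, sigma2_m = _moments_estimates(y, subjects)
    ll_sm = _restricted_loglik(tau2, sigma2, counts, means_i, ssw)
    ll_mo = _restricted_loglik(tau2_m, sigma2_m, counts, means_i, ssw)
    if ll_mo > ll_sm:
        tau2, sigma2 = tau2_m, sigma2_m
    mu = _gls_mean(tau2, sigma2, counts, means_i)
    return mu, tau2, sigma2


def fit_random_intercept(
    table: MeasurementTable,
    roi_group: str,
    mpg_scheme: int = 12,
    method: str = "reml",
    level: float = 0.95,
) -> RandomInterceptFit:
    """Fit the random-intercept model to one ROI group of a table.

    Parameters
    ----------
    table : measurement table holding the group's records
    roi_group : group to fit (records of other groups are ignored)
    mpg_scheme : gradient scheme (12 or 30) selecting the records
    method : ``"reml"`` (restricted maximum likelihood) or ``"moments"``
        (one-way ANOVA estimators)
    level : prediction-interval coverage probability
    """
    if method not in ("reml", "moments"):
        raise ValueError(f"method must be 'reml' or 'moments', got {method!r}")
    sub = table.subset(roi_group=roi_group, mpg_scheme=mpg_scheme)
    if not sub.records:
        raise GroupLookupError(
            f"no records for roi_group={roi_group!r}, mpg_scheme={mpg_scheme}"
        )
    y = np.array([r.fa for r in sub.records], dtype=float)
    subjects = np.array([r.subject_id for r in sub.records])
    n_subjects = len(np.unique(subjects))
    if n_subjects < 2:
        raise DegenerateDesignError(
            f"roi_group={roi_group!r}: between-subject variance is unidentifiable "
            f"with {n_subjects} subject(s); need >= 2"
        )
    if np.ptp(y) == 0.0:
        # constant data: exact degenerate fit, no optimizer involved
        mu, tau2, sigma2 = float(y[0]), 0.0, 0.0
    elif method == "moments":
        mu, tau2, sigma2 = _moments_estimates(y, subjects)
    else:
        mu, tau2, sigma2 = _reml_estimates(y, subjects)
    fit = RandomInterceptFit(
        roi_group=roi_group,
        mu_hat=mu,
        tau2_hat=tau2,
        sigma2_hat=sigma2,
        pi_low=np.nan,
        pi_high=np.nan,
        n_subjects=n_subjects,
        n_obs=len(y),
        method=method,
    )
    low, high = prediction_interval(fit, level=level)
    return RandomInterceptFit(
        roi_group=roi_group,
        mu_hat=mu,
        tau2_hat=tau2,
        sigma2_hat=sigma2,
        pi_low=low,
        pi_high=high,
        n_subjects=n_subjects,
        n_obs=len(y),
        method=method,
    )


def prediction_interval(
    fit: RandomInterceptFit,
    level: float = 0.95,
    include_mean_uncertainty: bool = False,
) -> tuple[float, float]:
    """Prediction interval for a new observation from a new subject.

    Returns ``mu_hat +/- z_{(1+level)/2} * sqrt(tau2 + sigma2)``; with
    ``include_mean_uncertainty`` the variance additionally includes
    Var(mu_hat) approximated as (tau2 + sigma2/k) / m for m subjects with
    average per-subject count k. Bounds are not clipped to [0, 1].
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    var = fit.tau2_hat + fit.sigma2_hat
    if include_mean_uncertainty and fit.n_subjects > 0:
        k = fit.n_obs / fit.n_subjects
        var = var + (fit.tau2_hat + fit.sigma2_hat / k) / fit.n_subjects
    half = z * float(np.sqrt(var))
    return fit.mu_hat - half, fit.mu_hat + half


def fit_all_groups(
    table: MeasurementTable,
    mpg_scheme: int = 12,
    method: str = "reml",
    groups: tuple[str, ...] = LUT_GROUPS,
) -> dict[str, RandomInterceptFit]:
    """Fit every LUT anchor group of a table.

    The circular corpus-callosum fit pools genu and splenium records (they
    carry the same ``CC_CROI`` group tag), reflecting that LUT anchors stand
    for fiber-density strata rather than single anatomical structures.
    """
    present = {r.roi_group for r in table.records if r.mpg_scheme == int(mpg_scheme)}
    missing = [g for g in groups if g not in present]
    if missing:
        raise GroupLookupError(
            f"table lacks required LUT group(s): {', '.join(missing)}"
        )
    return {
        g: fit_random_intercept(table, g, mpg_scheme=mpg_scheme, method=method)
        for g in groups
    }


def fits_to_json(fits: Mapping[str, RandomInterceptFit], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({g: f.to_dict() for g, f in fits.items()}, indent=2) + "\n"
    )


def fits_from_json(path: str | Path) -> dict[str, RandomInterceptFit]:
    raw = json.loads(Path(path).read_text())
    return {g: RandomInterceptFit(**d) for g, d in raw.items()}
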