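"""Time-to-onset analysis: onset-day samples, summaries, and the Weibull
shape parameter.

For each target-event case the onset time is the number of days from
study-drug initiation to event onset. Because a spontaneous reporting
system has no at-risk denominator, the hazard *shape* is read from the
two-parameter Weibull density

    f(t; alpha, beta) = (beta/alpha) * (t/alpha)**(beta-1) * exp(-(t/alpha)**beta),  t > 0,

whose shape parameter beta describes the hazard trend without a reference
population: beta < 1 decreasing hazard (early failure), beta ~ 1 constant
hazard (random failure), beta > 1 increasing hazard (wear-out failure).
The classification uses the 95% CI of beta: CI containing 1 (inclusive)
-> random; lower limit > 1 -> wear-out; upper limit < 1 -> early.

The day count uses a +1 convention (same-day onset = day 1) so every onset
time is positive, as Weibull support requires; a half-day convention is
available. The analysis window is 1,095 days (three years): later onsets
are excluded and counted, as are cases with missing or partial dates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError
from .jader import CaseRecord, normalize_drug_name
from .smq import CaseFlags

#: two-sided 95% normal critical value (matches the effect-table convention)
Z95 = 1.959964

DEFAULT_WINDOW_DAYS = 1095


class FailureType(str, enum.Enum):
    EARLY = "early"
    RANDOM = "random"
    WEAROUT = "wearout"


@dataclass
class OnsetSample:
    """Positive onset days within the analysis window, plus exclusion counts."""

    case_ids: list[str]
    days: np.ndarray
    n_excluded_missing_dates: int
    n_excluded_beyond_window: int
    window_days: int = DEFAULT_WINDOW_DAYS

    @property
    def n(self) -> int:
        return len(self.days)


@dataclass
class OnsetSummary:
    n: int
    median: float
    q1: float
    q3: float


@dataclass
class WeibullFit:
    beta: float  # shape (dimensionless)
    alpha: float  # scale (days)
    beta_ci: tuple[float, float]
    alpha_ci: tuple[float, float]
    loglik: float
    failure_type: FailureType
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "alpha": self.alpha,
            "alpha_ci": list(self.alpha_ci),
            "beta": self.beta,
            "beta_ci": list(self.beta_ci),
            "loglik": self.loglik,
            "failure_type": self.failure_type.value,
        }


def onset_days(
    cases: Iterable[CaseRecord],
    flags_by_case: Mapping[str, CaseFlags],
    drug_name: str = "clozapine",
    window_days: int = DEFAULT_WINDOW_DAYS,
    convention: str = "plus_one",
) -> OnsetSample:
    """Onset-day sample over the target-event cases of the study drug.

    day = (event onset date - earliest complete study-drug start date) + 1
    under the default convention, so same-day onset is day 1; the "half_day"
    convention uses the raw difference with same-day onset mapped to 0.5.
    Cases with a missing/partial onset or start date — or a nonpositive
    difference, which can only be a recording error — count as missing-date
    exclusions; days beyond the window count separately.
    """
    if convention not in ("plus_one", "half_day"):
        raise ValueError(f"unknown day-count convention: {convention}")
    target = normalize_drug_name(drug_name)
    ids: list[str] = []
    days: list[float] = []
    n_missing = 0
    n_beyond = 0
    for case in cases:
        flags = flags_by_case[case.case_id]
        if not flags.is_seizure_case:
            continue
        onset = flags.seizure_onset_date
        starts = [
            d.start_date
            for d in case.drugs
            if normalize_drug_name(d.drug_name) == target
            and d.start_date is not None
            and d.start_date.complete
        ]
        if onset is None or not starts:
            n_missing += 1
            continue
        start = min(starts, key=lambda d: d.to_date())
        delta = (onset.to_date() - start.to_date()).days
        if delta < 0:
            n_missing += 1  # onset before initiation: data error
            continue
        if convention == "plus_one":
            day = float(delta + 1)
        else:
            day = float(delta) if delta > 0 else 0.5
        if day > window_days:
            n_beyond += 1
            continue
        ids.append(case.case_id)
        days.append(day)
    return OnsetSample(
        case_ids=ids,
        days=np.asarray(days, dtype=float),
        n_excluded_missing_dates=n_missing,
        n_excluded_beyond_window=n_beyond,
        window_days=window_days,
    )


def summarize(sample: OnsetSample) -> OnsetSummary:
    """Median and quartiles by inclusive linear interpolation (the
    ``numpy`` default quantile rule), so results are bit-reproducible."""
    if sample.n == 0:
        raise FitError("empty onset sample")
    q1, med, q3 = np.quantile(sample.days, [0.25, 0.5, 0.75])
    return OnsetSummary(n=sample.n, median=float(med), q1=float(q1), q3=float(q3))


def proportion_within(sample: OnsetSample, t: float) -> float:
    """Fraction of onsets at or before day ``t``."""
    if sample.n == 0:
        raise FitError("empty onset sample")
    return float(np.count_nonzero(sample.days <= t) / sample.n)


def _weibull_negloglik(theta: np.ndarray, t: np.ndarray) -> float:
    log_alpha, log_beta = theta
    beta = math.exp(log_beta)
    z = beta * (np.log(t) - log_alpha)  # log of (t/alpha)^beta
    loglik = np.sum(log_beta - beta * log_alpha + (beta - 1.0) * np.log(t) - np.exp(z))
    return -float(loglik)


def _weibull_score(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Gradient of the negative log-likelihood wrt (log alpha, log beta)."""
    log_alpha, log_beta = theta
    beta = math.exp(log_beta)
    w = beta * (np.log(t) - log_alpha)  # beta * log(t/alpha)
    u = np.exp(w)  # (t/alpha)^beta
    d_la = -beta * len(t) + beta * np.sum(u)  # dl/dlog(alpha)
    d_lb = len(t) + np.sum(w) - np.sum(u * w)  # dl/dlog(beta)
    return np.array([-d_la, -d_lb])


def _numeric_hessian(f, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            tpp = theta.copy(); tpp[i] += eps; tpp[j] += eps
            tpm = theta.copy(); tpm[i] += eps; tpm[j] -= eps
            tmp = theta.copy(); tmp[i] -= eps; tmp[j] += eps
            tmm = theta.copy(); tmm[i] -= eps; tmm[j] -= eps
            H[i, j] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (4 * eps * eps)
    return (H + H.T) / 2.0


def fit_weibull(
    sample: OnsetSample | Sequence[float] | np.ndarray, conf: float = 0.95
) -> WeibullFit:
    """Two-parameter Weibull maximum-likelihood fit with Wald CIs.

    The likelihood is maximized over (log alpha, log beta); confidence
    intervals come from the observed information on the log scale and are
    back-transformed, keeping them inside the positive parameter space.
    Needs at least 3 positive onset days with some spread.
    """
    days = sample.days if isinstance(sample, OnsetSample) else np.asarray(sample, float)
    if len(days) < 3:
        raise FitError(f"need at least 3 onset days, got {len(days)}")
    if np.any(days <= 0):
        raise FitError("onset days must be positive")
    logs = np.log(days)
    if np.allclose(logs, logs[0]):
        raise FitError("degenerate sample: all onset days identical")

    # method-of-moments start: sd(log T) = (pi/sqrt(6))/beta
    s = float(np.std(logs, ddof=1))
    beta0 = (math.pi / math.sqrt(6.0)) / max(s, 1e-6)
    log_alpha0 = float(np.mean(logs) + 0.5772156649 / beta0)
    theta0 = np.array([log_alpha0, math.log(beta0)])

    obj = lambda th: _weibull_negloglik(th, days)
    res = optimize.minimize(
        obj, theta0, jac=lambda th: _weibull_score(th, days), method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    grad_ok = float(np.max(np.abs(_weibull_score(res.x, days)))) < 1e-6 * len(days)
    if not (res.success or grad_ok):
        # polish from the best point found; BFGS can stop on precision loss
        res2 = optimize.minimize(obj, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000})
        if res2.fun <= res.fun:
            res = res2
        if float(np.max(np.abs(_weibull_score(res.x, days)))) >= 1e-6 * len(days):
            raise FitError(f"Weibull fit did not converge: {res.message}")
    theta = res.x
    H = _numeric_hessian(obj, theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information matrix: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    z = stats.norm.ppf(0.5 + conf / 2.0) if conf != 0.95 else Z95

    log_alpha, log_beta = theta
    alpha, beta = math.exp(log_alpha), math.exp(log_beta)
    alpha_ci = (math.exp(log_alpha - z * se[0]), math.exp(log_alpha + z * se[0]))
    beta_ci = (math.exp(log_beta - z * se[1]), math.exp(log_beta + z * se[1]))
    return WeibullFit(
        beta=beta,
        alpha=alpha,
        beta_ci=beta_ci,
        alpha_ci=alpha_ci,
        loglik=-float(res.fun),
        failure_type=classify_failure(beta_ci),
        n=len(days),
    )


def classify_failure(beta_ci: tuple[float, float]) -> FailureType:
    """Hazard-trend trichotomy from the 95% CI of the Weibull shape.

    CI containing 1 (inclusive at either boundary) -> random failure;
    lower limit > 1 -> wear-out; upper limit < 1 -> early failure.
    """
    low, high = beta_ci
    if not (0 < low <= high):
        raise ValueError(f"invalid CI: {beta_ci}")
    if low > 1.0:
        return FailureType.WEAROUT
    if high < 1.0:
        return FailureType.EARLY
    return FailureType.RANDOM


def histogram(
    sample: OnsetSample, bin_width_days: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open bins [0, w), [w, 2w), ... covering the whole window.

    Returns (edges, counts); empty tail bins are retained so the axis always
    spans (0, window]; counts sum to n.
    """
    if bin_width_days <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(math.ceil(sample.window_days / bin_width_days))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_days
    counts = np.zeros(n_bins, dtype=int)
    idx = np.floor(np.asarray(sample.days) / bin_width_days).astype(int)
    idx = np.minimum(idx, n_bins - 1)  # day == last edge lands in final bin
    for i in idx:
        counts[i] += 1
    return edges, counts
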