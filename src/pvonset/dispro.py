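"""Reporting odds ratios, crude and adjusted.

A spontaneous reporting system has no exposure denominator, so signal
strength is expressed as a reporting odds ratio: the odds that a report of
the target event carries a given factor versus the odds among reports of
other events. The crude ROR comes from a 2x2 table,

    OR = (a * d) / (b * c),  CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)),

with the Haldane–Anscombe correction (add 0.5 to every cell) available when
a cell is zero. The adjusted ROR (aROR) is the exponentiated coefficient of
a multivariable logistic regression of case status (target event vs any
other event) on the covariate dummies, with Wald 95% intervals and p-values.

The logistic likelihood is maximized by Newton–Raphson (iteratively
reweighted least squares) via statsmodels; this module owns the design
coding, the convergence/separation policing, and the effect-table
construction on the odds-ratio scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import AgeCat, CohortRow, DoseCat, LithiumCat
from .errors import DesignMatrixError
from .jader import Sex

#: two-sided 95% normal critical value, fixed for bit-stable intervals
Z95 = 1.959964


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a = (factor, target event), b = (factor, other event),
    c = (no factor, target event), d = (no factor, other event)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")


@dataclass(frozen=True)
class EffectEstimate:
    label: str
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    defined: bool = True  # False when a zero cell made the OR undefined


@dataclass
class LogisticFit:
    params: np.ndarray  # intercept first, then dummies in coding order
    cov: np.ndarray  # inverse observed information at the optimum
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    column_names: list[str]
    n: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass(frozen=True)
class Coding:
    """Design-matrix bookkeeping: column names and human-readable labels
    ("level vs reference") for every non-intercept column."""

    column_names: tuple[str, ...]
    labels: tuple[str, ...]  # parallel to column_names[1:]


def crude_ror(t: TwoByTwo, correction: bool = True) -> EffectEstimate:
    """Crude reporting odds ratio from a 2x2 table with Wald CI.

    With a zero cell: if ``correction`` the Haldane–Anscombe 0.5 is added to
    every cell first; otherwise the estimate is flagged undefined (NaN
    fields) rather than raising.
    """
    cells = [float(t.a), float(t.b), float(t.c), float(t.d)]
    if 0 in cells:
        if not correction:
            return EffectEstimate(
                "exposure", math.nan, math.nan, math.nan, math.nan, defined=False
            )
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return EffectEstimate(
        "exposure",
        math.exp(log_or),
        math.exp(log_or - Z95 * se),
        math.exp(log_or + Z95 * se),
        p,
    )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns involved in a rank deficiency via QR pivoting."""
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return []
    # columns with (near-)zero diagonal in pivoted QR are the dependent ones
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    bad += [names[p] for p in piv[len(diag):]]
    return sorted(bad)


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    column_names: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS).

    Rank-deficient designs raise :class:`DesignMatrixError` naming the
    collinear columns. Separation or non-convergence yields a fit with
    ``converged=False`` and a warning — never silent estimates presented as
    converged.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and X must have the same number of rows")
    names = list(column_names) if column_names else [f"x{j}" for j in range(X.shape[1])]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise DesignMatrixError(
            f"design matrix is rank-deficient; collinear column(s): {bad}", bad
        )

    model = sm.Logit(y, X)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=0)
        except Exception as exc:  # singular Hessian under separation
            warnings.warn(f"logistic fit failed to converge: {exc}")
            res = model.fit(method="bfgs", maxiter=max_iter, disp=0)
            converged = False
        for w in caught:
            if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
                converged = False

    params = np.asarray(res.params, dtype=float)
    score = model.score(params)
    grad_norm = float(np.max(np.abs(score)))
    converged = converged and bool(res.mle_retvals.get("converged", True))
    if not converged:
        warnings.warn(
            "logistic regression did not converge (possible separation); "
            "estimates are unreliable"
        )
    hess = model.hessian(params)
    cov = np.linalg.inv(-hess)
    # symmetrize against round-off
    cov = (cov + cov.T) / 2.0
    return LogisticFit(
        params=params,
        cov=cov,
        loglik=float(res.llf),
        converged=converged,
        n_iter=int(res.mle_retvals.get("iterations", max_iter)),
        grad_norm=grad_norm,
        column_names=names,
        n=int(y.shape[0]),
    )


def effects_from_fit(fit: LogisticFit, coding: Coding) -> list[EffectEstimate]:
    """Exponentiate the non-intercept coefficients into aROR estimates."""
    se = fit.se()
    out = []
    for j, label in enumerate(coding.labels, start=1):
        b, s = fit.params[j], se[j]
        z = b / s if s > 0 else math.inf * np.sign(b)
        p = 2.0 * stats.norm.sf(abs(z))
        out.append(
            EffectEstimate(
                label,
                math.exp(b),
                math.exp(b - Z95 * s),
                math.exp(b + Z95 * s),
                float(p),
            )
        )
    return out


def dummy_code(
    rows: Sequence[CohortRow], sex_reference: Sex = Sex.MALE
) -> tuple[np.ndarray, np.ndarray, Coding]:
    """Treatment-coded design matrix in the documented fixed order.

    Columns: intercept, sex (non-reference level), age (4 dummies vs <=29),
    study-drug dose (medium, high vs low), polypharmacy, lithium (low, high
    vs none), fluvoxamine, antiepileptic, convulsive history — 1 + 13.
    ``y`` is 1 for seizure cases.
    """
    if sex_reference not in (Sex.MALE, Sex.FEMALE):
        raise ValueError("sex reference must be male or female")
    sex_level = Sex.FEMALE if sex_reference is Sex.MALE else Sex.MALE

    n = len(rows)
    X = np.zeros((n, 14))
    y = np.zeros(n)
    age_levels = [AgeCat.A30S, AgeCat.A40S, AgeCat.A50S, AgeCat.GE60]
    for i, r in enumerate(rows):
        y[i] = 1.0 if r.outcome_seizure else 0.0
        X[i, 0] = 1.0
        X[i, 1] = 1.0 if r.sex is sex_level else 0.0
        for k, lev in enumerate(age_levels):
            X[i, 2 + k] = 1.0 if r.age_cat is lev else 0.0
        X[i, 6] = 1.0 if r.cloz_dose_cat is DoseCat.MEDIUM else 0.0
        X[i, 7] = 1.0 if r.cloz_dose_cat is DoseCat.HIGH else 0.0
        X[i, 8] = 1.0 if r.polypharmacy else 0.0
        X[i, 9] = 1.0 if r.lithium_cat is LithiumCat.LOW else 0.0
        X[i, 10] = 1.0 if r.lithium_cat is LithiumCat.HIGH else 0.0
        X[i, 11] = 1.0 if r.fluvoxamine else 0.0
        X[i, 12] = 1.0 if r.antiepileptic else 0.0
        X[i, 13] = 1.0 if r.convulsive_history else 0.0

    coding = Coding(
        column_names=(
            "intercept",
            f"sex_{sex_level.value}",
            "age_30s",
            "age_40s",
            "age_50s",
            "age_ge60",
            "cloz_medium",
            "cloz_high",
            "polypharmacy",
            "lithium_low",
            "lithium_high",
            "fluvoxamine",
            "antiepileptic",
            "convulsive_history",
        ),
        labels=(
            f"sex: {sex_level.value} vs {sex_reference.value}",
            "age: 30-39 vs <=29",
            "age: 40-49 vs <=29",
            "age: 50-59 vs <=29",
            "age: >=60 vs <=29",
            "dose: medium vs low",
            "dose: high vs low",
            "polypharmacy: yes vs no",
            "lithium: low vs none",
            "lithium: high vs none",
            "fluvoxamine: yes vs no",
            "antiepileptic: yes vs no",
            "convulsive history: yes vs no",
        ),
    )
    return y, X, coding


def effects_to_frame(effects: Sequence[EffectEstimate], y: np.ndarray | None = None):
    """Effect table ready for writing (forest-plot order = coding order)."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "label": e.label,
                "aror": e.or_value,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p": e.p,
            }
            for e in effects
        ]
    )
    if y is not None:
        df["n_cases"] = int(np.sum(y))
        df["n_noncases"] = int(len(y) - np.sum(y))
    return df
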