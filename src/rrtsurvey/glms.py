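"""Visit-count and household-structure regressions.

Negative binomial (NB2, estimated dispersion) regression for visit
frequencies, reported as incidence rate ratios, and logistic regression for
household management / dependency outcomes, reported as odds ratios; both
with Wald 95% intervals.  Reference levels: urban, Carauari, single-sited,
wet season.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "DependencyMeasures",
    "GlmResult",
    "ConvergenceError",
    "SeparationError",
    "dependency_measures",
    "fit_negbin_visits",
    "fit_logistic_structure",
]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Fit failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace: object = None):
        super().__init__(message)
        self.trace = trace


class SeparationError(RuntimeError):
    """Complete separation in a logistic fit; names the covariate."""


@dataclass(frozen=True)
class DependencyMeasures:
    """Dependency of a household: minors per working adult, plus a flag for
    more minors than adults.  Both derive from the raw counts directly."""

    ratio: float | None
    exceeds_flag: int


def dependency_measures(
    n_minors: int, n_working_adults: int, n_adults_total: int
) -> DependencyMeasures:
    for name, v in (
        ("n_minors", n_minors),
        ("n_working_adults", n_working_adults),
        ("n_adults_total", n_adults_total),
    ):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if n_working_adults == 0:
        logger.warning("zero working adults: dependency ratio undefined, marked missing")
        ratio = None
    else:
        ratio = n_minors / n_working_adults
    return DependencyMeasures(ratio=ratio, exceeds_flag=int(n_minors > n_adults_total))


@dataclass(frozen=True)
class GlmResult:
    """One fitted model: per-term table plus dispersion (NB only)."""

    kind: str  # "negbin" or "logistic"
    terms: pd.DataFrame  # term, coef, se, effect, ci_low, ci_high
    dispersion: float | None
    n: int

    def format_effect(self, term: str) -> str:
        row = self.terms.set_index("term").loc[term]
        label = "IRR" if self.kind == "negbin" else "OR"
        return f"{label} {row['effect']:.2f}, 95% CI {row['ci_low']:.2f}–{row['ci_high']:.2f}"


def _check_design(X: pd.DataFrame) -> pd.DataFrame:
    X = X.astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def _term_table(params, bse, conf, names) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": names,
            "coef": np.asarray(params, dtype=float),
            "se": np.asarray(bse, dtype=float),
            "effect": np.exp(np.asarray(params, dtype=float)),
            "ci_low": np.exp(conf[:, 0]),
            "ci_high": np.exp(conf[:, 1]),
        }
    )


def fit_negbin_visits(counts: np.ndarray, X: pd.DataFrame) -> GlmResult:
    """NB2 maximum-likelihood regression of visit counts on the design.

    ``X`` must not contain an intercept column; one is added.  Coefficients
    are exponentiated to IRRs with Wald 95% intervals; the estimated NB2
    dispersion alpha is reported alongside.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(float)
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        counts = counts.astype(int)
    Xd = sm.add_constant(_check_design(X), prepend=True)
    model = sm.NegativeBinomial(counts, Xd, loglike_method="nb2")
    try:
        res = model.fit(disp=False, maxiter=200)
    except Exception as exc:  # statsmodels raises a mixed bag here
        raise ConvergenceError(f"negative binomial fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("negative binomial fit did not converge", trace=res.mle_retvals)
    if np.any(~np.isfinite(res.bse[:-1])):
        logger.warning("negbin fit: non-finite standard errors (separation-like degeneracy)")
    conf = np.asarray(res.conf_int())
    names = list(Xd.columns)
    # last parameter is the dispersion alpha, not a rate ratio
    table = _term_table(res.params[:-1], res.bse[:-1], conf[:-1], names)
    return GlmResult(
        kind="negbin",
        terms=table,
        dispersion=float(res.params[-1]),
        n=int(counts.size),
    )


def fit_logistic_structure(y: np.ndarray, X: pd.DataFrame) -> GlmResult:
    """Logistic maximum-likelihood regression of a binary outcome.

    Complete separation raises :class:`SeparationError` naming a suspect
    covariate (one whose coefficient diverged).
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    Xd = sm.add_constant(_check_design(X), prepend=True)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, Xd).fit(disp=False, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            f"complete separation in covariates {list(X.columns)}: {exc}"
        ) from exc
    big = np.abs(np.asarray(res.params)) > 15
    if big.any():
        suspects = [n for n, b in zip(Xd.columns, big) if b]
        raise SeparationError(f"complete separation suspected in covariates {suspects}")
    conf = np.asarray(res.conf_int())
    table = _term_table(res.params, res.bse, conf, list(Xd.columns))
    return GlmResult(kind="logistic", terms=table, dispersion=None, n=int(y.size))
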