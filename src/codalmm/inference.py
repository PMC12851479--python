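"""Coefficient tests, joint multivariate F/Wald tests, and likelihood-ratio
tests between nested covariance structures.

Denominator degrees of freedom follow the between-within ("inner-outer")
counting rule: in the stacked layout every fixed-effect term varies within
subjects (across the response index), so all terms share

    den_df = n_stacked_obs - n_subjects - p_fixed.

This is a counting approximation, not a Satterthwaite-style moment match;
it is not guaranteed to match any particular software row for row.  Joint
tests over a term's full response block are preferred to per-coordinate
t tests: the latter inflate the type-I error across the D-1 coordinates and
depend on the chosen basis, whereas the joint F over the complete block is
basis invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fit import FitResult

__all__ = ["TestResult", "coef_tests", "joint_test", "lrt"]


@dataclass(frozen=True)
class TestResult:
    term: str
    statistic: float
    num_df: int
    den_df: float          # may be inf (chi-square reference)
    p_value: float
    kind: str              # "F", "chi2", or "LR"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "kind": self.kind,
            "statistic": self.statistic,
            "num_df": self.num_df,
            "den_df": self.den_df,
            "p_value": self.p_value,
        }


def _require_converged(fit: FitResult) -> None:
    if not fit.converged:
        raise RuntimeError(
            "fit did not converge; diagnostics: "
            f"{fit.optimizer['attempts'][-1]}"
        )


def coef_tests(fit: FitResult) -> pd.DataFrame:
    """Per-coefficient Wald t tests (estimate, SE, t, df, p).

    Laid out one row per (response, term column); df from the between-within
    rule shared by all terms.
    """
    _require_converged(fit)
    out = fit.params.copy()
    out["t"] = out["estimate"] / out["se"]
    out["df"] = fit.den_df
    out["p"] = 2.0 * stats.t.sf(np.abs(out["t"]), fit.den_df)
    return out


def joint_test(
    fit: FitResult, term: str, use_chi2: bool = False
) -> TestResult:
    """Joint test of a term's coefficients across all D-1 responses.

    F = (L beta)' (L V L')^{-1} (L beta) / rank(L) with num_df = rank(L);
    for terms spanning the full response block the statistic is invariant to
    the olr basis.  ``use_chi2`` gives the asymptotic Wald chi-square form
    (statistic = num_df * F) instead.
    """
    _require_converged(fit)
    if term not in fit.design.term_slices:
        raise KeyError(
            f"unknown term {term!r}; available: {list(fit.design.term_slices)}"
        )
    cols = fit.term_block(term)
    b = fit.beta[cols]
    V = fit.vcov_beta[np.ix_(cols, cols)]
    q = np.linalg.matrix_rank(V)
    if q < len(cols):
        raise np.linalg.LinAlgError(f"contrast block for {term!r} is rank deficient")
    wald = float(b @ np.linalg.solve(V, b))
    if use_chi2:
        return TestResult(
            term=term, statistic=wald, num_df=q, den_df=np.inf,
            p_value=float(stats.chi2.sf(wald, q)), kind="chi2",
        )
    F = wald / q
    return TestResult(
        term=term, statistic=F, num_df=q, den_df=float(fit.den_df),
        p_value=float(stats.f.sf(F, q, fit.den_df)), kind="F",
    )


def joint_test_table(fit: FitResult, terms: list[str] | None = None) -> pd.DataFrame:
    """Joint F tests for every requested term (default: all terms)."""
    if terms is None:
        terms = list(fit.design.term_slices)
    return pd.DataFrame([joint_test(fit, t).as_dict() for t in terms])


def lrt(full: FitResult, reduced: FitResult) -> TestResult:
    """Likelihood-ratio test of nested covariance structures.

    Both fits must use the same criterion; under REML they must share
    identical fixed effects (the restricted likelihoods are otherwise not
    comparable).  Diagonal-vs-unstructured comparisons put correlations —
    interior points of their parameter space — to zero, so the chi-square
    reference applies without boundary corrections; variance components on
    the boundary would need a mixture reference instead.
    """
    if full.method != reduced.method:
        raise ValueError("cannot compare fits with different estimation methods")
    if full.n_params < reduced.n_params:
        raise ValueError("'full' has fewer parameters than 'reduced'")
    if full.method == "REML" and (
        full.n_fixed != reduced.n_fixed
        or list(full.params["label"]) != list(reduced.params["label"])
    ):
        raise ValueError("REML likelihoods require identical fixed effects")
    if full.n_obs != reduced.n_obs or full.n_subjects != reduced.n_subjects:
        raise ValueError("fits are not on the same data")
    df = full.n_params - reduced.n_params
    lr = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    return TestResult(
        term=f"{full.n_params} vs {reduced.n_params} params",
        statistic=lr, num_df=max(df, 1) if df else 1, den_df=np.inf,
        p_value=p if df > 0 else 1.0, kind="LR",
    )
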