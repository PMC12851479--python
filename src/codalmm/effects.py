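"""Back-transformation of fitted coordinates into the simplex.

A block of fixed effects for one term — its D-1 per-coordinate coefficients
— is itself a coordinate vector, so its inverse olr is a composition: for
the intercept block this is the baseline composition (closed to kappa, e.g.
min/day); for any other term it is a *perturbation vector* closed to 1,
read against the neutral element [1/D, ..., 1/D] — parts above 1/D receive
relatively more time under that condition, parts below 1/D less.
Predictions are inverse-olr of the linear predictor and therefore always
sum to kappa, unlike per-behaviour raw-minutes models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import OCCASION_COL
from .fit import FitResult
from .simplex import Composition, clr, olr_inv, perturb

__all__ = [
    "CompositionalCoefficient",
    "compositional_coefficients",
    "predict_composition",
    "logratio_difference",
    "perturbation_vs_neutral",
]


@dataclass(frozen=True)
class CompositionalCoefficient:
    term: str
    composition: Composition
    role: str  # "baseline" | "perturbation"

    def __post_init__(self) -> None:
        if self.role not in ("baseline", "perturbation"):
            raise ValueError(f"unknown role {self.role!r}")


def _require_olr_fit(fit: FitResult) -> None:
    if fit.response_kind != "olr" or fit.spec is None:
        raise ValueError("back-transformation requires a compositional (olr) fit")
    if len(fit.response_names) != fit.spec.basis.D - 1:
        raise ValueError(
            "fit does not carry the full coordinate vector; univariate "
            "comparator fits cannot be back-transformed term-wise"
        )


def compositional_coefficients(
    fit: FitResult, kappa: float | None = None
) -> list[CompositionalCoefficient]:
    """Inverse-olr of every term-column block of fixed effects.

    The intercept maps to the baseline composition on the kappa scale
    (reference occasion, covariates at zero/reference); every other design
    column maps to a perturbation vector closed to 1.
    """
    _require_olr_fit(fit)
    basis = fit.spec.basis
    if kappa is None:
        kappa = fit.kappa
    R = len(fit.response_names)
    out = []
    for pcol, colname in enumerate(fit.design.column_names):
        block = fit.beta[pcol * R: (pcol + 1) * R]
        if len(block) != R:  # pragma: no cover - structural guard
            raise ValueError(f"incomplete coefficient block for {colname!r}")
        if colname == "Intercept":
            out.append(
                CompositionalCoefficient(
                    term=colname,
                    composition=olr_inv(block, basis, kappa),
                    role="baseline",
                )
            )
        else:
            out.append(
                CompositionalCoefficient(
                    term=colname,
                    composition=olr_inv(block, basis, 1.0),
                    role="perturbation",
                )
            )
    return out


def coefficient_table(fit: FitResult, kappa: float | None = None) -> pd.DataFrame:
    """Compositional coefficients as a table, one row per design column.

    The ``closure`` column records the convention: the intercept row is on
    the kappa (e.g. min/day) scale, perturbation rows are closed to 1.
    """
    coefs = compositional_coefficients(fit, kappa)
    rows = []
    for c in coefs:
        row = {"term": c.term, "role": c.role, "closure": c.composition.kappa}
        row.update(dict(zip(c.composition.labels, c.composition.values)))
        rows.append(row)
    return pd.DataFrame(rows)


def predict_composition(
    fit: FitResult,
    newdata: dict | pd.DataFrame | None = None,
    include_blups: bool = False,
    subject: str | None = None,
    average_covariates: bool = True,
) -> Composition:
    """Model-based composition for a covariate setting, closed to kappa.

    Unspecified numeric covariates default to their sample mean and
    categorical ones to their reference level (the "average participant"
    convention); pass explicit values in ``newdata`` to override.  With
    ``include_blups`` the named subject's predicted random intercepts are
    added before back-transformation.
    """
    _require_olr_fit(fit)
    setting: dict = {}
    if average_covariates:
        setting.update(fit.design.numeric_means)
    setting.update(fit.design.categorical_references)
    if isinstance(newdata, pd.DataFrame):
        if len(newdata) != 1:
            raise ValueError("newdata must describe a single setting")
        setting.update(newdata.iloc[0].to_dict())
    elif newdata:
        setting.update(newdata)
    if fit.design.time_coding == "categorical" and OCCASION_COL not in setting:
        setting[OCCASION_COL] = fit.design.occasion_levels[0]
    frame = pd.DataFrame([setting])
    try:
        x0 = fit.design.build_rows(frame)[0]
    except Exception as exc:
        raise ValueError(f"cannot resolve covariate setting {setting}: {exc}") from exc
    R = len(fit.response_names)
    z = fit.beta.reshape(-1, R).T @ x0  # (R,) linear predictor per coordinate
    if include_blups:
        if subject is None:
            raise ValueError("include_blups requires a subject identifier")
        if subject not in fit.blups.index:
            raise KeyError(f"unknown subject {subject!r}")
        z = z + fit.blups.loc[subject].to_numpy()
    return olr_inv(z, fit.spec.basis, fit.kappa)


def predict_linear(fit: FitResult, long_rows: pd.DataFrame, include_blups: bool = False) -> np.ndarray:
    """Row-wise linear predictor (n, R) for observed data; used for fitted
    values of both compositional and raw-minutes fits."""
    X0 = fit.design.build_rows(long_rows)
    R = len(fit.response_names)
    Z = X0 @ fit.beta.reshape(-1, R)
    if include_blups:
        from .data import SUBJECT_COL
        b = fit.blups.reindex(long_rows[SUBJECT_COL].astype(str)).to_numpy()
        Z = Z + b
    return Z


def fitted_compositions(
    fit: FitResult, long_rows: pd.DataFrame, include_blups: bool = True
) -> pd.DataFrame:
    """Subject-level fitted compositions (n rows, D parts) on the kappa scale."""
    _require_olr_fit(fit)
    Z = predict_linear(fit, long_rows, include_blups=include_blups)
    W = np.exp(Z @ fit.spec.basis.contrast.T)
    vals = fit.kappa * W / W.sum(axis=1, keepdims=True)
    return pd.DataFrame(vals, columns=list(fit.spec.basis.part_labels),
                        index=long_rows.index)


def logratio_difference(a: Composition, b: Composition) -> np.ndarray:
    """clr(a) - clr(b): per-part log-ratio change between two compositions.

    Sums to zero; positive entries mark parts relatively higher in ``a``.
    Equals clr(a ⊖ b), so it is closure- and basis-free.
    """
    if a.labels != b.labels:
        raise ValueError("compositions have different parts")
    return clr(a) - clr(b)


def perturbation_vs_neutral(coef: CompositionalCoefficient) -> pd.DataFrame:
    """Signed deviation of a perturbation vector from the neutral 1/D.

    Positive deviations mean time is reallocated *toward* the part under
    that condition, negative *away* from it; deviations sum to zero.
    """
    if coef.role != "perturbation":
        raise ValueError(
            "only perturbation-role coefficients compare against the neutral "
            "element; the intercept is a baseline composition"
        )
    x = coef.composition
    dev = x.parts - 1.0 / x.D
    return pd.DataFrame(
        {
            "part": x.labels,
            "value": x.parts,
            "deviation": dev,
            "direction": ["toward" if d > 0 else ("away" if d < 0 else "none") for d in dev],
        }
    )
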