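"""Model specification and fixed-effect design construction.

In the stacked-response layout every fixed-effect term is interacted with
the response index: the model has no pooled intercept, but one intercept,
one set of time contrasts and one coefficient per covariate *per olr
coordinate*.  The per-record design matrix ``X0`` (built with patsy from the
long table) is therefore expanded so that column ``p`` of ``X0`` becomes
D-1 columns, one per response, ordered p-major::

    column index = p * R + r      (R = D-1 responses)

which keeps all responses of a term adjacent — convenient for joint tests
and for back-transformation of term blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import patsy

from .data import OCCASION_COL
from .simplex import OlrBasis

TIME_NUMERIC_COL = "_time"


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a compositional multivariate-response LMM.

    Parameters
    ----------
    basis
        Olr basis defining the D-1 response coordinates.
    time_coding
        ``"categorical"`` codes occasions as treatment contrasts against the
        first level; ``"continuous"`` uses a single linear slope per response.
    covariates
        Covariate column names; categorical columns are treatment-coded.
        Every covariate is automatically interacted with the response index.
    three_way_terms
        Covariates additionally interacted with the time term (hence, in the
        stacked model, covariate x time x response interactions).
    g_structure, e_structure
        ``"unstructured"`` (correlated responses) or ``"diagonal"``.
    method
        ``"REML"`` (default) or ``"ML"``.
    """

    basis: OlrBasis
    time_coding: Literal["categorical", "continuous"] = "categorical"
    covariates: tuple[str, ...] = ()
    three_way_terms: tuple[str, ...] = ()
    g_structure: Literal["unstructured", "diagonal"] = "unstructured"
    e_structure: Literal["unstructured", "diagonal"] = "unstructured"
    method: Literal["REML", "ML"] = "REML"
    occasion_levels: tuple[str, ...] | None = None
    categorical_levels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "three_way_terms", tuple(self.three_way_terms))
        if self.time_coding not in ("categorical", "continuous"):
            raise ValueError(f"unknown time_coding {self.time_coding!r}")
        for s in (self.g_structure, self.e_structure):
            if s not in ("unstructured", "diagonal"):
                raise ValueError(f"unknown covariance structure {s!r}")
        if self.method not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")
        unknown = set(self.three_way_terms) - set(self.covariates)
        if unknown:
            raise ValueError(f"three-way terms not among covariates: {sorted(unknown)}")

    def with_(self, **kw) -> "ModelSpec":
        return replace(self, **kw)

    @property
    def n_responses(self) -> int:
        return self.basis.D - 1


@dataclass
class Design:
    """Per-record design matrix and the bookkeeping to expand/predict."""

    X0: np.ndarray                      # (n_long, p0)
    design_info: patsy.DesignInfo
    term_slices: dict[str, slice]       # term name -> columns of X0
    column_names: list[str]             # p0 names
    response_names: list[str]
    numeric_means: dict[str, float]     # covariate means for default settings
    categorical_references: dict[str, str]  # covariate -> reference level
    occasion_levels: list[str] | None
    time_coding: str

    @property
    def p0(self) -> int:
        return self.X0.shape[1]

    @property
    def R(self) -> int:
        return len(self.response_names)

    @property
    def p(self) -> int:
        return self.p0 * self.R

    def stacked_column_labels(self) -> list[str]:
        return [
            f"{r}:{c}"
            for c in self.column_names
            for r in self.response_names
        ]

    def stacked_block(self, term: str) -> np.ndarray:
        """Column indices (in the stacked design) of a term across all responses."""
        sl = self.term_slices[term]
        cols = [p * self.R + r for p in range(sl.start, sl.stop) for r in range(self.R)]
        return np.asarray(cols, dtype=int)

    def build_rows(self, newdata: pd.DataFrame) -> np.ndarray:
        """Evaluate the per-record design on new data (prediction)."""
        (m,) = patsy.build_design_matrices([self.design_info], newdata)
        return np.asarray(m)


def _formula(spec: ModelSpec, data: pd.DataFrame) -> str:
    if spec.time_coding == "categorical":
        levels = list(spec.occasion_levels) if spec.occasion_levels else sorted(
            data[OCCASION_COL].astype(str).unique()
        )
        time_term = f"C({OCCASION_COL}, Treatment, levels={levels!r})"
    else:
        time_term = TIME_NUMERIC_COL
    terms = ["1", time_term]
    for cov in spec.covariates:
        if cov not in data.columns:
            raise ValueError(f"covariate {cov!r} not found in data")
        if pd.api.types.is_numeric_dtype(data[cov]):
            terms.append(cov)
        elif cov in spec.categorical_levels:
            lv = list(spec.categorical_levels[cov])
            terms.append(f"C({cov}, Treatment, levels={lv!r})")
        else:
            terms.append(f"C({cov})")
    for cov in spec.three_way_terms:
        base = cov if pd.api.types.is_numeric_dtype(data[cov]) else f"C({cov})"
        terms.append(f"{base}:{time_term}")
    return " + ".join(terms)


def build_design(long_table: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build the per-record fixed-effect design from the long table."""
    data = long_table.copy()
    if spec.time_coding == "continuous":
        data[TIME_NUMERIC_COL] = pd.to_numeric(data[OCCASION_COL])
    formula = _formula(spec, data)
    X0 = patsy.dmatrix(formula, data, return_type="dataframe")
    di = X0.design_info
    n_bad = len(data) - len(X0)
    if n_bad:
        raise ValueError(f"{n_bad} rows dropped by design construction (missing covariates?)")
    Xmat = np.asarray(X0, dtype=float)
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        raise ValueError(
            f"fixed-effect design is rank deficient (columns: {list(X0.columns)})"
        )
    # friendlier term names: strip the patsy Treatment boilerplate
    term_slices = {
        _short_term_name(t): sl for t, sl in di.term_name_slices.items()
    }
    col_names = [_short_col_name(c) for c in X0.columns]
    numeric_means = {
        c: float(data[c].mean())
        for c in (*spec.covariates, *((TIME_NUMERIC_COL,) if spec.time_coding == "continuous" else ()))
        if pd.api.types.is_numeric_dtype(data[c])
    }
    levels = None
    cat_refs: dict[str, str] = {}
    for fi in di.factor_infos.values():
        fname = fi.factor.name()
        if fi.type != "categorical":
            continue
        if OCCASION_COL in fname:
            if spec.time_coding == "categorical":
                levels = [str(c) for c in fi.categories]
            continue
        var = fname[2:-1].split(",")[0].strip() if fname.startswith("C(") else fname
        cat_refs[var] = fi.categories[0]
    return Design(
        X0=Xmat,
        design_info=di,
        term_slices=term_slices,
        column_names=col_names,
        response_names=list(spec.basis.coordinate_names),
        numeric_means=numeric_means,
        categorical_references=cat_refs,
        occasion_levels=levels,
        time_coding=spec.time_coding,
    )


def _short_term_name(term: str) -> str:
    if OCCASION_COL in term and term.startswith("C("):
        return "time" if ":" not in term else term  # plain time term
    if ":" in term and OCCASION_COL in term:
        left = term.split(":")[0]
        return f"{_short_term_name(left)}:time"
    if term.startswith("C(") and term.endswith(")"):
        return term[2:-1].split(",")[0]
    if term == TIME_NUMERIC_COL:
        return "time"
    return term

def _short_col_name(col: str) -> str:
    out = col
    if out.startswith("C(") and out.endswith("]"):
        # C(var, Treatment, levels=...)[T.lev] -> var[T.lev]
        var = out[2:].split(",")[0].split(")")[0].strip()
        out = ("time" if var == OCCASION_COL else var) + out[out.rindex("["):]
    out = out.replace(TIME_NUMERIC_COL, "time")
    return out


def expand_stacked(X0: np.ndarray, R: int) -> np.ndarray:
    """Expand an (n, p0) per-record design to the (n*R, p0*R) stacked design.

    Stacked rows are record-major (all R coordinates of a record adjacent);
    columns are p-major as documented in the module docstring.
    """
    n, p0 = X0.shape
    out = np.zeros((n, R, p0, R))
    # straightforward loop; R is a handful at most
    for r in range(R):
        out[:, r, :, r] = X0
    return out.reshape(n * R, p0 * R)
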