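"""Long-format ingestion, per-record olr computation, and response stacking.

The input is a long table: one row per subject x occasion carrying D
strictly positive behaviour-duration columns (summing to kappa per row) and
optional covariates.  ``compute_olr`` appends the D-1 olr coordinates,
``stack`` melts them into the stacked-response layout — one row per
(subject, occasion, coordinate) with one-hot response indicators — which is
what lets a univariate mixed-model engine express the multivariate model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simplex import OlrBasis, ZeroPartError, olr_matrix

logger = logging.getLogger(__name__)

SUBJECT_COL = "subject_id"
OCCASION_COL = "occasion"
RESPONSE_COL = "response"
OLR_VALUE_COL = "olr_value"


@dataclass
class ValidationReport:
    n_rows: int = 0
    n_reclosed: int = 0
    reclosed_rows: list = field(default_factory=list)
    messages: list = field(default_factory=list)


def validate_long(
    table: pd.DataFrame,
    labels: list[str],
    kappa: float,
    tolerance: float = 0.05,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Check and normalise a long table of compositions.

    Rows whose behaviour sum deviates from ``kappa`` by at most ``tolerance``
    (relative) are re-closed to ``kappa`` with a warning; larger deviations
    are rejected.  Zero or negative behaviour values are always rejected —
    zero replacement is a pre-processing concern, not performed here.
    """
    required = [SUBJECT_COL, OCCASION_COL, *labels]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    dup = table.duplicated([SUBJECT_COL, OCCASION_COL])
    if dup.any():
        pairs = table.loc[dup, [SUBJECT_COL, OCCASION_COL]].values.tolist()
        raise ValueError(f"duplicate (subject, occasion) pairs: {pairs[:5]}")

    out = table.copy()
    out[SUBJECT_COL] = out[SUBJECT_COL].astype(str)
    beh = out[labels].to_numpy(dtype=float)
    if not np.all(np.isfinite(beh)):
        bad = out.index[~np.isfinite(beh).all(axis=1)].tolist()
        raise ValueError(f"non-finite behaviour values in rows {bad[:5]}")
    nonpos = beh <= 0
    if nonpos.any():
        i, j = np.argwhere(nonpos)[0]
        raise ZeroPartError(
            f"behaviour {labels[j]!r} is <= 0 for subject "
            f"{out.iloc[i][SUBJECT_COL]!r} occasion {out.iloc[i][OCCASION_COL]!r}; "
            "zero replacement must be handled before modelling"
        )

    sums = beh.sum(axis=1)
    rel = np.abs(sums - kappa) / kappa
    too_far = rel > tolerance
    if too_far.any():
        rows = out.loc[too_far, [SUBJECT_COL, OCCASION_COL]].values.tolist()
        raise ValueError(
            f"behaviour sums deviate from kappa={kappa} by more than "
            f"{tolerance:.0%} in rows {rows[:5]}"
        )
    report = ValidationReport(n_rows=len(out))
    off = (rel > 1e-9) & ~too_far
    if off.any():
        beh = beh * (kappa / sums[:, None])
        out[labels] = beh
        report.n_reclosed = int(off.sum())
        report.reclosed_rows = out.loc[off, [SUBJECT_COL, OCCASION_COL]].values.tolist()
        msg = f"re-closed {report.n_reclosed} row(s) to kappa={kappa}"
        report.messages.append(msg)
        logger.warning(msg)
    return out, report


def compute_olr(table: pd.DataFrame, basis: OlrBasis) -> pd.DataFrame:
    """Append olr coordinate columns z1..z_{D-1} computed under ``basis``.

    Behaviour columns are kept so that round trips back to compositions can
    be checked downstream.
    """
    labels = list(basis.part_labels)
    missing = [c for c in labels if c not in table.columns]
    if missing:
        raise ValueError(f"basis parts not found in table: {missing}")
    out = table.copy()
    Z = olr_matrix(out[labels].to_numpy(dtype=float), basis)
    for j, name in enumerate(basis.coordinate_names):
        out[name] = Z[:, j]
    return out


def stack(olr_table: pd.DataFrame, coordinate_names: list[str] | None = None) -> pd.DataFrame:
    """Melt the D-1 olr columns into the stacked-response layout.

    Each source row yields D-1 stacked rows with identical predictors, a
    ``response`` label, one-hot indicator columns ``delta_1..delta_{D-1}``
    and the coordinate value in ``olr_value``.
    """
    if coordinate_names is None:
        coordinate_names = [c for c in olr_table.columns if _is_coord(c, olr_table)]
    missing = [c for c in coordinate_names if c not in olr_table.columns]
    if missing:
        raise ValueError(f"olr columns not found: {missing}")
    carried = [c for c in olr_table.columns if c not in coordinate_names]
    long = olr_table.melt(
        id_vars=carried,
        value_vars=coordinate_names,
        var_name=RESPONSE_COL,
        value_name=OLR_VALUE_COL,
    )
    # preserve source-row-major order: all coordinates of a record adjacent
    long["_src"] = np.tile(np.arange(len(olr_table)), len(coordinate_names))
    long[RESPONSE_COL] = pd.Categorical(long[RESPONSE_COL], categories=coordinate_names)
    long = long.sort_values(["_src", RESPONSE_COL], kind="stable").drop(columns="_src")
    long = long.reset_index(drop=True)
    for r, name in enumerate(coordinate_names):
        long[f"delta_{r + 1}"] = (long[RESPONSE_COL] == name).astype(int)
    return long


def unstack(stacked: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`stack`: one row per subject x occasion, one column
    per coordinate."""
    coordinate_names = list(stacked[RESPONSE_COL].cat.categories)
    carried = [
        c
        for c in stacked.columns
        if c not in (RESPONSE_COL, OLR_VALUE_COL) and not c.startswith("delta_")
    ]
    wide = stacked.pivot_table(
        index=carried, columns=RESPONSE_COL, values=OLR_VALUE_COL,
        observed=True, sort=False,
    ).reset_index()
    wide.columns.name = None
    return wide[carried + coordinate_names]


def _is_coord(c: str, table: pd.DataFrame) -> bool:
    return (
        c.startswith("z")
        and c[1:].isdigit()
        and pd.api.types.is_numeric_dtype(table[c])
    )


def read_long_csv(path, labels: list[str]) -> pd.DataFrame:
    """Read a long-format CSV: identifiers as strings, durations as floats."""
    df = pd.read_csv(path, dtype={SUBJECT_COL: str, OCCASION_COL: str})
    for c in labels:
        if c in df.columns:
            df[c] = df[c].astype(float)
    return df
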